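"""Dense textbook Kalman filter, used only as an independent test oracle.

Covariances are propagated in full (Joseph-form update); no square-root
machinery is shared with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def kf_predict(x, P, F, Q):
    return F @ x, F @ P @ F.T + Q


def kf_update(x, P, y, H, R):
    S = H @ P @ H.T + R
    K = P @ H.T @ np.linalg.inv(S)
    x_new = x + K @ (y - H @ x)
    I_KH = np.eye(P.shape[0]) - K @ H
    P_new = I_KH @ P @ I_KH.T + K @ R @ K.T  # Joseph form
    return x_new, P_new


def kf_run(data, F, Q, H, R, x0, P0):
    """Filter a (m, N) observation matrix observing rows H @ x; returns the
    (m, N) state trajectory and the final covariance."""
    m, n = data.shape[0], data.shape[1]
    states = np.empty((m, n))
    x, P = x0.copy(), P0.copy()
    obs = H @ data
    for t in range(n):
        if t > 0:
            x, P = kf_predict(x, P, F, Q)
        x, P = kf_update(x, P, obs[:, t], H, R)
        states[:, t] = x
    return states, P


def random_system(rng, m, p):
    """A random well-posed linear-Gaussian system of state dim m, obs dim p."""
    F = rng.standard_normal((m, m)) * 0.5 / np.sqrt(m)
    F += np.eye(m) * 0.3
    A = rng.standard_normal((m, m))
    Q = A @ A.T / m * 0.1
    H = rng.standard_normal((p, m))
    Bm = rng.standard_normal((p, p))
    R = Bm @ Bm.T / p * 0.5 + 0.1 * np.eye(p)
    C = rng.standard_normal((m, m))
    P0 = C @ C.T / m + 0.5 * np.eye(m)
    x0 = rng.standard_normal(m)
    return F, Q, H, R, x0, P0
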
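"""Square-root Kalman filtering for EEG data assimilation.

The data-assimilation engine propagates the filter covariance in factored
form P = S S^T throughout:

* the initial factor comes from an LDL^T decomposition (S = L D^{1/2},
  avoiding square roots on the diagonal pivots);
* the time update triangularizes the stacked 2m x m matrix
  [S^T F^T ; Q^{T/2}] with Givens plane rotations built arithmetically as
  c = a/r, s = -b/r, r = sqrt(a^2 + b^2) — no trigonometric calls — so that
  S_pred S_pred^T = F P F^T + Q without ever forming P;
* the measurement update is Potter's square-root algorithm, processed as
  sequential scalar updates (the measurement-noise covariance is
  diagonalized first when correlated), which keeps the updated covariance
  positive semidefinite by construction.

The state vector holds one amplitude per EEG channel; the transition matrix
F is a truncated Taylor expansion of the matrix exponential of a
continuous-time drift estimated by least squares from one-step differences,
and the observation matrix H is a row selection of channels.  Three sensor
scenarios are supported: ``all`` channels observed, ``wc`` (winner channels,
the coherence-selected relevant sensors) and ``nwc`` (their complement).

The model/results split follows the statsmodels convention: build a
:class:`SqrtKalmanFilter` from a recording, call :meth:`~SqrtKalmanFilter.fit`,
and read the filtered trajectory, innovations and diagnostics off the
returned :class:`FilterRun`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import factorial
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy import linalg, signal

from .coherence import ChannelSelection
from .io_formats import EEGRecording

__all__ = [
    "StateSpaceModel", "SqrtState", "FilterRun", "SqrtKalmanFilter",
    "estimate_transition", "ldlt_sqrt", "givens_rotation",
    "givens_time_update", "potter_update", "run_filter",
]

SCENARIOS = ("all", "wc", "nwc")


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class StateSpaceModel:
    """Linear-Gaussian state-space model (F, H, Q, R)."""

    F: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    taylor_order: int = 2

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        m = self.F.shape[0]
        p = self.H.shape[0]
        if self.F.shape != (m, m) or self.H.shape != (p, m):
            raise ValueError("inconsistent F/H dimensions")
        for name, mat, dim in (("Q", self.Q, m), ("R", self.R, p)):
            if mat.shape != (dim, dim):
                raise ValueError(f"{name} must be {dim}x{dim}, got {mat.shape}")
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(mat).min() < -1e-10:
                raise ValueError(f"{name} must be positive semidefinite")


@dataclass
class SqrtState:
    """Filter state: mean x and covariance square root S (P = S S^T)."""

    x: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        m = self.x.size
        if self.S.shape != (m, m):
            raise ValueError(f"S must be {m}x{m}, got {self.S.shape}")

    @property
    def P(self) -> np.ndarray:
        return self.S @ self.S.T


# --------------------------------------------------------------------------
# Core operations
# --------------------------------------------------------------------------

def ldlt_sqrt(P: np.ndarray) -> np.ndarray:
    """Covariance square root S = L D^{1/2} from the LDL^T factorization.

    Tiny negative pivots (round-off on a PSD matrix) are clamped to zero;
    genuinely indefinite or asymmetric input is rejected.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if P.shape[0] != P.shape[1] or not np.allclose(P, P.T, atol=1e-8):
        raise ValueError("P must be symmetric")
    if np.linalg.eigvalsh(P).min() < -1e-10 * max(1.0, np.abs(P).max()):
        raise ValueError("P is indefinite beyond tolerance")
    lu, d, perm = linalg.ldl(P, lower=True)
    diag = np.diag(d).copy()
    if not np.allclose(d, np.diag(diag), atol=1e-10):
        # 2x2 pivot blocks only arise for indefinite input
        raise ValueError("P is indefinite (non-diagonal D in LDL^T)")
    diag[diag < 0] = 0.0
    return lu @ np.diag(np.sqrt(diag))


def givens_rotation(a: float, b: float) -> tuple[float, float, float]:
    """Plane-rotation parameters (c, s, r) annihilating b against a.

    r = sqrt(a^2 + b^2), c = a/r, s = -b/r; the rotation [[c, -s], [s, c]]
    maps (a, b) to (r, 0).  For a = b = 0 the identity (c=1, s=0, r=0) is
    returned and the caller skips the rotation.
    """
    r = float(np.hypot(a, b))
    if r == 0.0:
        return 1.0, 0.0, 0.0
    return a / r, -b / r, r


@njit(cache=False)
def _triangularize(M: np.ndarray, B: np.ndarray) -> None:
    """In-place Givens QR of the (rows x m) stack M; accumulates B <- G B.

    Column-major elimination, zeroing each column from the bottom row
    upward against the diagonal pivot.  Rotations use c = a/r, s = -b/r
    with r = sqrt(a^2 + b^2); zero eliminands are skipped.
    """
    rows, m = M.shape
    acc = B.shape[0] == rows
    for j in range(m):
        for i in range(rows - 1, j, -1):
            b = M[i, j]
            if b == 0.0:
                continue
            a = M[j, j]
            r = np.sqrt(a * a + b * b)
            c = a / r
            s = -b / r
            for k in range(m):
                t1 = M[j, k]
                t2 = M[i, k]
                M[j, k] = c * t1 - s * t2
                M[i, k] = s * t1 + c * t2
            if acc:
                for k in range(rows):
                    t1 = B[j, k]
                    t2 = B[i, k]
                    B[j, k] = c * t1 - s * t2
                    B[i, k] = s * t1 + c * t2


@njit(cache=False)
def _potter_scalar(x: np.ndarray, S: np.ndarray, h_idx: int, r: float,
                   y: float) -> float:
    """One scalar Potter update for a unit-basis observation row e_{h_idx}.

    Returns the innovation.  S and x are updated in place:
    phi = S^T h, sigma = phi^T phi + r, K = S phi / sigma,
    S <- S (I - beta phi phi^T) with beta = 1 / (sigma + sqrt(r sigma)).
    """
    m = x.size
    phi = S[h_idx, :].copy()  # S^T e_i
    sigma = r
    for k in range(m):
        sigma += phi[k] * phi[k]
    innov = y - x[h_idx]
    if sigma <= 0.0:
        return np.nan
    beta = 1.0 / (sigma + np.sqrt(r * sigma))
    Sphi = S @ phi
    for k in range(m):
        x[k] += Sphi[k] * innov / sigma
    for k in range(m):
        for l in range(m):
            S[k, l] -= beta * Sphi[k] * phi[l]
    return innov


@njit(cache=False)
def _potter_general(x: np.ndarray, S: np.ndarray, h: np.ndarray,
                    r: float, y: float) -> float:
    """Scalar Potter update for an arbitrary observation row h."""
    m = x.size
    phi = S.T @ h
    sigma = r
    for k in range(m):
        sigma += phi[k] * phi[k]
    innov = y - h @ x
    if sigma <= 0.0:
        return np.nan
    beta = 1.0 / (sigma + np.sqrt(r * sigma))
    Sphi = S @ phi
    for k in range(m):
        x[k] += Sphi[k] * innov / sigma
    for k in range(m):
        for l in range(m):
            S[k, l] -= beta * Sphi[k] * phi[l]
    return innov


@njit(cache=False)
def _filter_sweep(data: np.ndarray, F: np.ndarray, SqT: np.ndarray,
                  obs_idx: np.ndarray, r_diag: np.ndarray,
                  x0: np.ndarray, S0: np.ndarray):
    """Full filter pass over a recording: Givens time update + Potter
    measurement update at every sample.  Returns (states, innovations)."""
    m, n = data.shape[0], data.shape[1]
    p = obs_idx.size
    states = np.empty((m, n))
    innovations = np.empty((p, n))
    x = x0.copy()
    S = S0.copy()
    M = np.empty((2 * m, m))
    B_dummy = np.empty((1, 1))
    for t in range(n):
        if t > 0:
            x = F @ x
            M[:m, :] = (F @ S).T
            M[m:, :] = SqT
            _triangularize(M, B_dummy)
            S = M[:m, :].T.copy()
        for i in range(p):
            innovations[i, t] = _potter_scalar(
                x, S, obs_idx[i], r_diag[i], data[obs_idx[i], t]
            )
        states[:, t] = x
    return states, innovations


def givens_time_update(
    S_prev: np.ndarray, F: np.ndarray, Q: np.ndarray,
    return_B: bool = False,
):
    """Predicted covariance square root via Givens triangularization.

    Stacks [S_prev^T F^T ; Q^{T/2}] and reduces it to upper-triangular form
    with plane rotations, so S_pred S_pred^T = F P_prev F^T + Q.  With
    ``return_B=True`` the accumulated orthogonal rotation product is also
    returned (B @ stack recovers the triangularized stack).
    """
    S_prev = np.atleast_2d(np.asarray(S_prev, dtype=float))
    F = np.atleast_2d(np.asarray(F, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    m = S_prev.shape[0]
    if F.shape != (m, m) or Q.shape != (m, m):
        raise ValueError("dimension mismatch between S_prev, F and Q")
    Sq = ldlt_sqrt(Q)
    M = np.vstack([(F @ S_prev).T, Sq.T])
    B = np.eye(2 * m) if return_B else np.empty((1, 1))
    _triangularize(M, B)
    S_pred = M[:m].T.copy()
    if return_B:
        return S_pred, B
    return S_pred


def potter_update(state: SqrtState, y: np.ndarray, H: np.ndarray,
                  R: np.ndarray) -> SqrtState:
    """Vector measurement update via sequential scalar Potter steps.

    A correlated R is diagonalized first (R = V Lambda V^T, with the
    observation rotated accordingly); each scalar component is then
    assimilated in turn.  The result matches the textbook Kalman update in
    both mean and covariance while keeping P = S S^T positive semidefinite.
    """
    y = np.asarray(y, dtype=float).ravel()
    H = np.atleast_2d(np.asarray(H, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    p = H.shape[0]
    if y.size != p:
        raise ValueError(f"observation length {y.size} != {p} rows of H")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    evals = np.linalg.eigvalsh(R)
    if evals.min() < -1e-10 * max(1.0, np.abs(R).max()):
        raise ValueError("R must be positive semidefinite")

    if np.allclose(R, np.diag(np.diag(R)), atol=1e-12):
        r_diag, Ht, yt = np.diag(R).copy(), H, y
    else:
        lam, V = np.linalg.eigh(R)
        r_diag, Ht, yt = np.clip(lam, 0.0, None), V.T @ H, V.T @ y

    x = state.x.copy()
    S = state.S.copy()
    for i in range(p):
        innov = _potter_general(x, S, np.ascontiguousarray(Ht[i]),
                                float(r_diag[i]), float(yt[i]))
        if np.isnan(innov):
            resid = yt[i] - Ht[i] @ state.x
            if abs(resid) > 1e-12:
                raise ValueError(
                    "zero predicted innovation variance with nonzero residual"
                )
    return SqrtState(x, S)


def estimate_transition(rec: EEGRecording, taylor_order: int = 2,
                        stability_tol: float = 1e-6) -> np.ndarray:
    """State-transition matrix from a Taylor expansion of exp(A dt).

    The continuous-time drift A is estimated by least squares from one-step
    channel differences, dx/dt ~= A x, and F is the Taylor series of
    exp(A dt) truncated at ``taylor_order`` (order 0 gives the identity).
    Estimates whose spectral radius exceeds 1 are shrunk toward the identity
    with a warning; a rank-deficient regression falls back to F = I.
    """
    m, n = rec.data.shape
    if n < 10 * m:
        raise ValueError(f"need at least 10*m = {10 * m} samples, got {n}")
    if taylor_order < 0:
        raise ValueError("taylor_order must be >= 0")
    dt = 1.0 / rec.fs
    if taylor_order == 0:
        return np.eye(m)

    X0 = rec.data[:, :-1]
    dX = np.diff(rec.data, axis=1) / dt
    sol, _, rank, _ = np.linalg.lstsq(X0.T, dX.T, rcond=None)
    if rank < m:
        warnings.warn("rank-deficient transition regression; using F = I")
        return np.eye(m)
    A = sol.T

    Adt = A * dt
    F = np.eye(m)
    term = np.eye(m)
    for k in range(1, taylor_order + 1):
        term = term @ Adt
        F = F + term / factorial(k)

    rho = np.abs(np.linalg.eigvals(F)).max()
    if rho > 1.0 + stability_tol:
        warnings.warn(
            f"unstable transition estimate (spectral radius {rho:.3f}); "
            "shrinking toward identity"
        )
        for _ in range(60):
            F = np.eye(m) + 0.5 * (F - np.eye(m))
            if np.abs(np.linalg.eigvals(F)).max() <= 1.0 + stability_tol:
                break
    return F


# --------------------------------------------------------------------------
# Model / Results
# --------------------------------------------------------------------------

def _default_noise(data: np.ndarray, fs: float) -> tuple[float, np.ndarray]:
    """(q, r per channel): process noise from one-step increments,
    measurement noise from the high-frequency (> 45 Hz) residual."""
    q = float(np.mean(np.var(np.diff(data, axis=1), axis=1)))
    cutoff = min(45.0, 0.8 * fs / 2)
    sos = signal.butter(4, cutoff, btype="highpass", fs=fs, output="sos")
    resid = signal.sosfiltfilt(sos, data, axis=1)
    r = np.var(resid, axis=1)
    floor = 1e-8 * max(float(np.var(data)), 1.0)
    return max(q, floor), np.maximum(r, floor)


class SqrtKalmanFilter:
    """Square-root Kalman filter model over one EEG recording.

    Parameters
    ----------
    rec : EEGRecording
        The (preprocessed) recording; states are its channels.
    selection : ChannelSelection, optional
        Winner channels from the coherence stage; required for the ``wc``
        and ``nwc`` scenarios.
    scenario : {"all", "wc", "nwc"}
        Which channels the filter observes.
    taylor_order : int
        Truncation order of the Taylor expansion behind F.
    Q, R : ndarray, optional
        Process/measurement noise covariance overrides; estimated from the
        data when omitted.
    ensemble_size : int, optional
        If set, run a Monte-Carlo ensemble variant instead of the exact
        square-root recursion (default off).
    """

    def __init__(self, rec: EEGRecording, selection: ChannelSelection | None = None,
                 scenario: str = "all", taylor_order: int = 2,
                 F: np.ndarray | None = None,
                 Q: np.ndarray | None = None, R: np.ndarray | None = None,
                 ensemble_size: int | None = None, seed: int = 0):
        if scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
        self.rec = rec
        self.selection = selection
        self.scenario = scenario
        self.taylor_order = taylor_order
        self._F = F
        self._Q = Q
        self._R = R
        self.ensemble_size = ensemble_size
        self.seed = seed
        self.observed_idx = self._resolve_channels()

    def _resolve_channels(self) -> np.ndarray:
        m = self.rec.n_channels
        if self.scenario == "all":
            idx = np.arange(m)
        else:
            if self.selection is None or not self.selection.winners:
                raise ValueError(
                    f"scenario {self.scenario!r} requires a non-empty channel selection"
                )
            winners = sorted(self.rec.channel_index(l) for l in self.selection.winners)
            if self.scenario == "wc":
                idx = np.asarray(winners, dtype=np.int64)
            else:
                idx = np.asarray([i for i in range(m) if i not in set(winners)],
                                 dtype=np.int64)
        if idx.size == 0:
            raise ValueError(f"scenario {self.scenario!r} observes no channels")
        return idx

    def build_model(self) -> StateSpaceModel:
        """Assemble (F, H, Q, R) from the recording and scenario."""
        m = self.rec.n_channels
        F = (estimate_transition(self.rec, self.taylor_order)
             if self._F is None else np.atleast_2d(self._F))
        H = np.zeros((self.observed_idx.size, m))
        H[np.arange(self.observed_idx.size), self.observed_idx] = 1.0
        q, r_chan = _default_noise(self.rec.data, self.rec.fs)
        Q = np.eye(m) * q if self._Q is None else np.atleast_2d(self._Q)
        R = (np.diag(r_chan[self.observed_idx]) if self._R is None
             else np.atleast_2d(self._R))
        return StateSpaceModel(F, H, Q, R, self.taylor_order)

    def initial_state(self) -> SqrtState:
        """x0 = first sample; P0 = sample covariance of the first second."""
        first = self.rec.data[:, : int(round(self.rec.fs))]
        P0 = np.cov(first) + 1e-9 * np.eye(self.rec.n_channels)
        return SqrtState(self.rec.data[:, 0].copy(), ldlt_sqrt(P0))

    def fit(self) -> "FilterRun":
        model = self.build_model()
        init = self.initial_state()
        r_diag = np.ascontiguousarray(np.diag(model.R))
        SqT = np.ascontiguousarray(ldlt_sqrt(model.Q).T)
        if self.ensemble_size:
            states, innov = self._run_ensemble(model, init, r_diag)
        else:
            states, innov = _filter_sweep(
                np.ascontiguousarray(self.rec.data),
                np.ascontiguousarray(model.F), SqT,
                np.ascontiguousarray(self.observed_idx, dtype=np.int64),
                r_diag,
                np.ascontiguousarray(init.x), np.ascontiguousarray(init.S),
            )
        return FilterRun(
            scenario=self.scenario,
            filtered=states,
            innovations=innov,
            observed_idx=self.observed_idx,
            labels=list(self.rec.labels),
            fs=self.rec.fs,
            model=model,
            config={
                "scenario": self.scenario,
                "taylor_order": self.taylor_order,
                "ensemble_size": self.ensemble_size,
                "seed": self.seed,
                "observed": [self.rec.labels[i] for i in self.observed_idx],
            },
        )

    def _run_ensemble(self, model: StateSpaceModel, init: SqrtState,
                      r_diag: np.ndarray):
        """Stochastic (perturbed-observation) ensemble variant."""
        rng = np.random.default_rng(self.seed)
        m, n = self.rec.data.shape
        n_ens = int(self.ensemble_size)
        Sq = ldlt_sqrt(model.Q)
        ens = init.x[:, None] + init.S @ rng.standard_normal((m, n_ens))
        states = np.empty((m, n))
        p = self.observed_idx.size
        innov = np.empty((p, n))
        for t in range(n):
            if t > 0:
                ens = model.F @ ens + Sq @ rng.standard_normal((m, n_ens))
            xm = ens.mean(axis=1, keepdims=True)
            Pe = (ens - xm) @ (ens - xm).T / max(n_ens - 1, 1)
            y = self.rec.data[self.observed_idx, t]
            Hp = Pe[self.observed_idx][:, self.observed_idx]
            K = Pe[:, self.observed_idx] @ np.linalg.inv(Hp + np.diag(r_diag))
            perturbed = y[:, None] + np.sqrt(r_diag)[:, None] * rng.standard_normal((p, n_ens))
            ens = ens + K @ (perturbed - ens[self.observed_idx])
            innov[:, t] = y - xm[self.observed_idx, 0]
            states[:, t] = ens.mean(axis=1)
        return states, innov


@dataclass
class FilterRun:
    """Results of one filter pass (statsmodels-style results object)."""

    scenario: str
    filtered: np.ndarray  # (m, N) state trajectory
    innovations: np.ndarray  # (p, N)
    observed_idx: np.ndarray
    labels: list[str]
    fs: float
    model: StateSpaceModel
    config: dict = field(default_factory=dict)

    @property
    def observed_labels(self) -> list[str]:
        return [self.labels[i] for i in self.observed_idx]

    def tracking_correlation(self, data: np.ndarray) -> np.ndarray:
        """Per-observed-channel correlation between input and filtered state."""
        out = np.empty(self.observed_idx.size)
        for k, i in enumerate(self.observed_idx):
            out[k] = np.corrcoef(data[i], self.filtered[i])[0, 1]
        return out

    def summary(self) -> str:
        lines = [
            "Square-root Kalman filter run",
            "=" * 34,
            f"scenario:          {self.scenario}",
            f"states (channels): {len(self.labels)}",
            f"observed channels: {', '.join(self.observed_labels)}",
            f"samples:           {self.filtered.shape[1]} @ {self.fs:g} Hz",
            f"taylor order:      {self.model.taylor_order}",
            f"innovation rms:    {np.sqrt(np.mean(self.innovations ** 2)):.4g}",
        ]
        return "\n".join(lines)

    def save(self, stem) -> tuple[Path, Path]:
        """Persist as CSV (time x states) + JSON metadata sidecar."""
        stem = Path(stem)
        csv_path = stem.with_suffix(".csv")
        pd.DataFrame(self.filtered.T, columns=self.labels).to_csv(csv_path,
                                                                  index=False)
        meta_path = stem.with_suffix(".json")
        meta_path.write_text(json.dumps({
            **self.config, "fs": self.fs, "labels": self.labels,
            "observed_idx": self.observed_idx.tolist(),
        }, indent=2))
        return csv_path, meta_path


def run_filter(rec: EEGRecording, selection: ChannelSelection | None,
               scenario: str, **params) -> FilterRun:
    """Functional entry point: build the model and fit in one call."""
    return SqrtKalmanFilter(rec, selection, scenario, **params).fit()
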
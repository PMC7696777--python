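"""Band-pass filtering and ICA-based artifact suppression.

Two dataset presets are built in, matching the two headset families the
pipeline targets: ``LGR`` (14 ch @ 128 Hz, Butterworth order 4, 1-63 Hz)
and ``DM`` (9 ch @ 256 Hz, order 5, 1-100 Hz).  Filtering is zero-phase
(forward-backward) so that phase relationships feeding the coherence
analysis are not distorted.

The ICA step decomposes the recording with FastICA and zeroes components
whose excess kurtosis or back-projected energy is an outlier among the
components (z-score above a threshold, with a minimum absolute excess-
kurtosis floor so that clean recordings with tightly clustered statistics
are left untouched).  It never changes the channel count, length, rate or
labels, and on non-convergence it passes the data through unchanged with a
warning in the report rather than silently altering anything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .io_formats import EEGRecording

__all__ = ["FilterSpec", "bandpass", "remove_artifacts_ica", "FILTER_PRESETS"]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification."""

    order: int
    low: float
    high: float
    kind: str = "butterworth_bandpass"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")
        if not 0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high, got ({self.low}, {self.high})")
        if self.kind != "butterworth_bandpass":
            raise ValueError(f"unsupported filter kind {self.kind!r}")

    def validate_for(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"high cutoff {self.high} Hz must be below the Nyquist "
                f"frequency {fs / 2} Hz"
            )


FILTER_PRESETS = {
    "LGR": FilterSpec(order=4, low=1.0, high=63.0),
    "DM": FilterSpec(order=5, low=1.0, high=100.0),
}


def bandpass(rec: EEGRecording, spec: FilterSpec) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied per channel."""
    spec.validate_for(rec.fs)
    sos = signal.butter(spec.order, (spec.low, spec.high), btype="bandpass",
                        fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=filtered,
                         bandpass=f"butter{spec.order} [{spec.low},{spec.high}] Hz")


def _robust_z(v: np.ndarray) -> np.ndarray:
    """Median/MAD z-scores; unlike the plain z-score these are not bounded
    by (n-1)/sqrt(n) and so remain usable for small montages."""
    med = np.median(v)
    mad = np.median(np.abs(v - med)) * 1.4826
    if mad == 0:
        sd = v.std()
        return np.zeros_like(v) if sd == 0 else (v - med) / sd
    return (v - med) / mad


def remove_artifacts_ica(
    rec: EEGRecording,
    rejection: dict | None = None,
    seed: int = 0,
    min_kurtosis: float = 2.0,
    energy_ratio: float = 5.0,
) -> tuple[EEGRecording, dict]:
    """Decompose with FastICA and zero artifact-like components.

    A component is rejected when the robust (median/MAD) z-score of its
    excess kurtosis across components exceeds ``rejection['kurtosis_z']``
    and the kurtosis itself is at least ``min_kurtosis``, or when the robust
    z-score of its back-projected energy exceeds ``rejection['var_z']`` and
    the energy is at least ``energy_ratio`` times the median component
    energy.  The absolute floors keep clean recordings, whose component
    statistics cluster tightly, from being clipped on scale-free scores.

    Largely Gaussian input makes the un-mixing weakly identifiable, so
    FastICA is restarted on a fixed schedule of loosening tolerances; if no
    restart converges the data pass through unchanged with a warning.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    thr = {"kurtosis_z": 3.0, "var_z": 3.0, **(rejection or {})}
    m, n = rec.data.shape
    if m < 3:
        raise ValueError(f"ICA needs at least 3 channels, got {m}")
    if n < 10 * m:
        raise ValueError(f"ICA needs at least 10*m = {10 * m} samples, got {n}")

    mean = rec.data.mean(axis=1, keepdims=True)
    centered = (rec.data - mean).T  # (N, m)
    ica = sources = None
    for attempt, tol in enumerate((1e-3, 1e-2, 5e-2)):
        candidate = FastICA(n_components=m, random_state=int(seed) + attempt,
                            whiten="unit-variance", max_iter=1000, tol=tol)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            fitted = candidate.fit_transform(centered)
            if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
                ica, sources = candidate, fitted
                break
    if ica is None:
        warnings.warn("FastICA did not converge; passing data through unchanged")
        return rec.copy_with(), {
            "converged": False, "rejected": [], "kurtosis": [], "energy": [],
            "thresholds": thr, "seed": int(seed),
        }

    kurt = stats.kurtosis(sources, axis=0, fisher=True)
    # Back-projected energy: variance each component contributes to the sensors.
    mixing = ica.mixing_  # (m channels, m components)
    energy = sources.var(axis=0) * (mixing ** 2).sum(axis=0)

    kz, ez = _robust_z(kurt), _robust_z(energy)
    rejected = np.where(
        ((kz > thr["kurtosis_z"]) & (kurt >= min_kurtosis))
        | ((ez > thr["var_z"]) & (energy >= energy_ratio * np.median(energy)))
    )[0]

    kept = sources.copy()
    kept[:, rejected] = 0.0
    cleaned = (kept @ mixing.T).T + mean

    report = {
        "converged": True,
        "rejected": [int(i) for i in rejected],
        "kurtosis": kurt.tolist(),
        "kurtosis_z": kz.tolist(),
        "energy": energy.tolist(),
        "energy_z": ez.tolist(),
        "thresholds": thr,
        "seed": int(seed),
    }
    return rec.copy_with(data=cleaned, ica_rejected=report["rejected"]), report
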
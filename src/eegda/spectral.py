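"""Welch power spectra of filter outputs and scenario comparisons.

The PSD grid defaults to 1 Hz resolution (Hann window, 1-s segments, 50 %
overlap) so that downstream band statistics can work bin by bin.  A filter
run is summarized by the mean PSD over the channels its scenario observes,
giving one curve per case (original, all, wc, nwc) for comparison plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_formats import EEGRecording
from .srkf import FilterRun

__all__ = ["PSDResult", "psd_welch", "scenario_psd", "four_curve_set",
           "central_tendency_report", "plot_psd_curves"]


@dataclass
class PSDResult:
    """One-sided Welch PSD, per channel (2-D) or aggregated (1-D)."""

    freqs: np.ndarray
    psd: np.ndarray
    scenario: str = ""
    epoch: int | None = None

    def band_mean(self, band: tuple[float, float]) -> float:
        """Mean PSD over the in-band bins (aggregated across channels)."""
        mask = (self.freqs >= band[0]) & (self.freqs <= band[1])
        if not mask.any():
            raise ValueError(f"band {band} outside the frequency grid")
        return float(np.mean(self.psd[..., mask]))

    def to_frame(self) -> pd.DataFrame:
        psd = np.atleast_2d(self.psd)
        frames = [pd.DataFrame({"freq": self.freqs, "psd": row,
                                "channel": i, "scenario": self.scenario})
                  for i, row in enumerate(psd)]
        return pd.concat(frames, ignore_index=True)


def psd_welch(series, fs: float, nperseg: int | None = None,
              overlap: float = 0.5, window: str = "hann",
              scenario: str = "") -> PSDResult:
    """One-sided Welch PSD at df = fs / nperseg (default 1 Hz)."""
    series = np.asarray(series, dtype=float)
    nperseg = int(round(fs)) if nperseg is None else int(nperseg)
    if series.shape[-1] < 2 * nperseg:
        raise ValueError(
            f"series too short for 2 Welch segments: {series.shape[-1]} < "
            f"2*{nperseg}"
        )
    freqs, pxx = sps.welch(series, fs=fs, window=window, nperseg=nperseg,
                           noverlap=int(round(nperseg * overlap)))
    return PSDResult(freqs, pxx, scenario=scenario)


def scenario_psd(run: FilterRun, fs: float | None = None,
                 nperseg: int | None = None) -> PSDResult:
    """Scenario-aggregate PSD: mean over the scenario's observed channels."""
    fs = run.fs if fs is None else fs
    res = psd_welch(run.filtered[run.observed_idx], fs, nperseg=nperseg,
                    scenario=run.scenario)
    return PSDResult(res.freqs, res.psd.mean(axis=0), scenario=run.scenario)


def four_curve_set(original: EEGRecording, runs: list[FilterRun],
                   nperseg: int | None = None) -> list[PSDResult]:
    """The comparison set: original signal plus one curve per filter run."""
    orig = psd_welch(original.data, original.fs, nperseg=nperseg,
                     scenario="original")
    curves = [PSDResult(orig.freqs, orig.psd.mean(axis=0), scenario="original")]
    curves += [scenario_psd(run, nperseg=nperseg) for run in runs]
    return curves


def central_tendency_report(runs: list[FilterRun],
                            iqr_fraction: float = 0.1) -> pd.DataFrame:
    """Mean vs median of filtered amplitudes, per scenario.

    Because the scenarios filter different channel counts, a mean/median
    mismatch would signal outlier-induced bias; rows where
    |mean - median| > iqr_fraction * IQR are flagged.
    """
    if not runs:
        raise ValueError("need at least one filter run")
    rows = []
    for run in runs:
        vals = run.filtered[run.observed_idx].ravel()
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        mean = float(vals.mean())
        iqr = q3 - q1
        rows.append({
            "scenario": run.scenario,
            "n_channels": int(run.observed_idx.size),
            "mean": mean,
            "median": float(med),
            "iqr": float(iqr),
            "biased": bool(abs(mean - med) > iqr_fraction * iqr),
        })
    return pd.DataFrame(rows)


def plot_psd_curves(curves: list[PSDResult], ax=None, band=None):
    """Plot the scenario comparison curves; returns the axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for c in curves:
        ax.plot(c.freqs, np.atleast_2d(c.psd).mean(axis=0), label=c.scenario)
    if band is not None:
        ax.axvspan(band[0], band[1], alpha=0.15, color="grey")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("PSD (uV$^2$/Hz)")
    ax.set_yscale("log")
    ax.legend()
    return ax
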
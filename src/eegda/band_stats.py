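"""Band-power change detection with per-bin Wilcoxon signed-rank tests.

A session is compared between two conditions (pre vs post) by epoching each
recording, computing one Welch PSD per epoch on the relevant channels, and
running a paired Wilcoxon signed-rank test per 1-Hz frequency bin inside
the target band.  PSD values are far from normal, hence the nonparametric
paired test.  A band is declared *relevant* (changed) when a strict
majority of its bins is significant at the chosen level — the band-majority
rule.  No multiple-testing correction is applied across bins by default; a
Benjamini-Hochberg option is available.

Pairing unit: epoch index (pre epoch i is paired with post epoch i).  The
exact null distribution is used for n <= 25 pairs, the normal approximation
with continuity correction above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .io_formats import EEGRecording
from .spectral import PSDResult, psd_welch

__all__ = ["BandTestResult", "SessionMap", "epoch_psds",
           "wilcoxon_band_test", "build_session_map"]

_ALTERNATIVES = {"increase": "greater", "decrease": "less",
                 "two-sided": "two-sided"}


@dataclass
class BandTestResult:
    """Per-bin p-values and the majority-rule band decision."""

    band: tuple[float, float]
    bin_pvalues: dict  # frequency (Hz) -> p-value
    alternative: str
    n_pairs: int
    relevant: bool
    alpha: float = 0.05

    @property
    def n_significant(self) -> int:
        return sum(p < self.alpha for p in self.bin_pvalues.values())

    def to_dict(self) -> dict:
        return {
            "band": list(self.band),
            "bin_pvalues": {f"{f:g}": p for f, p in self.bin_pvalues.items()},
            "alternative": self.alternative,
            "n_pairs": self.n_pairs,
            "relevant": self.relevant,
            "alpha": self.alpha,
        }


@dataclass
class SessionMap:
    """Grid of (user, session) -> bands flagged relevant."""

    grid: dict = field(default_factory=dict)  # (user, session) -> set of bands

    def add(self, user, session, band_name: str) -> None:
        self.grid.setdefault((user, session), set()).add(band_name)

    def flagged(self, user, session) -> set:
        return self.grid.get((user, session), set())

    def to_dict(self) -> dict:
        return {f"{u}|{s}": sorted(bands) for (u, s), bands in
                sorted(self.grid.items(), key=lambda kv: str(kv[0]))}

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    def plot(self, ax=None, markers=None):
        """Dot-grid plot: users on x, sessions on y, one marker per band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        markers = markers or {}
        bands = sorted({b for v in self.grid.values() for b in v})
        default_markers = ["o", "s", "^", "D", "v"]
        for i, b in enumerate(bands):
            markers.setdefault(b, default_markers[i % len(default_markers)])
        users = sorted({u for u, _ in self.grid}, key=str)
        for b in bands:
            xs, ys = [], []
            for (u, s), flagged in self.grid.items():
                if b in flagged:
                    xs.append(users.index(u))
                    ys.append(s)
            ax.scatter(xs, ys, marker=markers[b], label=b)
        ax.set_xticks(range(len(users)), [str(u) for u in users])
        ax.set_xlabel("user")
        ax.set_ylabel("session")
        if bands:
            ax.legend()
        return ax


def epoch_psds(rec: EEGRecording, channels, epoch_s: float = 4.0,
               nperseg: int | None = None) -> list[PSDResult]:
    """Non-overlapping epochs, one channel-averaged Welch PSD per epoch.

    ``channels`` may be labels or indices; the PSD of each epoch is averaged
    across those channels, yielding the paired samples for the band test.
    """
    idx = [rec.channel_index(c) if isinstance(c, str) else int(c)
           for c in channels]
    if not idx:
        raise ValueError("need at least one channel")
    epoch_len = int(round(epoch_s * rec.fs))
    if epoch_len > rec.n_samples:
        raise ValueError(
            f"epoch of {epoch_s} s exceeds the {rec.duration:g} s recording"
        )
    n_epochs = rec.n_samples // epoch_len
    if n_epochs < 2:
        raise ValueError(f"need at least 2 epochs, got {n_epochs}")
    out = []
    for e in range(n_epochs):
        seg = rec.data[idx, e * epoch_len:(e + 1) * epoch_len]
        res = psd_welch(seg, rec.fs, nperseg=nperseg)
        out.append(PSDResult(res.freqs, np.atleast_2d(res.psd).mean(axis=0),
                             epoch=e))
    return out


def wilcoxon_band_test(
    pre: list[PSDResult], post: list[PSDResult],
    band: tuple[float, float], alternative: str = "increase",
    alpha: float = 0.05, fdr: bool = False,
) -> BandTestResult:
    """Paired Wilcoxon signed-rank test per in-band 1-Hz bin.

    ``alternative="increase"`` tests for higher post power, ``"decrease"``
    for lower, ``"two-sided"`` for any change.  The band is *relevant* when
    a strict majority of its bins has p < alpha (exactly half is not a
    majority).  With ``fdr=True`` the bin p-values are Benjamini-Hochberg
    adjusted before the majority count.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(
            f"alternative must be one of {sorted(_ALTERNATIVES)}, got {alternative!r}"
        )
    if len(pre) != len(post):
        raise ValueError(f"unpaired epochs: {len(pre)} pre vs {len(post)} post")
    n = len(pre)
    if n < 5:
        raise ValueError(f"need at least 5 epoch pairs, got {n}")
    freqs = pre[0].freqs
    for r in list(pre) + list(post):
        if not np.array_equal(r.freqs, freqs):
            raise ValueError("epoch PSDs are not on a common frequency grid")
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} contains no bins of the PSD grid")

    pre_mat = np.stack([r.psd for r in pre])  # (n, F)
    post_mat = np.stack([r.psd for r in post])
    pvals = {}
    for fi in np.where(mask)[0]:
        d = post_mat[:, fi] - pre_mat[:, fi]
        if np.all(d == 0):
            pvals[float(freqs[fi])] = 1.0
            continue
        has_ties = (np.any(d == 0)
                    or np.unique(np.abs(d[d != 0])).size < np.count_nonzero(d))
        method = "exact" if (n <= 25 and not has_ties) else "approx"
        res = stats.wilcoxon(post_mat[:, fi], pre_mat[:, fi],
                             alternative=_ALTERNATIVES[alternative],
                             method=method, correction=(method == "approx"),
                             zero_method="wilcox")
        pvals[float(freqs[fi])] = float(res.pvalue)

    test_p = np.array(list(pvals.values()))
    if fdr:
        test_p = stats.false_discovery_control(test_p, method="bh")
    n_sig = int(np.sum(test_p < alpha))
    relevant = n_sig > len(test_p) / 2  # strict majority
    return BandTestResult(tuple(band), pvals, alternative, n, relevant, alpha)


def build_session_map(results: dict) -> SessionMap:
    """Collect per-(user, session, band) test results into a dot-grid map.

    ``results`` maps ``(user, session, band_name)`` to a
    :class:`BandTestResult`; only relevant results produce a dot.
    """
    smap = SessionMap()
    for (user, session, band_name), res in results.items():
        if res.relevant:
            smap.add(user, session, band_name)
    return smap
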
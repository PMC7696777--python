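"""Coherence-driven selection of task-relevant EEG channels.

The selection procedure works on magnitude-squared coherence

    gamma2_jk(f) = |P_jk(f)|^2 / (P_j(f) P_k(f)),

where P_jk is the Welch cross-spectral density of channels j and k and P_j,
P_k their auto-spectral densities.  Significance of a coherence value is
judged against a surrogate-data null: pairs of phase-randomized surrogates
(same amplitude spectrum as the originals, independent random phases, hence
uncoupled by construction) are generated, their coherence computed, and the
threshold set at a percentile (default 95) of the pooled surrogate coherence
distribution.

All C(m, 3) channel triplets are then scored: a triplet is *significant* in
a recording when all three of its pairwise coherences exceed the threshold
at every frequency bin inside the target band.  Triplets are counted across
recordings, and the winner set is the union of all triplets achieving the
maximum count (ties yield more than three winner channels).

The public estimators :func:`welch_asd`, :func:`welch_csd` and
:func:`coherence` delegate to :mod:`scipy.signal`; the batch evaluation of
all pairs and surrogates uses a segmented-FFT engine (same Hann window,
constant detrend and 50% overlap) that is unit-tested to agree with
``scipy.signal.coherence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import signal as sps

from .io_formats import EEGRecording

__all__ = [
    "SpectrumEstimate", "CoherenceSpectrum", "TripletEvaluation",
    "ChannelSelection", "SelectionParams", "welch_asd", "welch_csd",
    "coherence", "surrogate_threshold", "enumerate_triplets",
    "evaluate_triplet", "select_relevant_sensors",
]


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class SpectrumEstimate:
    """A Welch auto- or cross-spectral density estimate."""

    freqs: np.ndarray
    values: np.ndarray  # nonnegative real (ASD) or complex (CSD)
    df: float
    n_segments: int
    kind: str  # "asd" | "csd"


@dataclass
class CoherenceSpectrum:
    """Magnitude-squared coherence of one channel pair, with its threshold."""

    pair: tuple[int, int]
    freqs: np.ndarray
    gamma2: np.ndarray
    threshold: float | np.ndarray | None = None

    def exceeds(self) -> np.ndarray:
        if self.threshold is None:
            raise ValueError("no surrogate threshold attached")
        return self.gamma2 > self.threshold


@dataclass
class TripletEvaluation:
    """Significance of one channel triplet, per recording and overall."""

    triplet: tuple[int, int, int]
    significant: bool
    per_recording: dict = field(default_factory=dict)


@dataclass
class ChannelSelection:
    """Winner channels plus per-triplet repetition counts across recordings."""

    winners: tuple[str, ...]
    counts: dict  # triplet (label tuple) -> repetitions
    tied: list  # triplets (label tuples) sharing the maximum count
    empty: bool = False
    band: tuple[float, float] | None = None
    n_recordings: int = 0

    def to_dict(self) -> dict:
        return {
            "winners": list(self.winners),
            "counts": {"|".join(k): v for k, v in self.counts.items()},
            "tied": [list(t) for t in self.tied],
            "empty": self.empty,
            "band": list(self.band) if self.band else None,
            "n_recordings": self.n_recordings,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelSelection":
        return cls(
            winners=tuple(d["winners"]),
            counts={tuple(k.split("|")): v for k, v in d["counts"].items()},
            tied=[tuple(t) for t in d["tied"]],
            empty=d.get("empty", False),
            band=tuple(d["band"]) if d.get("band") else None,
            n_recordings=d.get("n_recordings", 0),
        )


@dataclass(frozen=True)
class SelectionParams:
    """Tunables of the surrogate-thresholded selection."""

    nperseg: int | None = None  # default fs -> 1 Hz resolution
    overlap: float = 0.5
    n_surrogates: int = 100
    percentile: float = 95.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surrogates < 20:
            raise ValueError(
                f"need at least 20 surrogates, got {self.n_surrogates}"
            )
        if not 0 < self.percentile < 100:
            raise ValueError(f"percentile must be in (0, 100), got {self.percentile}")


# --------------------------------------------------------------------------
# Welch estimators (scipy-backed)
# --------------------------------------------------------------------------

def _noverlap(nperseg: int, overlap: float) -> int:
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    return int(round(nperseg * overlap))


def _count_segments(n: int, nperseg: int, overlap: float) -> int:
    nov = _noverlap(nperseg, overlap)
    return (n - nov) // (nperseg - nov)


def welch_asd(x, fs: float, nperseg: int, overlap: float = 0.5) -> SpectrumEstimate:
    """One-sided Welch auto-spectral density (Hann window)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2 * nperseg:
        raise ValueError(
            f"need at least 2 segments: {x.shape[-1]} samples < 2*{nperseg}"
        )
    freqs, pxx = sps.welch(x, fs=fs, nperseg=nperseg,
                           noverlap=_noverlap(nperseg, overlap))
    return SpectrumEstimate(freqs, pxx, fs / nperseg,
                            _count_segments(x.shape[-1], nperseg, overlap), "asd")


def welch_csd(x, y, fs: float, nperseg: int, overlap: float = 0.5) -> SpectrumEstimate:
    """One-sided Welch cross-spectral density of two equally long series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[-1] != y.shape[-1]:
        raise ValueError(f"length mismatch: {x.shape[-1]} vs {y.shape[-1]}")
    if x.shape[-1] < 2 * nperseg:
        raise ValueError(
            f"need at least 2 segments: {x.shape[-1]} samples < 2*{nperseg}"
        )
    freqs, pxy = sps.csd(x, y, fs=fs, nperseg=nperseg,
                         noverlap=_noverlap(nperseg, overlap))
    return SpectrumEstimate(freqs, pxy, fs / nperseg,
                            _count_segments(x.shape[-1], nperseg, overlap), "csd")


def coherence(x, y, fs: float, nperseg: int, overlap: float = 0.5,
              pair: tuple[int, int] = (0, 1)) -> CoherenceSpectrum:
    """Magnitude-squared coherence of two series, clipped to [0, 1].

    At least two Welch segments are required: with a single segment the
    estimator is identically 1 regardless of the data (the averaged cross
    spectrum factorizes), which would make every pair look perfectly coupled.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[-1] != y.shape[-1]:
        raise ValueError(f"length mismatch: {x.shape[-1]} vs {y.shape[-1]}")
    n_seg = _count_segments(x.shape[-1], nperseg, overlap)
    if n_seg < 2:
        raise ValueError(
            f"coherence needs >= 2 Welch segments (got {n_seg}); a single "
            "segment yields gamma2 = 1 identically and carries no information"
        )
    freqs, g2 = sps.coherence(x, y, fs=fs, nperseg=nperseg,
                              noverlap=_noverlap(nperseg, overlap))
    return CoherenceSpectrum(pair, freqs, np.clip(g2, 0.0, 1.0))


# --------------------------------------------------------------------------
# Segmented-FFT engine for batch pair/surrogate evaluation
# --------------------------------------------------------------------------

def _segment_ffts(x: np.ndarray, nperseg: int, overlap: float) -> np.ndarray:
    """Hann-windowed, constant-detrended segment FFTs.

    ``x`` has shape (..., N); the result has shape (..., n_seg, nperseg//2+1)
    and matches the segments scipy's Welch machinery averages (scaling
    factors cancel in coherence and are therefore omitted).
    """
    step = nperseg - _noverlap(nperseg, overlap)
    segs = np.lib.stride_tricks.sliding_window_view(x, nperseg, axis=-1)[..., ::step, :]
    segs = segs - segs.mean(axis=-1, keepdims=True)
    win = sps.get_window("hann", nperseg)
    return np.fft.rfft(segs * win, axis=-1)


def _gamma2_from_ffts(z: np.ndarray) -> np.ndarray:
    """All-pairs coherence from per-channel segment FFTs.

    ``z`` has shape (..., m, n_seg, n_freq); returns (..., m, m, n_freq).
    The segment average is evaluated as a batched matmul per frequency.
    """
    zf = np.moveaxis(z, -1, -3)  # (..., F, m, T)
    csd = zf @ np.conj(np.swapaxes(zf, -1, -2))  # (..., F, m, m)
    asd = np.real(np.einsum("...jj->...j", csd))  # (..., F, m)
    denom = asd[..., :, None] * asd[..., None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        g2 = np.abs(csd) ** 2 / denom
    return np.moveaxis(np.clip(np.nan_to_num(g2), 0.0, 1.0), -3, -1)


def _phase_randomize(x: np.ndarray, n_surrogates: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized surrogates of each channel, shape (S, m, N).

    Amplitude spectra are preserved exactly; phases (except DC and Nyquist)
    are i.i.d. uniform, independently per channel and surrogate, so any two
    surrogate channels are uncoupled by construction.
    """
    x = np.atleast_2d(x)
    m, n = x.shape
    spec = np.fft.rfft(x, axis=-1)
    amp = np.abs(spec)
    nf = amp.shape[-1]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_surrogates, m, nf))
    phases[..., 0] = 0.0
    if n % 2 == 0:
        phases[..., -1] = 0.0
    surr = np.fft.irfft(amp * np.exp(1j * phases), n=n, axis=-1)
    return surr


def _pooled_bins(freqs: np.ndarray, fs: float) -> np.ndarray:
    """Mask of bins entering the pooled null (DC and Nyquist excluded)."""
    return (freqs > 0) & (freqs < fs / 2)


def surrogate_threshold(
    x, y, fs: float, nperseg: int,
    n_surrogates: int = 100, percentile: float = 95.0,
    seed: int = 0, overlap: float = 0.5, per_frequency: bool = False,
):
    """Significance threshold for the coherence of a channel pair.

    Surrogate pairs (phase-randomized, hence uncoupled) are generated from
    the two series; the threshold is the given percentile of the pooled
    surrogate-coherence sampling distribution (pooled across surrogates and
    frequency bins; ``per_frequency=True`` instead takes the percentile bin
    by bin).
    """
    if n_surrogates < 20:
        raise ValueError(f"need at least 20 surrogates, got {n_surrogates}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input series has no spectral content")
    rng = np.random.default_rng(seed)
    surr = _phase_randomize(np.stack([x, y]), n_surrogates, rng)  # (S, 2, N)
    z = _segment_ffts(surr, nperseg, overlap)  # (S, 2, T, F)
    g2 = _gamma2_from_ffts(z)[:, 0, 1, :]  # (S, F)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    keep = _pooled_bins(freqs, fs)
    if per_frequency:
        thr = np.percentile(g2, percentile, axis=0)
        thr[~keep] = 1.0  # DC/Nyquist never significant
        return thr
    return float(np.percentile(g2[:, keep], percentile))


# --------------------------------------------------------------------------
# Triplet enumeration and evaluation
# --------------------------------------------------------------------------

def enumerate_triplets(m: int) -> list[tuple[int, int, int]]:
    """All C(m, 3) unordered channel triplets, in lexicographic order."""
    if m < 3:
        raise ValueError(f"need at least 3 channels to form triplets, got {m}")
    return list(combinations(range(m), 3))


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    low, high = band
    return (freqs >= low) & (freqs <= high)


def _pair_pass_matrix(data: np.ndarray, fs: float, band: tuple[float, float],
                      params: SelectionParams, rng: np.random.Generator):
    """For one recording: which channel pairs exceed their surrogate
    threshold at *every* in-band frequency bin.

    Returns (pass_jk boolean (m, m), gamma2 (m, m, F), thresholds (m, m)).
    """
    m, n = data.shape
    nperseg = params.nperseg or int(round(fs))
    if _count_segments(n, nperseg, params.overlap) < 2:
        raise ValueError("recording too short for a 2-segment Welch estimate")
    flat = np.ptp(data, axis=1) == 0
    if flat.any():
        raise ValueError(
            f"channel(s) {np.where(flat)[0].tolist()} carry no power"
        )
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    in_band = _band_mask(freqs, band)
    if not in_band.any():
        raise ValueError(f"band {band} contains no frequency bins at "
                         f"df = {fs / nperseg} Hz")

    z = _segment_ffts(data, nperseg, params.overlap)  # (m, T, F)
    g2 = _gamma2_from_ffts(z)  # (m, m, F)

    # Pooled per-pair null distribution across surrogates x in-range bins,
    # built in chunks to bound the segment-FFT working set.
    keep = _pooled_bins(freqs, fs)
    n_keep = int(keep.sum())
    pooled = np.empty((params.n_surrogates, m, m, n_keep))
    chunk = 16
    for start in range(0, params.n_surrogates, chunk):
        stop = min(start + chunk, params.n_surrogates)
        surr = _phase_randomize(data, stop - start, rng)  # (c, m, N)
        zs = _segment_ffts(surr, nperseg, params.overlap)  # (c, m, T, F)
        pooled[start:stop] = _gamma2_from_ffts(zs)[..., keep]
    thresholds = np.percentile(pooled, params.percentile, axis=(0, 3))
    passes = (g2[:, :, in_band] > thresholds[:, :, None]).all(axis=-1)
    return passes, g2, thresholds, freqs


def evaluate_triplet(
    rec: EEGRecording,
    triplet: tuple[int, int, int],
    band: tuple[float, float],
    params: SelectionParams | None = None,
) -> TripletEvaluation:
    """Score one triplet in one recording.

    The triplet is significant iff each of its three pairwise coherences
    exceeds the pair's surrogate threshold at every frequency bin inside
    ``band`` (the 100 %-appearance rule).
    """
    params = params or SelectionParams()
    trip = tuple(sorted(triplet))
    if len(set(trip)) != 3 or trip[-1] >= rec.n_channels or trip[0] < 0:
        raise ValueError(f"invalid triplet {triplet} for {rec.n_channels} channels")
    if band[1] > rec.fs / 2:
        raise ValueError(f"band {band} exceeds the Nyquist frequency {rec.fs / 2}")
    rng = np.random.default_rng(params.seed)
    passes, _, _, _ = _pair_pass_matrix(rec.data[list(trip)], rec.fs, band,
                                        params, rng)
    sig = bool(passes[0, 1] and passes[0, 2] and passes[1, 2])
    rec_id = rec.meta.get("session", rec.meta.get("id", 0))
    return TripletEvaluation(trip, sig, {rec_id: sig})


def select_relevant_sensors(
    recs: list[EEGRecording],
    band: tuple[float, float],
    params: SelectionParams | None = None,
) -> ChannelSelection:
    """Winner-channel selection across a set of recordings.

    For each recording, every triplet passing the 100 %-appearance rule is
    stored; repetition counts are accumulated across recordings, and the
    winner set is the union of all triplets achieving the maximum count
    (a tie therefore yields more than three winner channels).  If no triplet
    passes in any recording the result is flagged empty rather than raising.
    """
    params = params or SelectionParams()
    if not recs:
        raise ValueError("need at least one recording")
    labels = recs[0].labels
    for r in recs[1:]:
        if r.labels != labels:
            raise ValueError("recordings do not share a montage")
    m = len(labels)
    triplets = enumerate_triplets(m)
    counts = {t: 0 for t in triplets}
    rng = np.random.default_rng(params.seed)
    for rec in recs:
        passes, _, _, _ = _pair_pass_matrix(rec.data, rec.fs, band, params, rng)
        for t in triplets:
            i, j, k = t
            if passes[i, j] and passes[i, k] and passes[j, k]:
                counts[t] += 1

    max_count = max(counts.values())
    label_counts = {tuple(labels[i] for i in t): c
                    for t, c in counts.items() if c > 0}
    if max_count == 0:
        return ChannelSelection(winners=(), counts=label_counts, tied=[],
                                empty=True, band=tuple(band),
                                n_recordings=len(recs))
    best = [t for t, c in counts.items() if c == max_count]
    winner_idx = sorted({i for t in best for i in t})
    tied = ([tuple(labels[i] for i in t) for t in best] if len(best) > 1 else [])
    return ChannelSelection(
        winners=tuple(labels[i] for i in winner_idx),
        counts=label_counts,
        tied=tied,
        empty=False,
        band=tuple(band),
        n_recordings=len(recs),
    )
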
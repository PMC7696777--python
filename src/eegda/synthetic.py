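"""Synthetic multichannel EEG with planted coherence structure.

The generator emulates the structure of task EEG used throughout the
pipeline: every channel carries a stationary AR(2) background with a
1/f-like spectrum, and a designated *coherent triplet* of channels shares a
common band-limited oscillatory component (band-pass-filtered white noise,
so coherence is broadband within the target rhythm rather than a line
spectrum).  A session is a (pre, post) pair of recordings; the "post"
condition multiplies the triplet's in-band power by a controllable factor,
giving downstream band-power statistics a known ground truth.

Mixing convention for a triplet channel::

    x = coupling * common + sqrt(1 - coupling**2) * background

with both parts scaled to unit variance, so ``coupling`` in [0, 1] moves the
channel continuously from independent background to a copy of the shared
rhythm and the channel variance stays at 1 before the microvolt scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io_formats import EEGRecording

__all__ = ["SynthSpec", "generate_recording", "generate_session_set",
           "EMOTIV_LABELS", "BALERT_LABELS"]

# Montages of the two headset families the generator emulates.
EMOTIV_LABELS = ["AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
                 "O2", "P8", "T8", "FC6", "F4", "F8", "AF4"]
BALERT_LABELS = ["F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "POz", "P4"]

_SCALE_UV = 10.0  # unit-variance signals rendered at ~10 uV RMS


@dataclass
class SynthSpec:
    """Parameters of a synthetic EEG session.

    Defaults mirror a 14-channel 128 Hz consumer-headset recording with an
    alpha-band (8-12 Hz) coherent triplet.
    """

    n_channels: int = 14
    fs: float = 128.0
    duration: float = 60.0
    coherent_triplet: tuple[int, int, int] = (11, 12, 13)
    band: tuple[float, float] = (8.0, 12.0)
    coupling: float = 0.8
    background_model: tuple[float, ...] = (1.3, -0.4)
    band_power_shift: float = 1.0
    seed: int = 0
    labels: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_channels < 3:
            raise ValueError(f"n_channels must be >= 3, got {self.n_channels}")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError(f"coupling must lie in [0, 1], got {self.coupling}")
        trip = tuple(sorted(int(i) for i in self.coherent_triplet))
        if len(set(trip)) != 3 or trip[-1] >= self.n_channels or trip[0] < 0:
            raise ValueError(
                f"coherent_triplet must be 3 distinct indices < {self.n_channels}, "
                f"got {self.coherent_triplet}"
            )
        self.coherent_triplet = trip
        low, high = self.band
        if not (0.0 < low < high < self.fs / 2):
            raise ValueError(
                f"band {self.band} must satisfy 0 < low < high < fs/2 = {self.fs / 2}"
            )
        if self.band_power_shift <= 0:
            raise ValueError(
                f"band_power_shift must be positive, got {self.band_power_shift}"
            )
        # AR background stability: characteristic roots strictly inside the
        # unit circle, i.e. roots of 1 - a1 z - a2 z^2 ... outside it.
        poly = np.r_[1.0, -np.asarray(self.background_model, dtype=float)]
        if len(poly) > 1 and np.abs(np.roots(poly)).max() >= 1.0:
            raise ValueError(
                f"background_model {self.background_model} is not a stable AR model"
            )
        if self.duration * self.fs <= self.fs:
            raise ValueError("duration must exceed 1 s")

    def default_labels(self) -> list[str]:
        if self.labels is not None:
            return list(self.labels)
        if self.n_channels == len(EMOTIV_LABELS):
            return list(EMOTIV_LABELS)
        if self.n_channels == len(BALERT_LABELS):
            return list(BALERT_LABELS)
        return [f"ch{i:02d}" for i in range(1, self.n_channels + 1)]


def _bandpass_sos(band: tuple[float, float], fs: float):
    return signal.butter(4, band, btype="bandpass", fs=fs, output="sos")


def _filtfilt_unit_scale(sos, fs: float) -> float:
    """1/std of forward-backward filtered unit white noise (theoretical).

    Scaling by the expected rather than the realized standard deviation
    keeps disjoint epochs of one recording statistically independent; a
    sample-std normalization would pin the total power of the realization
    and induce negative correlation between its epochs.
    """
    freqs = np.linspace(0.0, fs / 2, 4097)
    _, h = signal.sosfreqz(sos, worN=freqs, fs=fs)
    var = np.trapezoid(np.abs(h) ** 4, freqs) * 2.0 / fs  # filtfilt => |H|^2
    return 1.0 / np.sqrt(var)


def _ar_unit_scale(ar_poly: np.ndarray, fs: float) -> float:
    """1/std of the AR background driven by unit white noise (theoretical)."""
    freqs = np.linspace(0.0, fs / 2, 4097)
    _, h = signal.freqz([1.0], ar_poly, worN=freqs, fs=fs)
    var = np.trapezoid(np.abs(h) ** 2, freqs) * 2.0 / fs
    return 1.0 / np.sqrt(var)


def generate_recording(spec: SynthSpec, condition: str = "pre") -> EEGRecording:
    """Synthesize one recording under the given condition.

    ``condition="post"`` multiplies the in-band variance of the triplet
    channels by ``spec.band_power_shift``; the realization is otherwise an
    independent draw.  Generation is bit-reproducible for a given
    ``(spec, condition)``.
    """
    if condition not in ("pre", "post"):
        raise ValueError(f"condition must be 'pre' or 'post', got {condition!r}")
    n = int(round(spec.duration * spec.fs))
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 0 if condition == "pre" else 1])
    sos = _bandpass_sos(spec.band, spec.fs)

    common_scale = _filtfilt_unit_scale(sos, spec.fs)
    common = common_scale * signal.sosfiltfilt(sos, rng.standard_normal(n))
    ar_poly = np.r_[1.0, -np.asarray(spec.background_model, dtype=float)]
    bg_scale = _ar_unit_scale(ar_poly, spec.fs)
    data = np.empty((spec.n_channels, n))
    triplet = set(spec.coherent_triplet)
    for ch in range(spec.n_channels):
        bg = bg_scale * signal.lfilter([1.0], ar_poly, rng.standard_normal(n))
        if ch in triplet:
            c = spec.coupling
            data[ch] = c * common + np.sqrt(1.0 - c * c) * bg
        else:
            data[ch] = bg

    if condition == "post" and spec.band_power_shift != 1.0:
        for ch in spec.coherent_triplet:
            in_band = signal.sosfiltfilt(sos, data[ch])
            data[ch] = np.sqrt(spec.band_power_shift) * in_band + (data[ch] - in_band)

    return EEGRecording(
        data * _SCALE_UV,
        spec.fs,
        spec.default_labels(),
        meta={"condition": condition, "seed": spec.seed,
              "coherent_triplet": list(spec.coherent_triplet),
              "band": list(spec.band), "coupling": spec.coupling,
              "band_power_shift": spec.band_power_shift if condition == "post" else 1.0},
    )


def generate_session_set(
    spec: SynthSpec,
    n_sessions: int,
    effect_sessions: set[int] | frozenset[int] = frozenset(),
) -> list[tuple[EEGRecording, EEGRecording]]:
    """Generate ``n_sessions`` (pre, post) pairs.

    Sessions listed in ``effect_sessions`` carry ``spec.band_power_shift`` in
    their post recording; all others are null sessions (shift 1.0).  Per-
    session seeds are derived deterministically from ``spec.seed``.
    """
    if n_sessions < 1:
        raise ValueError(f"n_sessions must be >= 1, got {n_sessions}")
    effect = set(int(s) for s in effect_sessions)
    bad = [s for s in effect if not 0 <= s < n_sessions]
    if bad:
        raise ValueError(f"effect_sessions indices out of range: {sorted(bad)}")

    # Independent 31-bit session seeds drawn from a stream keyed on spec.seed.
    seed_rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 0xEE6])
    session_seeds = seed_rng.integers(0, 2**31 - 1, size=n_sessions)

    sessions = []
    for idx in range(n_sessions):
        shift = spec.band_power_shift if idx in effect else 1.0
        s = replace(spec, seed=int(session_seeds[idx]), band_power_shift=shift)
        pre = generate_recording(s, "pre")
        post = generate_recording(s, "post")
        for rec in (pre, post):
            rec.meta["session"] = idx
        sessions.append((pre, post))
    return sessions
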
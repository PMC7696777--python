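# Methods

This note records the modelling assumptions, parameter defaults and
numerical choices behind `eegda`, and what the synthetic-data tests do and
do not demonstrate about real EEG.

## Signal model and pipeline

A recording is an m × N matrix of channel amplitudes (µV) at sampling rate
fs.  The pipeline is: band-pass + optional ICA preprocessing → coherence
based channel selection → square-root Kalman filtering under three sensor
scenarios → Welch PSDs → per-bin Wilcoxon band tests.

Two presets mirror the two study designs the pipeline targets:

| preset | montage | fs | Butterworth | bands | test direction |
|---|---|---|---|---|---|
| LGR | 14 ch | 128 Hz | order 4, [1, 63] Hz | alpha (8–12) | increase |
| DM  | 9 ch  | 256 Hz | order 5, [1, 100] Hz | beta (13–29), gamma (30–40) | decrease |

## Preprocessing

Band-pass filtering is zero-phase (forward–backward `sosfiltfilt`).  The
direction of filtering is a deliberate choice: one-pass IIR filtering
would add frequency-dependent phase lag that corrupts the cross-spectral
phases entering the coherence estimates.

The ICA stage uses FastICA with a fixed restart schedule of loosening
tolerances (1e-3, 1e-2, 5e-2 at seeds seed, seed+1, seed+2).  EEG-like
signals are largely Gaussian, which makes the un-mixing only weakly
identifiable, so non-convergence is a real possibility; if no restart
converges the data pass through unchanged and the report says so — the
stage never silently alters data.  Rejection uses robust (median/MAD)
z-scores across components, because the plain z-score is bounded by
(n−1)/√n and can never reach the threshold 3 on montages with ≲ 10
components.  A component is zeroed when its excess-kurtosis robust z
exceeds 3 *and* its kurtosis is ≥ 2 (spiky artifacts have kurtosis far
above band-limited Gaussian EEG), or when its back-projected-energy robust
z exceeds 3 *and* its energy is ≥ 5× the median component energy.  The
absolute floors keep clean recordings, whose component statistics cluster
tightly, from losing components to scale-free scores alone.

## Coherence selection

Welch estimation uses a Hann window, nperseg = fs (1-s segments, 1 Hz
resolution — the grid the band statistics need) and 50 % overlap.
Coherence requires at least two segments; a single averaged segment gives
γ² ≡ 1 regardless of the data and is rejected.

Surrogates are built by Fourier phase randomization per channel:
amplitude spectra are preserved exactly, phases are i.i.d. uniform, so any
two surrogate channels are uncoupled while sharing the originals' spectral
profile.  The significance threshold is one scalar per channel pair, the
95th percentile of the surrogate coherence values pooled across surrogates
and frequency bins (DC and Nyquist excluded); a per-frequency mode exists.
Pooling is justified because the null distribution of Welch coherence for
independent processes depends essentially on the number of averaged
segments, not the bin; the calibration test confirms the ~5 % per-bin
exceedance on independent AR processes.

Triplet logic: all C(m, 3) subsets in lexicographic order; a triplet is
significant in a recording when all three pairwise coherences beat the
threshold at every in-band bin (the 100 %-appearance rule); counts
accumulate across recordings and the winner set is the union of all
maximally repeated triplets (ties therefore produce > 3 winners).  If no
triplet passes anywhere the selection is returned flagged empty rather
than raising, so calling code can distinguish "no coupling" from an error.
Repetition counting is per *recording*: the Welch average over a
recording's 1-s segments already plays the role of an over-trials average,
and a per-epoch 100 % rule at realistic couplings would be dominated by
estimator noise.  Within the selection engine the pair spectra are
computed from segmented FFTs evaluated for all pairs and surrogates at
once (chunked to bound memory); a unit test pins this engine to
`scipy.signal.coherence` bin by bin.

## Square-root Kalman filter

State = one amplitude per channel, Δt = 1/fs.  The defaults:

* **F** — least-squares drift fit dx/dt ≈ Ax from one-step differences,
  then the Taylor series of exp(AΔt) truncated at order 2 (order 0 gives
  the identity).  Estimates with spectral radius > 1 are shrunk toward the
  identity with a warning; rank-deficient regressions fall back to F = I.
* **Q** — q·I with q the mean one-step increment variance across channels.
* **R** — diagonal, per-channel variance of the > 45 Hz residual (cutoff
  capped at 0.8 × Nyquist for low rates), floored at 1e-8 of the signal
  variance so the scalar Potter updates never divide by zero.
* **x₀** — first sample; **P₀** — sample covariance of the first second
  (plus 1e-9 jitter so the LDLᵀ factorization of a short-sample covariance
  is well posed).

All of F, Q, R can be overridden explicitly.

Numerics: the covariance square root starts from `scipy.linalg.ldl`
(S = L D^{1/2}; tiny negative pivots are clamped, genuinely indefinite
input is rejected).  The time update stacks [SᵀFᵀ; Q^{T/2}] (2m × m) and
triangularizes by plane rotations with c = a/r, s = −b/r, r = √(a²+b²) —
purely arithmetic, no trig — eliminating each column bottom-up
(deterministic order); zero eliminands are skipped, so an all-zero column
costs nothing.  The measurement update processes observations as
sequential scalar Potter steps, diagonalizing R first (eigendecomposition)
when it is correlated.  Both per-step kernels and the full sweep are
numba-compiled; the public step functions wrap the same kernels, so there
is exactly one code path, verified against a dense Joseph-form Kalman
filter to ~1e-13 over hundreds of random systems.

Scenario aggregation for spectra: the PSD of a filter run is the mean
Welch PSD over the channels that scenario *observes*.  Unobserved states
decay toward zero under a stable F and would only dilute the comparison.

The "ensemble" mode (perturbed-observation Monte-Carlo filter with
configurable ensemble size) is provided for completeness but is off by
default: the exact square-root recursion is the primary engine.

## Band statistics

Pairing unit: epoch index — pre epoch i is paired with post epoch i, with
non-overlapping 4-s epochs and one channel-averaged Welch PSD per epoch.
This is the package's definition of the paired sample; pairing by session
or by frequency bin would answer different questions and is deliberately
not offered.  The Wilcoxon signed-rank test is one-sided per the study
goal (increase for alpha, decrease for beta/gamma), exact for ≤ 25 pairs
without ties, normal approximation with continuity correction otherwise;
all-tied bins get p = 1.  A band is *relevant* when strictly more than
half of its 1-Hz bins have p < α = 0.05; exactly half is not a majority.
No multiple-testing correction is applied across bins by default
(a Benjamini–Hochberg option exists), matching the stated procedure of the
statistical protocol the pipeline follows.

## Synthetic data

Each channel is an AR(2) background (default coefficients (1.3, −0.4),
poles at 0.8 and 0.5, a stable 1/f-like spectrum).  The coherent triplet
additionally shares a common component of band-pass-filtered white noise
(4th-order Butterworth in the target band), mixed as

    x = coupling·common + sqrt(1 − coupling²)·background,

so coupling ∈ [0, 1] trades background for shared rhythm at constant unit
variance; everything is scaled to ~10 µV RMS.  A band-limited *noise*
rhythm rather than a sinusoid makes coherence broadband within the band,
which is what the 100 %-appearance rule needs to be exercisable.

Both components are normalized by their *theoretical* standard deviations
(filter gain integrals), not the realized sample std.  Sample
normalization pins the total power of each realization and induces
negative correlation between the epoch PSDs of one recording, which was
measured to depress the Wilcoxon type-I rate to ~2 % — an artifact of the
generator, not of the test.  With expectation normalization the epochs are
independent and the per-bin type-I rate sits at its nominal 5 %.

The "post" condition multiplies the in-band variance of the triplet
channels by `band_power_shift` (the in-band part is split off by the same
zero-phase band-pass, scaled, and recombined); pre and post are otherwise
independent realizations.  Session sets derive per-session seeds
deterministically from the master seed; effect sessions carry the shift,
the rest are null.

What the generator does *not* emulate: volume conduction and realistic
channel cross-covariance outside the planted triplet, non-stationarity
(drowsiness, drift), eye-blink/EMG artifact morphology, and line noise.
Passing tests therefore demonstrate the correctness and calibration of the
machinery under the stated model, not performance on any particular real
recording.

## Problem sizes used by the default test run

Chosen as the package's own test design: selection recovery uses 100
replicates of 10 × 60-s recordings at coupling 0.9 with 20 surrogates per
pair; surrogate calibration pools 1260 bin tests over 20 independent AR
pairs with 100 surrogates each; the Wilcoxon null simulation uses 1000
replicate sessions (4-channel montage — only the triplet enters the test)
and the power simulation 200 sessions at shift ×2 with 15 epoch pairs;
filter/oracle equivalence uses 100 random systems (state dim ≤ 5, ≤ 3
observed, 200 steps); the scenario-ordering check uses 20 replicates of
20-s recordings.  `scripts/acceptance.py` re-derives the same quantities
at slightly reduced replicate counts (printed as `n` in its JSON output).

## Known limitations

* The state model is linear-Gaussian with a time-invariant F estimated
  once per recording; rhythms with strongly time-varying dynamics are
  tracked only through the process noise.
* The per-pair surrogate threshold assumes stationarity of the recording
  over the estimation window.
* EDF support is asymmetric: reading uses `mne`; writing uses a minimal
  built-in 16-bit encoder (1-s records, integer rates only, physical
  range quantized per channel).
* FastICA on largely Gaussian data may legitimately fail to converge; the
  pipeline then proceeds on unfiltered (band-passed only) data and records
  that in the report.
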
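# eegda — data-assimilation quantitative EEG analysis

`eegda` implements a quantitative-EEG (QEEG) analysis pipeline built on data
assimilation: it identifies the electrodes most relevant to a cognitive task
from their mutual spectral coherence, re-estimates the multichannel EEG
signal with a **square-root Kalman filter** under three sensor scenarios,
and tests whether the band power of the relevant channels changed between
two conditions (e.g., before vs after a concentration or motor-learning
task).  It is aimed at researchers analysing task EEG from consumer- or
research-grade headsets (tens of channels, 128–256 Hz) who want a
reproducible, scriptable alternative to visual QEEG inspection.

## Method

**1. Channel selection by surrogate-thresholded coherence.**  For channels
*j*, *k* the magnitude-squared coherence is

    γ²ⱼₖ(f) = |Pⱼₖ(f)|² / (Pⱼ(f) Pₖ(f)),

with auto-/cross-spectral densities estimated by Welch's method (Hann
window, 1-s segments, 50 % overlap, 1 Hz resolution).  Significance is
judged against phase-randomized surrogate pairs — same amplitude spectra,
independent phases, hence uncoupled — with the threshold at the 95th
percentile of the pooled surrogate coherence distribution.  All C(m, 3)
channel triplets are scored; a triplet counts in a recording when **all
three** pairwise coherences beat the threshold at **every** frequency bin
of the target band (alpha 8–12, beta 13–29 or gamma 30–40 Hz).  The winner
channels (WC) are the union of the triplets repeated most often across
recordings; ties yield more than three winners.

**2. Square-root Kalman filtering.**  The state is one amplitude per
channel; F is a truncated Taylor expansion of exp(AΔt) with the drift A
fitted by least squares; H selects the observed channels for the scenario
(`all`, `wc`, or `nwc` = not-winner channels).  The covariance is carried
in factored form P = SSᵀ throughout: S comes from an LDLᵀ decomposition,
the time update triangularizes the stacked [SᵀFᵀ; Q^{T/2}] with Givens
rotations (c = a/r, s = −b/r, r = √(a²+b²); no trigonometric calls), and
the measurement update is Potter's square-root algorithm extended to
vector measurements, which keeps P positive semidefinite by construction.
A Monte-Carlo ensemble mode is available but off by default.

**3. Band-power statistics.**  Each recording is cut into 4-s epochs; one
Welch PSD per epoch on the winner channels gives paired samples.  A
one-sided Wilcoxon signed-rank test is run per 1-Hz bin at α = 0.05
(exact null for ≤ 25 pairs) and a band is declared changed when a strict
majority of its bins is significant.

A seeded synthetic-data module generates EEG-like recordings (AR(2)
1/f-style backgrounds, a band-limited common rhythm shared by a coherent
triplet, controllable pre→post band-power shift) so the whole pipeline is
testable without external data.

## Worked example

```python
from eegda import (SynthSpec, generate_recording, SelectionParams,
                   select_relevant_sensors, SqrtKalmanFilter, scenario_psd,
                   epoch_psds, wilcoxon_band_test)

spec = SynthSpec(n_channels=14, fs=128, duration=60,
                 coherent_triplet=(11, 12, 13), band=(8, 12),
                 coupling=0.9, band_power_shift=2.0, seed=42)
pre = generate_recording(spec, "pre")
post = generate_recording(spec, "post")

sel = select_relevant_sensors([pre], (8, 12),
                              SelectionParams(n_surrogates=50, seed=0))
print("winner channels:", ", ".join(sel.winners))

runs = {sc: SqrtKalmanFilter(pre, sel, scenario=sc).fit()
        for sc in ("all", "wc", "nwc")}
print(runs["wc"].summary())
for sc, run in runs.items():
    print(f"mean in-band PSD [{sc:>3}]: "
          f"{scenario_psd(run).band_mean((8, 12)):7.2f} uV^2/Hz")

res = wilcoxon_band_test(epoch_psds(pre, sel.winners),
                         epoch_psds(post, sel.winners),
                         (8, 12), alternative="increase")
print(f"alpha-band change: relevant={res.relevant} "
      f"({res.n_significant}/{len(res.bin_pvalues)} bins significant)")
```

Output:

```
winner channels: F4, F8, AF4
Square-root Kalman filter run
==================================
scenario:          wc
states (channels): 14
observed channels: F4, F8, AF4
samples:           7680 @ 128 Hz
taylor order:      2
innovation rms:    4.707
mean in-band PSD [all]:    5.50 uV^2/Hz
mean in-band PSD [ wc]:   17.45 uV^2/Hz
mean in-band PSD [nwc]:    2.25 uV^2/Hz
alpha-band change: relevant=True (4/5 bins significant)
```

The selection recovers exactly the planted coherent triplet (channels
F4/F8/AF4 of the 14-channel montage).  The winner-channel filter run
concentrates the in-band power (17.45 vs 2.25 µV²/Hz for the complement),
and the doubled alpha power in the post recording is detected by the
band-majority rule.

The same pipeline is available from the shell:

```bash
eegda run-all --preset LGR --seed 1 --out results/
# or stage by stage: eegda simulate / select / assimilate / analyze
```

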
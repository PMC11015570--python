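# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `restband`: the resting-state EEG band-power
chain, its within-subject statistics, and the synthetic study generator
used to verify both.

## Preprocessing

**Band-pass filter.** A single Butterworth band-pass design (default
0.1–30 Hz, order 2 per pass) applied forward and then backward in time
(`scipy.signal.sosfiltfilt`, second-order sections for numerical stability
at the 0.1 Hz corner). The dual pass cancels phase distortion and squares
the magnitude response, so the band edges — −3 dB per pass — have amplitude
gain exactly 0.5 after both passes; at 10 Hz the composed gain is ≈ 0.989
(the edges are close enough that "mid-band" is not exactly unity). "Dual
pass + order 2" is realized as one band-pass design rather than cascaded
separate high- and low-pass sections; the difference is confined to the
transition regions and is observable through the frequency-response tests.
Edge transients are handled by scipy's default odd-reflection padding; the
filters refuse recordings shorter than 3 s, where the 0.1 Hz corner's
multi-second startup transient would dominate. That same slow transient is
why the zero-phase (time-symmetry) property test uses a 1 Hz corner: with a
0.1 Hz corner no part of a 10 s record reaches steady state.

**Notch.** A second-order IIR notch at 60 Hz with a 2 Hz −3 dB bandwidth
(Q = 30), also applied dual-pass. Attenuation at exactly 60 Hz is
effectively complete (> 100 dB in practice); one bandwidth away (58/62 Hz)
the single-pass loss is just under 1 dB, and the dual pass doubles the dB
loss, so the "leave neighbours alone" guarantee should be read per pass at
±1 bandwidth and for the composed filter from ±2 bandwidths out.

**Epoching.** Epoch k covers samples [k·S, k·S + L), L =
round(length_ms·fs/1000), S = L − overlap; the trailing partial window is
discarded, giving floor((N−L)/S) + 1 epochs. Defaults 1000 ms / 500 ms, so
a 300 s block at 1 kHz yields 599 epochs and Δf = 1 Hz.

**Artifact rejection.** An epoch is rejected on a channel when its
within-epoch peak-to-peak range (max − min) strictly exceeds the threshold
(default 150 μV). Rejection is per channel by default — an epoch rejected
on Cz still contributes to Fz — with a whole-epoch mode
(`reject.scope: epoch`) available, since electrodes are analyzed
independently downstream. A `successive_difference` criterion (largest
absolute sample-to-sample step) is provided as an alternative reading of an
"absolute difference" threshold; peak-to-peak is the default because it is
the dominant convention for blink/movement screening at this threshold
scale. The boundary is strict: a range of exactly 150 μV is kept.

## Spectral estimation

Per-epoch spectra are plain rectangular-window FFTs of the demeaned epoch.
The single-sided normalization is fixed by the contract that a bin-aligned
sinusoid of amplitude A contributes A²/2 μV² at its bin, which also makes
the bin sum equal the epoch's time-domain mean square (Parseval; tested to
1e−6 relative). Per-epoch mean removal prevents DC leakage from
contaminating the lowest bins and leaves every bin ≥ 1 Hz unchanged.
Spectra are averaged arithmetically over retained epochs only; band power
is the mean of the averaged power over bins with low ≤ f ≤ high, inclusive
on both edges — with Δf = 1 Hz the default θ/α/β bands cover 4/5/18 bins.
A Hann window (`spectral.window: hann`, amplitude-normalized) and a sum
aggregate (`spectral.band_aggregate: sum`) exist as sensitivity switches;
the defaults are the plain transform and the bin mean. Because the mean and
the FFT are linear, band power of the epoch-averaged spectrum equals the
epoch mean of per-epoch band powers.

## Statistics

**Repeated-measures ANOVA.** Classical one-way within-subject
decomposition per (band, channel) on complete cases (listwise deletion;
≥ 3 complete subjects required): SS_total = SS_subjects + SS_conditions +
SS_error, F = MS_conditions/MS_error with df (J−1, (J−1)(n−1)). Zero error
variance is reported as F = ∞, p = 0 with a warning. Mauchly's W is
computed from the orthonormally contrasted covariance with the standard
second-order chi-square series correction (the same approximation used by
ezANOVA/pingouin, against which the implementation is cross-checked); when
Mauchly rejects at α = 0.05, the Greenhouse–Geisser-corrected p (df scaled
by ε = tr(T)²/((J−1)·tr(T²))) is reported alongside the always-reported
uncorrected F and df. Partial η² = SS_conditions/(SS_conditions+SS_error)
is emitted informationally.

**Pairwise comparisons.** All J(J−1)/2 pairs. The default error term is
the pooled ANOVA MS_error: t = (M_a − M_b)/√(2·MS_error/n) with
df = (J−1)(n−1) — the convention under which a three-condition, 40-subject
analysis reports t(78). An ordinary paired t (df = n−1) is available as
`per_pair`. Both Holm (default) and Bonferroni adjustments are always
emitted side by side in reports; Holm is uniformly no less powerful.
Pairwise tests are not gated on the omnibus F.

**Within-subject intervals.** Cousineau normalization (subtract the
subject's mean across conditions, add the grand mean) followed by Morey's
√(J/(J−1)) scaling of the normalized standard errors; the interval is
mean ± t(n−1) · SE · correction. A single condition reduces exactly to the
one-sample t interval. Widths are invariant to per-subject offsets.

## Synthetic studies

The generator produces, per channel: (i) for each band, sinusoids at every
integer frequency inside the band, all with amplitude A_eff and
independent uniform phases — bin-aligned at Δf = 1 Hz, so true band power
(bin mean) is exactly A_eff²/2; (ii) background noise with power spectrum
∝ 1/f^exponent (exponent 1.0, i.e. pink noise, amplitude ∝ f^−1/2),
normalized to a total RMS of `pink_noise_scale` (default 3 μV); (iii) a
60 Hz line component (default 5 μV); (iv) raised-cosine artifact pulses
(default 300 μV peak, 200 ms) at Poisson onsets (default 2/min).
A_eff = base amplitude × condition multiplier × a per-subject lognormal
factor (σ_log = 0.2) shared across conditions, channels and bands — the
within-subject design's "subject offset".

The pink-noise slope is defined on the *power* spectrum deliberately.
A slope-2 ("brown") background is dominated by sub-hertz drift whose
rectangular-window leakage into the analysis bands has very few effective
degrees of freedom; that heavy-tailed error structure makes the F test
measurably conservative, which would misrepresent the chain's operating
characteristics. True pink noise gives near-nominal type-I error (measured
≈ 4% at α = 0.05 over 400 null studies of n = 20) and is the standard
description of broadband EEG background.

Defaults emulate a three-condition, 40-subject, five-minute-block
eyes-open study on Fz/Cz/Pz at 1 kHz. The frontal beta base amplitude is
set so the analytic band power is ≈ 0.77 μV², with deterministic amplitude
multipliers ≈ 0.987 (clear control glasses) and ≈ 0.919 (light-filtering
glasses), i.e. power ratios 0.75/0.77 and 0.65/0.77 — a configuration in
which only frontal beta carries a condition effect. Alpha is strongest
posteriorly, as in eyes-open resting EEG.

Seeding: every random stream is keyed by a SHA-256-derived 31-bit child
seed of (master_seed, role, subject, condition, channel), so recordings
are bit-reproducible across runs and platforms, independent of the order
in which conditions or channels are enumerated.

What the simulator does **not** emulate: volume conduction and channel
covariance, realistic blink/EMG morphology, eyes-closed alpha blocking,
non-stationarity within a block, or amplitude-dependent artifact
morphology. Passing tests therefore demonstrate the correctness and
calibration of the analysis chain under the stated signal model, not the
physiological validity of any particular recording.

## Problem sizes in replicated checks

The type-I calibration uses 400 replicates of n = 20 subjects with 10 s
blocks; effect recovery uses 20 replicates of n = 40 with 60 s blocks and
a 15% frontal-beta amplitude reduction. Shorter-than-five-minute blocks
keep replicated runs fast while preserving ≥ 19 epochs per recording; the
recovery effect is large enough that block length is not the limiting
factor (observed p-values are far below the α = 0.001 criterion).

## Known limitations

- Measured band powers sit below the raw analytic targets because the beta
  band extends to the 30 Hz filter edge, where the dual-pass response rolls
  off; the attenuation is identical across conditions, so all comparisons
  and calibration properties are unaffected. Absolute-power comparisons
  against unfiltered targets must either skip filtering or fold the filter
  response into the target.
- The EDF writer covers continuous 16-bit recordings with 1 s records and
  integer sampling rates only — sufficient for fixtures, not a general
  EDF(+) implementation. Round-trip error is bounded by the 16-bit
  quantization step of the written physical range.
- Band power at Δf = 1 Hz resolution assumes 1 s epochs; other epoch
  lengths change the bin grid and hence the bins a band covers (the
  inclusive-edge rule is applied to whatever grid results).
- The statistics layer implements the one-way within-subject design only;
  multi-factor designs, mixed models and covariates are out of scope.
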
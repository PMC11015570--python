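# restband

Resting-state EEG band-power analysis with a known-truth study simulator.

`restband` is for researchers analyzing multi-channel resting EEG as
condition-wise band power: it implements the standard spectral chain —
zero-phase (dual-pass) Butterworth band-pass filtering, mains-notch
filtering, segmentation into overlapping epochs, peak-to-peak artifact
rejection, rectangular-window FFT power averaged over retained epochs, and
band power for named frequency ranges (θ 4–7 Hz, α 8–12 Hz, β 13–30 Hz) at
midline electrodes (Fz, Cz, Pz) — together with the within-subject
statistics used to compare conditions, and a synthetic EEG study generator
whose band-power ground truth is analytic, so the whole chain can be
verified end to end without any real recordings.

## The analysis

For each subject *s* and condition *c*, a recording x(t) (μV, typically
five minutes at 1 kHz) is filtered with a zero-phase Butterworth band-pass
(0.1–30 Hz, order 2 per pass, forward–backward so the magnitude response is
squared and phase is cancelled) and a 60 Hz notch (Q = 30), then cut into
1000 ms epochs with 500 ms overlap. Epochs whose within-epoch peak-to-peak
amplitude max − min exceeds 150 μV on a channel are rejected on that
channel. Retained epochs are demeaned and Fourier transformed with the
single-sided normalization under which a bin-aligned sinusoid of amplitude
A carries A²/2 μV² at its bin; spectra are averaged over epochs, and band
power P(s, c, channel, band) is the mean of the averaged power over the
bins inside the band (inclusive edges; Δf = 1 Hz for 1 s epochs).

The statistics layer fits, per (band, channel), the one-way
repeated-measures ANOVA

    SS_total = SS_subjects + SS_conditions + SS_error,
    F = MS_conditions / MS_error,   df = (J−1, (J−1)(n−1)),

with Mauchly's sphericity test and Greenhouse–Geisser correction, pairwise
comparisons using the pooled error term t = (M_a − M_b)/√(2·MS_error/n)
under Holm (default) and Bonferroni adjustment, and Cousineau–Morey 95%
within-subject confidence intervals for the condition means.

The simulator composes, per channel, random-phase sinusoids at each band's
integer frequencies (bin-aligned, so true band power is exactly A²/2),
1/f background noise, a 60 Hz line component, and Poisson-timed 300 μV
raised-cosine artifact pulses; subjects get multiplicative lognormal
amplitude factors and conditions get deterministic multipliers (by default
a frontal-beta reduction in the "filter_glasses" condition).

## Worked example

```python
from restband import SimConfig, simulate_study, compute_band_power_table, rm_anova

cfg = SimConfig(n_subjects=12, duration_s=30.0, master_seed=7)
study, truth = simulate_study(cfg)
table = compute_band_power_table(study)
print(rm_anova(table, "beta", "Fz").summary())
```

prints

```
Repeated-measures ANOVA [beta @ Fz]
==========================================================
n subjects: 12    conditions: clear_glasses, filter_glasses, no_glasses
F(2, 22) = 43.02, p = 2.494e-08  (GG-corrected p = 3.939e-06)
MS_error = 0.0007036   partial eta^2 = 0.7964
Mauchly W = 0.478, p = 0.02495, GG epsilon = 0.657  [sphericity rejected]
----------------------------------------------------------
condition means (SD):
     clear_glasses: 0.6074 (0.2569)
    filter_glasses: 0.5283 (0.2167)
        no_glasses: 0.6216 (0.2554)
```

The simulated frontal beta reduction (amplitude ratio ≈ 0.92 in the
filtering-glasses condition, i.e. ≈ 0.84 in power) is recovered: the
`filter_glasses` mean is lowest, and the within-subject design removes the
large between-subject spread (SD ≈ 0.25) from the error term, giving a
decisive F — here with Mauchly's test rejecting sphericity in this small
sample, so the Greenhouse–Geisser-corrected p is reported alongside.
Condition means are lower than the simulator's raw analytic targets because
the 30 Hz band-pass edge attenuates the upper beta bins — identically in
every condition, so comparisons are unaffected.

The same run from a shell:

```sh
restband simulate --out study/ --seed 7 --n-subjects 12 --duration-s 30
restband run study/manifest.csv --out results/
```

which writes `band_power.csv`, `statistics.json`, `retained_epochs.csv`,
an archived `config.yaml`, and a condition-means figure.

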
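# respigate

Respiratory-gating analysis for whole-heart 4D flow MRI, built around the
comparison of two gating signals: an in-bore **camera** (contact-less,
20 Hz, arbitrary units) and the MRI-native **liver–lung navigator**
(2 Hz, millimetres). The package implements the retrospective analysis
chain of such a comparison study — respiratory phase binning with
expiration acceptance, gating-signal agreement, quantitative image
quality and the cohort statistics — and a synthetic-data module that
generates every input, so the whole pipeline runs and is tested without
any patient data.

## What it computes

**Phase binning.** A raw respiratory trace is rescaled to zero median,
smoothed over 1 s, and searched for extrema in two passes: first with a
minimal same-sign peak distance derived from a 45 breaths/min ceiling,
then again requiring a minimal peak prominence of one fourth of the
median trough-to-peak swing. After correcting double extrema, every
sample gets a phase bin 1–100: bins 1–40 span the trough→peak
(inspiration) segment, bins 41–100 the peak→trough (expiration) segment,
each linear in time. Accepting bins 41–100 is the 60% expiration phase
acceptance; on a breathing trace whose inspiration:expiration duration
ratio is 40:60, 60% of the samples are accepted.

**Signal agreement.** Two phase series are resampled to a common grid
and cross-correlated: `C_phase` is the peak normalised correlation and
`d_phase` the lag at the peak. A delay converts to a fraction of the
breathing cycle as `100 · |d| / (60000 / rate_bpm)` — 63 ms is 4.2% of a
cycle at 40 breaths/min and 2.1% at 20 breaths/min.

**Image quality.** Inside a 10×10×30 voxel ROI across the liver–lung
border: SNR = time-averaged liver-slice mean / time-averaged lung-slice
SD; LLE = mean width *d̄* (voxel) of sigmoid functions
`b + a/(1 + exp(−(z − z0)/w))` fitted to the 100 time-averaged z line
profiles. Blurrier borders give larger LLE.

**Statistics.** One-way repeated-measures ANOVA in the multivariate
form (Hotelling T² on within-subject differences; Wilks' Λ = 1/(1 +
T²/(n−1)), F on (k−1, n−k+1) df, partial η² = 1 − Λ); Bonferroni-corrected
paired comparisons with adjusted CIs; ordinal Krippendorff's α from the
coincidence matrix; Bland–Altman bias and 95% limits of agreement.

## Worked example

```sh
respigate simulate --seed 4 --duration 60 --out demo
respigate bin --input demo/cam.tsv --out demo/cam_phase.tsv
respigate bin --input demo/nav.tsv --interp-fs 20 --out demo/nav_phase.tsv
respigate compare --a demo/cam_phase.tsv --b demo/nav_phase.tsv \
    --out demo/agreement.json
```

prints

```
assigned 1122/1200 samples, acceptance 60.2%
assigned 1123/1191 samples, acceptance 58.5%
C_phase = 0.964, d_phase = 0 ms
```

— the camera trace binned at 20 Hz accepts ~60% of samples (the
expiration share of the simulated 40:60 breathing cycle), the 2 Hz
navigator (interpolated to the camera grid before binning) agrees, and
the two phase series correlate at 0.96 with no delay, as expected for
two sensors watching the same breathing.

The numbered scripts under `analysis/` run the full synthetic cohort
study end to end (simulate → bin → agreement → image quality → cohort
statistics) and write their tables under `results/`:

```sh
for s in analysis/0*.py; do python "$s"; done
```

On the default eight-subject cohort this reports phase correlations of
0.937 ± 0.035 (one-sided p vs 0.5 ≈ 2·10⁻⁹), near-exact recovery of each
subject's true edge width under gating (median error 0.01 voxel), and a
strongly significant LLE penalty for the ungated condition
(Wilks' Λ = 0.01, p ≈ 2·10⁻⁷) with no CAM-vs-NAV difference — the
behaviour a gating comparison should exhibit when both sensors observe
the same breathing. `respigate run --out DIR` does the same in one
command.

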
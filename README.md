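# pancfat

Quantification of pancreatic fat from dual-echo chemical-shift
(in-phase / opposed-phase) MRI, with the cohort statistics used to
characterize alcohol-related pancreatic steatosis and its spatial
heterogeneity. Intended for imaging scientists and biostatisticians
working with ROI-level signal tables from 3 T abdominal protocols —
no image processing is performed; the inputs are delimited-text
tables of ROI signal intensities.

## What it computes

**T1/T2\*-corrected fat fraction.** From the in-phase and
opposed-phase magnitude signals of a spoiled dual-echo gradient-echo
acquisition,

    FF = a·(SI_ip·e_y − SI_op·e_x) / [SI_ip·e_y·(a+b) + SI_op·e_x·(b−a)]

with steady-state factors
`a,b = sin α (1−e^(−TR/T1_{w,f})) / (1−cos α e^(−TR/T1_{w,f}))` for
water and fat and T2\* terms `e_x = e^(−TE_ip/T2*)`,
`e_y = e^(−TE_op/T2*)`; T2\* is estimated from a low-flip multi-echo
series by log-linear fit. This estimator inverts the two-point signal
model exactly (FF = f/(w+f)) for water-dominant tissue.

**Phantom calibration.** A 15-level fat–water phantom (0–14%) maps
calculated to actual fat fraction by OLS
(`actual = slope·calculated + intercept`), applied to pancreatic
values with extrapolation and clamping flags.

**Regional aggregation and heterogeneity.** Region fat fractions
(caput, corpus, cauda) are means of 9 ROIs each; the whole-pancreas
value is their mean and ΔFF = FF_max − FF_min indexes within-subject
heterogeneity.

**Cohort statistics.** Group summaries (n, mean, SD, CV = SD/mean) by
age band and exposure, one-way ANOVA, Miller's asymptotic u-test for
CV equality, Shapiro–Wilk normality annotation, intra-observer
ICC(A,1), and an abstinence-stratum analysis.

**Synthetic data.** Generators for phantoms, subjects, full cohorts
(282 subjects in the reference design) and raw per-ROI signal tables,
so the entire pipeline runs and is tested without any scanner data.

See `docs/methods.md` for the model, assumptions and defaults.

## Worked example

```bash
pancfat simulate-phantom --seed 1 --out phantom.csv
pancfat fit-calibration --phantom phantom.csv --out model.json
# INFO pancfat: calibration: actual = 0.9534 * calculated -3.4350 (R^2 = 0.9981)

pancfat report --seed 1 --outdir study/
# INFO pancfat: study report in study: 10 groups, 27 comparisons (5 ANOVA p<0.05)
```

The fitted calibration line for this seed (slope 0.9534, R² 0.9981)
scatters around the reference phantom regression
(0.9679·x − 3.6064, R² 0.991); averaging refits over 50 seeds
recovers the reference coefficients. `study/fat_fraction_summary.csv`
then contains one row per group, e.g. (rounded):

```
age_band exposure   n  whole_mean  whole_sd  delta_ff_mean
   20-30  control  32        2.46      0.45           0.93
   20-30  alcohol  36        5.00      1.24           1.04
   40-50  control  37        2.89      0.74           0.79
   40-50  alcohol  39        6.06      1.60           2.36
   50-70  alcohol  34        8.40      3.40           2.51
   20-50  control 104        2.78      0.70           0.86
   20-50  alcohol 106        5.68      1.66           1.62
```

Whole-pancreas fat is roughly doubled in the alcohol groups at every
age, and the ΔFF column shows the heterogeneity signature: drinkers
aged ≥ 40 have a within-subject regional spread near 2.4%, versus
≈ 0.8–0.9% in controls. `study/comparisons.json` holds every test,
e.g. the 20–30 alcohol-vs-control whole-FF ANOVA
(F = 119.6, p = 1.9e−16), and `study/cv_summary.csv` the CV table.

The same stages are available as library calls
(`pancfat.fat_fraction_corrected`, `fit_calibration`, `run_study`, …)
and accept/produce pandas DataFrames.

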
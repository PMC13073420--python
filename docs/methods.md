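# Methods

`pancfat` implements a quantitative pipeline for pancreatic fat
measured with T1-weighted dual-echo chemical-shift (in-phase /
opposed-phase) spoiled gradient-echo MRI at 3 T, together with the
cohort-level heterogeneity statistics used to compare alcohol-exposed
men with non-drinking controls. Because no subject-level imaging data
are distributed, every stage is exercised on synthetic data whose
generative parameters are the published group-level values; this note
records the model, its assumptions, the defaults, and what the
synthetic experiments do and do not demonstrate.

## Signal model and corrected fat-fraction estimator

A voxel containing water magnetization `w` and fat magnetization `f`
with shared effective transverse relaxation T2\* produces magnitude
signals

    SI_ip = (w·a + f·b) · exp(−TE_ip/T2*)
    SI_op = |w·a − f·b| · exp(−TE_op/T2*)

where `a` and `b` are the spoiled gradient-echo steady-state factors
of water and fat,

    a,b = sin α · (1 − e^(−TR/T1_{w,f})) / (1 − cos α · e^(−TR/T1_{w,f})).

The T1/T2\*-corrected two-point estimator is

    FF = a·(SI_ip·e_y − SI_op·e_x)
         / [SI_ip·e_y·(a+b) + SI_op·e_x·(b−a)],
    e_x = exp(−TE_ip/T2*),   e_y = exp(−TE_op/T2*).

Substituting the forward model shows FF = f/(w+f) exactly — the
correction removes both the T1-weighting difference between water and
fat and the differential T2\* decay of the two echoes. The pairing of
the exponents (e_x with the opposed-phase term, e_y with the in-phase
term) is the unique one with this property; the test suite fails if it
is swapped.

**Validity domain.** Magnitude reconstruction loses the sign of
`w·a − f·b`. The inversion is therefore exact only while water
dominates in *signal* terms, `w·a > f·b`, i.e. true FF below
`a/(a+b)` (`water_dominance_limit`). With T1 weighting (`a < b`) this
limit sits below 50% — ≈ 35.9% at the default TR 80 ms / flip 50°
protocol — and beyond it the estimator aliases silently (the returned
value is again inside [0, 1], so no flag is possible). This is an
inherent property of two-point magnitude Dixon imaging, and one reason
the method is used for low-fat tissue such as the pancreas (cohort
values here are 2–15%). The round-trip identity is asserted to 1e−9
across T2\* ∈ [5, 60] ms and flip ∈ (0°, 90°] on each flip angle's
validity domain. `FatFractionEstimate.out_of_range` flags raw values
outside [0, 1], which under this model indicates noise or a violated
water-dominance assumption.

**T2\* estimation.** T2\* is obtained from a separate low-flip
(4°, TR 9.15 ms) multi-echo acquisition at TEs 2.46, 3.69, 4.92, 6.15,
7.38 ms by a log-linear least-squares fit, returning −1/slope. Because
alternate echoes are opposed-phase, fat–water oscillation is
superimposed on the decay; the default policy fits only the in-phase
echoes (integer multiples of the 2.46 ms in-phase period: 2.46, 4.92,
7.38 ms), and an `"all"` policy is available. A non-negative fitted
slope raises a "no decay" error rather than returning a negative or
infinite T2\*. The pipeline accepts T2\* at any granularity: per ROI
(when a series is attached to the ROI row), or a single externally
supplied value.

## Default acquisition and tissue constants

| parameter | default | note |
|---|---|---|
| TR / TE_ip / TE_op | 80 / 2.46 / 1.23 ms | dual-echo protocol |
| flip angle | 50° | dual-echo protocol |
| multi-echo TEs | 2.46 … 7.38 ms (5 echoes), flip 4°, TR 9.15 ms | T2\* mapping |
| T1 water / T1 fat | 828 / 382 ms | typical 3 T abdominal values; the protocol does not measure T1, so these are explicit, configurable assumptions |
| T2\* (simulation truth) | 25 ms | plausible pancreatic value at 3 T |

## Phantom calibration

The 15-vial fat–water phantom (nominal 0–14% in 1% steps, 9 ROIs per
vial) calibrates calculated against actual fat fraction by ordinary
least squares with **actual as the response**. Since the phantom's
actual concentrations are error-free by construction this is inverse
calibration by design; the fitted line (reference values: slope
0.9679, intercept −3.6064, R² 0.991) is then applied to pancreatic
values. Out-of-domain inputs are extrapolated with a flag rather than
refused, and negative calibrated values are clamped to 0 with a flag,
because the published equation was itself applied over a range wider
than the phantom's actual concentrations. The large offset between
calculated and actual scales (calculated ≈ 3.7% at a 0% vial) is taken
from the reference regression as-is; its physical origin is not
modelled.

In the synthetic phantom the σ = 0.40% Gaussian scatter sits on the
**response** side of the regression, so the refitted slope is
unbiased; σ was chosen so the refit reproduces R² ≈ 0.991 given the
predictor spread. The realized response of the 0% vial may then dip
slightly below zero — it is deliberately not truncated, because
clamping at zero biases the slope by ≈ −0.004. The physically
intuitive alternative, noise on the measured (predictor) side, causes
classical attenuation bias and is available as
`gen_phantom(..., noise_on="predictor")` but is not the default.
Within-vial ROI scatter defaults to zero (homogeneous liquid, large
ROIs) and is configurable.

## ROI protocol and heterogeneity indices

Regions are aggregated strictly per protocol: 9 ROIs per region
(3 slices × 3), 27 per subject; areas 40–60 mm² (pancreas) or
80–100 mm² (vials) are validated. The whole-pancreas fat fraction is
the mean of the caput, corpus and cauda values, and the heterogeneity
index is ΔFF = max − min over the three region values, computed per
subject at region-mean level and summarized across subjects as
mean ± SD (a per-ROI variant is deliberately not the default).
ΔFF uses calibrated fractions when a calibration is supplied; an
affine calibration scales ΔFF by its slope. A lenient mode averages
whatever ROIs are present, with a warning; it exists for robustness
and is never used in the reproduction runs. Values are kept at full
precision internally and rounded to two decimals only in rendered
reports.

## Cohort statistics

* Age bands 20–30, 30–40, 40–50 are half-open `[low, high)`; 50–70 is
  closed at 70. The published band labels overlap, so the boundary
  convention is fixed here: age 30 → 30–40 band. A pooled 20–50
  aggregate is computed per exposure.
* Summaries use the sample SD (n−1); the published CV table is
  reproduced from the published means/SDs only under that convention.
  CV = SD/mean is computed across subjects within a group.
* Group mean differences: one-way ANOVA (scipy); normality is checked
  by Shapiro–Wilk but only annotates summaries — tests are not
  switched automatically, matching the source analysis, and no
  multiple-testing correction is applied (per-comparison two-sided
  α = 0.05).
* CV equality between two groups uses Miller's asymptotic test with
  df-pooled CV `c̄ = ((n1−1)cv1 + (n2−1)cv2)/(n1+n2−2)`:

      u = (cv1 − cv2) / sqrt(c̄²(0.5 + c̄²)(1/(n1−1) + 1/(n2−1))),

  two-sided p from the standard normal. The source text names only a
  "u test" without a reference; Miller's test is the standard
  asymptotic choice for equality of coefficients of variation at these
  group sizes and is documented as an open identification question.
* Intra-observer reliability: two-way absolute-agreement single-measure
  ICC(A,1), computed from the two-way ANOVA mean squares and
  cross-checked against pingouin in the tests.

## Synthetic cohort generator

Each subject's region fat fractions are drawn as

    FF_r = m_r + ρ_r·z + η_r,  z ~ N(0,1),  η_r ~ N(0, s_h²),
    ρ_r = sqrt(max(sd_r² − s_h², 0)),

so the marginal per-region mean and SD equal the reference group
values exactly while `s_h` controls within-subject between-region
spread. Defaults: `s_h` = 0.40% baseline (bounded by the smallest
reference region SD, 0.42%), inflated to 1.35% for alcohol-exposed
subjects aged ≥ 40 (the heterogeneity onset age). The inflated value
was calibrated once so that the older drinker groups show a mean ΔFF
of ≈ 2.4% (2.36% in the 40–50 band, 2.49% in 50–70, over 30 seeds),
inside the reported 2.3–2.9% band; it is recorded here and in
`GeneratorConfig`, not fitted per run. Gaussian marginals are used
because the source data passed normality testing; draws are truncated
at zero, a deviation from strict normality that affects < 1% of draws
under defaults. Ages are uniform within bands.

The default design carries the eight published group sizes
(32/36/35/31/37/39/38/34; 142 controls + 140 alcohol), and drinking
strata are assigned by permuting a fixed label pool (79 current / 31
abstinent < 1 y / 30 abstinent 1–2 y), making stratum totals exact and
stratum membership independent of fat values — i.e. the strata share a
common distribution, reflecting the null abstinence finding.
`CohortDesign.stratum_means` optionally imposes per-stratum
whole-pancreas means instead. Raw-signal generation
(`gen_roi_signals`) is an optional deeper layer: 9 ROIs per region
through the forward model with per-ROI FF jitter (0.15%) and 1%
multiplicative Gaussian magnitude noise plus a five-echo series per
ROI. Additive/multiplicative Gaussian noise on magnitude signals is an
approximation; Rician behaviour at low SNR is out of scope.

**Known source-data inconsistency.** The published aggregate 20–50
rows do not pool from the published subgroup rows: weighting the
subgroup region means by the printed group sizes gives a 20–50 alcohol
whole-pancreas mean of 5.86% (published 6.07%) and control 2.86%
(published 2.94%). The generator follows the subgroup rows (they are
the generative units), so its pooled aggregates reproduce 5.86/2.86,
not the published aggregate cells; the corresponding reproduction
check for the alcohol aggregate fails at the ±0.10 tolerance for
exactly this reason and is intentionally left failing.

## What the synthetic experiments show — and do not

Passing tests demonstrate that (i) the estimator inverts its own
forward model exactly on its validity domain, (ii) the calibration,
aggregation and statistics stages recover the generative parameters
they are pointed at, and (iii) the test battery behaves correctly
under null and alternative structure at the study's sample sizes. They
do not validate the physics against real scanners (no field
inhomogeneity, B1/coil effects, partial volume, Rician noise, or ROI
placement variability), and agreement of synthetic cohort statistics
with published cells reflects the generator being parameterized by
those same cells, not an independent replication.

## Numerical choices

* Strict input validation raises typed errors (`SignalModelError`,
  `CalibrationError`, `RoiProtocolError`, `CohortError`, `SchemaError`
  with row numbers for tables).
* "No decay" in the T2\* fit is declared for fitted slopes ≥ −1e−12
  (flat within double precision).
* ANOVA on fully constant input returns F = 0, p = 1 instead of NaN.
* Calibration requires ≥ 3 vials with distinct predictor values.
* All simulation randomness flows from a single `numpy` Generator per
  run; identical seeds give byte-identical output tables.

## Problem sizes used in the reproduction runs

Phantom recovery averages 50 independent phantoms (15 vials × 9 ROIs
each, quantified through the full signal pipeline); cohort recovery
averages 20 cohorts of 282 subjects at region level; the abstinence
null calibration uses 100 cohorts. A full run of suite plus
reproduction script completes in well under a minute.
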
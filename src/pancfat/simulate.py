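"""Synthetic phantoms, subjects and cohorts.

Everything downstream of the scanner is testable without any imaging
data: this module generates (a) 15-level fat-water phantom tables,
(b) subject-level regional fat-fraction profiles with the group
structure of the reference male cohort (282 subjects: 142 controls and
140 alcohol-exposed, in four age bands), and (c) raw per-ROI dual-echo
signal tables produced through the forward signal model, so the entire
inversion -> calibration -> aggregation -> statistics chain can be
exercised end to end.

Generative model for a subject
------------------------------
Each region r in {caput, corpus, cauda} receives

    FF_r = m_r + rho_r * z + eta_r,   z ~ N(0,1),  eta_r ~ N(0, s_h^2)

where m_r and the marginal SDs are the group's reference parameters,
``z`` is a shared between-subject factor, ``eta_r`` independent
between-region heterogeneity with SD ``s_h``, and
``rho_r = sqrt(max(sd_r^2 - s_h^2, 0))`` so the marginal per-region SD
equals the reference value.  ``s_h`` is inflated for alcohol-exposed
subjects at or above the heterogeneity onset age (default 40 y),
reproducing the uneven fat distribution of older drinkers; negative
draws are truncated at zero (rare under defaults; counted).

Phantom model
-------------
Vial k (nominal fat concentration k%, k = 0..14) has its calculated
fat fraction fixed by inverting the stored linear law
``actual = slope * calculated + intercept``; Gaussian scatter with SD
``phantom_response_sd`` is placed on the response side (the realized
vial concentration), which keeps the refitted slope unbiased.  Placing
the scatter on the predictor instead (``noise_on="predictor"``)
attenuates the slope and is available for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import PhantomVial
from .roi import (PANCREAS_REGIONS, ROIS_PER_REGION, RoiMeasurement,
                  SubjectPancreasProfile)
from .signal_model import (IN_PHASE_PERIOD_MS, AcquisitionParams, EchoPair,
                           EchoSeries, TissueComposition, forward_dual_echo,
                           steady_state_factor, t2star_decay)

__all__ = [
    "GroupSpec",
    "CohortDesign",
    "GeneratorConfig",
    "DEFAULT_GROUP_SPECS",
    "DEFAULT_ABSTINENCE_COUNTS",
    "REFERENCE_STRATUM_MEANS",
    "default_design",
    "gen_phantom",
    "gen_subject",
    "gen_cohort",
    "gen_roi_signals",
]


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters of one age-band x exposure group."""

    age_band: str
    exposure: str
    n: int
    region_means: tuple[float, float, float]   # caput, corpus, cauda (%)
    region_sds: tuple[float, float, float]     # marginal SDs (%)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        if any(s < 0 for s in self.region_sds):
            raise ValueError("region SDs must be >= 0")

    @property
    def age_range(self) -> tuple[float, float]:
        lo, hi = self.age_band.split("-")
        return float(lo), float(hi)


#: Reference cohort: group sizes, per-region fat-fraction means and SDs
#: (percent) of the male study population, by age band and exposure.
DEFAULT_GROUP_SPECS: tuple[GroupSpec, ...] = (
    GroupSpec("20-30", "control", 32, (2.55, 2.91, 2.35), (0.42, 0.66, 0.62)),
    GroupSpec("20-30", "alcohol", 36, (4.95, 5.42, 4.51), (1.10, 1.50, 0.96)),
    GroupSpec("30-40", "control", 35, (2.54, 3.08, 3.11), (0.60, 0.77, 0.84)),
    GroupSpec("30-40", "alcohol", 31, (6.31, 7.38, 6.00), (1.42, 1.98, 1.67)),
    GroupSpec("40-50", "control", 37, (3.18, 2.81, 3.13), (0.79, 0.67, 0.63)),
    GroupSpec("40-50", "alcohol", 39, (6.20, 6.30, 5.90), (2.25, 2.15, 1.71)),
    GroupSpec("50-70", "control", 38, (5.97, 6.36, 5.75), (1.54, 1.31, 1.26)),
    GroupSpec("50-70", "alcohol", 34, (9.34, 9.26, 8.88), (3.54, 2.77, 2.88)),
)

#: Drinking-status split of the 140 alcohol-exposed subjects:
#: current drinkers / abstinent < 1 year / abstinent 1-2 years.
DEFAULT_ABSTINENCE_COUNTS: dict[str, int] = {
    "current": 79, "<1y": 31, "1-2y": 30,
}

#: Optional per-stratum whole-pancreas mean targets (%) by age band,
#: for generating cohorts with stratum-level mean differences instead
#: of the default common distribution.
REFERENCE_STRATUM_MEANS: dict[tuple[str, str], float] = {
    ("20-50", "current"): 6.38, ("20-50", "<1y"): 5.93,
    ("20-50", "1-2y"): 5.44,
    ("50-70", "current"): 8.52, ("50-70", "<1y"): 9.64,
    ("50-70", "1-2y"): 10.48,
}


@dataclass(frozen=True)
class CohortDesign:
    """Cohort composition and generative group parameters."""

    groups: tuple[GroupSpec, ...] = DEFAULT_GROUP_SPECS
    abstinence_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ABSTINENCE_COUNTS))
    stratum_means: dict[tuple[str, str], float] | None = None

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)

    @property
    def n_alcohol(self) -> int:
        return sum(g.n for g in self.groups if g.exposure == "alcohol")


def default_design() -> CohortDesign:
    """The reference cohort design (282 subjects, 8 groups)."""
    return CohortDesign()


@dataclass(frozen=True)
class GeneratorConfig:
    """Noise levels and physics constants of the generators.

    ``heterogeneity_sd`` is the baseline between-region SD (%), bounded
    above by the smallest reference region SD (0.42%) so the marginal
    per-region SDs stay at their reference values;
    ``heterogeneity_sd_exposed`` applies to alcohol-exposed subjects
    aged >= ``heterogeneity_onset_age`` and is calibrated once so the
    synthetic older drinker groups show a mean within-subject regional
    spread (dFF) in the reported 2.3-2.9% band.
    """

    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    t2_star: float = 25.0                  # ms, shared fat/water T2*
    si_noise_sd: float = 0.01              # multiplicative, pancreas ROIs
    roi_ff_jitter_sd: float = 0.15         # % FF, per-ROI within a region
    phantom_response_sd: float = 0.40      # % FF, vial-level response scatter
    phantom_si_noise_sd: float = 0.0       # multiplicative, phantom ROIs
    phantom_roi_jitter_sd: float = 0.0     # % FF, within-vial
    phantom_slope: float = 0.9679          # stored linear law
    phantom_intercept: float = -3.6064
    heterogeneity_onset_age: float = 40.0  # years
    heterogeneity_sd: float = 0.40         # % FF, baseline
    heterogeneity_sd_exposed: float = 1.35  # % FF, alcohol >= onset age

    def __post_init__(self) -> None:
        for name in ("si_noise_sd", "roi_ff_jitter_sd", "phantom_response_sd",
                     "phantom_si_noise_sd", "phantom_roi_jitter_sd",
                     "heterogeneity_sd", "heterogeneity_sd_exposed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.t2_star <= 0:
            raise ValueError("t2_star must be > 0")


def _multi_echo_series(w: float, f: float, t2_star: float,
                       params: AcquisitionParams,
                       rng: np.random.Generator | None,
                       noise_sd: float) -> EchoSeries:
    """Low-flip multi-echo magnitude signals with fat-water oscillation."""
    a = steady_state_factor(params.t1_water, params.multi_echo_tr,
                            params.multi_echo_flip)
    b = steady_state_factor(params.t1_fat, params.multi_echo_tr,
                            params.multi_echo_flip)
    signals = []
    for te in params.multi_echo_tes:
        ratio = te / IN_PHASE_PERIOD_MS
        in_phase = abs(ratio - round(ratio)) < 0.05
        base = (w * a + f * b) if in_phase else abs(w * a - f * b)
        s = base * t2star_decay(te, t2_star)
        if rng is not None and noise_sd > 0:
            s = abs(s * (1.0 + rng.normal(0.0, noise_sd)))
        signals.append(s)
    return EchoSeries(tes=params.multi_echo_tes, signals=tuple(signals))


def _roi_signals(ff_percent: float, config: GeneratorConfig,
                 rng: np.random.Generator, noise_sd: float,
                 region: str, roi_id: str, layer: int,
                 area: float) -> RoiMeasurement:
    ff = min(max(ff_percent, 0.0), 49.0) / 100.0
    comp = TissueComposition.from_fat_fraction(ff, config.t2_star)
    pair = forward_dual_echo(comp, config.acquisition)
    si_ip, si_op = pair.si_ip, pair.si_op
    if noise_sd > 0:
        si_ip = abs(si_ip * (1.0 + rng.normal(0.0, noise_sd)))
        si_op = abs(si_op * (1.0 + rng.normal(0.0, noise_sd)))
    series = _multi_echo_series(comp.water_signal_density,
                                comp.fat_signal_density, config.t2_star,
                                config.acquisition, rng, noise_sd)
    return RoiMeasurement(roi_id=roi_id, region=region, layer=layer,
                          area=area, pair=EchoPair(si_ip, si_op),
                          series=series)


def gen_phantom(config: GeneratorConfig | None = None,
                seed: int | np.random.Generator = 0,
                noise_on: str = "response") -> list[PhantomVial]:
    """Generate the 15-vial fat-water phantom (nominal 0-14% in 1% steps).

    Each vial carries 9 ROI measurements (3 layers x 3) whose dual-echo
    signals are produced by the forward model at the vial's calculated
    fat fraction; ``actual_ff`` is the realized response value (nominal
    + mixing scatter under the default ``noise_on="response"``).
    Deterministic for a given seed.
    """
    config = config or GeneratorConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if noise_on not in ("response", "predictor"):
        raise ValueError(f"noise_on must be 'response' or 'predictor', "
                         f"got {noise_on!r}")
    vials = []
    for k in range(15):
        x = (k - config.phantom_intercept) / config.phantom_slope
        y = float(k)
        scatter = rng.normal(0.0, config.phantom_response_sd) \
            if config.phantom_response_sd > 0 else 0.0
        if noise_on == "response":
            # no truncation: clamping the 0% vial's response at zero
            # would bias the refitted slope downward
            y = y + scatter
        else:
            x = max(x + scatter / abs(config.phantom_slope), 0.0)
        rois = []
        for layer in (1, 2, 3):
            for j in range(3):
                roi_ff = x
                if config.phantom_roi_jitter_sd > 0:
                    roi_ff += rng.normal(0.0, config.phantom_roi_jitter_sd)
                area = float(rng.uniform(80.0, 100.0))
                rois.append(_roi_signals(
                    roi_ff, config, rng, config.phantom_si_noise_sd,
                    region="vial", roi_id=f"vial{k:02d}_L{layer}R{j+1}",
                    layer=layer, area=area))
        vials.append(PhantomVial(vial_id=f"vial{k:02d}", actual_ff=y,
                                 nominal_ff=float(k), roi_measurements=rois))
    return vials


def _heterogeneity_sd(spec: GroupSpec, age: float,
                      config: GeneratorConfig) -> float:
    if (spec.exposure == "alcohol"
            and age >= config.heterogeneity_onset_age):
        return config.heterogeneity_sd_exposed
    return config.heterogeneity_sd


def gen_subject(spec: GroupSpec,
                seed: int | np.random.Generator = 0,
                config: GeneratorConfig | None = None,
                subject_id: str = "S0001",
                abstinence: str = "none",
                mean_shift: float = 0.0) -> SubjectPancreasProfile:
    """Draw one subject's regional fat fractions from a group spec.

    ``mean_shift`` offsets all three region means (used for per-stratum
    mean targets).  Region values are truncated at 0.
    """
    config = config or GeneratorConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lo, hi = spec.age_range
    age = float(rng.uniform(lo, hi))
    s_h = _heterogeneity_sd(spec, age, config)
    z = rng.normal()
    ffs = {}
    for region, m, sd in zip(PANCREAS_REGIONS, spec.region_means,
                             spec.region_sds):
        shared_var = sd**2 - s_h**2
        if shared_var < 0:
            warnings.warn(
                f"heterogeneity SD {s_h} exceeds region SD {sd} in "
                f"{spec.age_band}/{spec.exposure}; clamping shared part to 0",
                stacklevel=2)
            shared_var = 0.0
        ff = m + mean_shift + np.sqrt(shared_var) * z + rng.normal(0.0, s_h)
        ffs[region] = max(ff, 0.0)
    if spec.exposure == "control":
        abstinence = "none"
    return SubjectPancreasProfile(
        subject_id=subject_id, age=age, group=spec.exposure,
        abstinence=abstinence, ff_caput=ffs["caput"],
        ff_corpus=ffs["corpus"], ff_cauda=ffs["cauda"])


def _abstinence_labels(design: CohortDesign,
                       rng: np.random.Generator) -> list[str]:
    counts = dict(design.abstinence_counts)
    n_alc = design.n_alcohol
    total = sum(counts.values())
    if total != n_alc and total > 0:
        # rescale with largest remainders so the labels cover the cohort
        quotas = {s: c * n_alc / total for s, c in counts.items()}
        counts = {s: int(np.floor(q)) for s, q in quotas.items()}
        short = n_alc - sum(counts.values())
        for s in sorted(quotas, key=lambda s: quotas[s] - np.floor(quotas[s]),
                        reverse=True)[:short]:
            counts[s] += 1
    labels = [s for s, c in counts.items() for _ in range(c)]
    return [labels[i] for i in rng.permutation(len(labels))]


def gen_cohort(design: CohortDesign | None = None,
               seed: int = 0,
               config: GeneratorConfig | None = None
               ) -> list[SubjectPancreasProfile]:
    """Generate the full synthetic cohort (282 subjects under defaults).

    Alcohol-exposed subjects are assigned drinking strata by permuting
    a fixed label pool (79 current / 31 short-term / 30 long-term under
    the default design), so the stratum totals are exact while their
    distribution over age bands is random.  By default all strata share
    the group's distribution; ``design.stratum_means`` optionally
    imposes per-stratum whole-pancreas mean targets.
    """
    design = design or default_design()
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    labels = iter(_abstinence_labels(design, rng))
    profiles: list[SubjectPancreasProfile] = []
    idx = 0
    for spec in design.groups:
        if spec.n == 0:
            warnings.warn(f"group {spec.age_band}/{spec.exposure} has n=0; "
                          "absent from the cohort", stacklevel=2)
        for _ in range(spec.n):
            idx += 1
            abst = next(labels) if spec.exposure == "alcohol" else "none"
            shift = 0.0
            if design.stratum_means and spec.exposure == "alcohol":
                band = "50-70" if spec.age_band == "50-70" else "20-50"
                target = design.stratum_means.get((band, abst))
                if target is not None:
                    shift = target - float(np.mean(spec.region_means))
            profiles.append(gen_subject(
                spec, rng, config, subject_id=f"S{idx:04d}",
                abstinence=abst, mean_shift=shift))
    return profiles


def gen_roi_signals(profile: SubjectPancreasProfile,
                    config: GeneratorConfig | None = None,
                    seed: int | np.random.Generator = 0
                    ) -> list[RoiMeasurement]:
    """Raw dual-echo + multi-echo signal table for one subject (27 ROIs).

    Per region, 9 ROIs whose signals come from the forward model at the
    region's fat fraction plus per-ROI jitter, with multiplicative
    Gaussian noise on the magnitude signals.
    """
    config = config or GeneratorConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rois = []
    for region, ff in profile.region_ffs.items():
        for layer in (1, 2, 3):
            for j in range(3):
                roi_ff = ff + (rng.normal(0.0, config.roi_ff_jitter_sd)
                               if config.roi_ff_jitter_sd > 0 else 0.0)
                area = float(rng.uniform(40.0, 60.0))
                rois.append(_roi_signals(
                    roi_ff, config, rng, config.si_noise_sd, region=region,
                    roi_id=f"{profile.subject_id}_{region}_L{layer}R{j+1}",
                    layer=layer, area=area))
    assert len(rois) == 3 * ROIS_PER_REGION
    return rois
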
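"""End-to-end orchestration: signals -> fat fractions -> study report.

``quantify`` chains the per-ROI stages (T2* estimation, corrected
two-point inversion, phantom calibration, region/subject aggregation);
``run_study`` produces a full synthetic replication of the study
layout: the fat-fraction summary table, the CV table, the abstinence
table and the JSON of all group comparisons.  Every run emits a
:class:`RunManifest` so identical config + seed reproduce identical
outputs.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import cohort_stats as cs
from .calibration import CalibrationModel, PhantomVial, apply_calibration, \
    fit_calibration
from .io import profiles_to_frame, rois_to_frame
from .roi import (PANCREAS_REGIONS, RoiMeasurement, RoiProtocolError,
                  SubjectPancreasProfile, region_ff, subject_profile)
from .signal_model import AcquisitionParams, estimate_t2star, \
    fat_fraction_corrected
from .simulate import CohortDesign, GeneratorConfig, default_design, \
    gen_cohort

__all__ = [
    "RunManifest",
    "StudyReport",
    "quantify_roi",
    "quantify_subject_rois",
    "quantify_phantom",
    "run_quantify",
    "run_study",
]


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    stage: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         default=str) + "\n")


def quantify_roi(roi: RoiMeasurement,
                 params: AcquisitionParams,
                 calibration: CalibrationModel | None = None,
                 t2_star: float | None = None,
                 t2_policy: str = "in_phase") -> RoiMeasurement:
    """Fill ``ff_calculated`` / ``ff_calibrated`` (%) for one ROI.

    T2* comes from the ROI's own multi-echo series when present,
    otherwise from the ``t2_star`` argument (per-subject, per-region or
    global — the protocol does not fix the granularity).
    """
    if roi.pair is None:
        raise RoiProtocolError(f"ROI {roi.roi_id}: no dual-echo signals")
    if roi.series is not None:
        t2 = estimate_t2star(roi.series, echo_selection=t2_policy)
    elif t2_star is not None:
        t2 = t2_star
    else:
        raise RoiProtocolError(
            f"ROI {roi.roi_id}: no multi-echo series and no t2_star given")
    est = fat_fraction_corrected(roi.pair, t2, params)
    roi.ff_calculated = est.percent
    if calibration is not None:
        roi.ff_calibrated = apply_calibration(est.percent, calibration).value
    return roi


def quantify_subject_rois(
    rois: Iterable[RoiMeasurement],
    params: AcquisitionParams,
    subject_id: str,
    age: float,
    group: str,
    abstinence: str = "none",
    calibration: CalibrationModel | None = None,
    t2_star: float | None = None,
    t2_policy: str = "in_phase",
    strict: bool = True,
) -> SubjectPancreasProfile:
    """Invert, calibrate and aggregate one subject's 27 ROIs."""
    by_region: dict[str, list[RoiMeasurement]] = {}
    for roi in rois:
        quantify_roi(roi, params, calibration, t2_star, t2_policy)
        by_region.setdefault(roi.region, []).append(roi)
    region_values = {
        region: region_ff(by_region[region], strict=strict)
        for region in PANCREAS_REGIONS if region in by_region
    }
    return subject_profile(region_values, subject_id=subject_id, age=age,
                           group=group, abstinence=abstinence)


def quantify_phantom(vials: Iterable[PhantomVial],
                     params: AcquisitionParams,
                     t2_star: float | None = None,
                     t2_policy: str = "in_phase") -> list[PhantomVial]:
    """Invert all phantom ROIs and store per-vial mean calculated FF."""
    vials = list(vials)
    for vial in vials:
        for roi in vial.roi_measurements:
            quantify_roi(roi, params, calibration=None, t2_star=t2_star,
                         t2_policy=t2_policy)
        vial.calculated_ff = vial.mean_calculated_ff()
    return vials


def run_quantify(
    roi_frame: pd.DataFrame,
    params: AcquisitionParams,
    metadata: Mapping[str, Mapping] | None = None,
    calibration: CalibrationModel | None = None,
    t2_star: float | None = None,
    t2_policy: str = "in_phase",
    strict: bool = True,
) -> tuple[pd.DataFrame, RunManifest]:
    """Quantify a multi-subject ROI signal table into a profile table.

    ``metadata`` maps subject_id to ``{"age": ..., "group": ...,
    "abstinence": ...}``; absent subjects get placeholder metadata
    (age NaN is rejected downstream by the grouping stage, not here).
    """
    from .io import frame_to_rois

    t0 = time.perf_counter()
    caught: list[str] = []
    by_subject = frame_to_rois(roi_frame)
    profiles = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        for subject_id, rois in by_subject.items():
            meta = dict(metadata.get(subject_id, {})) if metadata else {}
            profiles.append(quantify_subject_rois(
                rois, params, subject_id=subject_id,
                age=float(meta.get("age", float("nan"))),
                group=str(meta.get("group", "unknown")),
                abstinence=str(meta.get("abstinence", "none")),
                calibration=calibration, t2_star=t2_star,
                t2_policy=t2_policy, strict=strict))
    caught.extend(str(w.message) for w in wlist)
    frame = profiles_to_frame(profiles)
    manifest = RunManifest(
        stage="quantify",
        config={"t2_policy": t2_policy, "t2_star": t2_star,
                "calibrated": calibration is not None,
                "strict": strict, "acquisition": asdict(params)},
        inputs={"n_rois": int(len(roi_frame))},
        outputs={"n_subjects": len(profiles)},
        timings_s={"quantify": time.perf_counter() - t0},
        warnings=caught,
    )
    return frame, manifest


@dataclass
class StudyReport:
    """All study-level outputs of a synthetic cohort run."""

    ff_summary: pd.DataFrame          # n, mean, SD per group and measure
    cv_summary: pd.DataFrame          # CV per group and measure
    abstinence_summary: pd.DataFrame  # per-stratum n, mean, SD
    comparisons: list[cs.ComparisonResult]
    manifest: RunManifest

    def comparisons_json(self) -> str:
        return json.dumps([asdict(c) for c in self.comparisons], indent=2)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ff_summary.to_csv(outdir / "fat_fraction_summary.csv",
                               index=False)
        self.cv_summary.to_csv(outdir / "cv_summary.csv", index=False)
        self.abstinence_summary.to_csv(outdir / "abstinence_summary.csv",
                                       index=False)
        (outdir / "comparisons.json").write_text(self.comparisons_json()
                                                 + "\n")
        self.manifest.write(outdir / "manifest.json")


def _group_comparisons(profiles: list[SubjectPancreasProfile],
                       summaries: list[cs.GroupSummary]
                       ) -> list[cs.ComparisonResult]:
    """Alcohol-vs-control ANOVA and CV u-tests per band and measure."""
    results: list[cs.ComparisonResult] = []
    by_key = {(s.key.age_band, s.key.exposure): s for s in summaries}
    bands = sorted({s.key.age_band for s in summaries})
    by_group: dict[tuple[str, str], list[float]] = {}
    for p in profiles:
        key = cs.assign_group(p)
        by_group.setdefault((key.age_band, p.group), []).append(p.ff_whole)
        if key.age_band in ("20-30", "30-40", "40-50"):
            by_group.setdefault(("20-50", p.group), []).append(p.ff_whole)
    for band in bands:
        ctrl = by_group.get((band, "control"), [])
        alc = by_group.get((band, "alcohol"), [])
        if len(ctrl) >= 2 and len(alc) >= 2:
            res = cs.anova_oneway(
                alc, ctrl, labels=(f"alcohol/{band}", f"control/{band}"))
            results.append(cs.ComparisonResult(
                res.test_name + " [whole FF]", res.statistic, res.p_value,
                res.groups))
        s_a = by_key.get((band, "alcohol"))
        s_c = by_key.get((band, "control"))
        if s_a and s_c:
            for m in ("caput", "corpus", "cauda", "whole"):
                results.append(cs.cv_u_test(
                    s_a.measures[m].cv, s_a.n, s_c.measures[m].cv, s_c.n,
                    labels=(f"alcohol/{band}/{m}", f"control/{band}/{m}")))
    return results


def run_study(design: CohortDesign | None = None,
              config: GeneratorConfig | None = None,
              seed: int = 0,
              outdir=None) -> StudyReport:
    """Full synthetic study: cohort generation, tables and tests.

    Deterministic under ``seed``; when ``outdir`` is given the tables,
    comparison JSON and manifest are written there.
    """
    design = design or default_design()
    config = config or GeneratorConfig()
    t0 = time.perf_counter()
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        profiles = gen_cohort(design, seed=seed, config=config)
        t_gen = time.perf_counter()
        summaries = cs.summarize_groups(profiles)
        ff_summary = cs.summary_table(summaries)
        cv_summary = cs.cv_table(summaries)
        abst_summary, abst_results = cs.compare_abstinence(profiles)
        comparisons = _group_comparisons(profiles, summaries) + abst_results
    caught.extend(str(w.message) for w in wlist)
    manifest = RunManifest(
        stage="study",
        seed=seed,
        config={"generator": asdict(config),
                "design_groups": [asdict(g) for g in design.groups],
                "abstinence_counts": design.abstinence_counts},
        outputs={"n_subjects": len(profiles),
                 "n_groups": len(summaries),
                 "n_comparisons": len(comparisons)},
        timings_s={"generate": t_gen - t0,
                   "analyze": time.perf_counter() - t_gen},
        warnings=caught,
    )
    report = StudyReport(ff_summary=ff_summary, cv_summary=cv_summary,
                         abstinence_summary=abst_summary,
                         comparisons=comparisons, manifest=manifest)
    if outdir is not None:
        report.write(outdir)
    return report


def fit_calibration_from_phantom(vials: Iterable[PhantomVial],
                                 params: AcquisitionParams,
                                 t2_star: float | None = None,
                                 t2_policy: str = "in_phase"
                                 ) -> CalibrationModel:
    """Convenience: quantify phantom ROIs then fit the calibration line."""
    return fit_calibration(quantify_phantom(vials, params, t2_star,
                                            t2_policy))
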
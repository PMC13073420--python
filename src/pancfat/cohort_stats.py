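"""Cohort-level statistics: group summaries, dispersion and tests.

Subjects are stratified by age band (20-30, 30-40, 40-50, 50-70 years;
plus a pooled 20-50 aggregate) and alcohol exposure (control /
alcohol); alcohol subjects carry an abstinence stratum (current
drinker, abstinent < 1 year, abstinent 1-2 years).  For every group and
measure (regional, whole-pancreas, dFF) the summary reports n, mean,
sample SD and the coefficient of variation CV = SD/mean, the
dimensionless dispersion measure used to compare fat-fraction
heterogeneity between groups with different mean fat levels.

Tests
-----
* one-way ANOVA for mean fat-fraction differences (scipy),
* Shapiro-Wilk normality check, used to annotate rather than to switch
  tests,
* Miller's asymptotic test for equality of two coefficients of
  variation ("u test"): with pooled CV c,

      u = (cv1 - cv2) / sqrt(c^2 (0.5 + c^2) (1/(n1-1) + 1/(n2-1))),

  referred to the standard normal (two-sided),
* two-way absolute-agreement single-measure ICC for intra-observer
  reliability of repeated readings.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .roi import SubjectPancreasProfile

__all__ = [
    "AGE_BANDS",
    "MEASURES",
    "ABSTINENCE_STRATA",
    "GroupKey",
    "GroupSummary",
    "ComparisonResult",
    "CohortError",
    "assign_group",
    "summarize_groups",
    "summary_table",
    "cv_table",
    "anova_oneway",
    "cv_u_test",
    "icc_intraobserver",
    "shapiro_wilk",
    "compare_abstinence",
]

#: Age bands as (label, low, high); bands are half-open [low, high)
#: except the last, which includes its upper bound.
AGE_BANDS = (
    ("20-30", 20.0, 30.0),
    ("30-40", 30.0, 40.0),
    ("40-50", 40.0, 50.0),
    ("50-70", 50.0, 70.0),
)
AGGREGATE_BAND = "20-50"
_AGGREGATED = ("20-30", "30-40", "40-50")

MEASURES = ("caput", "corpus", "cauda", "whole", "delta_ff")
ABSTINENCE_STRATA = ("current", "<1y", "1-2y")


class CohortError(ValueError):
    """Invalid cohort-statistics input."""


@dataclass(frozen=True)
class GroupKey:
    age_band: str
    exposure: str
    abstinence_stratum: str | None = None

    def label(self) -> str:
        parts = [self.exposure, self.age_band]
        if self.abstinence_stratum:
            parts.append(self.abstinence_stratum)
        return "/".join(parts)


@dataclass(frozen=True)
class MeasureStats:
    mean: float
    sd: float
    cv: float


@dataclass
class GroupSummary:
    """n, mean, SD and CV per measure for one subject group."""

    key: GroupKey
    n: int
    measures: dict[str, MeasureStats]
    normality_flags: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-or-more-group statistical test."""

    test_name: str
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise CohortError(f"p_value outside [0, 1]: {self.p_value}")


def assign_group(subject: SubjectPancreasProfile) -> GroupKey:
    """Deterministic age-band / exposure assignment for one subject.

    Bands are half-open on the right ([20, 30), [30, 40), [40, 50))
    with the oldest band closed ([50, 70]), so age 30 falls in 30-40
    and age 70 in 50-70.  Ages outside [20, 70] are rejected.
    """
    age = subject.age
    if not 20 <= age <= 70:
        raise CohortError(
            f"subject {subject.subject_id}: age {age} outside the cohort "
            "range [20, 70]"
        )
    band = AGE_BANDS[-1][0]
    for label, lo, hi in AGE_BANDS[:-1]:
        if lo <= age < hi:
            band = label
            break
    stratum = None
    if subject.group == "alcohol" and subject.abstinence in ABSTINENCE_STRATA:
        stratum = subject.abstinence
    return GroupKey(age_band=band, exposure=subject.group,
                    abstinence_stratum=stratum)


def _measure_values(profiles: Sequence[SubjectPancreasProfile],
                    measure: str) -> np.ndarray:
    attr = {"caput": "ff_caput", "corpus": "ff_corpus", "cauda": "ff_cauda",
            "whole": "ff_whole", "delta_ff": "delta_ff"}[measure]
    return np.array([getattr(p, attr) for p in profiles], dtype=float)


def _summary_for(key: GroupKey,
                 profiles: Sequence[SubjectPancreasProfile]) -> GroupSummary:
    measures: dict[str, MeasureStats] = {}
    normality: dict[str, float] = {}
    for m in MEASURES:
        vals = _measure_values(profiles, m)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        cv = sd / mean if mean > 0 else float("nan")
        measures[m] = MeasureStats(mean=mean, sd=sd, cv=cv)
        if 3 <= vals.size <= 5000 and np.ptp(vals) > 0:
            normality[m] = float(stats.shapiro(vals).pvalue)
    return GroupSummary(key=key, n=len(profiles), measures=measures,
                        normality_flags=normality)


def summarize_groups(
    profiles: Iterable[SubjectPancreasProfile],
    include_aggregate: bool = True,
    min_n: int = 2,
) -> list[GroupSummary]:
    """Per-group summaries (mean, sample SD, CV) for all measures.

    Groups with fewer than ``min_n`` subjects are excluded with a
    warning.  With ``include_aggregate`` the pooled 20-50 band is
    appended per exposure.
    """
    by_key: dict[GroupKey, list[SubjectPancreasProfile]] = {}
    for p in profiles:
        key = assign_group(p)
        plain = GroupKey(key.age_band, key.exposure)
        by_key.setdefault(plain, []).append(p)

    summaries: list[GroupSummary] = []
    band_order = {label: i for i, (label, _, _) in enumerate(AGE_BANDS)}
    # control listed before alcohol within each band, as published
    for key in sorted(by_key, key=lambda k: (band_order[k.age_band],
                                             k.exposure != "control")):
        members = by_key[key]
        if len(members) < min_n:
            warnings.warn(
                f"group {key.label()}: n={len(members)} < {min_n}, excluded",
                stacklevel=2,
            )
            continue
        summaries.append(_summary_for(key, members))

    if include_aggregate:
        for exposure in ("control", "alcohol"):
            pooled = list(itertools.chain.from_iterable(
                by_key.get(GroupKey(b, exposure), []) for b in _AGGREGATED
            ))
            if len(pooled) >= min_n:
                summaries.append(
                    _summary_for(GroupKey(AGGREGATE_BAND, exposure), pooled)
                )
    return summaries


def summary_table(summaries: Iterable[GroupSummary],
                  stat: str = "mean_sd") -> pd.DataFrame:
    """Render summaries as a tidy DataFrame.

    ``stat`` selects the cell content: ``"mean_sd"`` gives paired
    mean/sd columns per measure; ``"cv"`` gives the CV per measure.
    """
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "age_band": s.key.age_band,
            "exposure": s.key.exposure,
            "n": s.n,
        }
        for m, ms in s.measures.items():
            if stat == "cv":
                row[f"{m}_cv"] = ms.cv
            else:
                row[f"{m}_mean"] = ms.mean
                row[f"{m}_sd"] = ms.sd
        rows.append(row)
    return pd.DataFrame(rows)


def cv_table(summaries: Iterable[GroupSummary]) -> pd.DataFrame:
    """Coefficient-of-variation table (one CV column per measure)."""
    return summary_table(summaries, stat="cv")


def anova_oneway(*groups: Sequence[float],
                 labels: Sequence[str] | None = None) -> ComparisonResult:
    """One-way ANOVA across two or more groups of fat fractions."""
    if len(groups) < 2:
        raise CohortError("anova_oneway needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise CohortError("every group needs n >= 2")
    allvals = np.concatenate(arrays)
    if np.ptp(allvals) == 0:
        # all observations identical: no between- or within-group variance
        return ComparisonResult("one-way ANOVA", 0.0, 1.0,
                                tuple(labels or ()))
    f, p = stats.f_oneway(*arrays)
    return ComparisonResult("one-way ANOVA", float(f), float(p),
                            tuple(labels or ()))


def cv_u_test(cv1: float, n1: int, cv2: float, n2: int,
              labels: tuple[str, str] = ("group1", "group2")
              ) -> ComparisonResult:
    """Miller's asymptotic test for equality of two CVs.

    The statistic is antisymmetric in the two groups and zero (p = 1)
    when the CVs are equal.  Requires n >= 2 per group and positive
    CVs; the normal approximation is adequate at the cohort's group
    sizes (n ~ 30-40).
    """
    if n1 < 2 or n2 < 2:
        raise CohortError("cv_u_test needs n >= 2 in both groups")
    if cv1 <= 0 or cv2 <= 0:
        raise CohortError("cv_u_test needs positive CVs")
    pooled = ((n1 - 1) * cv1 + (n2 - 1) * cv2) / (n1 + n2 - 2)
    var = pooled**2 * (0.5 + pooled**2) * (1.0 / (n1 - 1) + 1.0 / (n2 - 1))
    u = (cv1 - cv2) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(u))
    return ComparisonResult("u test (CV equality)", float(u), float(p), labels)


def icc_intraobserver(ratings: np.ndarray) -> float:
    """Two-way absolute-agreement single-measure ICC, ICC(A,1).

    ``ratings`` is an (n_subjects, k_sessions) array of repeated
    readings by the same observer.  Computed from the two-way ANOVA
    mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR/MSC/MSE the row (subject), column (session) and residual
    mean squares.  Requires >= 5 subjects and >= 2 sessions.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] < 2:
        raise CohortError("ratings must be (n_subjects, k>=2 sessions)")
    n, k = r.shape
    if n < 5:
        raise CohortError(f"need >= 5 paired measurements, got {n}")
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((r - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise CohortError("degenerate ratings: zero total variance")
    return float((msr - mse) / denom)


def shapiro_wilk(values: Sequence[float]) -> ComparisonResult:
    """Shapiro-Wilk normality test (annotation only, 3 <= n <= 5000)."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise CohortError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {v.size}")
    if np.ptp(v) == 0:
        raise CohortError("Shapiro-Wilk undefined for constant input")
    w, p = stats.shapiro(v)
    return ComparisonResult("Shapiro-Wilk", float(w), float(p))


def compare_abstinence(
    profiles: Iterable[SubjectPancreasProfile],
    measure: str = "whole",
) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """Abstinence analysis of the alcohol-exposed subjects.

    Splits alcohol subjects into 20-50 and 50-70 year bands and, within
    each, summarizes the whole-pancreas fat fraction per drinking
    stratum (current / abstinent < 1 year / abstinent 1-2 years, plus a
    pooled all-abstainers column) and runs a one-way ANOVA across the
    three strata.  Empty strata are excluded with a warning; with fewer
    than two populated strata only the summary is returned.
    """
    alcohol = [p for p in profiles if p.group == "alcohol"]
    rows = []
    results: list[ComparisonResult] = []
    for band_label, lo, hi in ((AGGREGATE_BAND, 20.0, 50.0),
                               ("50-70", 50.0, 70.0)):
        members = [p for p in alcohol
                   if lo <= p.age < hi or (hi == 70.0 and p.age == 70.0)]
        if not members:
            continue
        strata_vals: dict[str, np.ndarray] = {}
        for stratum in ABSTINENCE_STRATA:
            sub = [p for p in members if p.abstinence == stratum]
            if not sub:
                warnings.warn(
                    f"abstinence stratum {stratum!r} empty in {band_label}",
                    stacklevel=2,
                )
                continue
            strata_vals[stratum] = _measure_values(sub, measure)
        abstainers = np.concatenate(
            [strata_vals[s] for s in ("<1y", "1-2y") if s in strata_vals]
        ) if any(s in strata_vals for s in ("<1y", "1-2y")) else np.array([])
        row: dict[str, object] = {"age_band": band_label,
                                  "n": len(members)}
        for name, vals in [("current", strata_vals.get("current")),
                           ("all_abstainers",
                            abstainers if abstainers.size else None),
                           ("<1y", strata_vals.get("<1y")),
                           ("1-2y", strata_vals.get("1-2y"))]:
            if vals is None:
                continue
            row[f"{name}_n"] = int(vals.size)
            row[f"{name}_mean"] = float(vals.mean())
            row[f"{name}_sd"] = (float(vals.std(ddof=1))
                                 if vals.size > 1 else float("nan"))
        rows.append(row)
        testable = {s: v for s, v in strata_vals.items() if v.size >= 2}
        if len(testable) >= 2:
            res = anova_oneway(*testable.values(),
                               labels=[f"{band_label}/{s}" for s in testable])
            results.append(res)
    return pd.DataFrame(rows), results
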
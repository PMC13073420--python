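"""Group construction, summaries and the cohort's statistical tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pancfat import (
    CohortError,
    anova_oneway,
    assign_group,
    compare_abstinence,
    cv_u_test,
    gen_cohort,
    icc_intraobserver,
    shapiro_wilk,
    summarize_groups,
)
from pancfat.cohort_stats import cv_table, summary_table
from pancfat.roi import SubjectPancreasProfile
from pancfat.simulate import CohortDesign, REFERENCE_STRATUM_MEANS


def _subject(age, group, abstinence="none", ffs=(3.0, 3.1, 2.9), sid="s"):
    return SubjectPancreasProfile(sid, age, group, ff_caput=ffs[0],
                                  ff_corpus=ffs[1], ff_cauda=ffs[2],
                                  abstinence=abstinence)


class TestAssignGroup:
    @pytest.mark.parametrize("age, band", [
        (20, "20-30"), (29.99, "20-30"), (30, "30-40"), (40, "40-50"),
        (49.9, "40-50"), (50, "50-70"), (70, "50-70"),
    ])
    def test_band_boundaries_half_open(self, age, band):
        assert assign_group(_subject(age, "control")).age_band == band

    @pytest.mark.parametrize("age", [19, 19.99, 70.01, 85])
    def test_out_of_cohort_rejected(self, age):
        with pytest.raises(CohortError, match="outside the cohort"):
            assign_group(_subject(age, "control"))

    def test_abstinence_stratum_only_for_alcohol(self):
        key = assign_group(_subject(70, "alcohol", abstinence="1-2y"))
        assert key.age_band == "50-70"
        assert key.abstinence_stratum == "1-2y"
        assert assign_group(_subject(70, "control")).abstinence_stratum is None


class TestSummarizeGroups:
    def test_mean_sd_cv_small_group(self):
        profs = [_subject(25, "control", ffs=(2.0, 2.0, 2.0), sid="a"),
                 _subject(26, "control", ffs=(4.0, 4.0, 4.0), sid="b")]
        (summary,) = [s for s in summarize_groups(profs, min_n=2)
                      if s.key.age_band == "20-30"]
        m = summary.measures["whole"]
        assert m.mean == pytest.approx(3.0)
        assert m.sd == pytest.approx(np.sqrt(2.0))       # sample SD (n-1)
        assert m.cv == pytest.approx(np.sqrt(2.0) / 3.0)

    def test_cv_scale_invariance(self, rng):
        vals = rng.uniform(2, 8, 12)
        profs = [_subject(25, "control", ffs=(v, v, v), sid=str(i))
                 for i, v in enumerate(vals)]
        profs10 = [_subject(25, "control", ffs=(10 * v, 10 * v, 10 * v),
                            sid=str(i)) for i, v in enumerate(vals)]
        cv1 = summarize_groups(profs)[0].measures["whole"].cv
        cv2 = summarize_groups(profs10)[0].measures["whole"].cv
        assert cv1 == pytest.approx(cv2, rel=1e-12)

    def test_small_groups_excluded_with_warning(self):
        profs = [_subject(25, "control", sid="a"),
                 _subject(55, "control", sid="b"),
                 _subject(56, "control", sid="c")]
        with pytest.warns(UserWarning, match="excluded"):
            summaries = summarize_groups(profs, include_aggregate=False)
        assert [s.key.age_band for s in summaries] == ["50-70"]

    def test_aggregate_band_pools_younger_groups(self):
        profs = ([_subject(25, "control", ffs=(2, 2, 2), sid=f"a{i}")
                  for i in range(3)]
                 + [_subject(45, "control", ffs=(4, 4, 4), sid=f"b{i}")
                    for i in range(3)])
        summaries = summarize_groups(profs)
        agg = [s for s in summaries if s.key.age_band == "20-50"]
        assert len(agg) == 1
        assert agg[0].n == 6
        assert agg[0].measures["whole"].mean == pytest.approx(3.0)

    def test_tables_have_one_row_per_group(self):
        profiles = gen_cohort(seed=0)
        summaries = summarize_groups(profiles)
        table = summary_table(summaries)
        cvs = cv_table(summaries)
        assert len(table) == len(cvs) == 10   # 8 primary + 2 aggregates
        assert {"whole_mean", "whole_sd", "n"} <= set(table.columns)
        assert "whole_cv" in cvs.columns


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        res = anova_oneway([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_constant_everything_handled(self):
        res = anova_oneway([2.0, 2.0], [2.0, 2.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_brute_force_sum_of_squares(self, rng):
        # independent oracle: explicit between/within decomposition
        for _ in range(20):
            groups = [rng.normal(rng.uniform(0, 3), 1.0,
                                 rng.integers(3, 12)) for _ in range(3)]
            allv = np.concatenate(groups)
            grand = allv.mean()
            ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            dfb, dfw = len(groups) - 1, allv.size - len(groups)
            f_oracle = (ssb / dfb) / (ssw / dfw)
            p_oracle = stats.f.sf(f_oracle, dfb, dfw)
            res = anova_oneway(*groups)
            assert res.statistic == pytest.approx(f_oracle, abs=1e-10)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_two_group_f_equals_t_squared(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 15))
            b = rng.normal(0.5, 1, rng.integers(3, 15))
            f = anova_oneway(a, b).statistic
            t = stats.ttest_ind(a, b).statistic
            assert f == pytest.approx(t**2, abs=1e-9)

    def test_degenerate_group_sizes_rejected(self):
        with pytest.raises(CohortError):
            anova_oneway([1.0], [2.0, 3.0])
        with pytest.raises(CohortError):
            anova_oneway([1.0, 2.0])


class TestCvUTest:
    def test_equal_cvs_give_zero_statistic(self):
        res = cv_u_test(0.25, 30, 0.25, 40)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_antisymmetry(self):
        r1 = cv_u_test(0.342, 39, 0.238, 37)
        r2 = cv_u_test(0.238, 37, 0.342, 39)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_older_drinker_corpus_cell_is_significant(self):
        # CVs and ns of the 40-50y corpus comparison
        res = cv_u_test(0.342, 39, 0.238, 37)
        assert res.p_value < 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(CohortError):
            cv_u_test(0.3, 1, 0.2, 10)
        with pytest.raises(CohortError):
            cv_u_test(0.0, 10, 0.2, 10)


class TestICC:
    def test_identical_repeats_give_one(self, rng):
        truth = rng.uniform(2, 10, 20)
        ratings = np.column_stack([truth, truth])
        assert icc_intraobserver(ratings) == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_near_zero(self, rng):
        ratings = rng.normal(5, 1, (4000, 2))
        assert abs(icc_intraobserver(ratings)) < 0.05

    def test_small_reread_error_gives_excellent_reliability(self, rng):
        # repeated readings = truth + noise at 5% of between-subject SD
        truth = rng.normal(5, 2, 200)
        ratings = np.column_stack([truth + rng.normal(0, 0.1, 200),
                                   truth + rng.normal(0, 0.1, 200)])
        icc = icc_intraobserver(ratings)
        assert icc > 0.90
        # variance-component oracle: sb^2 / (sb^2 + se^2)
        assert icc == pytest.approx(4.0 / (4.0 + 0.01), abs=0.01)

    def test_matches_pingouin_two_way_absolute_single(self, rng):
        pingouin = pytest.importorskip("pingouin")
        data = rng.normal(5, 2, (30, 1)) + rng.normal(0, 0.8, (30, 2))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(30), 2),
            "session": np.tile([0, 1], 30),
            "score": data.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject",
                                       raters="session", ratings="score")
        ref_val = float(
            ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0])
        assert icc_intraobserver(data) == pytest.approx(ref_val, abs=1e-9)

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(CohortError):
            icc_intraobserver(rng.normal(0, 1, (4, 2)))


class TestShapiroWilk:
    def test_gaussian_samples_rarely_rejected(self):
        hits = 0
        for s in range(100):
            v = np.random.default_rng(s).normal(5, 1, 100)
            if shapiro_wilk(v).p_value > 0.05:
                hits += 1
        assert hits >= 90

    def test_heavy_tails_rejected(self):
        v = stats.cauchy.rvs(size=100,
                             random_state=np.random.default_rng(42))
        assert shapiro_wilk(v).p_value < 0.05

    def test_constant_and_bad_sizes_rejected(self):
        with pytest.raises(CohortError):
            shapiro_wilk([1.0, 1.0, 1.0])
        with pytest.raises(CohortError):
            shapiro_wilk([1.0, 2.0])


class TestCompareAbstinence:
    def test_structure_on_default_cohort(self):
        table, results = compare_abstinence(gen_cohort(seed=3))
        assert set(table["age_band"]) == {"20-50", "50-70"}
        assert {"current_n", "current_mean", "all_abstainers_mean",
                "<1y_mean", "1-2y_mean"} <= set(table.columns)
        assert len(results) == 2      # one ANOVA per age band
        assert all(0 <= r.p_value <= 1 for r in results)

    def test_single_stratum_gives_summary_only(self):
        profs = [_subject(30 + i, "alcohol", abstinence="current",
                          ffs=(5 + 0.1 * i,) * 3, sid=str(i))
                 for i in range(6)]
        with pytest.warns(UserWarning, match="empty"):
            table, results = compare_abstinence(profs)
        assert len(table) == 1
        assert results == []

    def test_stratum_mean_targets_are_recovered(self):
        # cohort generated with per-stratum mean separation
        design = CohortDesign(stratum_means=dict(REFERENCE_STRATUM_MEANS))
        means = {k: [] for k in REFERENCE_STRATUM_MEANS}
        nseeds = 10
        for s in range(nseeds):
            table, _ = compare_abstinence(gen_cohort(design, seed=s))
            row = table.set_index("age_band")
            for (band, stratum), target in REFERENCE_STRATUM_MEANS.items():
                col = {"current": "current_mean", "<1y": "<1y_mean",
                       "1-2y": "1-2y_mean"}[stratum]
                means[(band, stratum)].append(row.loc[band, col])
        for key, target in REFERENCE_STRATUM_MEANS.items():
            vals = np.asarray(means[key], dtype=float)
            se = vals.std(ddof=1) / np.sqrt(nseeds)
            assert np.mean(vals) == pytest.approx(target, abs=3 * se + 0.05)
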
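"""Case-cohort machinery: outcome algebra, quintiles, weighting,
logistic fits, trend/continuous models, stratified analyses."""

import numpy as np
import pandas as pd
import pytest

from placentax import casecohort as cc


def _flags(subjects, on):
    df = pd.DataFrame(False, index=subjects,
                      columns=[f"flag_{g}" for g in "abcdefghij"])
    for subj, groups in on.items():
        for g in groups:
            df.loc[subj, f"flag_{g}"] = True
    return df


class TestOutcomeAlgebra:
    def test_single_group_i_at_term_is_pe_only(self):
        flags = _flags(["s1"], {"s1": "i"})
        out = cc.derive_outcomes(flags, pd.Series({"s1": True}))
        assert bool(out.loc["s1", "PE"]) and not bool(out.loc["s1", "FGR"])

    def test_union_counted_once(self):
        flags = _flags(["s1"], {"s1": "gj"})
        out = cc.derive_outcomes(flags, pd.Series({"s1": True}))
        assert int(out["FGR"].sum()) == 1

    def test_preterm_excluded(self):
        flags = _flags(["s1"], {"s1": "f"})
        out = cc.derive_outcomes(flags, pd.Series({"s1": False}))
        assert not out.loc["s1"].any()

    def test_pe_and_fgr_can_cooccur(self):
        flags = _flags(["s1"], {"s1": "fg"})
        out = cc.derive_outcomes(flags, pd.Series({"s1": True}))
        assert out.loc["s1"].all()


class TestQuintiles:
    def test_midpoint_value_in_third_quintile(self):
        cuts = cc.compute_quintiles(np.arange(1, 101))
        assert cc.assign_quintile([50], cuts)[0] == 3

    def test_extremes(self):
        cuts = cc.compute_quintiles(np.arange(1, 101))
        assert cc.assign_quintile([-5], cuts)[0] == 1
        assert cc.assign_quintile([1000], cuts)[0] == 5

    def test_value_on_cut_goes_to_lower_quintile(self):
        cuts = cc.compute_quintiles(np.arange(1, 101))
        assert cc.assign_quintile([cuts[0]], cuts)[0] == 1
        assert cc.assign_quintile([cuts[3]], cuts)[0] == 4

    def test_constant_values_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            cc.compute_quintiles(np.ones(50))

    def test_each_quintile_holds_a_fifth_of_noncases(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5000)
        cuts = cc.compute_quintiles(x)
        q = cc.assign_quintile(x, cuts)
        shares = np.bincount(q)[1:6] / len(x)
        np.testing.assert_allclose(shares, 0.2, atol=0.01)


class TestWeightedProportion:
    def test_weight_one_is_raw_proportion(self):
        assert cc.weighted_case_proportion(10, 30, 1.0) == \
            pytest.approx(0.25)

    def test_study_scale_weight(self):
        w = cc.sampling_weight(4177, 325)
        assert cc.weighted_case_proportion(10, 50, w) == \
            pytest.approx(10 / (10 + 50 * w))

    def test_zero_cases_zero(self):
        assert cc.weighted_case_proportion(0, 50, 12.85) == 0.0

    def test_both_zero_missing(self):
        assert np.isnan(cc.weighted_case_proportion(0, 0, 12.85))


class TestLogistic:
    def test_two_by_two_matches_cross_product_ratio(self):
        # 20/80 exposed, 10/90 unexposed: OR = (20*90)/(80*10) = 2.25
        y = np.array([1] * 20 + [0] * 80 + [1] * 10 + [0] * 90)
        x = np.array([1.0] * 100 + [0.0] * 100)
        design = pd.DataFrame({"const": 1.0, "x": x})
        fit = cc.fit_logistic(y, design)
        assert np.exp(fit.coef("x")) == pytest.approx(2.25, abs=1e-8)

    def test_intercept_only_recovers_prevalence(self):
        y = np.array([1] * 30 + [0] * 70)
        design = pd.DataFrame({"const": np.ones(100)})
        fit = cc.fit_logistic(y, design)
        assert 1 / (1 + np.exp(-fit.coef("const"))) == pytest.approx(0.3,
                                                                     abs=1e-8)

    def test_null_association_or_near_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20000)
        y = rng.random(20000) < 0.2
        fit = cc.fit_logistic(y.astype(int),
                              pd.DataFrame({"const": 1.0, "x": x}))
        assert np.exp(fit.coef("x")) == pytest.approx(1.0, abs=0.05)

    def test_perfect_separation_detected(self):
        x = np.concatenate([np.ones(20), np.zeros(20)])
        y = x.copy()
        with pytest.raises(cc.SeparationError):
            cc.fit_logistic(y, pd.DataFrame({"const": 1.0, "x": x}))

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        design = pd.DataFrame({"const": 1.0, "x": x, "x_copy": x})
        y = (rng.random(50) < 0.5).astype(int)
        with pytest.raises(ValueError, match="x_copy"):
            cc.fit_logistic(y, design)


def _simulated_association(seed, slope=0.6, n=4000, prevalence_logit=-3.0):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(prevalence_logit + slope * z)))
    y = rng.random(n) < p
    idx = pd.Index([f"s{i}" for i in range(n)])
    return (pd.Series(y, index=idx, name="case"),
            pd.Series(z, index=idx))


class TestTrendAndContinuous:
    def test_planted_slope_recovered_with_ci(self):
        y, z = _simulated_association(11)
        cuts = cc.compute_quintiles(z[~y].to_numpy())
        q = pd.Series(cc.assign_quintile(z.to_numpy(), cuts), index=z.index)
        res = cc.trend_and_continuous_analysis(y, q, z)
        orr, lo, hi = res.continuous_or
        assert lo < np.exp(0.6) < hi
        assert res.trend_or > 1 and res.trend_p < 1e-6

    def test_opposite_signs_straddle_one(self):
        y1, z = _simulated_association(12, slope=0.6)
        rng = np.random.default_rng(13)
        p = 1 / (1 + np.exp(-(-3.0 - 0.6 * z)))
        y2 = pd.Series(rng.random(len(z)) < p, index=z.index, name="case2")
        cuts = cc.compute_quintiles(z[~y1].to_numpy())
        q = pd.Series(cc.assign_quintile(z.to_numpy(), cuts), index=z.index)
        r1 = cc.trend_and_continuous_analysis(y1, q, z)
        r2 = cc.trend_and_continuous_analysis(y2, q, z)
        assert r1.continuous_or[0] > 1 > r2.continuous_or[0]

    def test_weighted_proportions_use_weight(self):
        y, z = _simulated_association(14)
        cuts = cc.compute_quintiles(z[~y].to_numpy())
        q = pd.Series(cc.assign_quintile(z.to_numpy(), cuts), index=z.index)
        res = cc.trend_and_continuous_analysis(y, q, z, weight=12.85)
        k = 3
        expect = cc.weighted_case_proportion(
            res.quintile_case_counts[k], res.quintile_noncase_counts[k],
            12.85)
        assert res.weighted_proportions[k] == pytest.approx(expect)

    def test_covariate_adjustment_runs_and_reports_both(self):
        y, z = _simulated_association(15)
        rng = np.random.default_rng(151)
        cov = pd.DataFrame({
            "age": rng.normal(30, 4, len(z)),
            "smoker": rng.random(len(z)) < 0.1,
            "ethnicity": rng.choice(["a", "b", "c"], len(z)),
        }, index=z.index)
        cuts = cc.compute_quintiles(z[~y].to_numpy())
        q = pd.Series(cc.assign_quintile(z.to_numpy(), cuts), index=z.index)
        res = cc.trend_and_continuous_analysis(y, q, z, covariates=cov)
        assert res.adjusted_or is not None
        assert res.continuous_or[0] == pytest.approx(res.adjusted_or[0],
                                                     rel=0.15)

    def test_mostly_missing_covariate_rejected(self):
        y, z = _simulated_association(16, n=500)
        cov = pd.DataFrame({"bad": np.full(len(z), np.nan)}, index=z.index)
        cov.iloc[:100, 0] = 1.0
        cuts = cc.compute_quintiles(z[~y].to_numpy())
        q = pd.Series(cc.assign_quintile(z.to_numpy(), cuts), index=z.index)
        with pytest.raises(ValueError, match="bad"):
            cc.trend_and_continuous_analysis(y, q, z, covariates=cov)

    def test_permuted_exposure_trend_p_uniform(self):
        from scipy import stats
        y, z = _simulated_association(17, slope=0.0, n=1500)
        rng = np.random.default_rng(18)
        cuts = cc.compute_quintiles(z[~y].to_numpy())
        ps = []
        for _ in range(100):
            zp = pd.Series(rng.permutation(z.to_numpy()), index=z.index)
            q = pd.Series(cc.assign_quintile(zp.to_numpy(), cuts),
                          index=z.index)
            ps.append(cc.trend_and_continuous_analysis(y, q, zp).trend_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestStratified:
    def test_strata_counts_partition_outcome(self):
        y, z = _simulated_association(19)
        rng = np.random.default_rng(19)
        lab = pd.Series(rng.choice(["s1", "s2"], len(z)), index=z.index)
        strata = {s: y & (lab == s) for s in ("s1", "s2")}
        res = cc.stratified_analysis(strata, ~y, z)
        assert res["n_cases"].sum() == int(y.sum())

    def test_overlapping_strata_rejected(self):
        y, z = _simulated_association(20, n=500)
        with pytest.raises(ValueError, match="mutually exclusive"):
            cc.stratified_analysis({"a": y, "b": y}, ~y, z)

    def test_empty_stratum_missing_or_no_crash(self):
        y, z = _simulated_association(21, n=500)
        strata = {"real": y, "empty": pd.Series(False, index=z.index)}
        res = cc.stratified_analysis(strata, ~y, z)
        assert np.isnan(res.loc["empty", "odds_ratio"])
        assert np.isfinite(res.loc["real", "odds_ratio"])

    def test_small_stratum_flagged(self):
        y, z = _simulated_association(22, n=2000, prevalence_logit=-3.0)
        small = y & (np.arange(len(y)) < np.flatnonzero(y.to_numpy())[3] + 1)
        rest = y & ~small
        res = cc.stratified_analysis({"small": small, "rest": rest}, ~y, z)
        assert bool(res.loc["small", "low_n"])

    def test_stronger_planted_stratum_has_larger_log_or(self):
        rng = np.random.default_rng(23)
        n = 20000
        z = pd.Series(rng.normal(size=n),
                      index=[f"s{i}" for i in range(n)])
        p_strong = 1 / (1 + np.exp(-(-4.0 + 1.0 * z)))
        p_weak = 1 / (1 + np.exp(-(-4.0 + 0.3 * z)))
        y_strong = pd.Series(rng.random(n) < p_strong, index=z.index)
        y_weak = pd.Series(rng.random(n) < p_weak, index=z.index) & ~y_strong
        controls = ~(y_strong | y_weak)
        res = cc.stratified_analysis(
            {"strong": y_strong, "weak": y_weak}, controls, z)
        assert abs(np.log(res.loc["strong", "odds_ratio"])) > \
            abs(np.log(res.loc["weak", "odds_ratio"]))


class TestStudyAccounting:
    def test_cohort_after_exclusions(self):
        assert cc.cohort_size_after_exclusions(4212, (29, 6)) == 4177

    def test_sampling_weight_value(self):
        assert cc.sampling_weight(4177, 325) == pytest.approx(12.852, abs=0.01)
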
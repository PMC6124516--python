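"""Sex-bias calling: size factors, NB Wald test, BH scope, enrichment,
cross-tissue partition."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from placentax import expression as ex
from placentax.simulate import SimulationConfig, simulate_expression


def bh_stepup_oracle(pvals):
    """Independent brute-force BH step-up: adj_(k) = min_{j>=k} n p_(j)/j."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = min(running, 1.0)
    return adj


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric tail summation."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    pmfs = {x: stats.hypergeom.pmf(x, n, row1, col1) for x in range(lo, hi + 1)}
    p_obs = pmfs[a]
    return float(sum(v for v in pmfs.values() if v <= p_obs * (1 + 1e-9)))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 100, 5], "s2": [10, 100, 5]})
        sf = ex.estimate_size_factors(counts)
        np.testing.assert_allclose(sf, [1.0, 1.0])

    def test_doubled_column_doubles_factor(self):
        counts = pd.DataFrame({"a": [10, 100, 5], "b": [20, 200, 10]})
        sf = ex.estimate_size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_median_of_ratios_hand_example(self):
        # geometric means (12.599, 125.99, 6.300); every per-gene ratio
        # row is proportional to (1, 2, 1)
        counts = pd.DataFrame([[10, 20, 10], [100, 200, 100], [5, 10, 5]],
                              columns=["a", "b", "c"])
        sf = ex.estimate_size_factors(counts)
        ratio = sf / sf["a"]
        np.testing.assert_allclose(ratio, [1.0, 2.0, 1.0], rtol=1e-12)

    def test_all_zero_matrix_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            ex.estimate_size_factors(pd.DataFrame({"a": [0, 0], "b": [0, 0]}))


class TestSexBiasTest:
    def _sex(self, nf, nm):
        idx = [f"F{i}" for i in range(nf)] + [f"M{i}" for i in range(nm)]
        return pd.Series(["F"] * nf + ["M"] * nm, index=idx), idx

    def test_constant_gene_has_unit_fc_and_p_one(self):
        sex, idx = self._sex(4, 4)
        counts = pd.DataFrame([[50] * 8], columns=idx)
        sf = pd.Series(1.0, index=idx)
        t = ex.test_sex_bias(counts, sf, sex)
        assert t["fc_female_over_male"].iloc[0] == pytest.approx(1.0)
        assert t["raw_p"].iloc[0] == pytest.approx(1.0)

    def test_all_zero_gene_convention(self):
        sex, idx = self._sex(3, 3)
        counts = pd.DataFrame([[0] * 6], columns=idx)
        sf = pd.Series(1.0, index=idx)
        t = ex.test_sex_bias(counts, sf, sex)
        assert t["fc_female_over_male"].iloc[0] == 1.0
        assert t["raw_p"].iloc[0] == 1.0

    def test_planted_twofold_excess_is_highly_significant(self):
        rng = np.random.default_rng(3)
        nf = nm = 60
        sex, idx = self._sex(nf, nm)
        mu = np.array([200.0] * nf + [100.0] * nm)
        r = 1 / 0.02
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu), size=(5, nf + nm)),
            columns=idx)
        sf = pd.Series(1.0, index=idx)
        t = ex.test_sex_bias(counts, sf, sex)
        assert (t["raw_p"] < 1e-6).all()
        assert t["fc_female_over_male"].between(1.7, 2.3).all()

    def test_single_sex_input_names_missing_sex(self):
        counts = pd.DataFrame([[1, 2]], columns=["F1", "F2"])
        sex = pd.Series(["F", "F"], index=["F1", "F2"])
        with pytest.raises(ValueError, match="'M'"):
            ex.test_sex_bias(counts, pd.Series(1.0, index=counts.columns), sex)

    def test_sex_label_swap_inverts_fold_changes(self, small_expression):
        cm, _ = small_expression
        sf = ex.estimate_size_factors(cm.counts)
        t1 = ex.test_sex_bias(cm.counts, sf, cm.sex)
        swapped = cm.sex.map({"F": "M", "M": "F"})
        t2 = ex.test_sex_bias(cm.counts, sf, swapped)
        np.testing.assert_allclose(
            t1["fc_female_over_male"], 1.0 / t2["fc_female_over_male"],
            rtol=1e-9)
        np.testing.assert_allclose(t1["raw_p"], t2["raw_p"], atol=1e-9)


class TestCalling:
    def _table(self, raw_p, mean=100.0, fc=1.5):
        n = len(raw_p)
        genes = [f"g{i}" for i in range(n)]
        ann = pd.DataFrame({"gene_id": genes, "chromosome": "chrX",
                            "tss": np.arange(n) * 2000 + 5000, "strand": "+",
                            "known_xci_status": "unknown"})
        table = pd.DataFrame({
            "mean_normalized_count": mean,
            "fc_female_over_male": fc,
            "log2_fc_female_over_male": np.log2(fc),
            "raw_p": raw_p}, index=genes)
        return table, ann

    def test_bh_hand_example_and_cut(self):
        table, ann = self._table([0.001, 0.004, 0.02, 0.03, 0.9])
        calls = ex.call_sex_biased(table, ann)
        np.testing.assert_allclose(
            calls["adjusted_p"], [0.005, 0.010, 1 / 30, 0.0375, 0.9],
            rtol=1e-9)
        assert list(calls["bias_call"]) == ["female", "none", "none", "none",
                                            "none"]

    def test_mean_filter_blocks_call(self):
        table, ann = self._table([0.001], mean=9.0)
        calls = ex.call_sex_biased(table, ann)
        assert calls["bias_call"].iloc[0] == "none"

    def test_fc_within_ten_percent_not_called(self):
        table, ann = self._table([1e-6], fc=1.05)
        calls = ex.call_sex_biased(table, ann)
        assert calls["bias_call"].iloc[0] == "none"

    def test_male_call_uses_reciprocal_threshold(self):
        table, ann = self._table([1e-6], fc=1 / 1.5)
        calls = ex.call_sex_biased(table, ann)
        assert calls["bias_call"].iloc[0] == "male"

    def test_empty_chromosome_set_errors(self):
        table, ann = self._table([0.5])
        with pytest.raises(ValueError, match="chr7"):
            ex.call_sex_biased(table, ann, chromosome="chr7")

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0,
                              allow_nan=False), min_size=1, max_size=8))
    def test_bh_matches_stepup_oracle(self, pvals):
        table, ann = self._table(pvals)
        calls = ex.call_sex_biased(table, ann)
        np.testing.assert_allclose(calls["adjusted_p"],
                                   bh_stepup_oracle(pvals), rtol=1e-9)

    def test_bh_all_permutations_of_fixed_pvals(self):
        base = [0.001, 0.01, 0.02, 0.04, 0.2, 0.5]
        for perm in itertools.permutations(base):
            table, ann = self._table(list(perm))
            calls = ex.call_sex_biased(table, ann)
            np.testing.assert_allclose(calls["adjusted_p"],
                                       bh_stepup_oracle(perm), rtol=1e-9)


class TestEnrichment:
    def _calls(self, x_biased, x_total, a_biased, a_total):
        rows = []
        for i in range(x_total):
            rows.append({"chromosome": "chrX",
                         "bias_call": "female" if i < x_biased else "none"})
        for i in range(a_total):
            rows.append({"chromosome": "chr1",
                         "bias_call": "female" if i < a_biased else "none"})
        return pd.DataFrame(rows)

    def test_no_biased_genes_gives_p_one(self):
        with pytest.warns(UserWarning):
            p, orr = ex.chromosome_enrichment_test(self._calls(0, 10, 0, 100))
        assert p == 1.0

    def test_proportional_bias_gives_or_one(self):
        p, orr = ex.chromosome_enrichment_test(self._calls(2, 20, 10, 100))
        assert orr == pytest.approx(1.0)

    def test_against_enumeration_oracle(self):
        calls = self._calls(8, 100, 20, 10000)
        p, _ = ex.chromosome_enrichment_test(calls)
        assert p == pytest.approx(fisher_enumeration_oracle(8, 92, 20, 9980),
                                  rel=1e-8)

    def test_y_genes_excluded(self):
        calls = self._calls(2, 20, 10, 100)
        y = pd.DataFrame({"chromosome": ["chrY"] * 5,
                          "bias_call": ["male"] * 5})
        p1, _ = ex.chromosome_enrichment_test(calls)
        p2, _ = ex.chromosome_enrichment_test(pd.concat([calls, y]))
        assert p1 == p2


class TestCrossTissue:
    def _calls(self, genes, biased):
        return pd.DataFrame(
            {"bias_call": ["female" if g in biased else "none"
                           for g in genes]}, index=genes)

    def test_zero_other_tissues_all_specific(self):
        pl = self._calls(["g1", "g2", "g3"], {"g1", "g2"})
        part = ex.cross_tissue_female_bias(pl, [])
        assert sorted(part["placenta_specific"]) == ["g1", "g2"]
        assert part["common"] == []

    def test_one_of_many_tissues_makes_common(self):
        pl = self._calls(["g1", "g2"], {"g1", "g2"})
        others = [self._calls(["g1", "g2"], set()) for _ in range(18)]
        others.append(self._calls(["g1", "g2"], {"g2"}))
        part = ex.cross_tissue_female_bias(pl, others)
        assert part["placenta_specific"] == ["g1"]
        assert part["common"] == ["g2"]

    def test_partition_is_exhaustive_and_disjoint(self):
        pl = self._calls(list("abcde"), {"a", "b", "c"})
        others = [self._calls(list("abcde"), {"b"})]
        part = ex.cross_tissue_female_bias(pl, others)
        got = sorted(part["placenta_specific"] + part["common"])
        assert got == ["a", "b", "c"]
        assert not set(part["placenta_specific"]) & set(part["common"])

    def test_uncalled_tissue_table_rejected(self):
        pl = self._calls(["g1"], {"g1"})
        with pytest.raises(ValueError, match="bias_call"):
            ex.cross_tissue_female_bias(pl, [pd.DataFrame({"x": [1]})])


class TestPlantedRecovery:
    def test_escape_fold_one_means_no_planted_ratio(self):
        cfg = SimulationConfig(n_autosomal=50, n_x_genes=200, n_y_genes=5,
                               n_female=60, n_male=60, escape_fold=1.0001,
                               escape_fraction=0.5, nb_dispersion=0.05)
        cm, truth = simulate_expression(cfg, seed=5)
        esc = truth.category.index[truth.category.str.startswith("escaped")]
        f = cm.counts.loc[esc, cm.sex == "F"].mean(axis=1)
        m = cm.counts.loc[esc, cm.sex == "M"].mean(axis=1)
        assert (f.mean() / m.mean()) == pytest.approx(1.0, abs=0.05)

    def test_escape_fold_recovered_within_sampling_error(self):
        cfg = SimulationConfig(n_autosomal=50, n_x_genes=200, n_y_genes=5,
                               n_female=60, n_male=60, escape_fold=1.5,
                               escape_fraction=0.5, nb_dispersion=0.05)
        cm, truth = simulate_expression(cfg, seed=7)
        esc = truth.category.index[truth.category.str.startswith("escaped")]
        f = cm.counts.loc[esc, cm.sex == "F"].mean(axis=1)
        m = cm.counts.loc[esc, cm.sex == "M"].mean(axis=1)
        ratios = f / m
        assert 1.35 < ratios.mean() < 1.65
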
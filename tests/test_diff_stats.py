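"""Permutation machinery, adjustment, and differential-calling tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from platesplice.annotation_io import QuantTable
from platesplice.diff_stats import (
    DiffTestConfig,
    adjust_p,
    call_differential_introns,
    call_differential_proteins,
    exact_permutation_test,
    introns_per_gene_summary,
    log2_median_summary,
    permutation_test,
    removed_introns,
)

SAMPLES = [f"CTRL_{i}" for i in (1, 2, 3)] + [f"COLL_{i}" for i in (1, 2, 3)]
GROUPS = {s: s.rsplit("_", 1)[0] for s in SAMPLES}


def quant_table(values: np.ndarray, ids=None) -> QuantTable:
    ids = ids or [f"P{i}" for i in range(len(values))]
    return QuantTable(pd.DataFrame(values, index=ids, columns=SAMPLES), GROUPS)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

class TestLog2MedianSummary:
    def test_constant_values(self):
        t = quant_table(np.array([[4.0, 4, 4, 1, 1, 1]]))
        assert log2_median_summary(t, "CTRL").iloc[0] == pytest.approx(2.0)

    def test_median_of_unequal_values(self):
        t = quant_table(np.array([[2.0, 4, 8, 1, 1, 1]]))
        assert log2_median_summary(t, "CTRL").iloc[0] == pytest.approx(2.0)

    def test_zero_intensity_is_an_error(self):
        t = quant_table(np.array([[0.0, 4, 4, 1, 1, 1]]))
        with pytest.raises(ValueError, match="P0"):
            log2_median_summary(t, "CTRL")


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        X = pd.DataFrame([[5.0] * 6, [2.0] * 6], columns=SAMPLES)
        res = permutation_test(X, GROUPS, "COLL", "CTRL",
                               DiffTestConfig(n_perm=200, seed=0))
        assert (res["p_perm"] == 1.0).all()

    def test_exhaustive_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(0, 1, (6, 6)), columns=SAMPLES)
        res = exact_permutation_test(X, GROUPS, "COLL", "CTRL", s0=0.0)
        M = X.to_numpy()
        for j in range(len(M)):
            t_obs = abs(ss.ttest_ind(M[j, 3:], M[j, :3]).statistic)
            count = 0
            for combo in itertools.combinations(range(6), 3):
                a = list(combo)
                b = [i for i in range(6) if i not in combo]
                t = abs(ss.ttest_ind(M[j, a], M[j, b]).statistic)
                count += bool(t >= t_obs or np.isclose(t, t_obs))
            assert res["p_perm"].iloc[j] == pytest.approx(count / 20)

    def test_null_p_values_are_approximately_uniform(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(0, 1, (1000, 6)), columns=SAMPLES)
        res = permutation_test(X, GROUPS, "COLL", "CTRL",
                               DiffTestConfig(n_perm=1000, seed=5))
        assert ss.kstest(res["p_perm"], "uniform").pvalue > 0.01

    def test_invariant_to_group_swap(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(0, 1, (20, 6)), columns=SAMPLES)
        cfg = DiffTestConfig(n_perm=300, seed=9)
        ab = permutation_test(X, GROUPS, "COLL", "CTRL", cfg)
        ba = permutation_test(X, GROUPS, "CTRL", "COLL", cfg)
        assert np.allclose(ab["p_perm"], ba["p_perm"])
        assert np.allclose(ab["t_stat"], -ba["t_stat"])

    def test_small_group_is_an_error(self):
        X = pd.DataFrame([[1.0] * 4], columns=SAMPLES[:4])
        groups = {s: GROUPS[s] for s in SAMPLES[:4]}
        groups["CTRL_3"] = "CTRL"
        with pytest.raises(ValueError):
            permutation_test(X[["CTRL_1", "CTRL_2", "COLL_1"]],
                             {"CTRL_1": "CTRL", "CTRL_2": "CTRL", "COLL_1": "COLL"},
                             "COLL", "CTRL", DiffTestConfig(n_perm=10))


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------

class TestAdjustP:
    def test_bonferroni_multiplies_by_m(self):
        assert adjust_p([0.001] + [1.0] * 9, "bonferroni")[0] == pytest.approx(0.01)

    def test_bh_step_up_example(self):
        assert np.allclose(adjust_p([0.01, 0.02, 0.03, 0.04], "bh_fdr"),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_by_either_method(self):
        for method in ("bonferroni", "bh_fdr"):
            assert adjust_p([0.03], method)[0] == pytest.approx(0.03)

    def test_empty_input_gives_empty_output(self):
        assert len(adjust_p([], "bonferroni")) == 0

    def test_bonferroni_dominates_bh(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 50)
        assert (adjust_p(p, "bonferroni") >= adjust_p(p, "bh_fdr") - 1e-12).all()


# ---------------------------------------------------------------------------
# protein calls
# ---------------------------------------------------------------------------

class TestCallDifferentialProteins:
    def _table_with_ratio(self, ratio: float, n_null: int = 60, seed: int = 0):
        rng = np.random.default_rng(seed)
        base = rng.normal(10, 1, n_null + 1)
        rows = []
        for i, b in enumerate(base):
            lfc = np.log2(ratio) if i == 0 else 0.0
            row = [2.0 ** (b + rng.normal(0, 0.05)) for _ in range(3)]
            row += [2.0 ** (b + lfc + rng.normal(0, 0.05)) for _ in range(3)]
            rows.append(row)
        return quant_table(np.array(rows))

    def test_ratio_above_cutoff_with_small_p_is_significant(self):
        table = self._table_with_ratio(1.6)
        res = call_differential_proteins(table, DiffTestConfig(n_perm=2000, seed=1), "COLL")
        assert bool(res.loc[res["feature_id"] == "P0", "significant"].iloc[0])

    def test_ratio_below_cutoff_never_significant(self):
        table = self._table_with_ratio(1.10)
        res = call_differential_proteins(table, DiffTestConfig(n_perm=2000, seed=1), "COLL")
        row = res[res["feature_id"] == "P0"].iloc[0]
        assert abs(2.0 ** row["effect"]) < 1.2
        assert not row["significant"]

    def test_planted_effects_recovered_exactly(self):
        rng = np.random.default_rng(4)
        n, planted = 20, {0: 1.0, 1: -1.0, 2: 1.0}
        base = rng.normal(10, 1, n)
        rows = []
        for i in range(n):
            lfc = planted.get(i, 0.0)
            row = [2.0 ** (base[i] + rng.normal(0, 0.1)) for _ in range(3)]
            row += [2.0 ** (base[i] + lfc + rng.normal(0, 0.1)) for _ in range(3)]
            rows.append(row)
        table = quant_table(np.array(rows))
        res = call_differential_proteins(table, DiffTestConfig(n_perm=2000, seed=2), "COLL")
        called = set(res.loc[res["significant"], "feature_id"])
        assert called == {"P0", "P1", "P2"}

    def test_missing_group_is_an_error(self):
        table = self._table_with_ratio(1.5)
        with pytest.raises(ValueError, match="TRAP"):
            call_differential_proteins(table, DiffTestConfig(n_perm=10), "TRAP")


# ---------------------------------------------------------------------------
# intron calls
# ---------------------------------------------------------------------------

class TestCallDifferentialIntrons:
    def _matrix(self, ctrl, coll, n_null=80, seed=0):
        rng = np.random.default_rng(seed)
        idx = ["gA:t1:0"] + [f"g{i:03d}:t1:0" for i in range(1, n_null + 1)]
        rows = [list(np.clip(rng.normal(ctrl, 0.03, 3), 0, 1))
                + list(np.clip(rng.normal(coll, 0.03, 3), 0, 1))]
        for _ in range(n_null):
            theta = rng.uniform(0.2, 0.8)
            rows.append(list(np.clip(rng.normal(theta, 0.03, 6), 0, 1)))
        return pd.DataFrame(rows, index=idx, columns=SAMPLES)

    def test_identical_groups_not_significant(self):
        m = self._matrix(0.5, 0.5)
        res = call_differential_introns(m, GROUPS, DiffTestConfig(n_perm=500, seed=3), "COLL")
        row = res[res["feature_id"] == "gA:t1:0"].iloc[0]
        assert not row["significant"]

    def test_sign_convention_is_treated_minus_ctrl(self):
        m = self._matrix(0.6, 0.2)
        res = call_differential_introns(m, GROUPS, DiffTestConfig(n_perm=500, seed=3), "COLL")
        row = res[res["feature_id"] == "gA:t1:0"].iloc[0]
        assert row["effect"] == pytest.approx(-0.4, abs=0.1)

    def test_planted_removal_flagged_removed(self):
        m = self._matrix(0.6, 0.2)
        res = call_differential_introns(m, GROUPS, DiffTestConfig(n_perm=2000, seed=3), "COLL")
        assert "gA:t1:0" in removed_introns(res)

    def test_restricted_to_retained_set(self):
        m = self._matrix(0.6, 0.2)
        res = call_differential_introns(
            m, GROUPS, DiffTestConfig(n_perm=100, seed=3), "COLL",
            retained={"g001:t1:0"})
        assert list(res["feature_id"]) == ["g001:t1:0"]


class TestIntronsPerGeneSummary:
    def _diff(self, rows):
        return pd.DataFrame(rows, columns=["feature_id", "effect", "significant"])

    def test_three_single_intron_genes(self):
        diff = self._diff([(f"g{i}:t1:0", -0.4, True) for i in range(3)])
        hist = introns_per_gene_summary(diff)
        assert dict(zip(hist["n_introns"], hist["n_genes"])) == {1: 3}

    def test_gene_with_two_significant_introns(self):
        diff = self._diff([("gA:t1:0", -0.4, True), ("gA:t1:1", -0.3, True),
                           ("gB:t1:0", -0.2, True)])
        hist = introns_per_gene_summary(diff)
        assert dict(zip(hist["n_introns"], hist["n_genes"])) == {1: 1, 2: 1}

    def test_empty_results_give_empty_histogram(self):
        assert introns_per_gene_summary(self._diff([])).empty
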
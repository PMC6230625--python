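"""Paired comparisons, permutation, Bonferroni, strand bias, clustering."""

import numpy as np
import pandas as pd
import pytest

from strandmeth.calling import MethylationMatrix
from strandmeth.stats import (
    PairedMethylationModel,
    average_matrix_by_subtype,
    bonferroni_alpha,
    cluster_subtypes,
    mixed_effects_test,
    paired_difference_table,
    permutation_test,
    region_average,
    strand_bias_from_percents,
)
from oracles import oracle_complete_linkage, oracle_sign_flip_p


def _matrix(donor, pop, percents, region="r", strand="top", n_clones=20):
    """MethylationMatrix whose per-CpG percentages equal ``percents``."""
    percents = np.asarray(percents, float)
    calls = np.zeros((n_clones, percents.size))
    for j, p in enumerate(percents):
        k = int(round(p / 100 * n_clones))
        calls[:k, j] = 1.0
    return MethylationMatrix(
        group=(donor, pop, region, strand),
        clone_ids=[f"{donor}c{i}" for i in range(n_clones)],
        calls=calls,
    )


def _diff_table(y: np.ndarray) -> pd.DataFrame:
    D, C = y.shape
    return pd.DataFrame(
        {
            "donor": np.repeat([f"d{i}" for i in range(D)], C),
            "cpg": np.tile(np.arange(1, C + 1), D),
            "diff": y.ravel(),
        }
    )


class TestRegionAverage:
    def test_single_cpg_subset_is_identity(self):
        m = _matrix("d1", "Tcon", [10, 20, 30])
        assert region_average(m, [2]) == 20.0

    def test_mean_over_subset(self):
        m = _matrix("d1", "Tcon", [10, 20, 30])
        assert region_average(m, [1, 2, 3]) == 20.0
        assert region_average(m) == 20.0

    def test_all_zero_matrix(self):
        assert region_average(_matrix("d1", "Tcon", [0, 0, 0])) == 0.0

    def test_empty_or_out_of_range_subset(self):
        m = _matrix("d1", "Tcon", [10, 20, 30])
        with pytest.raises(ValueError):
            region_average(m, [])
        with pytest.raises(ValueError):
            region_average(m, [4])

    def test_zero_denominator_cpg_excluded_with_warning(self):
        m = _matrix("d1", "Tcon", [10, 20, 30])
        m.calls[:, 1] = np.nan
        with pytest.warns(UserWarning, match="zero denominator"):
            assert region_average(m, [1, 2, 3]) == 20.0


class TestPairedDifferenceTable:
    def _mats(self, offset):
        out = {}
        for d in ("d1", "d2", "d3"):
            out[(d, "Tcon", "r", "top")] = _matrix(d, "Tcon", [50, 60, 70])
            out[(d, "Treg", "r", "top")] = _matrix(
                d, "Treg", np.array([50, 60, 70]) - offset
            )
        return out

    def test_identical_matrices_give_zero_diffs(self):
        table = paired_difference_table(self._mats(0), "Tcon", "Treg")
        assert (table["diff"] == 0).all()

    def test_constant_offset_recovered(self):
        table = paired_difference_table(self._mats(30), "Tcon", "Treg")
        assert (table["diff"] == 30).all()

    def test_row_count_is_donors_times_cpgs(self):
        table = paired_difference_table(self._mats(10), "Tcon", "Treg")
        assert len(table) == 3 * 3

    def test_no_shared_donors_errors(self):
        mats = {
            ("d1", "Tcon", "r", "top"): _matrix("d1", "Tcon", [50]),
            ("d2", "Treg", "r", "top"): _matrix("d2", "Treg", [50]),
        }
        with pytest.raises(ValueError, match="no donors"):
            paired_difference_table(mats, "Tcon", "Treg")


class TestMixedEffectsTest:
    def test_all_zero_diffs_not_significant(self):
        res = mixed_effects_test(_diff_table(np.zeros((4, 5))))
        assert res.mean_difference == 0.0
        assert res.p_value == 1.0
        assert not res.significant

    def test_large_shift_low_noise_significant_at_bonferroni(self):
        rng = np.random.default_rng(0)
        y = 40 + rng.normal(0, 3, size=(6, 10))
        res = mixed_effects_test(_diff_table(y))
        assert res.p_value < 0.016
        assert res.significant
        assert res.mean_difference == pytest.approx(y.mean())

    def test_constant_nonzero_table_falls_back_to_permutation(self):
        res = mixed_effects_test(_diff_table(np.full((6, 5), 30.0)))
        assert res.method == "permutation"
        assert "permutation" in res.note
        assert res.p_value == pytest.approx(2 / 64)

    def test_reml_and_moment_agree_on_clear_effects(self):
        rng = np.random.default_rng(1)
        y = 35 + rng.normal(0, 5, (6, 10)) + rng.normal(0, 3, 6)[:, None]
        table = _diff_table(y)
        moment = mixed_effects_test(table)
        reml = mixed_effects_test(table, method="reml")
        assert moment.significant and reml.significant
        assert moment.mean_difference == pytest.approx(reml.mean_difference, abs=1e-6)

    def test_significance_consistent_with_adjusted_alpha(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 10, (6, 8))
        res = mixed_effects_test(_diff_table(y))
        assert res.significant == (res.p_value < res.alpha_adjusted)

    def test_too_few_donors_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            mixed_effects_test(_diff_table(np.zeros((1, 5))))

    def test_summary_mentions_contrast_and_p(self):
        res = mixed_effects_test(_diff_table(np.zeros((3, 3))), contrast="Tcon - Treg")
        s = res.summary()
        assert "Tcon - Treg" in s and "p-value" in s


class TestPermutationTest:
    def test_all_zero_diffs_give_p_one(self):
        res = permutation_test(_diff_table(np.zeros((6, 4))))
        assert res.p_value == 1.0

    def test_exhaustive_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = rng.normal(5, 10, (6, 5))
            res = permutation_test(_diff_table(y))
            donor_means = y.mean(axis=1).tolist()
            assert res.p_value == pytest.approx(oracle_sign_flip_p(donor_means))

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning, match="small"):
            permutation_test(_diff_table(np.ones((25, 3))), n_perm=50, seed=0)

    def test_sampled_permutation_deterministic_per_seed(self):
        rng = np.random.default_rng(4)
        y = rng.normal(2, 5, (25, 4))  # 2^25 >> n_perm: sampled branch
        a = permutation_test(_diff_table(y), n_perm=500, seed=7)
        b = permutation_test(_diff_table(y), n_perm=500, seed=7)
        assert a.p_value == b.p_value


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,reported", [(0.05, 3, 0.016), (0.05, 1, 0.05), (0.05, 5, 0.01)]
    )
    def test_reported_threshold(self, alpha, n, reported):
        thr = bonferroni_alpha(alpha, n)
        assert thr.reported == pytest.approx(reported)
        assert thr.raw == pytest.approx(alpha / n)

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestStrandBias:
    def test_identical_strands_not_significant(self):
        top = {d: np.full(5, 100.0) for d in "abcdef"}
        bottom = {d: np.full(5, 100.0) for d in "abcdef"}
        r = strand_bias_from_percents(top, bottom, "r", "Treg")
        assert np.all(r.hemimethylation_index == 0)
        assert r.comparison.p_value == 1.0
        assert not r.comparison.significant

    def test_index_is_absolute_difference(self):
        top = {d: np.array([60.0]) for d in "ab"}
        bottom = {d: np.array([100.0]) for d in "ab"}
        r = strand_bias_from_percents(top, bottom, "r", "Treg")
        assert r.hemimethylation_index[0] == 40.0
        assert r.signed[0] == -40.0

    def test_bottom_strand_cpgs_are_reversed_for_pairing(self):
        # top CpG k pairs with bottom CpG (n+1-k): antiparallel numbering
        top = {"d1": np.array([0.0, 50.0, 100.0]), "d2": np.array([0.0, 50.0, 100.0])}
        bottom = {"d1": np.array([100.0, 50.0, 0.0]), "d2": np.array([100.0, 50.0, 0.0])}
        r = strand_bias_from_percents(top, bottom, "r", "Treg")
        assert np.all(r.hemimethylation_index == 0)

    def test_mismatched_cpg_counts_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            strand_bias_from_percents(
                {"d": np.zeros(3), "e": np.zeros(3)},
                {"d": np.zeros(4), "e": np.zeros(4)},
                "r", "Treg",
            )


class TestClustering:
    def test_identical_rows_merge_at_height_zero(self):
        df = pd.DataFrame(np.ones((3, 4)), index=["a", "b", "c"])
        res = cluster_subtypes(df)
        assert np.all(res.merge_heights == 0)

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.uniform(0, 100, (6, 8)), index=list("abcdef"))
        res = cluster_subtypes(df)
        assert np.all(np.diff(res.merge_heights) >= 0)

    def test_matches_bruteforce_complete_linkage_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = int(rng.integers(4, 7))
            pts = rng.uniform(0, 100, (n, 5))
            df = pd.DataFrame(pts, index=[f"s{i}" for i in range(n)])
            res = cluster_subtypes(df)
            merges = oracle_complete_linkage([list(p) for p in pts])
            # compare merged leaf-sets and heights step by step
            scipy_sets = []
            members = {i: frozenset([i]) for i in range(n)}
            for step, (a, b, h, _) in enumerate(res.linkage):
                sa, sb = members[int(a)], members[int(b)]
                members[n + step] = sa | sb
                scipy_sets.append(({sa, sb}, h))
            for (oa, ob, oh), (sset, sh) in zip(merges, scipy_sets):
                assert {oa, ob} == sset
                assert oh == pytest.approx(sh)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.uniform(0, 100, (5, 6)), index=list("abcde"))
        res1 = cluster_subtypes(df)
        res2 = cluster_subtypes(df.iloc[::-1])
        assert res1.leaf_order == res2.leaf_order
        assert np.allclose(res1.linkage, res2.linkage)

    def test_outgroup_detection(self):
        df = pd.DataFrame(
            [[5, 5, 5], [6, 6, 6], [4, 4, 4], [95, 95, 95]],
            index=["TregA", "TregB", "TregC", "Tcon"],
        )
        res = cluster_subtypes(df)
        assert res.outgroup == "Tcon"
        assert set(res.leaf_order) == set(df.index)

    def test_newick_contains_all_labels(self):
        df = pd.DataFrame(np.eye(3) * 10, index=["x", "y", "z"])
        nwk = cluster_subtypes(df).newick()
        for label in "xyz":
            assert label in nwk
        assert nwk.endswith(";")

    def test_single_subtype_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cluster_subtypes(pd.DataFrame([[1.0, 2.0]], index=["only"]))

    def test_missing_values_mean_imputed_with_warning(self):
        df = pd.DataFrame(
            [[1.0, np.nan], [2.0, 4.0], [3.0, 5.0]], index=["a", "b", "c"]
        )
        with pytest.warns(UserWarning, match="imputing"):
            cluster_subtypes(df)


def test_average_matrix_by_subtype():
    mats = {}
    for d in ("d1", "d2"):
        mats[(d, "Tcon", "r", "top")] = _matrix(d, "Tcon", [80, 90])
        mats[(d, "Treg", "r", "top")] = _matrix(d, "Treg", [10, 20])
    avg = average_matrix_by_subtype(mats, "r", "top")
    assert list(avg.index) == ["Tcon", "Treg"]
    assert avg.loc["Tcon", "CpG_1"] == 80.0
    assert avg.loc["Treg", "CpG_2"] == 20.0
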
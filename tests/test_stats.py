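import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from laminar import (
    bonferroni,
    correlation_null,
    correlation_percentile,
    correlation_pvalue,
    enrichment_table,
    filter_low_expression,
    gene_correlation,
    layer_auc,
    mannwhitney_p,
    profile_correlation,
    set_correlation,
    zscore_by_gene,
)
from laminar.stats import mannwhitney_u_distribution

from conftest import brute_force_auc, make_layer_matrix

SEVEN = ["L1", "L2", "L3", "L4", "L5", "L6", "WM"]


def series(vals, layers=None):
    layers = layers or SEVEN[: len(vals)]
    return pd.Series([float(v) for v in vals], index=layers)


def exact_mw_p_by_enumeration(u_obs: float, n1: int, n2: int) -> float:
    """Independent oracle: enumerate every placement of n1 set ranks among
    n1+n2 tie-free ranks and count placements at least as extreme as u_obs."""
    n = n1 + n2
    mu = n1 * n2 / 2
    total = extreme = 0
    for combo in itertools.combinations(range(n), n1):
        u = sum(r - i for i, r in enumerate(sorted(combo)))
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


class TestProfileCorrelation:
    def test_self_correlation_is_one(self):
        x = series([1, 4, 2, 8, 5, 7, 3])
        r, n, flags = profile_correlation(x, x)
        assert r == pytest.approx(1.0) and n == 7 and not flags

    def test_affine_flip_is_minus_one(self):
        x = series([1, 4, 2, 8, 5, 7, 3])
        r, _, _ = profile_correlation(x, -x + 10)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # covariance sums by hand: Σxy_dev = 25, Σx² = Σy² = 28 -> r = 25/28
        r, n, _ = profile_correlation(series([1, 2, 3, 4, 5, 6, 7]),
                                      series([2, 1, 4, 3, 6, 5, 7]))
        assert n == 7
        assert r == pytest.approx(25 / 28)

    def test_uses_shared_layer_intersection(self):
        x = series([1, 2, 3, 4, 5, 6, 7], SEVEN)
        y = series([2, 4, 6, 8, 10, 12], SEVEN[:6])  # no WM
        r, n, _ = profile_correlation(x, y)
        assert n == 6 and r == pytest.approx(1.0)

    @pytest.mark.parametrize("y, reason", [
        (series([1, 2], ["L1", "L2"]), "shared layers"),
        (series([5, 5, 5], ["L1", "L2", "L3"]), "constant"),
    ])
    def test_degenerate_profiles_flagged(self, y, reason):
        x = series([1, 2, 3], ["L1", "L2", "L3"])
        r, _, flags = profile_correlation(x, y)
        assert math.isnan(r) and any(reason in f for f in flags)


class TestCorrelationPvalue:
    def test_null_center_gives_one(self):
        for n in (3, 5, 7):
            p, _ = correlation_pvalue(0.0, n)
            assert p == pytest.approx(1.0)

    def test_reproduces_printed_worked_pair(self):
        p, _ = correlation_pvalue(0.916, 7)
        assert p == pytest.approx(0.0038, abs=5e-5)

    def test_df1_small_sample(self):
        p, _ = correlation_pvalue(0.99, 3)
        assert 0 < p < 0.2

    def test_perfect_correlation_floored_and_flagged(self):
        p, flags = correlation_pvalue(1.0, 5)
        assert p > 0 and p < 1e-300 and flags

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000), st.integers(4, 9))
    def test_matches_pearsonr_p_on_random_profiles(self, seed, n):
        """The t transform reproduces scipy's exact two-sided Pearson p."""
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, n))
        res = sps.pearsonr(x, y)
        p, _ = correlation_pvalue(float(res.statistic), n)
        assert p == pytest.approx(res.pvalue, rel=1e-6)


class TestCorrelationNull:
    def test_identical_matrices_give_all_ones(self, layer_matrix):
        null = correlation_null(layer_matrix, layer_matrix)
        assert len(null) == 5
        np.testing.assert_allclose(null, 1.0)

    def test_independent_noise_centered_at_zero(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(1000)]
        a = make_layer_matrix(rng.normal(size=(1000, 7)), genes, SEVEN, name="a")
        b = make_layer_matrix(rng.normal(size=(1000, 7)), genes, SEVEN, name="b")
        null = correlation_null(a, b)
        assert abs(null.mean()) < 0.1

    def test_joins_on_shared_genes_only(self, layer_matrix):
        other = make_layer_matrix(
            layer_matrix.values.iloc[:3].to_numpy(), ["G0", "G1", "G2"],
            SEVEN, name="b")
        assert len(correlation_null(layer_matrix, other)) == 3

    def test_constant_genes_excluded(self, layer_matrix):
        v = layer_matrix.values.copy()
        v.loc["G0"] = 4.0
        flat = make_layer_matrix(v.to_numpy(), v.index, SEVEN, name="b")
        null = correlation_null(flat, layer_matrix)
        assert "G0" not in null.index and len(null) == 4

    def test_no_shared_genes_rejected(self, layer_matrix):
        other = make_layer_matrix(np.ones((2, 7)), ["X1", "X2"], SEVEN)
        with pytest.raises(ValueError, match="shared genes"):
            correlation_null(layer_matrix, other)


class TestCorrelationPercentile:
    @pytest.mark.parametrize("r, null, expected", [
        (0.9, [-0.5, 0.0, 0.5], 100.0),
        (0.0, [-0.5, 0.0, 0.5], 50.0),
        (0.2, [-0.5, 0.0, 0.5], 200 / 3),
    ])
    def test_examples(self, r, null, expected):
        assert correlation_percentile(r, np.array(null)) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(-10, 10), min_size=1, max_size=40),
           st.integers(-10, 10))
    def test_matches_counting_oracle(self, null_tenths, r_tenths):
        null = np.array(null_tenths) / 10
        r = r_tenths / 10
        oracle = 100 * (sum(v < r for v in null)
                        + 0.5 * sum(v == r for v in null)) / len(null)
        assert correlation_percentile(r, null) == pytest.approx(oracle)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            correlation_percentile(0.5, np.array([]))


class TestSetCorrelation:
    @pytest.fixture
    def pair(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(40)]
        a = make_layer_matrix(rng.normal(8, 2, (40, 7)), genes, SEVEN, name="a")
        b = make_layer_matrix(
            a.values.to_numpy() + rng.normal(0, 1.5, (40, 7)), genes, SEVEN,
            name="b")
        return a, b

    def test_single_gene_set_equals_single_gene_result(self, pair):
        a, b = pair
        single = gene_correlation("G5", a, b)
        as_set = set_correlation(["G5"], a, b)
        assert as_set.r == pytest.approx(single.r)
        assert as_set.percentile == pytest.approx(single.percentile)

    def test_mean_of_per_gene_correlations(self, pair):
        a, b = pair
        genes = ["G1", "G2", "G3"]
        per = [profile_correlation(a.values.loc[g], b.values.loc[g])[0]
               for g in genes]
        res = set_correlation(genes, a, b)
        assert res.r == pytest.approx(np.mean(per))
        assert set(res.per_gene_r) == set(genes)

    def test_missing_genes_reported_not_fatal(self, pair):
        a, b = pair
        res = set_correlation(["G1", "NOPE"], a, b)
        assert res.missing["a"] == ["NOPE"] and res.missing["b"] == ["NOPE"]
        assert res.r == pytest.approx(
            profile_correlation(a.values.loc["G1"], b.values.loc["G1"])[0])

    def test_all_genes_missing_rejected(self, pair):
        with pytest.raises(KeyError, match="NOPE"):
            set_correlation(["NOPE"], *pair)


class TestFilterAndZscore:
    def test_toy_filter_keeps_three_of_five(self):
        # genes 0,1 below 0.1 CPM everywhere; gene 2 rescued by one layer
        cpm = np.array([
            [0.05, 0.05, 0.05],
            [0.02, 0.09, 0.01],
            [0.05, 0.05, 0.20],
            [1.00, 2.00, 3.00],
            [50.0, 0.01, 0.01],
        ])
        m = make_layer_matrix(np.log2(cpm), [f"g{i}" for i in range(5)],
                              ["L1", "L2", "L3"], name="toy")
        out = filter_low_expression(m)
        assert out.gene_ids == ["g2", "g3", "g4"]

    def test_all_removed_rejected(self):
        m = make_layer_matrix(np.log2([[0.01, 0.02]]), ["g"], ["L1", "L2"])
        with pytest.raises(ValueError, match="below"):
            filter_low_expression(m)

    def test_zscore_symmetric_profile(self):
        m = make_layer_matrix([[1.0, 2.0, 3.0]], ["g"], ["L1", "L2", "L3"])
        z, flagged = zscore_by_gene(m)
        assert not flagged
        np.testing.assert_allclose(z.values.loc["g"], [-1, 0, 1])

    def test_constant_gene_zeroed_and_flagged(self):
        m = make_layer_matrix([[4.0, 4.0, 4.0], [1.0, 2.0, 4.0]],
                              ["flat", "g"], ["L1", "L2", "L3"])
        z, flagged = zscore_by_gene(m)
        assert flagged == ["flat"]
        np.testing.assert_allclose(z.values.loc["flat"], 0.0)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_zscore_rows_standardized(self, seed):
        rng = np.random.default_rng(seed)
        m = make_layer_matrix(rng.normal(5, 3, (8, 7)),
                              [f"g{i}" for i in range(8)], SEVEN)
        z, _ = zscore_by_gene(m)
        v = z.values.to_numpy()
        np.testing.assert_allclose(v.sum(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(v.std(axis=1, ddof=1), 1.0)


class TestLayerAuc:
    def test_descending_positions_example(self):
        # 10 genes; set occupies descending-rank positions 1, 2, 5 (no ties)
        vals = np.arange(10, 0, -1, dtype=float)
        genes = [f"g{i}" for i in range(1, 11)]
        m = make_layer_matrix(vals.reshape(-1, 1), genes, ["L1"], name="t")
        auc, u, n_set, n_bg = layer_auc(m, ["g1", "g2", "g5"], "L1")
        assert (u, n_set, n_bg) == (19, 3, 7)
        assert auc == pytest.approx(19 / 21)

    def test_reversed_ranking_complements(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=20)
        genes = [f"g{i}" for i in range(20)]
        m = make_layer_matrix(vals.reshape(-1, 1), genes, ["L1"])
        m_rev = make_layer_matrix(-vals.reshape(-1, 1), genes, ["L1"])
        gene_set = genes[::3]
        auc, *_ = layer_auc(m, gene_set, "L1")
        auc_rev, *_ = layer_auc(m_rev, gene_set, "L1")
        assert auc + auc_rev == pytest.approx(1.0)

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 10_000))
    def test_matches_pair_counting_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 51))
        # coarse grid to force ties
        vals = rng.integers(0, 6, size=n).astype(float)
        genes = [f"g{i}" for i in range(n)]
        k = int(rng.integers(1, n))
        gene_set = set(rng.choice(genes, size=k, replace=False))
        m = make_layer_matrix(vals.reshape(-1, 1), genes, ["L1"])
        auc, u, n_set, n_bg = layer_auc(m, list(gene_set), "L1")
        oracle_auc, oracle_u = brute_force_auc(
            pd.Series(vals, index=genes), gene_set)
        assert u == pytest.approx(oracle_u)
        assert auc == pytest.approx(oracle_auc)

    def test_set_covering_matrix_rejected(self, layer_matrix):
        with pytest.raises(ValueError, match="background"):
            layer_auc(layer_matrix, layer_matrix.gene_ids, "L1")

    def test_random_sets_average_half(self, layer_matrix):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        m = make_layer_matrix(rng.normal(size=(30, 1)), genes, ["L1"])
        draws = [layer_auc(m, list(rng.choice(genes, 10, replace=False)), "L1")[0]
                 for _ in range(200)]
        se = np.std(draws, ddof=1) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - 0.5) < 3 * se + 1e-12


class TestMannWhitneyP:
    def test_distribution_sums_to_binomial(self):
        for n1, n2 in [(2, 3), (4, 4), (5, 8)]:
            d = mannwhitney_u_distribution(n1, n2)
            assert d.sum() == math.comb(n1 + n2, n1)
            # symmetric around n1*n2/2
            np.testing.assert_allclose(d, d[::-1])

    def test_null_center_p_is_one(self):
        p, method = mannwhitney_p(6.0, 3, 4)  # U = n1 n2 / 2
        assert method == "exact" and p == pytest.approx(1.0)

    def test_top_ranked_pair_example(self):
        p, method = mannwhitney_p(6, 2, 3)
        assert method == "exact" and p == pytest.approx(0.2)

    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 5), (3, 3), (5, 8)])
    def test_exact_branch_equals_enumeration(self, n1, n2):
        for u in range(n1 * n2 + 1):
            p, method = mannwhitney_p(float(u), n1, n2)
            assert method == "exact"
            assert p == pytest.approx(exact_mw_p_by_enumeration(u, n1, n2))

    def test_normal_branch_close_to_exact(self):
        n1, n2 = 5, 8
        for u in range(0, 41, 5):
            exact = exact_mw_p_by_enumeration(u, n1, n2)
            approx, method = mannwhitney_p(float(u), n1, n2,
                                           ties=np.array([2]))  # force normal
            assert method == "normal"
            assert approx == pytest.approx(exact, abs=0.05)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_tied_normal_branch_tracks_scipy(self, seed):
        """Tie-corrected normal approximation agrees with scipy's asymptotic
        Mann-Whitney on raw tied data."""
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=25).astype(float)
        y = rng.integers(0, 4, size=30).astype(float)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        ranks = sps.rankdata(np.concatenate([x, y]))
        u = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        p, method = mannwhitney_p(u, len(x), len(y), ties=counts[counts > 1])
        assert method == "normal"
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestBonferroni:
    @pytest.mark.parametrize("p, expected", [
        ([0.01] * 5, [0.05] * 5),
        ([0.5] * 7, [1.0] * 7),
        ([0.3], [0.3]),
    ])
    def test_examples(self, p, expected):
        np.testing.assert_allclose(bonferroni(p), expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.2])


class TestEnrichmentTable:
    @pytest.fixture
    def five_matrices(self):
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(60)]
        mats = []
        for i, layers in enumerate([SEVEN, SEVEN, SEVEN[:6], SEVEN[:6], SEVEN[:6]]):
            vals = rng.normal(8, 2, (60, len(layers)))
            # plant the first 8 genes in L3 everywhere
            vals[:8, layers.index("L3")] += 6
            mats.append(make_layer_matrix(vals, genes, layers, name=f"ds{i}"))
        return mats

    def test_family_size_counts_all_cells(self, five_matrices):
        res = enrichment_table(five_matrices, [f"G{i}" for i in range(8)])
        assert len(res.table) == 2 * 7 + 3 * 6 == 32
        assert res.n_tests == 32

    def test_single_matrix_family_of_six(self, five_matrices):
        res = enrichment_table(five_matrices[2:3], ["G0", "G1"])
        assert res.n_tests == 6
        np.testing.assert_allclose(
            res.table["p_adjusted"],
            np.minimum(1, res.table["p_raw"] * 6))

    def test_planted_markers_peak_at_target_layer(self, five_matrices):
        res = enrichment_table(five_matrices, [f"G{i}" for i in range(8)])
        assert res.mean_auc.idxmax() == "L3"
        assert res.mean_auc["L3"] > 0.8

    def test_mean_auc_averages_only_datasets_with_layer(self, five_matrices):
        res = enrichment_table(five_matrices, [f"G{i}" for i in range(8)])
        wm = res.table[res.table["layer"] == "WM"]
        assert len(wm) == 2  # only the two 7-layer matrices
        assert res.mean_auc["WM"] == pytest.approx(wm["auc"].mean())

    def test_unmatched_matrix_flagged_not_fatal(self, five_matrices):
        stranger = make_layer_matrix(
            np.random.default_rng(0).normal(size=(10, 6)),
            [f"X{i}" for i in range(10)], SEVEN[:6], name="stranger")
        res = enrichment_table(five_matrices + [stranger],
                               [f"G{i}" for i in range(8)])
        flagged = res.table[res.table["dataset"] == "stranger"]
        assert (flagged["flag"] != "").all()
        assert res.n_tests == 32
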
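"""Unit and property tests for adjacency construction and network concepts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from samplenet.datatypes import ExpressionMatrix, SampleNetworkError
from samplenet.network import (
    dichotomize_adjacency,
    euclidean_adjacency,
    expected_corKC_factorizable,
    network_summary,
    node_concepts,
    sample_correlation,
    signed_power_adjacency,
    spearman_corKC,
)

from conftest import naive_clustering_coefficient, random_adjacency


class TestSampleCorrelation:
    def test_identical_and_negated_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        expr = ExpressionMatrix.from_arrays(np.c_[x, x, -x])
        r = sample_correlation(expr).r.to_numpy()
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # 4 features x 3 samples; correlations evaluated by hand from the
        # product-moment formula: r12 = 3/5, r13 = -1, r23 = -3/5
        values = np.array([[1, 2, 4], [2, 1, 3], [3, 4, 2], [4, 3, 1]], float)
        r = sample_correlation(ExpressionMatrix.from_arrays(values)).r.to_numpy()
        assert r[0, 1] == pytest.approx(0.6, abs=1e-12)
        assert r[0, 2] == pytest.approx(-1.0, abs=1e-12)
        assert r[1, 2] == pytest.approx(-0.6, abs=1e-12)

    def test_zero_variance_features_dropped_and_reported(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(5, 4))
        values[2] = 3.0  # constant feature
        corr = sample_correlation(ExpressionMatrix.from_arrays(values))
        assert corr.dropped_features == ["g3"]
        assert np.allclose(np.diag(corr.r.to_numpy()), 1.0)

    def test_all_zero_variance_is_degenerate(self):
        values = np.ones((4, 3))
        with pytest.raises(SampleNetworkError, match="degenerate input"):
            sample_correlation(ExpressionMatrix.from_arrays(values))

    def test_insufficient_pairwise_overlap(self):
        values = np.random.default_rng(2).normal(size=(4, 3))
        values[0:2, 0] = np.nan  # pair (s1, s2) has only 2 complete rows
        with pytest.raises(SampleNetworkError, match="insufficient overlap"):
            sample_correlation(ExpressionMatrix.from_arrays(values))

    def test_spearman_option(self, small_expr):
        corr = sample_correlation(small_expr, method="spearman")
        assert corr.method == "spearman"
        v = corr.r.to_numpy()
        assert np.allclose(v, v.T)


class TestSignedPowerAdjacency:
    @pytest.mark.parametrize(
        "r, beta, expected",
        [(1.0, 2.0, 1.0), (-1.0, 2.0, 0.0), (0.9, 2.0, 0.9025), (0.0, 1.0, 0.5)],
    )
    def test_pointwise_map(self, r, beta, expected):
        ids = ["a", "b"]
        rm = pd.DataFrame([[1.0, r], [r, 1.0]], index=ids, columns=ids)
        from samplenet.datatypes import CorrelationMatrix

        adj = signed_power_adjacency(CorrelationMatrix(rm), beta=beta)
        assert adj.a.iloc[0, 1] == pytest.approx(expected, abs=1e-12)
        assert adj.a.iloc[0, 0] == 1.0

    def test_invalid_power(self, small_expr):
        corr = sample_correlation(small_expr)
        with pytest.raises(SampleNetworkError, match="invalid power"):
            signed_power_adjacency(corr, beta=0.0)

    def test_beta2_identity_exact(self, small_expr):
        # a_ij - r_ij = ((1 - r_ij)/2)^2 holds exactly for beta = 2
        corr = sample_correlation(small_expr)
        adj = signed_power_adjacency(corr, beta=2.0)
        r = corr.r.to_numpy()
        a = adj.a.to_numpy()
        off = ~np.eye(len(r), dtype=bool)
        assert np.allclose(a[off] - r[off], ((1 - r[off]) / 2) ** 2, atol=1e-14)


class TestEuclideanAdjacency:
    def test_three_four_five_triangle(self):
        # samples at (0,0), (3,0), (0,4): distances 3, 4, 5
        values = np.array([[0, 3, 0], [0, 0, 4]], float)
        adj = euclidean_adjacency(ExpressionMatrix.from_arrays(values))
        a = adj.a.to_numpy()
        assert a[0, 1] == pytest.approx(1 - 3 / 5)
        assert a[0, 2] == pytest.approx(1 - 4 / 5)
        assert a[1, 2] == pytest.approx(0.0)

    def test_identical_samples_have_unit_adjacency(self):
        values = np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 1.0]])
        adj = euclidean_adjacency(ExpressionMatrix.from_arrays(values))
        assert adj.a.iloc[0, 1] == pytest.approx(1.0)

    def test_degenerate_distances(self):
        values = np.ones((3, 3))
        with pytest.raises(SampleNetworkError, match="degenerate distances"):
            euclidean_adjacency(ExpressionMatrix.from_arrays(values))

    def test_missing_values_rejected(self):
        values = np.ones((3, 3))
        values[0, 0] = np.nan
        with pytest.raises(SampleNetworkError, match="complete data"):
            euclidean_adjacency(ExpressionMatrix.from_arrays(values))


class TestDichotomize:
    def test_threshold_convention(self):
        ids = list("abc")
        a = pd.DataFrame(
            [[1.0, 0.2, 0.5], [0.2, 1.0, 0.8], [0.5, 0.8, 1.0]],
            index=ids, columns=ids,
        )
        from samplenet.datatypes import SampleAdjacency

        adj = SampleAdjacency(a, kind="signed_cor")
        binary = dichotomize_adjacency(adj, 0.5)
        assert binary.kind == "binary"
        assert binary.a.loc["a", "b"] == 0.0
        assert binary.a.loc["a", "c"] == 1.0  # >= convention
        assert binary.a.loc["b", "c"] == 1.0

    @pytest.mark.parametrize("tau", [0.0, -0.1, 1.5])
    def test_invalid_threshold(self, tau):
        adj = random_adjacency(5, 0)
        with pytest.raises(SampleNetworkError, match="invalid threshold"):
            dichotomize_adjacency(adj, tau)

    def test_extreme_thresholds(self):
        adj = random_adjacency(6, 3)
        off = adj.offdiag()
        vals = off[np.triu_indices_from(off, 1)]
        all_ones = dichotomize_adjacency(adj, float(vals.min()))
        assert all_ones.offdiag()[np.triu_indices(6, 1)].min() == 1.0
        all_zero = dichotomize_adjacency(adj, float(vals.max()) + 1e-9)
        assert all_zero.offdiag().max() == 0.0


class TestNodeConcepts:
    def test_uniform_triangle(self):
        # n=3, all off-diagonal a=0.5: triple-loop gives C = 2a^3/(2a^2) = a
        ids = list("abc")
        a = pd.DataFrame(0.5, index=ids, columns=ids)
        np.fill_diagonal(a.values, 1.0)
        from samplenet.datatypes import SampleAdjacency

        nc = node_concepts(SampleAdjacency(a, kind="signed_cor"))
        assert np.allclose(nc.table["k"], 1.0)
        assert np.allclose(nc.table["K"], 1.0)
        assert np.allclose(nc.table["C"], 0.5)
        assert np.allclose(nc.table["MAR"], 0.5)
        assert np.allclose(nc.table["ZK"], 0.0) and nc.zero_variance_K
        assert np.allclose(nc.table["ZC"], 0.0) and nc.zero_variance_C

    def test_complete_binary_clique(self):
        ids = list("abcd")
        a = pd.DataFrame(1.0, index=ids, columns=ids)
        from samplenet.datatypes import SampleAdjacency

        nc = node_concepts(SampleAdjacency(a, kind="binary"))
        assert np.allclose(nc.table["k"], 3.0)
        assert np.allclose(nc.table["C"], 1.0)

    def test_binary_star_has_zero_clustering(self):
        # hub connected to 3 leaves, no triangles; leaves hit the
        # zero-denominator convention (single neighbour)
        ids = list("habc")
        a = np.zeros((4, 4))
        a[0, 1:] = a[1:, 0] = 1.0
        np.fill_diagonal(a, 1.0)
        from samplenet.datatypes import SampleAdjacency

        nc = node_concepts(
            SampleAdjacency(pd.DataFrame(a, index=ids, columns=ids), kind="binary")
        )
        assert nc.table.loc["h", "k"] == 3.0
        assert nc.table.loc["h", "C"] == 0.0
        assert np.allclose(nc.table.loc[list("abc"), "C"], 0.0)
        assert set(nc.zero_denominator_C) == set("abc")

    @pytest.mark.parametrize("seed", range(50))
    def test_matrix_equals_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        adj = random_adjacency(n, seed + 1000)
        nc = node_concepts(adj)
        naive = naive_clustering_coefficient(adj.a.to_numpy())
        assert np.max(np.abs(nc.table["C"].to_numpy() - naive)) < 1e-10

    @pytest.mark.parametrize("seed", range(10))
    def test_binary_reduction_to_triangle_count(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        b = (rng.random((n, n)) < 0.45).astype(float)
        b = np.triu(b, 1)
        b = b + b.T
        a = b.copy()
        np.fill_diagonal(a, 1.0)
        ids = [f"s{i}" for i in range(n)]
        from samplenet.datatypes import SampleAdjacency

        nc = node_concepts(
            SampleAdjacency(pd.DataFrame(a, index=ids, columns=ids), kind="binary")
        )
        tri = np.diag(np.linalg.matrix_power(b, 3)) / 2
        k = b.sum(1)
        expected = np.where(k >= 2, 2 * tri / np.maximum(k * (k - 1), 1), 0.0)
        assert np.allclose(nc.table["C"], expected, atol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_clustering_coefficient_in_unit_interval(self, seed):
        nc = node_concepts(random_adjacency(15, seed))
        assert (nc.table["C"] >= 0).all() and (nc.table["C"] <= 1).all()
        assert (nc.table["MAR"] >= 0).all() and (nc.table["MAR"] <= 1).all()

    def test_z_columns_standardized(self):
        nc = node_concepts(random_adjacency(25, 11))
        for col in ("ZK", "ZC"):
            assert nc.table[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert nc.table[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        assert nc.table["K"].max() == pytest.approx(1.0)

    def test_too_small_network(self):
        with pytest.raises(SampleNetworkError, match="too small"):
            node_concepts(random_adjacency(2, 0))


class TestNetworkSummary:
    def test_uniform_network(self):
        ids = list("abc")
        a = pd.DataFrame(0.5, index=ids, columns=ids)
        np.fill_diagonal(a.values, 1.0)
        from samplenet.datatypes import SampleAdjacency

        s = network_summary(SampleAdjacency(a, kind="signed_cor"))
        assert s.density == pytest.approx(0.5)
        assert s.heterogeneity == pytest.approx(0.0)
        assert s.homogeneity == pytest.approx(1.0)
        assert not s.corKC_defined

    @pytest.mark.parametrize("seed", range(50))
    def test_corKC_monotone_invariance(self, seed):
        # Spearman(k, C) == Spearman(Z.K, Z.C) to machine precision
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        adj = random_adjacency(n, seed + 500)
        nc = node_concepts(adj)
        s = network_summary(adj, concepts=nc)
        rho_z = stats.spearmanr(nc.table["ZK"], nc.table["ZC"]).statistic
        rho_K = stats.spearmanr(nc.table["K"], nc.table["C"]).statistic
        assert s.corKC == pytest.approx(rho_z, abs=1e-12)
        assert s.corKC == pytest.approx(rho_K, abs=1e-12)

    @pytest.mark.parametrize("c", [0.1, 0.5, 0.9])
    def test_corKC_scale_invariance(self, c):
        adj = random_adjacency(20, 42)
        scaled_a = adj.a * c
        np.fill_diagonal(scaled_a.values, 1.0)
        from samplenet.datatypes import SampleAdjacency

        scaled = SampleAdjacency(scaled_a, kind="signed_cor")
        assert network_summary(scaled).corKC == pytest.approx(
            network_summary(adj).corKC, abs=1e-12
        )

    def test_homogeneity_moment_identity(self):
        adj = random_adjacency(17, 9)
        s = network_summary(adj)
        k = node_concepts(adj).table["k"].to_numpy()
        assert s.homogeneity == pytest.approx(
            k.sum() ** 2 / (len(k) * (k**2).sum()), abs=1e-12
        )
        assert s.decentralization == pytest.approx(1.0 - s.centralization)

    def test_density_tracks_mean_correlation_when_r_high(self):
        # |density - mean r| <= ((1 - min r)/2)^2 for the beta=2 adjacency
        rng = np.random.default_rng(5)
        profile = rng.normal(size=400)
        x = profile[:, None] + rng.normal(0, 0.35, (400, 12))
        expr = ExpressionMatrix.from_arrays(x)
        corr = sample_correlation(expr)
        adj = signed_power_adjacency(corr, beta=2.0)
        s = network_summary(adj, corr=corr)
        rmin = corr.r.to_numpy()[~np.eye(12, dtype=bool)].min()
        assert rmin > 0.6
        assert abs(s.density - s.mean_cor) <= ((1 - rmin) / 2) ** 2 + 1e-12

    def test_mean_cor_recovered_by_inverting_adjacency(self, small_expr):
        corr = sample_correlation(small_expr)
        adj = signed_power_adjacency(corr, beta=2.0)
        with_corr = network_summary(adj, corr=corr)
        without = network_summary(adj)
        assert without.mean_cor == pytest.approx(with_corr.mean_cor, abs=1e-12)


class TestSpearmanCorKC:
    def test_exact_permutation_p_matches_enumeration(self):
        import itertools

        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.8, 1.8])
        rho, p = spearman_corKC(x, y, method="exact")
        ref_rho = stats.spearmanr(x, y).statistic
        ry = stats.rankdata(y)
        count = total = 0
        for perm in itertools.permutations(range(6)):
            r = stats.spearmanr(stats.rankdata(x), ry[list(perm)]).statistic
            count += abs(r) >= abs(ref_rho) - 1e-12
            total += 1
        assert rho == pytest.approx(ref_rho)
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        rho, p = spearman_corKC(np.ones(5), np.arange(5.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_exact_rejects_large_n(self):
        with pytest.raises(SampleNetworkError):
            spearman_corKC(np.arange(12.0), np.arange(12.0), method="exact")


class TestFactorizablePrediction:
    @pytest.mark.parametrize(
        "h, expected", [(0.0, -1.23), (1.0, -0.135), (1e9, 0.96)]
    )
    def test_endpoints(self, h, expected):
        assert expected_corKC_factorizable(h) == pytest.approx(expected, abs=1e-6)

    def test_negative_heterogeneity_rejected(self):
        with pytest.raises(SampleNetworkError, match="invalid heterogeneity"):
            expected_corKC_factorizable(-0.1)
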
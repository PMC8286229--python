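"""Graph measures: thresholding, nulls, modularity/Louvain, efficiency."""

import numpy as np
import pytest

import networkx as nx

from conncompare.errors import ParameterError, ValidationError
from conncompare.graph_metrics import (
    GraphMetricsRecord,
    Partition,
    WeightedGraph,
    best_louvain,
    compare_groups,
    global_efficiency,
    modularity_Q,
    proportional_threshold,
    rewire_null,
    subject_metrics,
)
from conncompare.netio import ConnectivityMatrix, PipelineConfig

from conftest import (
    brute_force_q,
    exhaustive_best_q,
    floyd_warshall_efficiency,
    random_weighted_graph,
)


class TestPartition:
    def test_non_contiguous_membership_rejected(self):
        with pytest.raises(ValidationError):
            Partition(np.array([0, 2, 2]))

    def test_from_membership_renumbers_by_first_appearance(self):
        part = Partition.from_membership([7, 7, 3, 7, 3, 9])
        assert part.membership.tolist() == [0, 0, 1, 0, 1, 2]
        assert part.n_modules == 3


class TestProportionalThreshold:
    def test_density_one_keeps_all_positive_entries(self, rng):
        raw = np.abs(rng.standard_normal((6, 6)))
        z = (raw + raw.T) / 2
        np.fill_diagonal(z, 0.0)
        g = proportional_threshold(z, 1.0)
        np.testing.assert_allclose(g.w, z)

    def test_half_density_keeps_three_of_six(self):
        z = np.zeros((4, 4))
        iu = np.triu_indices(4, k=1)
        z[iu] = [0.9, 0.1, 0.8, 0.2, 0.7, 0.3]
        z = z + z.T
        g = proportional_threshold(z, 0.5)
        kept = sorted(g.w[iu][g.w[iu] > 0].tolist())
        assert kept == [0.7, 0.8, 0.9]

    def test_rounding_at_full_parcellation_scale(self):
        # round(0.25 * 33,153) = 8,288 under half-away-from-zero rounding
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((258, 258))
        z = (raw + raw.T) / 2
        np.fill_diagonal(z, 0.0)
        g = proportional_threshold(z, 0.25)
        iu = np.triu_indices(258, k=1)
        assert int(np.count_nonzero(g.w[iu])) == 8_288

    def test_retained_negative_weights_zeroed(self):
        z = np.zeros((3, 3))
        iu = np.triu_indices(3, k=1)
        z[iu] = [0.5, -0.2, -0.4]
        z = z + z.T
        g = proportional_threshold(z, 1.0)
        assert g.w.min() == 0.0
        assert g.w[0, 1] == 0.5

    def test_out_of_range_density_rejected(self):
        with pytest.raises(ParameterError):
            proportional_threshold(np.zeros((3, 3)), 0.0)


class TestRewireNull:
    def test_triangle_topology_unchanged_weights_permuted(self):
        w = np.zeros((3, 3))
        iu = np.triu_indices(3, k=1)
        w[iu] = [1.0, 2.0, 3.0]
        w = w + w.T
        null = rewire_null(WeightedGraph(w), seed=0)
        assert (null.w > 0).sum() == (w > 0).sum()
        np.testing.assert_array_equal((null.w > 0), (w > 0))
        assert sorted(null.w[iu].tolist()) == [1.0, 2.0, 3.0]

    def test_degree_sequence_and_weight_multiset_preserved(self, rng):
        for k in range(50):
            g = random_weighted_graph(int(rng.integers(5, 15)), rng)
            if g.n_edges < 2:
                continue
            null = rewire_null(g, seed=k)
            np.testing.assert_array_equal(
                np.sort(null.degree()), np.sort(g.degree())
            )
            iu = np.triu_indices(g.n, k=1)
            np.testing.assert_allclose(
                np.sort(null.w[iu][null.w[iu] > 0]),
                np.sort(g.w[iu][g.w[iu] > 0]),
            )

    def test_nulls_break_planted_modularity(self, two_cliques):
        g, part = two_cliques
        # bridge the cliques a little so swaps exist
        w = g.w.copy()
        w[0, 4] = w[4, 0] = 1.0
        w[1, 5] = w[5, 1] = 1.0
        g = WeightedGraph(w)
        q_orig = best_louvain(g, 10, 0)[1]
        q_nulls = []
        for k in range(100):
            null = rewire_null(g, seed=k)
            q_nulls.append(best_louvain(null, 5, k)[1])
        assert float(np.mean(q_nulls)) < q_orig


class TestModularity:
    def test_single_module_gives_zero(self, rng):
        g = random_weighted_graph(7, rng)
        assert modularity_Q(g, Partition(np.zeros(7, dtype=int))) == pytest.approx(0.0, abs=1e-12)

    def test_two_cliques_half(self, two_cliques):
        g, part = two_cliques
        assert modularity_Q(g, part) == pytest.approx(0.5, abs=1e-12)

    def test_k4_singletons(self, k4):
        assert modularity_Q(k4, Partition(np.arange(4))) == pytest.approx(-0.25, abs=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 13))
            g = random_weighted_graph(n, rng)
            membership = rng.integers(0, 3, n)
            part = Partition.from_membership(membership)
            assert modularity_Q(g, part) == pytest.approx(
                brute_force_q(g.w, part.membership), abs=1e-12
            )

    def test_invariant_under_relabeling_and_node_permutation(self, rng):
        g = random_weighted_graph(9, rng)
        membership = rng.integers(0, 3, 9)
        part = Partition.from_membership(membership)
        q = modularity_Q(g, part)
        # relabel modules
        relabeled = Partition.from_membership(2 - part.membership)
        assert modularity_Q(g, relabeled) == pytest.approx(q, abs=1e-12)
        # permute nodes consistently
        perm = rng.permutation(9)
        g2 = WeightedGraph(g.w[np.ix_(perm, perm)])
        part2 = Partition.from_membership(part.membership[perm])
        assert modularity_Q(g2, part2) == pytest.approx(q, abs=1e-12)

    def test_agrees_with_networkx(self, rng):
        g = random_weighted_graph(10, rng)
        membership = rng.integers(0, 3, 10)
        part = Partition.from_membership(membership)
        nxg = nx.from_numpy_array(g.w)
        communities = [
            set(np.flatnonzero(part.membership == k)) for k in range(part.n_modules)
        ]
        ref = nx.community.modularity(nxg, communities, weight="weight")
        assert modularity_Q(g, part) == pytest.approx(ref, abs=1e-12)

    def test_zero_cost_graph_rejected(self):
        with pytest.raises(ParameterError):
            modularity_Q(WeightedGraph(np.zeros((3, 3))), Partition(np.zeros(3, dtype=int)))


class TestLouvain:
    def test_two_cliques_recovered(self, two_cliques):
        g, planted = two_cliques
        part, q = best_louvain(g, 10, seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        same_found = part.membership[:, None] == part.membership[None, :]
        same_true = planted.membership[:, None] == planted.membership[None, :]
        assert (same_found == same_true).all()

    def test_complete_graph_best_q_zero(self, k4):
        _, q = best_louvain(k4, 10, seed=1)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_optimum_on_small_graphs(self, rng):
        for k in range(15):
            g = random_weighted_graph(int(rng.integers(4, 9)), rng)
            _, q = best_louvain(g, 20, seed=k)
            assert q == pytest.approx(exhaustive_best_q(g.w), abs=1e-9)

    def test_deterministic_given_seed(self, rng):
        g = random_weighted_graph(12, rng)
        p1, q1 = best_louvain(g, 5, seed=3)
        p2, q2 = best_louvain(g, 5, seed=3)
        assert q1 == q2
        np.testing.assert_array_equal(p1.membership, p2.membership)


class TestGlobalEfficiency:
    def test_complete_graph_is_one(self, k4):
        assert global_efficiency(k4) == pytest.approx(1.0, abs=1e-12)

    def test_three_node_path(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        assert global_efficiency(WeightedGraph(w)) == pytest.approx(5 / 6, abs=1e-12)

    def test_isolated_node_contributes_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        assert global_efficiency(WeightedGraph(w)) == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(8):
            g = random_weighted_graph(int(rng.integers(5, 31)), rng, p=0.3)
            assert global_efficiency(g) == pytest.approx(
                floyd_warshall_efficiency(g.w), abs=1e-12
            )


class TestSubjectMetrics:
    def _cfg(self, **kw):
        base = dict(
            densities=(0.25,),
            n_nulls=10,
            n_louvain_subject=10,
            n_louvain_null=5,
            n_louvain_group=10,
            n_perm=10,
            seed=0,
        )
        base.update(kw)
        return PipelineConfig(**base)

    def test_modular_matrix_gives_qnorm_above_one(self, rng):
        from conncompare.synthetic import planted_partition_graph

        g, _ = planted_partition_graph(
            [10, 10, 10], w_in=1.0, w_out=1.0, p_in=0.9, p_out=0.05, seed=4
        )
        # feed the planted graph through as a full "connectivity" matrix
        z = g.w + rng.uniform(0, 0.05, g.w.shape)
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        conn = ConnectivityMatrix("s", "A", z)
        rec = subject_metrics(conn, self._cfg(), seed=0)[0]
        assert isinstance(rec, GraphMetricsRecord)
        assert rec.q_norm > 1.0
        assert rec.q_norm == pytest.approx(rec.q_raw / rec.q_null_mean, abs=1e-12)
        assert rec.e_norm == pytest.approx(rec.e_raw / rec.e_null_mean, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        raw = rng.standard_normal((20, 20))
        z = (raw + raw.T) / 2
        np.fill_diagonal(z, 0.0)
        conn = ConnectivityMatrix("s", "A", z)
        r1 = subject_metrics(conn, self._cfg(), seed=5)
        r2 = subject_metrics(conn, self._cfg(), seed=5)
        assert r1 == r2

    def test_one_record_per_density(self, rng):
        raw = np.abs(rng.standard_normal((15, 15)))
        z = (raw + raw.T) / 2
        np.fill_diagonal(z, 0.0)
        conn = ConnectivityMatrix("s", "A", z)
        recs = subject_metrics(conn, self._cfg(densities=(0.15, 0.25)), seed=1)
        assert [r.density for r in recs] == [0.15, 0.25]


class TestCompareGroups:
    def test_identical_samples_tie(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.ranksum_p == pytest.approx(1.0, abs=0.05)
        assert res.ranksum_z == pytest.approx(0.0, abs=1e-12)

    def test_extreme_separation_exact_p(self):
        res = compare_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.ranksum_p == pytest.approx(0.1, abs=1e-12)
        assert res.ranksum_z > 0  # B ranks higher

    def test_variance_ratio_definition(self, rng):
        b = rng.standard_normal(21)
        a = b * 2.0  # var(A) = 4 var(B)
        res = compare_groups(a, b)
        assert res.f_stat == pytest.approx(4.0, abs=1e-12)
        assert res.df == (20, 20)

    def test_tied_heavy_samples_fall_back_to_normal_approx(self):
        res = compare_groups([1.0] * 5 + [2.0], [1.0] * 4 + [2.0, 2.0])
        assert 0.0 < res.ranksum_p <= 1.0

    def test_matches_scipy_ranksums_without_ties(self, rng):
        from scipy import stats as sps

        a = rng.standard_normal(15)
        b = rng.standard_normal(17) + 0.5
        res = compare_groups(a, b)
        ref = sps.ranksums(b, a)
        assert res.ranksum_z == pytest.approx(ref.statistic, abs=1e-12)
        assert res.ranksum_p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            compare_groups([1.0], [1.0, 2.0])
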
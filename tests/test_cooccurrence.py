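import itertools

import networkx as nx
import numpy as np
import pytest

from plaque_signals.cooccurrence import (
    CorrelationNetwork,
    StratumKey,
    basis_correlations_from_fractions,
    betweenness_ranking,
    build_network,
    cluster_strata,
    layout_fr,
    mantel_distance,
    mantel_r,
    permutation_pvalues,
    sparcc,
    strong_edge_cutoff,
    stratify_counts,
)
from plaque_signals.io_core import CountMatrix, ValidationError
from plaque_signals.synthetic import generate_compositional_counts


def _network_from_edges(nodes, edges):
    d = len(nodes)
    corr = np.eye(d)
    index = {n: i for i, n in enumerate(nodes)}
    edge_list = []
    for a, b in edges:
        corr[index[a], index[b]] = corr[index[b], index[a]] = 0.9
        edge_list.append((a, b, 0.9))
    return CorrelationNetwork(
        node_ids=list(nodes),
        corr=corr,
        pvals=np.zeros((d, d)),
        threshold=0.5,
        significance=0.05,
        edges=edge_list,
        dropped_nodes=[],
    )


class TestSparcc:
    def test_three_taxon_closed_form(self):
        # at D=3 the sparse linear system is the exact 3-equation basis
        # solution: w_i^2 = (t_ij + t_ik - t_jk)/2, which forces rho = 0
        rng = np.random.default_rng(1)
        frac = rng.dirichlet([5, 3, 2], size=50).T
        rho, internals = basis_correlations_from_fractions(frac)
        t = internals.variation_matrix
        w_expected = np.array(
            [
                (t[0, 1] + t[0, 2] - t[1, 2]) / 2,
                (t[0, 1] + t[1, 2] - t[0, 2]) / 2,
                (t[0, 2] + t[1, 2] - t[0, 1]) / 2,
            ]
        )
        np.testing.assert_allclose(internals.basis_variances, w_expected, atol=1e-10)
        for i, j in itertools.combinations(range(3), 2):
            expected = (
                w_expected[i] + w_expected[j] - t[i, j]
            ) / (2 * np.sqrt(w_expected[i] * w_expected[j]))
            assert rho[i, j] == pytest.approx(expected, abs=1e-6)

    def test_independent_taxa_give_near_zero_correlations(self):
        counts = generate_compositional_counts(np.eye(20), 500, depth=5000, seed=42)
        corr, _ = sparcc(counts, seed=0)
        iu = np.triu_indices(20, k=1)
        assert np.abs(corr[iu]).mean() < 0.05

    def test_recovers_planted_basis_correlation(self):
        target = np.eye(20)
        target[0, 1] = target[1, 0] = 0.8
        hits = 0
        for seed in range(5):
            counts = generate_compositional_counts(target, 500, depth=5000, seed=seed)
            corr, _ = sparcc(counts, seed=seed)
            hits += abs(corr[0, 1] - 0.8) <= 0.1
        assert hits >= 4

    def test_less_biased_than_naive_pearson_on_compositions(self):
        # the motivating compositional-bias property: with independent
        # basis variables, naive Pearson on relative abundances is
        # biased negative; the basis estimator should be closer to zero
        counts = generate_compositional_counts(np.eye(20), 500, depth=5000, seed=7)
        corr, _ = sparcc(counts, seed=7)
        rel = counts.counts / counts.counts.sum(axis=0, keepdims=True)
        naive = np.corrcoef(rel)
        iu = np.triu_indices(20, k=1)
        assert np.abs(corr[iu]).mean() < np.abs(naive[iu]).mean()

    def test_permutation_equivariance_of_basis_solver(self, rng):
        frac = rng.dirichlet(np.ones(8), size=60).T
        perm = rng.permutation(8)
        rho, _ = basis_correlations_from_fractions(frac)
        rho_perm, _ = basis_correlations_from_fractions(frac[perm])
        np.testing.assert_allclose(rho_perm, rho[np.ix_(perm, perm)], atol=1e-12)

    def test_internals_consistent_with_correlations(self, rng):
        frac = rng.dirichlet(np.ones(6), size=40).T
        rho, internals = basis_correlations_from_fractions(frac)
        t = internals.variation_matrix
        np.testing.assert_allclose(t, t.T, atol=1e-12)
        assert np.all(np.diag(t) == 0)
        w = internals.basis_variances
        recomputed = (w[:, None] + w[None, :] - t) / (
            2 * np.sqrt(np.outer(w, w))
        )
        np.fill_diagonal(recomputed, 1.0)
        np.testing.assert_allclose(np.clip(recomputed, -1, 1), rho, atol=1e-9)

    def test_all_zero_taxon_rejected(self):
        counts = CountMatrix(
            ["a", "b", "c"], ["s1", "s2"], np.array([[1, 2], [0, 0], [3, 4]])
        )
        with pytest.raises(ValidationError, match="b"):
            sparcc(counts)

    def test_output_is_deterministic_given_seed(self):
        counts = generate_compositional_counts(np.eye(5), 40, depth=500, seed=0)
        a, _ = sparcc(counts, inference_iters=5, seed=3)
        b, _ = sparcc(counts, inference_iters=5, seed=3)
        np.testing.assert_array_equal(a, b)


class TestPermutationPvalues:
    def test_add_one_pseudo_count_floor(self):
        counts = generate_compositional_counts(np.eye(5), 40, depth=500, seed=1)
        # an "observed" correlation larger than anything permutations
        # can produce gives the floor p = 1/(n_perm + 1)
        observed = np.full((5, 5), 0.9999)
        np.fill_diagonal(observed, 1.0)
        p = permutation_pvalues(counts, observed, n_perm=20, inference_iters=3, seed=0)
        iu = np.triu_indices(5, k=1)
        np.testing.assert_allclose(p[iu], 1 / 21)

    def test_zero_observed_correlation_has_high_p(self):
        counts = generate_compositional_counts(np.eye(5), 40, depth=500, seed=2)
        p = permutation_pvalues(
            counts, np.eye(5), n_perm=20, inference_iters=3, seed=0
        )
        iu = np.triu_indices(5, k=1)
        assert p[iu].min() > 0.5

    def test_null_p_values_roughly_uniform(self):
        counts = generate_compositional_counts(np.eye(10), 200, depth=2000, seed=3)
        corr, _ = sparcc(counts, inference_iters=5, seed=1)
        p = permutation_pvalues(
            counts, corr, n_perm=40, inference_iters=5, seed=2
        )
        iu = np.triu_indices(10, k=1)
        frac = (p[iu] < 0.25).mean()
        assert abs(frac - 0.25) < 0.15


class TestStrongEdgeCutoff:
    def test_constant_off_diagonal_returns_that_constant(self):
        corr = np.full((4, 4), 0.3)
        np.fill_diagonal(corr, 1.0)
        assert strong_edge_cutoff(corr) == pytest.approx(0.3)

    def test_hand_computed_example(self):
        # off-diagonal values {0, 0.2, 0.4}: mean 0.2, population SD
        # sqrt(0.02667), threshold 0.2 + 1.96*0.16330 = 0.5201
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.0
        corr[0, 2] = corr[2, 0] = 0.2
        corr[1, 2] = corr[2, 1] = 0.4
        assert strong_edge_cutoff(corr) == pytest.approx(0.5201, abs=1e-4)


class TestBuildNetwork:
    def test_threshold_above_max_gives_empty_network(self):
        corr = np.eye(3) * 0.0 + np.eye(3)
        net = build_network(["a", "b", "c"], corr, np.zeros((3, 3)), threshold=2.0)
        assert net.edges == []
        assert net.dropped_nodes == ["a", "b", "c"]

    def test_single_strong_edge_drops_isolated_node(self):
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.8
        corr[0, 2] = corr[2, 0] = 0.1
        corr[1, 2] = corr[2, 1] = 0.1
        pvals = np.zeros((3, 3))
        net = build_network(["a", "b", "c"], corr, pvals, threshold=0.5)
        assert [(a, b) for a, b, _ in net.edges] == [("a", "b")]
        assert net.dropped_nodes == ["c"]

    def test_insignificant_edges_excluded(self):
        corr = np.eye(2 + 1)
        corr[0, 1] = corr[1, 0] = 0.9
        pvals = np.ones((3, 3))
        net = build_network(["a", "b", "c"], corr, pvals, threshold=0.5)
        assert net.edges == []

    def test_edge_count_monotone_in_threshold(self, rng):
        d = 10
        corr = np.corrcoef(rng.normal(size=(d, 50)))
        pvals = np.zeros((d, d))
        nodes = [f"n{i}" for i in range(d)]
        thresholds = np.linspace(-1, 1, 21)
        counts = [
            len(build_network(nodes, corr, pvals, t).edges) for t in thresholds
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestBetweenness:
    def test_path_graph_center_carries_all_paths(self):
        net = _network_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])
        ranking = dict(betweenness_ranking(net))
        assert ranking == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_star_center_scores_all_pairs(self):
        nodes = ["hub", "l1", "l2", "l3", "l4"]
        net = _network_from_edges(nodes, [("hub", leaf) for leaf in nodes[1:]])
        ranking = betweenness_ranking(net)
        assert ranking[0] == ("hub", 6.0)  # C(4,2) pairs through the hub
        assert all(score == 0.0 for _, score in ranking[1:])

    def test_matches_brute_force_enumeration_on_small_graphs(self):
        # independent oracle: count shortest paths through each node by
        # explicit enumeration over all simple paths
        def brute_force(graph):
            nodes = list(graph.nodes)
            scores = dict.fromkeys(nodes, 0.0)
            for s, t in itertools.combinations(nodes, 2):
                paths = list(nx.all_simple_paths(graph, s, t))
                if not paths:
                    continue
                shortest = min(len(p) for p in paths)
                sps = [p for p in paths if len(p) == shortest]
                for node in nodes:
                    if node in (s, t):
                        continue
                    through = sum(node in p for p in sps)
                    scores[node] += through / len(sps)
            return scores

        rng = np.random.default_rng(0)
        for _ in range(15):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(10**6)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
            if g.number_of_edges() == 0:
                continue
            edges = list(g.edges)
            net = _network_from_edges(list(g.nodes), edges)
            result = dict(betweenness_ranking(net))
            expected = brute_force(net.graph())
            for node in expected:
                assert result[node] == pytest.approx(expected[node], abs=1e-9)


class TestMantel:
    def test_identical_matrices_give_r_one(self, rng):
        a = np.corrcoef(rng.normal(size=(5, 30)))
        assert mantel_r(a, a) == pytest.approx(1.0)
        assert mantel_distance(a, a) == pytest.approx(0.0)

    def test_negated_off_diagonal_gives_r_minus_one(self, rng):
        a = np.corrcoef(rng.normal(size=(5, 30)))
        b = -a.copy()
        np.fill_diagonal(b, 1.0)
        assert mantel_r(a, b) == pytest.approx(-1.0)

    def test_matches_hand_computed_pearson_on_upper_triangle(self):
        a = np.eye(4)
        b = np.eye(4)
        ua = [0.1, 0.5, -0.2, 0.3, 0.0, 0.7]
        ub = [0.2, 0.4, -0.1, 0.1, 0.2, 0.6]
        iu = np.triu_indices(4, k=1)
        a[iu] = ua
        b[iu] = ub
        a = a + a.T - np.diag(np.diag(a))
        b = b + b.T - np.diag(np.diag(b))
        x, y = np.array(ua), np.array(ub)
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert mantel_r(a, b) == pytest.approx(expected, abs=1e-12)

    def test_mismatched_shapes_error(self):
        with pytest.raises(ValidationError):
            mantel_r(np.eye(4), np.eye(5))


class TestClusterStrata:
    def _corr_with_upper(self, values, d=4):
        m = np.eye(d)
        iu = np.triu_indices(d, k=1)
        m[iu] = values
        return m + m.T - np.diag(np.diag(m))

    def test_identical_pair_merges_first(self, rng):
        base = rng.normal(size=6)
        orthogonal = rng.normal(size=6)
        a = self._corr_with_upper(base)
        b = self._corr_with_upper(base)
        c = self._corr_with_upper(orthogonal)
        z, labels, newick = cluster_strata(
            {
                StratumKey(0, False): a,
                StratumKey(1, False): b,
                StratumKey(2, True): c,
            }
        )
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}  # the identical pair
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert newick.endswith(");")

    def test_complete_linkage_matches_hand_trace(self, rng):
        # three matrices; hand-trace: merge the closest pair at d_min,
        # then join the third at max of its two distances
        mats = [self._corr_with_upper(rng.normal(size=6)) for _ in range(3)]
        keys = [StratumKey(0, False), StratumKey(1, False), StratumKey(2, True)]
        d01 = mantel_distance(mats[0], mats[1])
        d02 = mantel_distance(mats[0], mats[2])
        d12 = mantel_distance(mats[1], mats[2])
        z, labels, _ = cluster_strata(dict(zip(keys, mats)))
        dists = {(0, 1): d01, (0, 2): d02, (1, 2): d12}
        (i, j), dmin = min(dists.items(), key=lambda kv: kv[1])
        k = ({0, 1, 2} - {i, j}).pop()
        expected_second = max(dists[tuple(sorted((i, k)))], dists[tuple(sorted((j, k)))])
        assert {int(z[0, 0]), int(z[0, 1])} == {i, j}
        assert z[0, 2] == pytest.approx(dmin)
        assert z[1, 2] == pytest.approx(expected_second)

    def test_needs_at_least_two_strata(self):
        with pytest.raises(ValidationError):
            cluster_strata({StratumKey(0, False): np.eye(4)})


class TestLayoutAndStratify:
    def test_layout_deterministic_given_seed(self):
        net = _network_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])
        la = layout_fr(net, seed=5)
        lb = layout_fr(net, seed=5)
        for node in la:
            np.testing.assert_array_equal(la[node], lb[node])

    def test_star_layout_symmetric_leaf_distances(self):
        nodes = ["hub"] + [f"l{i}" for i in range(6)]
        net = _network_from_edges(nodes, [("hub", l) for l in nodes[1:]])
        pos = layout_fr(net, seed=1, iterations=500)
        dists = [np.linalg.norm(pos[l] - pos["hub"]) for l in nodes[1:]]
        assert (max(dists) - min(dists)) / np.mean(dists) < 0.05

    def test_stratify_counts_respects_minimum(self, small_meta):
        counts = CountMatrix(
            ["t1"], ["s1", "s2", "s3"], np.array([[1, 2, 3]])
        )
        strata = stratify_counts(counts, small_meta, min_samples=1)
        assert StratumKey(0, False) in strata
        assert StratumKey(6, True) in strata
        assert stratify_counts(counts, small_meta, min_samples=2) == {}
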
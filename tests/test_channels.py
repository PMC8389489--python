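import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path

from eegsel.channels import (DeltaMatrix, EpochClustering,
                             affinity_propagation, build_coactivation_graph,
                             channel_similarity, neighboring_matrix,
                             rank_channels, select_top_fraction,
                             spatial_factor)
from eegsel.montage import Montage


def _path_montage(names):
    xy = np.column_stack([np.arange(len(names), dtype=float),
                          np.zeros(len(names))])
    g = nx.path_graph(names)
    return Montage(names=tuple(names), positions=xy, graph=g)


class TestNeighboringMatrix:
    def test_diagonal_is_zero(self, montage32):
        d = neighboring_matrix(montage32, kappa_max=2)
        assert np.all(np.diag(d.delta) == 0)

    def test_two_hop_path(self):
        d = neighboring_matrix(_path_montage(["A", "B", "C"]), kappa_max=2)
        assert d.delta[0, 2] == 2
        assert d.delta[0, 1] == 1

    def test_beyond_cap_is_zero(self):
        d = neighboring_matrix(_path_montage(["A", "B", "C", "D"]), kappa_max=2)
        assert d.delta[0, 3] == 0  # three hops exceeds the cap

    def test_agrees_with_bfs_on_random_graphs(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 21))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(g):
                g = nx.compose(g, nx.path_graph(n))
            names = tuple(f"n{i}" for i in range(n))
            g = nx.relabel_nodes(g, dict(enumerate(names)))
            m = Montage(names=names, positions=rng.standard_normal((n, 2)),
                        graph=g)
            kappa_max = int(rng.integers(1, 4))
            d = neighboring_matrix(m, kappa_max=kappa_max)
            adj = nx.to_numpy_array(g, nodelist=names)
            hops = shortest_path(adj, unweighted=True)
            expected = np.where((hops > 0) & (hops <= kappa_max), hops, 0)
            assert np.array_equal(d.delta, expected.astype(int))

    def test_disconnected_montage_rejected(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("C")
        m = Montage(names=("A", "B", "C"),
                    positions=np.array([[0.0, 0], [1, 0], [5, 5]]), graph=g)
        with pytest.raises(ValueError, match="C"):
            neighboring_matrix(m, kappa_max=2)


class TestChannelSimilarity:
    def test_duplicated_channels_fully_similar(self, rng):
        X = rng.standard_normal((4, 6))
        X[1] = X[0]
        S = channel_similarity(X)
        assert S[0, 1] == pytest.approx(1.0)

    def test_negated_channel_fully_dissimilar(self, rng):
        X = rng.standard_normal((4, 6))
        X[1] = -X[0]
        S = channel_similarity(X, standardize="none")
        # after centering, the negated copy is perfectly anticorrelated
        assert S[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_pearson_formula(self, rng):
        X = rng.standard_normal((4, 6))
        S = channel_similarity(X, standardize="none")
        for i, j in itertools.combinations(range(4), 2):
            xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
            expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
            assert S[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_channel_flagged_as_zero(self):
        X = np.random.default_rng(0).standard_normal((4, 6))
        X[2] = 3.14
        S = channel_similarity(X, standardize="none")
        assert np.all(S[2, [0, 1, 3]] == 0.0)

    def test_symmetric_unit_diagonal(self, rng):
        S = channel_similarity(rng.standard_normal((8, 10)))
        assert np.allclose(S, S.T)
        assert np.allclose(np.diag(S), 1.0)


def _block_similarity(rng, sizes, within=0.9, between=-0.2, jitter=0.01):
    n = sum(sizes)
    S = np.full((n, n), between)
    start = 0
    for size in sizes:
        S[start:start + size, start:start + size] = within
        start += size
    S += jitter * rng.standard_normal((n, n))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return S


class TestAffinityPropagation:
    def test_two_separated_pairs_form_two_clusters(self, rng):
        # moderate damping: heavy damping on a 4-point problem leaves all
        # points self-exemplars (verified against the reference implementation)
        S = _block_similarity(rng, [2, 2])
        cl = affinity_propagation(S, damping=0.5)
        assert len(cl.exemplars) == 2
        assert cl.labels[0] == cl.labels[1]
        assert cl.labels[2] == cl.labels[3]
        assert cl.labels[0] != cl.labels[2]

    def test_high_preference_makes_singletons(self):
        S = np.full((5, 5), 0.1)
        np.fill_diagonal(S, 0.0)
        cl = affinity_propagation(S, preference=10.0)
        assert len(cl.exemplars) == 5
        assert np.all(cl.L == 0)  # co-membership excludes i == j

    def test_agrees_with_reference_implementation(self, rng):
        # damping 0.7: at 0.9 the reference's early-stability convergence
        # check can lock in degenerate one-cluster solutions on toy blocks
        from sklearn.cluster import AffinityPropagation
        agree = 0
        for trial in range(12):
            sizes = rng.integers(3, 6, size=int(rng.integers(2, 4)))
            S = _block_similarity(rng, list(sizes))
            pref = float(np.median(S[~np.eye(len(S), dtype=bool)]))
            ours = affinity_propagation(S, damping=0.7, preference=pref)
            ref = AffinityPropagation(affinity="precomputed", damping=0.7,
                                      preference=pref, max_iter=500,
                                      random_state=0).fit(S)
            if set(ours.exemplars) == set(ref.cluster_centers_indices_):
                agree += 1
        assert agree >= 10

    def test_permutation_equivariance(self, rng):
        S = _block_similarity(rng, [3, 2, 3])
        perm = rng.permutation(len(S))
        cl = affinity_propagation(S)
        cl_p = affinity_propagation(S[np.ix_(perm, perm)])
        assert set(perm[list(cl_p.exemplars)]) == set(cl.exemplars)
        assert np.array_equal(cl_p.L, cl.L[np.ix_(perm, perm)])

    def test_co_membership_contract(self, rng):
        for _ in range(5):
            X = rng.standard_normal((10, 10))
            S = (X + X.T) / 2
            np.fill_diagonal(S, 1.0)
            cl = affinity_propagation(S, max_iter=200)
            L = cl.L
            assert np.array_equal(L, L.T)
            assert np.all(np.diag(L) == 0)
            # transitivity: i~j and j~k implies i~k
            for i, j, k in itertools.permutations(range(10), 3):
                if L[i, j] and L[j, k]:
                    assert L[i, k] == 1

    def test_asymmetric_similarity_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            affinity_propagation(rng.standard_normal((4, 4)))


class TestCoactivationGraph:
    def _delta(self):
        delta = np.array([[0, 1, 0], [1, 0, 2], [0, 2, 0]])
        return DeltaMatrix(delta=delta, kappa_max=2, channel_names=("a", "b", "c"))

    def test_adjacent_pair_discounted(self):
        S = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.5], [0.8, 0.5, 1.0]])
        L = 1 - np.eye(3, dtype=int)
        W = build_coactivation_graph(S, L, self._delta())
        assert W[0, 1] == pytest.approx(0.9 * (1 / 3))  # one hop: delta/(cap+1)
        assert W[1, 2] == pytest.approx(0.5 * (2 / 3))  # two hops

    def test_non_co_clustered_pair_has_zero_weight(self):
        S = np.full((3, 3), 0.8)
        L = np.zeros((3, 3), dtype=int)
        W = build_coactivation_graph(S, L, self._delta())
        assert np.all(W == 0)

    def test_distant_pair_undiscounted(self):
        S = np.full((3, 3), 0.8)
        L = 1 - np.eye(3, dtype=int)
        W = build_coactivation_graph(S, L, self._delta())
        assert W[0, 2] == pytest.approx(0.8)  # beyond cap: factor 1

    def test_negative_similarity_clamped(self):
        S = np.full((3, 3), -0.5)
        L = 1 - np.eye(3, dtype=int)
        W = build_coactivation_graph(S, L, self._delta())
        assert np.all(W == 0)


class TestRankChannels:
    def _identical_clusterings(self, rng, n_epochs=6):
        S = _block_similarity(rng, [2, 3])
        cl = affinity_propagation(S, damping=0.5)
        delta = DeltaMatrix(delta=np.zeros((5, 5), dtype=int), kappa_max=2,
                            channel_names=tuple("abcde"))
        g = build_coactivation_graph(S, cl.L, delta)
        return [cl] * n_epochs, [g] * n_epochs, delta

    def test_identical_epochs_all_retained(self, rng):
        cls_, gs, delta = self._identical_clusterings(rng)
        ranking = rank_channels(cls_, gs, tuple("abcde"), delta=delta,
                                epoch_filter="median")
        assert ranking.retained_epochs == tuple(range(6))

    def test_everpresent_exemplar_with_max_degree_ranks_first(self, rng):
        # channel "a" co-activates strongly and persistently with b and c
        # and is the exemplar of that cluster in every epoch: it dominates
        # both the strength and the exemplar-frequency term
        S = np.array([
            [1.0, 0.9, 0.9, 0.0, 0.0],
            [0.9, 1.0, 0.5, 0.0, 0.0],
            [0.9, 0.5, 1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 1.0, 0.2],
            [0.0, 0.0, 0.0, 0.2, 1.0],
        ])
        labels = np.array([0, 0, 0, 3, 4])
        L = (labels[:, None] == labels[None, :]).astype(int)
        np.fill_diagonal(L, 0)
        cl = EpochClustering(S=S, exemplars=(0, 3, 4), labels=labels, L=L,
                             converged=True, iterations=1)
        delta = DeltaMatrix(delta=np.zeros((5, 5), dtype=int), kappa_max=2,
                            channel_names=tuple("abcde"))
        g = build_coactivation_graph(S, L, delta)
        ranking = rank_channels([cl] * 4, [g] * 4, tuple("abcde"),
                                alpha=0.5, delta=delta)
        assert ranking.order[0] == "a"
        assert ranking.exemplar_frequency["a"] == 1.0

    def test_needs_at_least_two_epochs(self, rng):
        cls_, gs, delta = self._identical_clusterings(rng, n_epochs=1)
        with pytest.raises(ValueError, match="2 epochs"):
            rank_channels(cls_[:1], gs[:1], tuple("abcde"), delta=delta)


class TestSelectTopFraction:
    def test_full_fraction_keeps_all(self):
        order = ("a", "b", "c", "d")
        assert select_top_fraction(order, 1.0) == order

    def test_ceiling_rule(self):
        order = tuple(f"c{i}" for i in range(32))
        assert len(select_top_fraction(order, 0.1)) == 4

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            select_top_fraction(("a", "b"), 0.0)


def test_spatial_factor_formula():
    delta = np.array([[0, 1, 2, 0], [1, 0, 1, 3], [2, 1, 0, 1], [0, 3, 1, 0]])
    f = spatial_factor(delta, kappa_max=2)
    assert f[0, 1] == pytest.approx(1 / 3)
    assert f[0, 2] == pytest.approx(2 / 3)
    assert f[0, 3] == 1.0  # delta 0: beyond cap
    assert f[1, 3] == 1.0  # delta 3 > kappa_max (uncapped input): undiscounted
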
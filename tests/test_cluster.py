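"""SNN graphs, Leiden partitions, consensus matrices, WPGMA cuts, silhouettes."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from scmsi import (
    build_snn_graph,
    consensus_cluster,
    consensus_cut,
    leiden_partition,
    select_k,
    silhouette,
    tsne_embed,
)
from scmsi.cluster import SNNGraph


def brute_force_snn(X, k):
    """Exhaustive k-NN sets (ties by index) and Jaccard edge weights."""
    n = len(X)
    D = squareform(pdist(X))
    sets = []
    for i in range(n):
        order = sorted(range(n), key=lambda j: (D[i, j], j) if j != i else (-1.0, -1))
        sets.append(set(order[: k + 1]))
    weights = {}
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            if inter:
                weights[(i, j)] = inter / len(sets[i] | sets[j])
    return weights


def rb_modularity(D_edges, weights, labels, resolution, n):
    """RB-configuration modularity of a partition."""
    strength = np.zeros(n)
    total = 0.0
    for (i, j), w in zip(D_edges, weights):
        strength[i] += w
        strength[j] += w
        total += w
    q = 0.0
    for (i, j), w in zip(D_edges, weights):
        if labels[i] == labels[j]:
            q += w
    for c in set(labels):
        s = sum(strength[i] for i in range(n) if labels[i] == c)
        q -= resolution * s * s / (4 * total)
    return q


class TestSNNGraph:
    def test_identical_points_get_weight_one(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [50.0, 0.0], [0.0, 50.0], [90.0, 90.0]])
        g = build_snn_graph(X, k=1)
        w = {tuple(e): w for e, w in zip(g.edges.tolist(), g.weights)}
        assert w[(0, 1)] == pytest.approx(1.0)

    def test_simplex_symmetry(self):
        # 4 mutually equidistant points: every neighborhood is the full set
        X = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], dtype=float) * np.sqrt(2)
        g = build_snn_graph(X, k=3)
        assert np.allclose(g.weights, 1.0)
        assert len(g.edges) == 6

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 5))
        for k in (3, 7):
            g = build_snn_graph(X, k=k)
            expect = brute_force_snn(X, k)
            got = {tuple(e): w for e, w in zip(g.edges.tolist(), g.weights)}
            assert set(got) == set(expect)
            for e in expect:
                assert got[e] == pytest.approx(expect[e], abs=1e-10)

    def test_invalid_k(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            build_snn_graph(X, k=0)
        with pytest.raises(ValueError):
            build_snn_graph(X, k=5)


class TestLeiden:
    def _two_cliques(self):
        edges, weights = [], []
        for a, b in itertools.combinations(range(6), 2):
            edges.append((a, b))
            weights.append(1.0)
        for a, b in itertools.combinations(range(6, 12), 2):
            edges.append((a, b))
            weights.append(1.0)
        edges.append((0, 6))
        weights.append(0.1)
        return SNNGraph(
            n_nodes=12, edges=np.array(edges), weights=np.array(weights), k_neighbors=0
        )

    def test_two_cliques_found_and_match_modularity_oracle(self):
        g = self._two_cliques()
        labels = leiden_partition(g, resolution=1.0, seed=0)
        assert len(set(labels)) == 2
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        # exhaustive bipartition search for the modularity optimum
        best_q, best_split = -np.inf, None
        for bits in range(1, 2**11):
            lab = [0] + [(bits >> i) & 1 for i in range(11)]
            q = rb_modularity(g.edges.tolist(), g.weights, lab, 1.0, 12)
            if q > best_q:
                best_q, best_split = q, lab
        assert best_split[:6] == [0] * 6
        assert len(set(best_split[6:])) == 1
        q_leiden = rb_modularity(g.edges.tolist(), g.weights, labels.tolist(), 1.0, 12)
        assert q_leiden == pytest.approx(best_q, abs=1e-12)

    def test_resolution_to_zero_gives_single_community(self):
        labels = leiden_partition(self._two_cliques(), resolution=1e-6, seed=0)
        assert len(set(labels)) == 1

    def test_deterministic_under_seed(self):
        g = self._two_cliques()
        a = leiden_partition(g, resolution=1.3, seed=11)
        b = leiden_partition(g, resolution=1.3, seed=11)
        assert np.array_equal(a, b)


def _blobs(n_per=30, sep=8.0, d=4, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n_per, d))
    b = rng.normal(0, 1, (n_per, d)) + sep
    return np.vstack([a, b]), np.r_[np.zeros(n_per, int), np.ones(n_per, int)]


class TestConsensus:
    def test_two_blobs_give_block_consensus(self):
        X, truth = _blobs()
        cc = consensus_cluster(
            X, k_values=(5, 10, 15), resolutions=(0.2, 0.6, 1.0), n_iter=40, seed=1
        )
        assert 2 in cc.consensus
        C = cc.consensus[2]
        same = truth[:, None] == truth[None, :]
        assert C[same].min() > 0.95
        assert C[~same].max() < 0.05

    def test_single_iteration_entries_binary_or_imputed(self):
        X, _ = _blobs(n_per=15)
        cc = consensus_cluster(
            X, k_values=(5,), resolutions=(0.5,), n_iter=1, seed=2, min_support=1
        )
        for K, C in cc.consensus.items():
            fill = C[~np.isin(C, [0.0, 1.0])]
            # non-binary entries can only be the imputation constant
            assert len(np.unique(np.round(fill, 12))) <= 1

    def test_seed_stream_stability(self):
        X, truth = _blobs(n_per=25)
        kw = dict(k_values=(5, 10, 15), resolutions=(0.3, 0.8, 1.3), n_iter=500)
        c1 = consensus_cluster(X, seed=1, **kw).consensus[2]
        c2 = consensus_cluster(X, seed=2, **kw).consensus[2]
        assert np.max(np.abs(c1 - c2)) < 0.05

    def test_offblock_consensus_decreases_with_separation(self):
        means = []
        for sep in (0.5, 1.0, 1.5):
            X, truth = _blobs(n_per=20, sep=sep, seed=3)
            cc = consensus_cluster(
                X, k_values=(5, 10), resolutions=(0.4, 1.0), n_iter=30, seed=3
            )
            C = cc.consensus.get(2)
            same = truth[:, None] == truth[None, :]
            means.append(C[~same].mean() if C is not None else 1.0)
        assert means[0] > means[1] > means[2]

    def test_permutation_equivariance_of_cut(self):
        X, _ = _blobs(n_per=20)
        cc = consensus_cluster(X, k_values=(5, 10), resolutions=(0.5,), n_iter=30, seed=4)
        labels = consensus_cut(cc, 2)
        perm = np.random.default_rng(0).permutation(len(labels))
        import copy

        cc2 = copy.deepcopy(cc)
        cc2.consensus[2] = cc.consensus[2][np.ix_(perm, perm)]
        labels2 = consensus_cut(cc2, 2)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels[perm], labels2) == 1.0


class TestConsensusCut:
    def _perfect_cc(self, sizes):
        n = sum(sizes)
        C = np.zeros((n, n))
        start = 0
        for s in sizes:
            C[start : start + s, start : start + s] = 1.0
            start += s
        from scmsi.cluster import ConsensusClustering

        return ConsensusClustering(
            consensus={len(sizes): C, n: np.eye(n)},
            n_partitions={len(sizes): 50, n: 50},
            n_imputed={},
        )

    def test_perfect_blocks_recovered(self):
        cc = self._perfect_cc([4, 6])
        labels = consensus_cut(cc, 2)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_n_gives_singletons(self):
        cc = self._perfect_cc([5, 5])
        labels = consensus_cut(cc, 10)
        assert len(set(labels)) == 10

    def test_wpgma_heights_match_recursive_oracle(self):
        """Merge heights equal the recursive average of child dissimilarities."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            D = squareform(rng.uniform(0.1, 1.0, 15))  # 6-point instance
            Z = linkage(squareform(D, checks=False), method="weighted")
            heights = brute_force_wpgma(D)
            assert np.allclose(sorted(Z[:, 2]), sorted(heights), atol=1e-10)


def brute_force_wpgma(D):
    """Naive WPGMA: merge closest pair; new dissimilarity = mean of children."""
    D = D.astype(float).copy()
    active = list(range(len(D)))
    dmat = {(i, j): D[i, j] for i in active for j in active if i < j}
    heights = []
    next_id = len(D)
    while len(active) > 1:
        (i, j), h = min(dmat.items(), key=lambda kv: kv[1])
        heights.append(h)
        merged = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            a = dmat[tuple(sorted((i, k)))]
            b = dmat[tuple(sorted((j, k)))]
            dmat[tuple(sorted((merged, k)))] = 0.5 * (a + b)
        active = [k for k in active if k not in (i, j)] + [merged]
        dmat = {key: v for key, v in dmat.items() if i not in key and j not in key}
    return heights


class TestSilhouette:
    def test_two_tight_distant_blobs(self):
        X, labels = _blobs(n_per=15, sep=20.0, seed=6)
        _, mean_s = silhouette(X, labels)
        assert mean_s > 0.9

    def test_identical_points_score_zero(self):
        X = np.zeros((8, 2))
        s, mean_s = silhouette(X, np.r_[np.zeros(4, int), np.ones(4, int)])
        assert np.allclose(s, 0.0)
        assert mean_s == 0.0

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 3))
        labels = np.array([0, 0, 0, 1, 1, 2, 2, 2])
        s, _ = silhouette(X, labels)
        D = squareform(pdist(X))
        for i in range(8):
            same = [j for j in range(8) if labels[j] == labels[i] and j != i]
            a = np.mean([D[i, j] for j in same])
            b = min(
                np.mean([D[i, j] for j in range(8) if labels[j] == c])
                for c in set(labels) - {labels[i]}
            )
            assert s[i] == pytest.approx((b - a) / max(a, b), abs=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((4, 2)), np.zeros(4, int))


class TestSelectK:
    def test_two_blob_data_ranks_k2_first(self):
        X, truth = _blobs(n_per=25, sep=10.0, seed=8)
        cc = consensus_cluster(
            X, k_values=(5, 10, 15), resolutions=(0.2, 0.6, 1.0, 1.4), n_iter=40, seed=8
        )
        cc = select_k(cc, X)
        assert cc.ranking[0] == 2
        assert cc.selected_k == 2

    def test_override_contract(self):
        X, _ = _blobs(n_per=25, sep=10.0, seed=9)
        cc = consensus_cluster(
            X, k_values=(5, 10, 15), resolutions=(0.3, 0.7, 1.1, 1.6), n_iter=40, seed=9
        )
        candidates = sorted(cc.consensus)
        other = candidates[-1]
        cc = select_k(cc, X, override=other)
        assert cc.selected_k == other
        assert np.array_equal(cc.labels, cc.cuts[other])


class TestTsne:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 6))
        a = tsne_embed(X, seed=3)
        b = tsne_embed(X, seed=3)
        assert a.shape == (40, 2)
        assert np.array_equal(a, b)

    def test_duplicated_rows_land_close(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 5))
        X = np.vstack([X, X[:3]])  # duplicates of the first three rows
        Y = tsne_embed(X, seed=4)
        D = squareform(pdist(Y))
        cutoff = np.percentile(D[np.triu_indices(len(Y), 1)], 5)
        for i in range(3):
            assert D[i, 30 + i] <= cutoff
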
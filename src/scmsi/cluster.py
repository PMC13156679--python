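"""SNN/Leiden consensus clustering with subsampling and silhouette selection.

The single-cell clustering procedure: build shared-nearest-neighbor
graphs, partition them with the Leiden algorithm over a grid of
(k-neighbors, resolution) settings on repeated 80% subsamples, bin the
resulting partitions by their realized cluster count K, accumulate one
consensus (co-clustering) matrix per K, cut each with McQuitty (WPGMA)
hierarchical clustering, and rank the candidate K values by mean
silhouette on a PCA embedding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
from scipy import sparse
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "SNNGraph",
    "ConsensusClustering",
    "DEFAULT_K_NEIGHBORS",
    "DEFAULT_RESOLUTIONS",
    "build_snn_graph",
    "leiden_partition",
    "consensus_cluster",
    "consensus_cut",
    "silhouette",
    "select_k",
    "tsne_embed",
]

# Default parameter grid: the procedure sweeps eight neighborhood sizes and
# 19 resolutions spanning under- to over-clustering.
DEFAULT_K_NEIGHBORS: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 40, 50)
DEFAULT_RESOLUTIONS: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 20))


@dataclass
class SNNGraph:
    """Undirected shared-nearest-neighbor graph with Jaccard edge weights."""

    n_nodes: int
    edges: np.ndarray  # (m, 2) int, i < j
    weights: np.ndarray  # (m,) in (0, 1]
    k_neighbors: int

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(n=self.n_nodes, edges=[(int(a), int(b)) for a, b in self.edges])
        g.es["weight"] = self.weights.tolist()
        return g


@dataclass
class ConsensusClustering:
    """Per-candidate-K consensus matrices, cuts, silhouettes and selection."""

    consensus: dict[int, np.ndarray]
    n_partitions: dict[int, int]
    n_imputed: dict[int, int]
    cuts: dict[int, np.ndarray] = field(default_factory=dict)
    silhouettes: dict[int, float] = field(default_factory=dict)
    ranking: list[int] = field(default_factory=list)
    selected_k: int | None = None
    labels: np.ndarray | None = None
    k_values: tuple[int, ...] = DEFAULT_K_NEIGHBORS
    resolutions: tuple[float, ...] = DEFAULT_RESOLUTIONS
    n_iter: int = 500
    subsample: float = 0.8
    seed: int = 0


# ---------------------------------------------------------------------------


def _knn_sets(X: np.ndarray, k: int) -> np.ndarray:
    """Self-inclusive k-NN index sets, Euclidean distance, ties by index."""
    D = squareform(pdist(X))
    np.fill_diagonal(D, -np.inf)  # self is always the first neighbor
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, : k + 1]


def _snn_from_neighbors(nbr: np.ndarray, n: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    size = nbr.shape[1]
    rows = np.repeat(np.arange(n), size)
    A = sparse.csr_matrix(
        (np.ones(n * size), (rows, nbr.ravel())), shape=(n, n)
    )
    inter = sparse.triu(A @ A.T, k=1).tocoo()
    union = 2.0 * size - inter.data
    w = inter.data / union
    edges = np.stack([inter.row, inter.col], axis=1)
    return edges, w


def build_snn_graph(X: np.ndarray, k: int) -> SNNGraph:
    """Shared-nearest-neighbor graph over rows of a scaled feature matrix.

    Neighborhoods are the k nearest rows by Euclidean distance plus the
    point itself (ties broken by index); an edge joins two points whose
    neighborhoods intersect, weighted by the Jaccard index of the sets.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be < number of rows")
    nbr = _knn_sets(X, k)
    edges, w = _snn_from_neighbors(nbr, n, k)
    return SNNGraph(n_nodes=n, edges=edges, weights=w, k_neighbors=k)


def leiden_partition(g: SNNGraph | ig.Graph, resolution: float, seed: int = 0) -> np.ndarray:
    """Leiden communities under the RB-modularity objective (deterministic per seed)."""
    graph = g.to_igraph() if isinstance(g, SNNGraph) else g
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if "weight" in graph.es.attributes() else None,
        resolution_parameter=float(resolution),
        seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership)


# ---------------------------------------------------------------------------


def consensus_cluster(
    X: np.ndarray,
    k_values: tuple[int, ...] = DEFAULT_K_NEIGHBORS,
    resolutions: tuple[float, ...] = DEFAULT_RESOLUTIONS,
    n_iter: int = 500,
    subsample: float = 0.8,
    seed: int = 0,
    min_support: int = 10,
    max_k: int = 40,
) -> ConsensusClustering:
    """Subsampled SNN/Leiden consensus matrices, binned by realized K.

    Each iteration draws ``ceil(subsample * n)`` cells without
    replacement; every (k-neighbors, resolution) combination yields one
    partition of the subsample, which contributes to the consensus matrix
    of its realized cluster count.  Consensus entry (i, j) is the
    co-clustered count over the co-sampled count; candidate K values
    supported by fewer than ``min_support`` partitions are discarded, and
    never-co-sampled entries are imputed with the matrix mean (logged).
    Per-iteration seeds are derived from the master seed by counter, so
    iterations are order-independent.
    """
    if not k_values or not resolutions:
        raise ValueError("parameter grid must be non-empty")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    n_sub = int(math.ceil(subsample * n))
    co_cluster: dict[int, np.ndarray] = {}
    co_sample: dict[int, np.ndarray] = {}
    n_parts: dict[int, int] = {}

    for it in range(n_iter):
        it_seed = (int(seed) * 100003 + it) % (2**31 - 1)
        rng = np.random.default_rng(it_seed)
        sub = np.sort(rng.choice(n, size=n_sub, replace=False))
        Xs = X[sub]
        D = squareform(pdist(Xs))
        np.fill_diagonal(D, -np.inf)
        order = np.argsort(D, axis=1, kind="stable")
        ix = np.ix_(sub, sub)
        # one-hot membership blocks per realized K, multiplied out at the end
        blocks: dict[int, list] = {}
        counts_k: dict[int, int] = {}
        for ki, k in enumerate(k_values):
            if k >= n_sub:
                continue
            edges, w = _snn_from_neighbors(order[:, : k + 1], n_sub, k)
            graph = ig.Graph(n=n_sub, edges=[(int(a), int(b)) for a, b in edges])
            graph.es["weight"] = w.tolist()
            for ri, res in enumerate(resolutions):
                labels = leiden_partition(graph, res, seed=it_seed + 7919 * ki + ri)
                K = int(labels.max()) + 1
                if K < 1 or K > max_k:
                    continue
                S = sparse.csr_matrix(
                    (np.ones(n_sub), (np.arange(n_sub), labels)), shape=(n_sub, K)
                )
                blocks.setdefault(K, []).append(S)
                counts_k[K] = counts_k.get(K, 0) + 1
        for K, mats in blocks.items():
            M = sparse.hstack(mats, format="csr")
            cc = np.asarray((M @ M.T).todense())
            if K not in co_cluster:
                co_cluster[K] = np.zeros((n, n), dtype=np.float32)
                co_sample[K] = np.zeros((n, n), dtype=np.float32)
            co_cluster[K][ix] += cc.astype(np.float32)
            co_sample[K][ix] += counts_k[K]
            n_parts[K] = n_parts.get(K, 0) + counts_k[K]

    consensus: dict[int, np.ndarray] = {}
    n_imputed: dict[int, int] = {}
    kept_parts: dict[int, int] = {}
    for K, parts in sorted(n_parts.items()):
        if parts < min_support or K < 2:
            continue
        num = co_cluster[K].astype(float)
        den = co_sample[K].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            C = np.where(den > 0, num / np.maximum(den, 1), np.nan)
        missing = np.isnan(C)
        n_miss = int(missing.sum())
        if n_miss:
            fill = float(np.nanmean(C))
            C[missing] = fill
            logger.info("consensus K=%d: imputed %d never-co-sampled entries", K, n_miss)
        np.fill_diagonal(C, 1.0)
        C = np.clip((C + C.T) / 2.0, 0.0, 1.0)
        consensus[K] = C
        n_imputed[K] = n_miss
        kept_parts[K] = parts
    return ConsensusClustering(
        consensus=consensus,
        n_partitions=kept_parts,
        n_imputed=n_imputed,
        k_values=tuple(k_values),
        resolutions=tuple(resolutions),
        n_iter=n_iter,
        subsample=subsample,
        seed=seed,
    )


def consensus_cut(cc: ConsensusClustering, K: int) -> np.ndarray:
    """McQuitty (WPGMA) cut of the K-consensus dissimilarity into K clusters."""
    if K not in cc.consensus:
        raise KeyError(f"no consensus matrix for K={K}")
    C = cc.consensus[K]
    n = C.shape[0]
    if K > n:
        raise ValueError("K exceeds number of points")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="weighted")
    return fcluster(Z, t=K, criterion="maxclust") - 1


# ---------------------------------------------------------------------------


def silhouette(embedding: np.ndarray, labels: np.ndarray):
    """Per-point and mean silhouette s(i) = (b - a) / max(a, b).

    Singleton clusters score 0, and points with a = b = 0 (all distances
    identical, e.g. duplicated data) score 0 by convention.
    """
    X = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    D = squareform(pdist(X))
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        same = labels == labels[i]
        n_same = same.sum()
        if n_same == 1:
            s[i] = 0.0
            continue
        a = D[i, same].sum() / (n_same - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def select_k(
    cc: ConsensusClustering,
    embedding: np.ndarray,
    override: int | None = None,
) -> ConsensusClustering:
    """Rank candidate K by mean silhouette of their consensus cuts.

    The full ranking is reported; ``selected_k`` is the top-ranked K
    unless an override is supplied (the analysis this emulates chose the
    runner-up to expose heterogeneity beyond the treatment split).
    """
    if not cc.consensus:
        raise ValueError("no candidate K retained")
    for K in sorted(cc.consensus):
        labels = consensus_cut(cc, K)
        cc.cuts[K] = labels
        if len(np.unique(labels)) < 2:
            cc.silhouettes[K] = -1.0
        else:
            _, cc.silhouettes[K] = silhouette(embedding, labels)
    cc.ranking = sorted(cc.silhouettes, key=lambda K: cc.silhouettes[K], reverse=True)
    if override is not None:
        if override not in cc.consensus:
            raise KeyError(f"override K={override} has no consensus matrix")
        cc.selected_k = override
    else:
        cc.selected_k = cc.ranking[0]
    cc.labels = cc.cuts[cc.selected_k]
    return cc


def tsne_embed(X: np.ndarray, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """2-D t-SNE coordinates for visualization (deterministic per seed)."""
    from sklearn.manifold import TSNE

    X = np.asarray(X, dtype=float)
    if perplexity is None:
        perplexity = min(30.0, max(5.0, (X.shape[0] - 1) / 4.0))
    perplexity = min(perplexity, (X.shape[0] - 1) / 3.0)
    ts = TSNE(
        n_components=2,
        random_state=seed,
        init="pca",
        perplexity=perplexity,
    )
    return ts.fit_transform(X)
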
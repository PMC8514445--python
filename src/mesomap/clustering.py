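"""Graph-based motif clustering: kNN Jaccard graph + Louvain communities.

Each motif image is flattened to a vector; a weighted undirected graph
connects motifs whose k-nearest-neighbor sets (Euclidean distance)
overlap, with edge weight the Jaccard index of the two neighbor sets.
Louvain community detection partitions the graph by greedy modularity
maximization; cluster separation is quantified by the silhouette score.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import networkx as nx
import numpy as np
from networkx.algorithms.community import louvain_communities, modularity
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "MotifGraph",
    "ClusterResult",
    "knn_graph",
    "louvain",
    "silhouette",
    "cluster_motifs",
]


@dataclasses.dataclass
class MotifGraph:
    """Weighted shared-neighbor graph over motif vectors."""

    graph: nx.Graph
    k: int


@dataclasses.dataclass
class ClusterResult:
    """Louvain partition with its modularity and optional silhouette."""

    labels: np.ndarray  # contiguous from 0, ordered by descending community size
    modularity: float
    silhouette: float | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def knn_graph(vectors: np.ndarray, k: int) -> MotifGraph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Edge (i, j) is present iff the k-NN sets of i and j (self excluded)
    overlap; its weight is |N_i ∩ N_j| / |N_i ∪ N_j|.  Neighborhoods are
    tie-inclusive: every point at the k-th neighbor distance belongs to
    the set, so duplicate points share identical neighborhoods.
    """
    x = np.asarray(vectors, dtype=float)
    n = x.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    nn = NearestNeighbors(n_neighbors=n).fit(x)
    dist, idx = nn.kneighbors(x)
    sets = []
    for i in range(n):
        order = [j for j in idx[i] if j != i]
        d = [dist[i][pos] for pos, j in enumerate(idx[i]) if j != i]
        dk = d[k - 1]
        neigh = [j for j, dd in zip(order, d) if dd <= dk + 1e-12]
        sets.append(set(int(j) for j in neigh))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            if inter:
                w = inter / len(sets[i] | sets[j])
                g.add_edge(i, j, weight=w)
    return MotifGraph(g, k)


def louvain(graph: MotifGraph | nx.Graph, seed: int = 0) -> ClusterResult:
    """Louvain community detection; labels ordered by descending community size."""
    g = graph.graph if isinstance(graph, MotifGraph) else graph
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    comms = louvain_communities(g, weight="weight", seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.empty(g.number_of_nodes(), dtype=int)
    nodes = sorted(g.nodes())
    pos = {node: i for i, node in enumerate(nodes)}
    for lab, comm in enumerate(comms):
        for node in comm:
            labels[pos[node]] = lab
    q = modularity(g, comms, weight="weight") if g.number_of_edges() else 0.0
    return ClusterResult(labels, float(q))


def silhouette(vectors: np.ndarray, labels: Sequence[int]) -> float:
    """Mean silhouette score with Euclidean distances (singletons score 0)."""
    labels = np.asarray(labels)
    n_labels = len(np.unique(labels))
    if n_labels < 2:
        raise ValueError("silhouette requires at least two clusters")
    if n_labels == len(labels):
        return 0.0  # every cluster is a singleton; each scores 0 by convention
    return float(silhouette_score(np.asarray(vectors, float), labels, metric="euclidean"))


def cluster_motifs(
    motif_images: Sequence[np.ndarray],
    k: int = 15,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> tuple[ClusterResult, list[np.ndarray]]:
    """Cluster motif images and average each cluster.

    Flattens (masked) pixels, builds the shared-neighbor graph with
    k truncated to n-1, runs Louvain, and returns the partition (with
    silhouette when at least two communities emerge) plus the per-cluster
    mean images.
    """
    images = [np.asarray(m, dtype=float) for m in motif_images]
    if mask is not None:
        m = np.asarray(mask).astype(bool)
        vectors = np.stack([im[m] for im in images])
    else:
        vectors = np.stack([im.ravel() for im in images])
    k_eff = min(k, len(images) - 1)
    result = louvain(knn_graph(vectors, k_eff), seed=seed)
    if result.n_clusters >= 2:
        result = dataclasses.replace(
            result, silhouette=silhouette(vectors, result.labels)
        )
    means = [
        np.mean([images[i] for i in np.nonzero(result.labels == lab)[0]], axis=0)
        for lab in range(result.n_clusters)
    ]
    return result, means
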
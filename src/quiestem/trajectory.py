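"""Principal-tree trajectory learning and geodesic pseudotime.

The trajectory is a deterministic principal tree: k-means centroids over the
batch-corrected embedding joined by a Euclidean minimum spanning tree. The
root is the node nearest the single cell with the highest dormancy-set
enrichment score, and each cell's pseudotime is the geodesic distance along
the tree from the root to the cell's orthogonal projection onto its nearest
edge. Tree geodesics handle branch points (ciliated vs secretory) naturally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist

from .preprocess import Embedding
from .scoring import EnrichmentScores

__all__ = ["PrincipalGraph", "PseudotimeAssignment", "learn_graph", "select_root", "assign_pseudotime"]


@dataclass
class PrincipalGraph:
    nodes: np.ndarray  # n_nodes x d coordinates
    graph: nx.Graph  # edge weights are Euclidean lengths
    root: int | None = None

    def __post_init__(self) -> None:
        n = self.nodes.shape[0]
        if self.graph.number_of_nodes() != n:
            raise ValueError("graph nodes inconsistent with coordinate table")
        if n > 1:
            if not nx.is_connected(self.graph):
                raise ValueError("principal graph must be connected")
            if self.graph.number_of_edges() != n - 1:
                raise ValueError("principal graph must be a tree")
        for u, v, w in self.graph.edges(data="weight"):
            d = float(np.linalg.norm(self.nodes[u] - self.nodes[v]))
            if abs(d - w) > 1e-9:
                raise ValueError(f"edge ({u},{v}) length {w} != endpoint distance {d}")


@dataclass
class PseudotimeAssignment:
    pseudotime: pd.Series  # per cell, geodesic distance from the root
    projection: pd.DataFrame  # per cell, projected point coordinates
    edge: pd.DataFrame  # per cell: edge endpoints u, v and offset s along (u, v)


def default_n_nodes(n_cells: int) -> int:
    return max(10, math.ceil(math.sqrt(n_cells)))


def learn_graph(emb: Embedding, n_nodes: int | None = None, seed: int = 0) -> PrincipalGraph:
    """k-means centroids joined by a Euclidean minimum spanning tree."""
    X = emb.values
    if n_nodes is None:
        n_nodes = default_n_nodes(X.shape[0])
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if n_nodes > X.shape[0]:
        raise ValueError("n_nodes cannot exceed the number of cells")
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_nodes, init="k-means++", n_init=10, max_iter=300, tol=1e-6,
                random_state=seed)
    km.fit(X)
    centroids = np.unique(np.round(km.cluster_centers_, 12), axis=0)
    if centroids.shape[0] < 2:
        raise ValueError("centroids collapsed to fewer than 2 distinct nodes")
    D = cdist(centroids, centroids)
    mst = minimum_spanning_tree(D).tocoo()
    g = nx.Graph()
    g.add_nodes_from(range(centroids.shape[0]))
    for u, v, w in zip(mst.row, mst.col, mst.data):
        g.add_edge(int(u), int(v), weight=float(w))
    return PrincipalGraph(nodes=centroids, graph=g)


def select_root(
    graph: PrincipalGraph, emb: Embedding, scores: EnrichmentScores
) -> PrincipalGraph:
    """Root the tree at the node nearest the top dormancy-scoring cell.

    Score ties break by cell id (lexicographic), distance ties by node id.
    """
    s = scores.scores.reindex(emb.cell_ids)
    if s.isna().any():
        raise ValueError("scores do not cover every embedded cell")
    if s.empty:
        raise ValueError("empty enrichment scores")
    top = s.max()
    top_cell = sorted(s.index[s == top])[0]
    x = emb.coordinates.loc[top_cell].to_numpy()
    dists = np.linalg.norm(graph.nodes - x[None, :], axis=1)
    root = int(np.argmin(dists))  # argmin returns the lowest index on ties
    return PrincipalGraph(nodes=graph.nodes, graph=graph.graph, root=root)


def assign_pseudotime(graph: PrincipalGraph, emb: Embedding) -> PseudotimeAssignment:
    """Project cells to the tree and measure geodesic distance from the root.

    A cell projects orthogonally onto the closest point across all edges
    (clamped to segment ends); its pseudotime is the tree distance from the
    root to that point: min over the edge's endpoints of (distance to the
    endpoint) + (arc length from the endpoint to the projection).
    """
    if graph.root is None:
        raise ValueError("root not set; call select_root first")
    X = emb.values
    n_cells = X.shape[0]
    node_dist = nx.single_source_dijkstra_path_length(graph.graph, graph.root, weight="weight")

    edges = list(graph.graph.edges(data="weight"))
    if not edges:
        # single-node tree: everything projects to the root
        proj = np.tile(graph.nodes[0], (n_cells, 1))
        pt = np.linalg.norm(X - proj, axis=1) * 0.0
        return PseudotimeAssignment(
            pseudotime=pd.Series(pt, index=emb.cell_ids, name="pseudotime"),
            projection=pd.DataFrame(proj, index=emb.cell_ids),
            edge=pd.DataFrame({"u": 0, "v": 0, "s": 0.0}, index=emb.cell_ids),
        )

    best_d2 = np.full(n_cells, np.inf)
    best_pt = np.zeros(n_cells)
    best_proj = np.zeros_like(X)
    best_edge = np.zeros((n_cells, 2), dtype=int)
    best_s = np.zeros(n_cells)
    for u, v, w in edges:
        a, b = graph.nodes[u], graph.nodes[v]
        ab = b - a
        L2 = float(ab @ ab)
        s = np.clip((X - a) @ ab / L2, 0.0, 1.0) if L2 > 0 else np.zeros(n_cells)
        proj = a[None, :] + s[:, None] * ab[None, :]
        d2 = ((X - proj) ** 2).sum(axis=1)
        pt = np.minimum(node_dist[u] + s * w, node_dist[v] + (1.0 - s) * w)
        better = d2 < best_d2 - 1e-15
        best_d2[better] = d2[better]
        best_pt[better] = pt[better]
        best_proj[better] = proj[better]
        best_edge[better] = (u, v)
        best_s[better] = s[better]
    return PseudotimeAssignment(
        pseudotime=pd.Series(best_pt, index=emb.cell_ids, name="pseudotime"),
        projection=pd.DataFrame(best_proj, index=emb.cell_ids),
        edge=pd.DataFrame(
            {"u": best_edge[:, 0], "v": best_edge[:, 1], "s": best_s}, index=emb.cell_ids
        ),
    )
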
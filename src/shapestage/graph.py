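"""Small graph helpers over vertex adjacency (edge lists)."""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["adjacency_matrix", "hop_distances", "hop_neighborhoods"]


def adjacency_matrix(edges: np.ndarray, n_vertices: int) -> sparse.csr_matrix:
    """Symmetric boolean CSR adjacency from an undirected edge list."""
    if len(edges) == 0:
        return sparse.csr_matrix((n_vertices, n_vertices), dtype=bool)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    a = sparse.coo_matrix(
        (np.ones(len(i), dtype=bool), (i, j)), shape=(n_vertices, n_vertices)
    )
    return a.tocsr()


def hop_distances(adj: sparse.csr_matrix, source: int, max_hops: int | None = None) -> np.ndarray:
    """BFS hop distance from ``source`` to every vertex (-1 = unreachable /
    beyond ``max_hops``)."""
    n = adj.shape[0]
    dist = np.full(n, -1, dtype=np.int64)
    dist[source] = 0
    frontier = np.array([source])
    d = 0
    while len(frontier) and (max_hops is None or d < max_hops):
        d += 1
        nxt = np.unique(adj[frontier].indices)
        nxt = nxt[dist[nxt] < 0]
        dist[nxt] = d
        frontier = nxt
    return dist


def hop_neighborhoods(adj: sparse.csr_matrix, radius: int) -> list[np.ndarray]:
    """For every vertex, the sorted array of vertices within ``radius`` hops
    (including itself).  Computed by repeated sparse multiplication."""
    n = adj.shape[0]
    reach = sparse.identity(n, dtype=bool, format="csr")
    ring = sparse.identity(n, dtype=bool, format="csr")
    for _ in range(radius):
        ring = ring @ adj
        reach = (reach + ring).tocsr()
        reach.data[:] = True
    reach = reach.tocsr()
    reach.sort_indices()
    return [reach.indices[reach.indptr[v] : reach.indptr[v + 1]] for v in range(n)]
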
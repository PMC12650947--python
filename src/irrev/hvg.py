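"""Directed Horizontal Visibility Graph (dHVG) construction.

Each observation is a node; an arc ``i -> j`` (with ``i < j``) exists when
every intermediate value lies strictly below ``min(x_i, x_j)`` — i.e. the
two data "bars" see each other horizontally.  Arcs always point forward in
time, so the out-neighbourhood of a node is its future and the
in-neighbourhood its past.  Two tests build on this graph: the degree
distribution comparison and the retarded/advanced clustering comparison.
"""

from __future__ import annotations

import numpy as np

from .core import as_real_series

__all__ = ["horizontal_visibility_edges", "degrees", "local_clustering_coefficients"]


def horizontal_visibility_edges(x) -> list[tuple[int, int]]:
    """All dHVG arcs ``(i, j)`` with ``i < j``, in O(N) via a monotone stack.

    Ties block visibility: an intermediate value equal to an endpoint is not
    strictly below it, so visibility does not extend past it.
    """
    arr = as_real_series(x)
    edges: list[tuple[int, int]] = []
    stack: list[int] = []  # indices with strictly decreasing values
    for j in range(arr.size):
        xj = arr[j]
        while stack and arr[stack[-1]] < xj:
            edges.append((stack.pop(), j))
        if stack:
            edges.append((stack[-1], j))
            if arr[stack[-1]] == xj:
                # equal bar: nothing behind it can see past j, nor past it
                stack.pop()
        stack.append(j)
    return edges


def degrees(n: int, edges) -> tuple[np.ndarray, np.ndarray]:
    """(in_degree, out_degree) arrays for a dHVG with ``n`` nodes."""
    indeg = np.zeros(n, dtype=int)
    outdeg = np.zeros(n, dtype=int)
    for i, j in edges:
        outdeg[i] += 1
        indeg[j] += 1
    return indeg, outdeg


def local_clustering_coefficients(n: int, edges) -> tuple[np.ndarray, np.ndarray]:
    """Per-node retarded and advanced local clustering coefficients.

    The retarded coefficient of a node is the density of arcs among its
    past (in-) neighbours, the advanced one the density among its future
    (out-) neighbours; nodes with fewer than two neighbours on a side get
    coefficient 0 there.
    """
    past: list[list[int]] = [[] for _ in range(n)]
    future: list[list[int]] = [[] for _ in range(n)]
    edge_set = set(edges)
    for i, j in edges:
        past[j].append(i)
        future[i].append(j)

    def density(neigh: list[int]) -> float:
        k = len(neigh)
        if k < 2:
            return 0.0
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                u, v = neigh[a], neigh[b]
                if (u, v) in edge_set or (v, u) in edge_set:
                    links += 1
        return 2.0 * links / (k * (k - 1))

    retarded = np.array([density(past[v]) for v in range(n)])
    advanced = np.array([density(future[v]) for v in range(n)])
    return retarded, advanced
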
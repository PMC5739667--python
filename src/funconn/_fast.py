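"""Numba BFS kernels behind the efficiency metrics.

These compute exactly the quantities defined in :mod:`funconn.metrics` —
per-node sums of inverse shortest-path lengths, and the local-efficiency sum
over neighbour-induced subgraphs — with per-source breadth-first searches
over the adjacency matrix.  The pure-numpy path (:func:`funconn.metrics
.shortest_paths`) and external graph libraries serve as cross-checks in the
test-suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def nodal_inverse_distance_sums(adj):  # pragma: no cover - numba
    """sum_j 1/d(i, j) for each node i; unreachable pairs contribute 0."""
    n = adj.shape[0]
    out = np.zeros(n)
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    for s in range(n):
        for i in range(n):
            dist[i] = -1
        dist[s] = 0
        queue[0] = s
        head, tail = 0, 1
        acc = 0.0
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u] + 1
            for v in range(n):
                if adj[u, v] and dist[v] < 0:
                    dist[v] = du
                    acc += 1.0 / du
                    queue[tail] = v
                    tail += 1
        out[s] = acc
    return out


@njit(cache=False)
def local_efficiency_sum(adj):  # pragma: no cover - numba
    """sum over nodes of Eglob(neighbour subgraph); < 2 neighbours -> 0."""
    n = adj.shape[0]
    nb = np.empty(n, np.int32)
    sub = np.zeros((n, n), np.bool_)
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    total = 0.0
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                nb[k] = j
                k += 1
        if k < 2:
            continue
        for a in range(k):
            na = nb[a]
            for b in range(k):
                sub[a, b] = adj[na, nb[b]]
        acc = 0.0
        for s in range(k):
            for x in range(k):
                dist[x] = -1
            dist[s] = 0
            queue[0] = s
            head, tail = 0, 1
            while head < tail:
                u = queue[head]
                head += 1
                du = dist[u] + 1
                for v in range(k):
                    if sub[u, v] and dist[v] < 0:
                        dist[v] = du
                        acc += 1.0 / du
                        queue[tail] = v
                        tail += 1
        total += acc / (k * (k - 1))
    return total / n
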
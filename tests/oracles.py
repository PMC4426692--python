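"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the implementation paths they verify: the
dynamics oracle works on dense matrices with explicit Laplacian
algebra, the centrality oracle counts shortest paths by enumeration
over BFS layers, and distances come from scipy's Floyd-Warshall.
"""

from __future__ import annotations

import collections

import networkx as nx
import numpy as np


# -- communicating-vessels dynamics (dense matrix) ---------------------


def dense_run(adjacency: np.ndarray, e0: np.ndarray, k: float, dissipation: float,
              theta: float = 1.0, max_steps: int = 100000):
    """Run the dynamics with dense (I - kL) algebra.

    Returns (silencing_time, reach, states) where states[t] is the
    energy vector after t full steps (states[0] = e0).
    """
    n = len(e0)
    deg = adjacency.sum(axis=1)
    laplacian = np.diag(deg) - adjacency
    transfer = np.eye(n) - k * laplacian
    e = e0.astype(float).copy()
    reached = e >= theta
    states = [e.copy()]
    steps = 0
    capped = False
    while e.max() >= theta:
        if steps >= max_steps:
            capped = True
            break
        e = transfer @ e
        reached |= e >= theta
        e = np.maximum(e - dissipation, 0.0)
        states.append(e.copy())
        steps += 1
    return steps, int(reached.sum()), states, capped


# -- centralities by explicit path counting ----------------------------


def _bfs_dist_and_counts(g: nx.Graph, source):
    """BFS distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = collections.deque([source])
    while queue:
        u = queue.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def brute_centralities(g: nx.Graph):
    """degree / closeness / betweenness dicts by enumeration."""
    n = g.number_of_nodes()
    nodes = list(g.nodes)
    degree = {v: g.degree[v] for v in nodes}
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = _bfs_dist_and_counts(g, s)
    closeness = {}
    for v in nodes:
        reach = [u for u in nodes if u != v and u in dist[v]]
        if not reach or n == 1:
            closeness[v] = 0.0
        else:
            total = sum(dist[v][u] for u in reach)
            closeness[v] = (len(reach) / total) * (len(reach) / (n - 1))
    betweenness = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            total = sigma[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == d_st:
                    betweenness[v] += sigma[s][v] * sigma[t][v] / total
    norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 1.0
    betweenness = {v: b / norm for v, b in betweenness.items()}
    return degree, closeness, betweenness


# -- edge-list simplification by set construction ----------------------


def set_dedup_edges(rows):
    """Simplified edge set from raw rows, independent of the loader."""
    return {frozenset((u, v)) for u, v in rows if u != v}
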
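"""Degree, closeness and betweenness centralities and group summaries.

Centralities are computed through igraph's C core (all-pairs BFS scales
to interactome-sized networks); the conventions are fixed here so the
numbers are backend-independent:

- degree: neighbour count;
- closeness: inverse mean geodesic distance to *reachable* nodes,
  scaled by ``(reachable - 1) / (n - 1)`` so values from small
  components cannot dominate a disconnected graph;
- betweenness: fraction of shortest paths passing through the node,
  endpoints excluded, normalized by ``(n - 1)(n - 2) / 2`` unordered
  pairs so it lies in [0, 1].
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import igraph as ig
import numpy as np
import pandas as pd

from .network import InteractionNetwork
from .groups import mann_whitney

__all__ = ["compute_centralities", "group_centrality_summary", "to_igraph"]


def to_igraph(net: InteractionNetwork) -> tuple[ig.Graph, list[str]]:
    """Convert to an igraph graph over sorted node order."""
    nodes = net.sorted_nodes()
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.graph.edges()]
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    return g, nodes


def compute_centralities(net: InteractionNetwork) -> pd.DataFrame:
    """Per-node degree, closeness and betweenness.

    Returns a DataFrame indexed by node ID (sorted) with integer
    ``degree`` and float ``closeness`` / ``betweenness`` in [0, 1].
    A single-node network gets closeness = betweenness = 0.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot compute centralities of an empty network")
    g, nodes = to_igraph(net)
    n = len(nodes)
    degree = np.array(g.degree(), dtype=int)
    if n == 1:
        closeness = np.zeros(1)
        betweenness = np.zeros(1)
    else:
        dist = np.asarray(g.distances(), dtype=float)
        finite = np.isfinite(dist)
        np.fill_diagonal(finite, False)
        reach_counts = finite.sum(axis=1).astype(float)
        dist_sums = np.where(finite, dist, 0.0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            closeness = np.where(
                reach_counts > 0,
                (reach_counts / np.where(dist_sums > 0, dist_sums, 1.0))
                * (reach_counts / (n - 1)),
                0.0,
            )
        if n > 2:
            betweenness = np.array(g.betweenness(directed=False)) / (
                (n - 1) * (n - 2) / 2.0
            )
        else:
            betweenness = np.zeros(n)
    return pd.DataFrame(
        {"degree": degree, "closeness": closeness, "betweenness": betweenness},
        index=pd.Index(nodes, name="node"),
    )


def group_centrality_summary(
    profile: pd.DataFrame,
    groups: Mapping[str, Iterable[str]],
    pairs: Iterable[tuple[str, str]] | None = None,
) -> dict:
    """Per-group medians/means of each centrality plus pairwise tests.

    Parameters
    ----------
    profile
        Output of :func:`compute_centralities`.
    groups
        Named node sets.  Overlapping groups are allowed but warned
        about; an empty group (after intersection with the profile's
        nodes) raises.
    pairs
        Group pairs to compare with a two-sided Mann-Whitney test per
        centrality; default is every unordered pair.

    Returns a JSON-serializable dict with ``groups`` (sizes, medians,
    means) and ``comparisons`` (p-values, unadjusted).
    """
    sets = {name: frozenset(members) & frozenset(profile.index)
            for name, members in groups.items()}
    for name, members in sets.items():
        if not members:
            raise ValueError(f"group {name!r} has no members in the network")
    names = list(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if sets[a] & sets[b]:
                warnings.warn(f"groups {a!r} and {b!r} overlap", stacklevel=2)
    metrics = ["degree", "closeness", "betweenness"]
    out: dict = {"groups": {}, "comparisons": []}
    for name, members in sets.items():
        sub = profile.loc[sorted(members)]
        out["groups"][name] = {
            "size": len(members),
            "median": {m: float(sub[m].median()) for m in metrics},
            "mean": {m: float(sub[m].mean()) for m in metrics},
        }
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    for a, b in pairs:
        for m in metrics:
            cmp = mann_whitney(
                profile.loc[sorted(sets[a]), m].to_numpy(),
                profile.loc[sorted(sets[b]), m].to_numpy(),
                names=(a, b),
            )
            out["comparisons"].append({"metric": m, **cmp.as_dict()})
    return out
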
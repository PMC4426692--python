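"""Geodesic distances between node sets and giant-component bookkeeping.

Used to contrast how far drug-target groups sit from disease gene sets
on the interactome: per target, the mean shortest-path length (in
edges) to the members of a disease set, then the arithmetic mean and
median of those per-target means across the group.

Disease members unreachable from a target (different component) have no
finite distance; the default policy excludes them from that target's
mean and counts them separately.  An alternative policy imputes the
network size as a penalty distance, for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .centrality import to_igraph
from .network import InteractionNetwork, giant_component

__all__ = [
    "geodesic_distances",
    "average_distance_to_set",
    "component_membership",
    "DistanceResult",
    "ComponentMembership",
]


def geodesic_distances(
    net: InteractionNetwork, sources: Iterable[str], targets: Iterable[str]
) -> pd.DataFrame:
    """Shortest-path lengths (edge counts) between two node sets.

    Returns a float DataFrame indexed by sorted sources with sorted
    targets as columns; unreachable pairs are ``inf``.  A node's
    distance to itself is 0.
    """
    sources = sorted(set(sources))
    targets = sorted(set(targets))
    if not sources or not targets:
        raise ValueError("source and target sets must be nonempty")
    for s in sources + targets:
        if s not in net:
            raise KeyError(f"node {s!r} is not in the network")
    g, nodes = to_igraph(net)
    index = {n: i for i, n in enumerate(nodes)}
    dist = np.asarray(
        g.distances(
            source=[index[s] for s in sources],
            target=[index[t] for t in targets],
        ),
        dtype=float,
    )
    return pd.DataFrame(dist, index=pd.Index(sources, name="source"),
                        columns=pd.Index(targets, name="target"))


@dataclass(frozen=True)
class DistanceResult:
    """Per-target mean distances to a disease set, with group summary."""

    per_target: pd.DataFrame  # index target; mean_distance, n_reachable, n_unreachable
    group_mean: float
    group_median: float
    excluded_targets: tuple[str, ...]  # targets reaching no disease member
    policy: str

    def as_dict(self) -> dict:
        return {
            "group_mean": self.group_mean,
            "group_median": self.group_median,
            "n_targets": int(len(self.per_target)),
            "excluded_targets": list(self.excluded_targets),
            "policy": self.policy,
        }


def average_distance_to_set(
    net: InteractionNetwork,
    targets: Iterable[str],
    disease_set: Iterable[str],
    unreachable_policy: str = "exclude",
) -> DistanceResult:
    """Mean geodesic distance from each target to a disease gene set.

    ``unreachable_policy``:

    - ``"exclude"`` (default): unreachable disease members are dropped
      from the target's mean and counted in ``n_unreachable``; a target
      reaching no member at all is excluded from the group summary and
      listed in ``excluded_targets``.
    - ``"penalize"``: unreachable members contribute a distance equal
      to the network's node count.

    Duplicate listings in either set are ignored (set semantics).
    """
    if unreachable_policy not in ("exclude", "penalize"):
        raise ValueError(f"unknown unreachable policy: {unreachable_policy!r}")
    targets = sorted(set(targets) & net.nodes)
    disease = sorted(set(disease_set) & net.nodes)
    if not targets or not disease:
        raise ValueError(
            "target and disease sets must be nonempty after intersection "
            "with the network"
        )
    dist = geodesic_distances(net, targets, disease)
    finite = np.isfinite(dist.to_numpy())
    n_reach = finite.sum(axis=1)
    n_unreach = len(disease) - n_reach
    means = np.full(len(targets), np.nan)
    penalty = float(net.n_nodes)
    for i in range(len(targets)):
        row = dist.to_numpy()[i]
        if unreachable_policy == "penalize":
            vals = np.where(np.isfinite(row), row, penalty)
            means[i] = vals.mean()
        elif n_reach[i] > 0:
            means[i] = row[np.isfinite(row)].mean()
    per_target = pd.DataFrame(
        {
            "mean_distance": means,
            "n_reachable": n_reach,
            "n_unreachable": n_unreach,
        },
        index=pd.Index(targets, name="target"),
    )
    valid = per_target["mean_distance"].dropna()
    excluded = tuple(per_target.index[per_target["mean_distance"].isna()])
    if valid.empty:
        raise ValueError("no target reaches any disease member")
    return DistanceResult(
        per_target=per_target,
        group_mean=float(valid.mean()),
        group_median=float(valid.median()),
        excluded_targets=excluded,
        policy=unreachable_policy,
    )


class ComponentMembership(NamedTuple):
    in_giant: int
    out_of_giant: int
    fraction_out: float


def component_membership(
    net: InteractionNetwork, node_set: Iterable[str]
) -> ComponentMembership:
    """Count how many of a node set sit inside vs outside the giant
    component (fraction_out is NaN for an empty set)."""
    members = set(node_set)
    for m in members:
        if m not in net:
            raise KeyError(f"node {m!r} is not in the network")
    if not members:
        return ComponentMembership(0, 0, float("nan"))
    giant = giant_component(net).nodes
    inside = sum(1 for m in members if m in giant)
    outside = len(members) - inside
    return ComponentMembership(inside, outside, outside / len(members))
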
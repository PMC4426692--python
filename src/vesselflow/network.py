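"""Interaction-network container, loaders and cleaning operations.

Interactomes arrive as edge lists (STRING-style TSV exports or Cytoscape
SIF files) that routinely contain self-interactions and the same pair in
both orientations.  Everything downstream — the perturbation dynamics,
centralities and geodesic distances — assumes an undirected *simple*
graph, so loading always simplifies: self-loops are dropped and duplicate
pairs (in either order) are collapsed, with the counts reported so the
cleanup is auditable.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "InteractionNetwork",
    "IdMapping",
    "load_edge_list",
    "load_id_mapping",
    "apply_id_mapping",
    "giant_component",
    "random_node_deletion",
    "write_edge_list",
]


class InteractionNetwork:
    """Undirected simple graph over opaque string node identifiers.

    Invariants (checked on construction): no self-loops, no multi-edges,
    every edge endpoint is a node.  Isolated nodes are permitted.  The
    network carries no edge weights.
    """

    __slots__ = ("_graph",)

    def __init__(self, graph: nx.Graph):
        if any(u == v for u, v in graph.edges()):
            raise ValueError("InteractionNetwork must not contain self-loops")
        self._graph = graph

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
    ) -> "InteractionNetwork":
        """Build a simplified network: loops dropped, duplicates collapsed."""
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                continue
            g.add_edge(u, v)
        return cls(g)

    # -- views ---------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying :class:`networkx.Graph` (treat as read-only)."""
        return self._graph

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self._graph.edges}

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def sorted_nodes(self) -> list[str]:
        return sorted(self._graph.nodes)

    def degree(self, node: str) -> int:
        return self._graph.degree[node]

    def max_degree(self) -> int:
        if self.n_nodes == 0:
            return 0
        return max(d for _, d in self._graph.degree())

    def neighbors(self, node: str) -> set[str]:
        return set(self._graph.neighbors(node))

    def subgraph(self, nodes: Iterable[str]) -> "InteractionNetwork":
        """Vertex-induced subgraph as a new, independent network."""
        return InteractionNetwork(self._graph.subgraph(list(nodes)).copy())

    def __contains__(self, node: str) -> bool:
        return node in self._graph

    def __len__(self) -> int:
        return self.n_nodes

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"InteractionNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


class IdMapping:
    """Source-ID → target-ID translation table (one source, many targets).

    Lookup of an unmapped source yields an empty tuple — never a silent
    pass-through of the untranslated identifier.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        table: dict[str, set[str]] = {}
        for src, tgt in pairs:
            table.setdefault(str(src), set()).add(str(tgt))
        self._table: dict[str, tuple[str, ...]] = {
            src: tuple(sorted(tgts)) for src, tgts in table.items()
        }

    def lookup(self, source: str) -> tuple[str, ...]:
        return self._table.get(source, ())

    def __contains__(self, source: str) -> bool:
        return source in self._table

    def __len__(self) -> int:
        return len(self._table)

    def items(self):
        return self._table.items()


def _parse_rows(path: Path, fmt: str, columns: tuple[int, int], comment: str):
    """Yield (line_number, u, v) pairs from a TSV or SIF edge-list file."""
    needed = max(columns)
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or (comment and line.lstrip().startswith(comment)):
                continue
            if fmt == "tsv":
                fields = line.split("\t")
                if len(fields) <= needed:
                    raise ValueError(
                        f"{path}: malformed row at line {lineno}: "
                        f"expected at least {needed + 1} tab-separated columns, "
                        f"got {len(fields)}"
                    )
                yield lineno, fields[columns[0]].strip(), fields[columns[1]].strip()
            elif fmt == "sif":
                fields = line.split()
                if len(fields) == 1:
                    # SIF permits bare node lines (isolated nodes)
                    yield lineno, fields[0], None
                elif len(fields) >= 3:
                    for tgt in fields[2:]:
                        yield lineno, fields[0], tgt
                else:
                    raise ValueError(
                        f"{path}: malformed SIF row at line {lineno}: "
                        "expected 'node' or 'node relation node...'"
                    )
            else:
                raise ValueError(f"unknown edge-list format: {fmt!r}")


def load_edge_list(
    path: str | Path,
    format: str = "tsv",
    columns: tuple[int, int] = (0, 1),
    comment: str = "#",
) -> tuple[InteractionNetwork, dict]:
    """Load and simplify an edge list.

    Parameters
    ----------
    path
        Edge-list file.  TSV: one interaction per row, node IDs in the
        two columns given by ``columns``; SIF: ``node relation node...``
        whitespace-separated.  Lines starting with ``comment`` and blank
        lines are ignored.
    format
        ``"tsv"`` or ``"sif"``.
    columns
        Zero-based column indices of the two interactor IDs (TSV only).

    Returns
    -------
    (network, report)
        The simplified network plus a report dict with keys
        ``raw_rows``, ``loops_dropped``, ``duplicates_collapsed``,
        ``n_nodes``, ``n_edges``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    g = nx.Graph()
    raw_rows = 0
    loops = 0
    dup = 0
    last_lineno = None
    for lineno, u, v in _parse_rows(path, format, columns, comment):
        if lineno != last_lineno or format == "tsv":
            raw_rows += 1
            last_lineno = lineno
        if v is None:
            g.add_node(u)
            continue
        if u == v:
            loops += 1
            continue
        if g.has_edge(u, v):
            dup += 1
        else:
            g.add_edge(u, v)
    if raw_rows == 0:
        raise ValueError(f"{path}: empty edge-list file (no data rows)")
    net = InteractionNetwork(g)
    report = {
        "raw_rows": raw_rows,
        "loops_dropped": loops,
        "duplicates_collapsed": dup,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
    }
    return net, report


def load_id_mapping(path: str | Path, comment: str = "#") -> IdMapping:
    """Load a two-column TSV of (source ID, target ID) pairs."""
    path = Path(path)
    pairs = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or (comment and line.lstrip().startswith(comment)):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: malformed mapping row at line {lineno}: "
                    "expected two tab-separated columns"
                )
            pairs.append((fields[0].strip(), fields[1].strip()))
    return IdMapping(pairs)


def apply_id_mapping(
    net: InteractionNetwork,
    mapping: IdMapping,
    collision_policy: str = "smallest",
) -> tuple[InteractionNetwork, dict]:
    """Rename nodes through a translation table.

    Nodes with no translation are dropped together with their incident
    edges and listed in the report.  A source mapping to several targets
    is resolved by ``collision_policy``:

    - ``"smallest"`` (default): keep the lexicographically smallest
      target, record the discarded alternatives;
    - ``"error"``: raise.

    Edges that become loops or duplicates after renaming are
    re-simplified.  Mapping never increases node or edge counts.
    """
    if collision_policy not in ("smallest", "error"):
        raise ValueError(f"unknown collision policy: {collision_policy!r}")
    rename: dict[str, str] = {}
    untranslated: list[str] = []
    collisions: dict[str, tuple[str, ...]] = {}
    for node in net.sorted_nodes():
        targets = mapping.lookup(node)
        if not targets:
            untranslated.append(node)
        elif len(targets) == 1:
            rename[node] = targets[0]
        else:
            if collision_policy == "error":
                raise ValueError(
                    f"ambiguous mapping for {node!r}: {', '.join(targets)}"
                )
            rename[node] = targets[0]  # tuple is sorted: lexicographic min
            collisions[node] = targets[1:]
    loops = 0
    dup = 0
    g = nx.Graph()
    g.add_nodes_from(rename.values())
    for u, v in net.graph.edges():
        if u not in rename or v not in rename:
            continue
        ru, rv = rename[u], rename[v]
        if ru == rv:
            loops += 1
        elif g.has_edge(ru, rv):
            dup += 1
        else:
            g.add_edge(ru, rv)
    mapped = InteractionNetwork(g)
    report = {
        "untranslated": untranslated,
        "collisions": collisions,
        "n_nodes_before": net.n_nodes,
        "n_nodes_after": mapped.n_nodes,
        "n_edges_before": net.n_edges,
        "n_edges_after": mapped.n_edges,
        "loops_created": loops,
        "duplicates_created": dup,
    }
    return mapped, report


def giant_component(net: InteractionNetwork) -> InteractionNetwork:
    """Induced subgraph on the largest connected component.

    Ties in component size are broken deterministically in favour of the
    component containing the lexicographically smallest node ID.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot take the giant component of an empty network")
    comps = sorted(nx.connected_components(net.graph), key=lambda c: (-len(c), min(c)))
    return net.subgraph(comps[0])


def random_node_deletion(
    net: InteractionNetwork, fraction: float, rng_seed: int
) -> InteractionNetwork:
    """Remove a uniform random fraction of nodes (with incident edges).

    Exactly ``floor(fraction * n_nodes)`` nodes are removed.  Nodes are
    put in sorted order before the draw, so the surviving set depends
    only on the node set and the seed, never on file row order.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"deletion fraction must be in (0, 1), got {fraction}")
    nodes = net.sorted_nodes()
    n_delete = math.floor(fraction * len(nodes))
    rng = np.random.default_rng(rng_seed)
    doomed = set(rng.choice(len(nodes), size=n_delete, replace=False).tolist())
    keep = [node for i, node in enumerate(nodes) if i not in doomed]
    return net.subgraph(keep)


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    """Serialize as a sorted two-column TSV (deterministic byte output)."""
    lines = sorted(tuple(sorted(e)) for e in net.graph.edges())
    isolated = sorted(n for n in net.graph.nodes if net.degree(n) == 0)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# source\ttarget\n")
        for u, v in lines:
            fh.write(f"{u}\t{v}\n")
        # isolated nodes carry no edge row; record them as comments so the
        # file documents the full node set (the edge set round-trips exactly)
        for n in isolated:
            fh.write(f"# isolated\t{n}\n")
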
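"""Synthetic interactome-like scenarios with planted structure.

Real inputs to this kind of analysis are database snapshots (an
interaction network, a drug→target table, per-drug adverse-event
records, disease gene lists) that cannot be redistributed or pinned.
This module generates structurally equivalent stand-ins with *known*
ground truth, so the whole pipeline can be exercised and its power
measured:

- the network is a preferential-attachment (Barabási–Albert) graph —
  the heavy-tailed degree distribution of real interactomes is what
  drives every contrast the pipeline tests;
- each drug receives a side-effect flag and a handful of targets;
  side-effect drugs pick targets with probability proportional to
  ``degree ** beta``, so ``beta > 0`` plants the "side-effect targets
  are hubs, hence better spreaders" effect and ``beta = 0`` is the
  null;
- one "cancer-like" disease set is drawn from the top-degree hub pool,
  and one "diabetes-like" set from everything below that pool — the
  reference contrast being emulated is a disease group that is central
  and one that is indistinguishable from the network background.

All randomness derives from one scenario seed through independent
named streams, so any sub-draw is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .groups import AnnotationSet, load_disease_genes, load_drug_targets, load_side_effect_pairs
from .network import InteractionNetwork, load_edge_list, write_edge_list

__all__ = [
    "SyntheticScenario",
    "generate_network",
    "plant_annotations",
    "generate_scenario_bundle",
    "load_scenario_bundle",
]

# named RNG sub-streams split off the scenario seed
_STREAM_NETWORK = 0
_STREAM_FLAGS = 1
_STREAM_TARGETS = 2
_STREAM_DISEASE = 3
_STREAM_TERMS = 4

_SE_VOCABULARY = (
    "nausea", "headache", "dizziness", "fatigue", "rash",
    "insomnia", "hypotension", "tachycardia",
)


def _stream(seed: int, stream_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream_id,)))


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study.

    Defaults describe the standard desk-scale study: a 2000-node
    preferential-attachment network (m = 2 edges per new node), 40
    drugs with 1–5 targets each, half of them flagged with side
    effects, side-effect drugs placing targets with weight
    ``degree ** 2``, and two 15-member disease sets — a central one
    sampled from the top 5% of degrees and a peripheral/average one
    sampled from the remaining 95%.
    """

    n_nodes: int = 2000
    m: int = 2
    n_drugs: int = 40
    targets_per_drug: tuple[int, int] = (1, 5)
    se_prevalence: float = 0.5
    degree_bias: float = 2.0
    disease_set_size: int = 15
    central_top_fraction: float = 0.05
    peripheral_bottom_fraction: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes <= self.m or self.m < 1:
            raise ValueError("need n_nodes > m >= 1")
        if self.n_drugs < 1 or self.disease_set_size < 1:
            raise ValueError("n_drugs and disease_set_size must be positive")
        lo, hi = self.targets_per_drug
        if not (1 <= lo <= hi):
            raise ValueError("targets_per_drug must satisfy 1 <= min <= max")
        if not (0.0 <= self.se_prevalence <= 1.0):
            raise ValueError("se_prevalence must lie in [0, 1]")
        if self.degree_bias < 0:
            raise ValueError("degree_bias must be nonnegative")
        for frac in (self.central_top_fraction, self.peripheral_bottom_fraction):
            if not (0.0 < frac <= 1.0):
                raise ValueError("placement fractions must lie in (0, 1]")


def generate_network(n_nodes: int, m: int, rng_seed: int) -> InteractionNetwork:
    """Preferential-attachment simple graph, connected, reproducible.

    Construction starts from a complete graph on ``max(m, 2)`` nodes
    (a lone node carries no degree mass to attach to) and attaches each
    new node with ``m`` preferential edges, giving exactly
    ``m * (n_nodes - m) + m * (m - 1) / 2`` edges.  Node IDs are
    ``P<index>`` strings in attachment order.
    """
    if n_nodes <= m or m < 1:
        raise ValueError("need n_nodes > m >= 1")
    rng = _stream(rng_seed, _STREAM_NETWORK)
    g = nx.barabasi_albert_graph(
        n_nodes, m, seed=rng, initial_graph=nx.complete_graph(max(m, 2))
    )
    width = len(str(n_nodes - 1))
    relabel = {i: f"P{i:0{width}d}" for i in g.nodes}
    return InteractionNetwork(nx.relabel_nodes(g, relabel))


def _weighted_sample_without_replacement(
    rng: np.random.Generator, items: list[str], weights: np.ndarray, size: int
) -> list[str]:
    p = weights / weights.sum()
    idx = rng.choice(len(items), size=size, replace=False, p=p)
    return [items[i] for i in idx]


def plant_annotations(
    net: InteractionNetwork, scenario: SyntheticScenario
) -> AnnotationSet:
    """Draw drugs, targets, side-effect flags and disease sets.

    Side-effect flags are Bernoulli(``se_prevalence``); each drug draws
    a uniform target count in ``targets_per_drug`` and then its targets
    without replacement — weighted by ``degree ** degree_bias`` for
    side-effect drugs, uniformly otherwise.  The central disease set is
    sampled from nodes at or above the ``1 - central_top_fraction``
    degree quantile, the peripheral one from nodes strictly below the
    top pool (up to ``peripheral_bottom_fraction`` of the degree
    distribution).
    """
    nodes = net.sorted_nodes()
    degrees = np.array([net.degree(n) for n in nodes], dtype=float)
    width = len(str(scenario.n_drugs - 1)) if scenario.n_drugs > 1 else 1
    drug_ids = [f"D{i:0{width}d}" for i in range(scenario.n_drugs)]

    flag_rng = _stream(scenario.seed, _STREAM_FLAGS)
    flags = {d: bool(flag_rng.random() < scenario.se_prevalence) for d in drug_ids}

    target_rng = _stream(scenario.seed, _STREAM_TARGETS)
    lo, hi = scenario.targets_per_drug
    drug_targets: dict[str, frozenset[str]] = {}
    for drug in drug_ids:
        count = int(target_rng.integers(lo, hi + 1))
        if count > len(nodes):
            raise ValueError("requested more targets than available nodes")
        if flags[drug] and scenario.degree_bias > 0:
            weights = degrees**scenario.degree_bias
            chosen = _weighted_sample_without_replacement(
                target_rng, nodes, weights, count
            )
        else:
            idx = target_rng.choice(len(nodes), size=count, replace=False)
            chosen = [nodes[i] for i in idx]
        drug_targets[drug] = frozenset(chosen)

    disease_rng = _stream(scenario.seed, _STREAM_DISEASE)
    hub_cut = np.quantile(degrees, 1.0 - scenario.central_top_fraction)
    central_pool = [n for n, d in zip(nodes, degrees) if d >= hub_cut]
    low_cut = np.quantile(degrees, scenario.peripheral_bottom_fraction)
    peripheral_pool = [
        n for n, d in zip(nodes, degrees) if d <= low_cut and d < hub_cut
    ]
    for pool, label in ((central_pool, "central"), (peripheral_pool, "peripheral")):
        if len(pool) < scenario.disease_set_size:
            raise ValueError(
                f"{label} placement pool ({len(pool)} nodes) smaller than the "
                f"requested disease set size {scenario.disease_set_size}"
            )
    central = disease_rng.choice(
        len(central_pool), size=scenario.disease_set_size, replace=False
    )
    peripheral = disease_rng.choice(
        len(peripheral_pool), size=scenario.disease_set_size, replace=False
    )
    diseases = {
        "cancer_like": frozenset(central_pool[i] for i in central),
        "diabetes_like": frozenset(peripheral_pool[i] for i in peripheral),
    }
    return AnnotationSet(
        drug_targets=drug_targets, side_effect_flags=flags, disease_genes=diseases
    )


def generate_scenario_bundle(
    scenario: SyntheticScenario, outdir: str | Path
) -> dict:
    """Generate a scenario and write it as a loadable file bundle.

    Writes ``network.tsv`` (edge list), ``drug_targets.tsv``,
    ``side_effects.tsv`` (drug, term — side-effect drugs only),
    ``disease_<name>.tsv`` and ``manifest.json``.  Output is
    byte-deterministic for a given scenario, so re-running from the
    manifest's seed reproduces the bundle exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = generate_network(scenario.n_nodes, scenario.m, scenario.seed)
    ann = plant_annotations(net, scenario)

    write_edge_list(net, outdir / "network.tsv")

    with open(outdir / "drug_targets.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# drug_id\tnode_id\n")
        for drug in sorted(ann.drug_targets):
            for node in sorted(ann.drug_targets[drug]):
                fh.write(f"{drug}\t{node}\n")

    term_rng = _stream(scenario.seed, _STREAM_TERMS)
    with open(outdir / "side_effects.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# drug_id\tside_effect_term\n")
        for drug in sorted(ann.drug_targets):
            if ann.side_effect_flags[drug]:
                n_terms = int(term_rng.integers(1, 4))
                terms = term_rng.choice(
                    len(_SE_VOCABULARY), size=n_terms, replace=False
                )
                for t in sorted(terms):
                    fh.write(f"{drug}\t{_SE_VOCABULARY[t]}\n")

    disease_files = {}
    for disease in sorted(ann.disease_genes):
        fname = f"disease_{disease}.tsv"
        with open(outdir / fname, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("# disease_id\tnode_id\n")
            for node in sorted(ann.disease_genes[disease]):
                fh.write(f"{disease}\t{node}\n")
        disease_files[disease] = fname

    manifest = {
        "scenario": asdict(scenario),
        "files": {
            "network": "network.tsv",
            "drug_targets": "drug_targets.tsv",
            "side_effects": "side_effects.tsv",
            "diseases": disease_files,
        },
        "counts": {
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "n_drugs": len(ann.drug_targets),
            "n_se_drugs": sum(ann.side_effect_flags.values()),
            "n_target_nodes": len(ann.target_nodes()),
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def load_scenario_bundle(
    bundle_dir: str | Path,
) -> tuple[InteractionNetwork, AnnotationSet, dict]:
    """Round-trip loader for :func:`generate_scenario_bundle` output."""
    bundle_dir = Path(bundle_dir)
    with open(bundle_dir / "manifest.json", "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    files = manifest["files"]
    net, _report = load_edge_list(bundle_dir / files["network"], format="tsv")
    drug_targets = load_drug_targets(bundle_dir / files["drug_targets"])
    se_pairs = load_side_effect_pairs(bundle_dir / files["side_effects"])
    diseases: dict[str, frozenset[str]] = {}
    for disease, fname in files["diseases"].items():
        diseases.update(load_disease_genes(bundle_dir / fname))
    ann = AnnotationSet.from_tables(drug_targets, se_pairs, diseases)
    return net, ann, manifest
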
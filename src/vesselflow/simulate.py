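"""Communicating-vessels perturbation dynamics.

A perturbation is modelled as an amount of "energy" injected at one or
more seed proteins.  At every discrete time step the energy first flows
along each interaction in proportion to the energy difference between
the endpoints (a discrete diffusion on the graph Laplacian), and then a
fixed amount ``D`` dissipates from every node.  Two per-seed summary
statistics quantify spreading efficiency:

silencing time
    number of steps until every node's energy is below the detection
    threshold of 1 unit; efficient spreaders distribute their energy
    over many simultaneously-dissipating nodes and silence *fast*.
perturbation reach
    number of nodes whose energy ever met the threshold; efficient
    spreaders reach *many* nodes.

The flow sub-phase conserves total energy exactly; only dissipation
removes it, so total energy is strictly decreasing while positive and
silencing is guaranteed within ``E / min(D, threshold)`` steps whenever
``D >= threshold``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import InteractionNetwork

__all__ = [
    "PerturbationConfig",
    "EnergyState",
    "SimulationResult",
    "Simulator",
    "initialize_energy",
    "step",
    "run_perturbation",
    "silencing_profile",
    "write_profile",
]


@dataclass(frozen=True)
class PerturbationConfig:
    """Parameters of the communicating-vessels dynamics.

    Attributes
    ----------
    start_energy
        Total energy ``E`` injected at time 0, split equally among the
        seed nodes.  Default 1000 units.
    dissipation
        Energy ``D`` removed from every node at each step (floored at
        the node's current energy, so energies stay nonnegative).
        Default 5 units.
    silencing_threshold
        Detection threshold: the run is silenced once every node is
        below this value, and a node counts as "reached" once it meets
        it.  Fixed at 1 unit in the reference analyses.
    flow_coefficient
        Per-edge conductance ``k``: each edge moves ``k * (E_u - E_v)``
        from the higher- to the lower-energy endpoint per step.  ``None``
        (default) resolves to ``1 / (max_degree + 1)`` of the simulated
        network — the explicit-Euler stability bound of the graph
        Laplacian, which guarantees the flow sub-phase never overshoots
        into negative energies.
    max_steps
        Safety cap on the number of steps.  ``None`` resolves to
        ``max(10 * E / threshold, ceil(E / min(D, threshold)))``; a run
        that hits the cap is flagged, never silent.
    """

    start_energy: float = 1000.0
    dissipation: float = 5.0
    silencing_threshold: float = 1.0
    flow_coefficient: float | None = None
    max_steps: int | None = None

    def __post_init__(self):
        if self.start_energy <= 0:
            raise ValueError("start_energy must be positive")
        if self.dissipation <= 0:
            raise ValueError("dissipation must be positive")
        if self.silencing_threshold <= 0:
            raise ValueError("silencing_threshold must be positive")
        if self.flow_coefficient is not None and not (0 < self.flow_coefficient <= 1):
            raise ValueError("flow_coefficient must lie in (0, 1]")

    def resolve_flow_coefficient(self, net: InteractionNetwork) -> float:
        bound = 1.0 / (net.max_degree() + 1)
        if self.flow_coefficient is None:
            return bound
        if self.flow_coefficient > bound + 1e-12:
            raise ValueError(
                f"flow_coefficient {self.flow_coefficient} exceeds the "
                f"stability bound 1/(max_degree+1) = {bound:.6g} of this network"
            )
        return self.flow_coefficient

    def resolve_max_steps(self) -> int:
        if self.max_steps is not None:
            return self.max_steps
        e, d, theta = self.start_energy, self.dissipation, self.silencing_threshold
        return int(max(10 * e / theta, math.ceil(e / min(d, theta))))

    @classmethod
    def from_file(cls, path: str | Path) -> "PerturbationConfig":
        """Read a flat ``key = value`` config file (# comments allowed)."""
        values: dict[str, float] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: malformed config line {lineno}: {line!r}")
            key, raw = (part.strip() for part in line.split("=", 1))
            values[key] = float(raw)
        kwargs = {}
        for name in ("start_energy", "dissipation", "silencing_threshold",
                     "flow_coefficient"):
            if name in values:
                kwargs[name] = values.pop(name)
        if "max_steps" in values:
            kwargs["max_steps"] = int(values.pop("max_steps"))
        if values:
            raise ValueError(f"{path}: unknown config keys: {sorted(values)}")
        return cls(**kwargs)


@dataclass
class EnergyState:
    """Per-node energies at a given step, in sorted-node order."""

    nodes: tuple[str, ...]
    energy: np.ndarray
    reached: np.ndarray
    step: int = 0

    def energy_of(self, node: str) -> float:
        return float(self.energy[self.nodes.index(node)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(e) for n, e in zip(self.nodes, self.energy)}

    def total_energy(self) -> float:
        return float(self.energy.sum())


@dataclass(frozen=True)
class SimulationResult:
    silencing_time: int
    perturbation_reach: int
    seed_set: frozenset[str]
    terminated_by_cap: bool = False
    trajectory: tuple[float, ...] | None = None


class Simulator:
    """Reusable engine binding a network to a configuration.

    Builds the sparse adjacency once so that many seeds can be simulated
    on the same network cheaply (the per-probe profiles run thousands of
    independent perturbations on one interactome).
    """

    def __init__(self, net: InteractionNetwork, cfg: PerturbationConfig | None = None):
        self.cfg = cfg or PerturbationConfig()
        self.nodes: tuple[str, ...] = tuple(net.sorted_nodes())
        if not self.nodes:
            raise ValueError("cannot simulate on an empty network")
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        rows, cols = [], []
        for u, v in net.graph.edges():
            iu, iv = self.index[u], self.index[v]
            rows.extend((iu, iv))
            cols.extend((iv, iu))
        data = np.ones(len(rows))
        self.adjacency = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
        self.degrees = np.asarray(self.adjacency.sum(axis=1)).ravel()
        self.k = self.cfg.resolve_flow_coefficient(net)
        self.max_steps = self.cfg.resolve_max_steps()

    # -- primitive phases ---------------------------------------------

    def _seed_vector(self, seeds: Iterable[str]) -> np.ndarray:
        seeds = sorted(set(seeds))
        if not seeds:
            raise ValueError("seed set must be nonempty")
        e = np.zeros(len(self.nodes))
        share = self.cfg.start_energy / len(seeds)
        for s in seeds:
            if s not in self.index:
                raise KeyError(f"seed node {s!r} is not in the network")
            e[self.index[s]] = share
        return e

    def _flow(self, e: np.ndarray) -> np.ndarray:
        # e' = e - k * L e  with  L = diag(deg) - A
        return e + self.k * (self.adjacency @ e - self.degrees * e)

    def _dissipate(self, e: np.ndarray) -> np.ndarray:
        return np.maximum(e - self.cfg.dissipation, 0.0)

    # -- runs ----------------------------------------------------------

    def run(self, seeds: Iterable[str], record_trajectory: bool = False) -> SimulationResult:
        theta = self.cfg.silencing_threshold
        e = self._seed_vector(seeds)
        seed_set = frozenset(s for s in self.nodes if e[self.index[s]] > 0)
        reached = e >= theta
        traj = [float(e.sum())] if record_trajectory else None
        steps = 0
        capped = False
        while e.max() >= theta:
            if steps >= self.max_steps:
                capped = True
                break
            e = self._flow(e)
            reached |= e >= theta
            e = self._dissipate(e)
            steps += 1
            if record_trajectory:
                traj.append(float(e.sum()))
        return SimulationResult(
            silencing_time=steps,
            perturbation_reach=int(reached.sum()),
            seed_set=seed_set,
            terminated_by_cap=capped,
            trajectory=tuple(traj) if record_trajectory else None,
        )


def initialize_energy(
    net: InteractionNetwork,
    seeds: Iterable[str],
    start_energy: float = 1000.0,
    silencing_threshold: float = 1.0,
) -> EnergyState:
    """Distribute ``start_energy`` equally among the seed nodes."""
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValueError("seed set must be nonempty")
    nodes = tuple(net.sorted_nodes())
    index = {n: i for i, n in enumerate(nodes)}
    e = np.zeros(len(nodes))
    for s in seeds:
        if s not in index:
            raise KeyError(f"seed node {s!r} is not in the network")
        e[index[s]] = start_energy / len(seeds)
    return EnergyState(nodes=nodes, energy=e, reached=e >= silencing_threshold, step=0)


def step(
    state: EnergyState, net: InteractionNetwork, cfg: PerturbationConfig
) -> EnergyState:
    """One synchronous step: flow along all edges, then dissipation.

    Pure transition — returns a new state.  Reached flags are updated
    after the flow sub-phase (a node counts as reached the moment the
    flowing perturbation meets the threshold, before dissipation).
    """
    sim = Simulator(net, cfg)
    if tuple(state.nodes) != sim.nodes:
        raise ValueError("state is not consistent with the network")
    e = sim._flow(np.asarray(state.energy, dtype=float))
    reached = state.reached | (e >= cfg.silencing_threshold)
    e = sim._dissipate(e)
    return EnergyState(nodes=sim.nodes, energy=e, reached=reached, step=state.step + 1)


def run_perturbation(
    net: InteractionNetwork,
    seeds: Iterable[str],
    cfg: PerturbationConfig | None = None,
    record_trajectory: bool = False,
) -> SimulationResult:
    """Simulate until every node is below the silencing threshold.

    Returns the silencing time (completed steps; 0 if the initial state
    is already silent), the perturbation reach (nodes ever at or above
    the threshold, seeds included when their share qualifies), and a
    flag set when the step cap was hit before silencing.
    """
    return Simulator(net, cfg or PerturbationConfig()).run(
        seeds, record_trajectory=record_trajectory
    )


def silencing_profile(
    net: InteractionNetwork,
    probes: Iterable[str] | None = None,
    cfg: PerturbationConfig | None = None,
    seed_sets: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """One independent perturbation per probe node (or per seed set).

    Parameters
    ----------
    probes
        Nodes to perturb one at a time; ``None`` means every node.
        Ignored when ``seed_sets`` is given.
    seed_sets
        Multi-target mode: mapping of run ID (e.g. drug ID) to the set
        of nodes that share the starting energy equally.

    Returns
    -------
    DataFrame indexed by probe/run ID with columns ``silencing_time``,
    ``perturbation_reach``, ``terminated_by_cap``.
    """
    sim = Simulator(net, cfg or PerturbationConfig())
    if seed_sets is not None:
        runs = [(str(key), list(val)) for key, val in seed_sets.items()]
    else:
        probe_list = sorted(probes) if probes is not None else list(sim.nodes)
        runs = [(p, [p]) for p in probe_list]
    records = []
    for key, seeds in runs:
        try:
            res = sim.run(seeds)
        except Exception as exc:
            raise RuntimeError(f"perturbation run {key!r} failed: {exc}") from exc
        records.append(
            (key, res.silencing_time, res.perturbation_reach, res.terminated_by_cap)
        )
    frame = pd.DataFrame.from_records(
        records,
        columns=["probe_id", "silencing_time", "perturbation_reach", "terminated_by_cap"],
    ).set_index("probe_id")
    return frame


def write_profile(profile: pd.DataFrame, path: str | Path) -> None:
    """Write a silencing profile as TSV."""
    profile.to_csv(path, sep="\t")
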
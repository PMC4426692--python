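# vesselflow

Perturbation spreading on protein–protein interaction networks.

A local change to a protein — a drug binding it, a mutation — does not
stay local: it propagates through the interactome and decays.
`vesselflow` models this with a *communicating-vessels* dynamics: an
amount of energy *E* is injected at one or more seed proteins, flows
along every interaction in proportion to the energy difference between
its endpoints, and dissipates by *D* units per protein per step.  Two
statistics summarize how well a seed spreads:

- **silencing time** — steps until every node is below 1 energy unit.
  Good spreaders hand their energy to many simultaneously-dissipating
  neighbours and silence *fast*;
- **perturbation reach** — number of nodes whose energy ever met the
  1-unit threshold.

Formally, with adjacency matrix **A**, degree matrix **Δ** and graph
Laplacian **L = Δ − A**, one step maps the energy vector **e** to

```
e  ←  max( (I − k·L)·e − D, 0 )
```

with per-edge conductance `k = 1/(deg_max + 1)` by default (the
explicit-Euler stability bound, so the flow phase never overshoots).
The flow phase conserves total energy exactly; only dissipation
removes it, which bounds the silencing time by `E/θ` for `D ≥ θ`.

Around the simulator the package provides the full analysis workflow
used to ask whether drug targets — and especially targets of drugs
with recorded side effects — are better spreaders than other proteins,
and whether disease gene sets are central or peripheral:

- `network`: edge-list/SIF loading with cleanup (self-loops dropped,
  duplicate pairs collapsed, counts reported), ID translation with
  explicit handling of untranslated IDs, giant component, seeded
  random node deletion;
- `simulate`: the dynamics, per-probe silencing profiles, multi-target
  energy splitting;
- `groups`: drug→target / side-effect / disease annotations, the
  three-way target partition, cumulative distributions, Mann-Whitney
  (R `wilcox.test`-compatible) and Welch tests;
- `centrality`: degree / closeness / betweenness with group summaries;
- `distances`: target→disease geodesic distances and giant-component
  membership;
- `synth`: synthetic interactomes (preferential attachment) with
  planted annotations — degree-biased side-effect targets, central
  ("cancer-like") and background-like ("diabetes-like") disease sets —
  so the pipeline's power and calibration are measurable;
- `pipeline`: end-to-end orchestration, replicate Monte-Carlo designs
  and node-deletion robustness, plus a thin `vesselflow` CLI
  (`synth`, `simulate`, `analyze`, `robustness`, `report`).

## Worked example

`examples/` contains one narrative script per capability.  The core
question, on a synthetic interactome with a planted hub bias
(`examples/03_target_group_comparison.py`):

```
targets of side-effect drugs : 46
targets of other drugs       : 24
median silencing time with SE    : 20 steps
median silencing time without SE : 67 steps
Mann-Whitney two-sided p         : 1.39e-07 (direction: b_greater)
```

Side-effect drugs picked their targets with weight `degree²`, so those
targets are hubs; a perturbation started on them silences in a median
of 20 steps versus 67 for the unbiased target group, and the rank-sum
test detects the shift (`b_greater`: the second group's values are
larger).  The disease contrast (`examples/04_...py`) shows the same
logic for gene sets: a hub-placed set has median degree 17 against a
background median of 3 (p ≈ 8e-10), silences in 16 steps versus 71 for
the background-like set, and drug targets sit on average 3.34 edges
from the central set but 4.21 edges from the peripheral one (Welch
p ≈ 2e-15).

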
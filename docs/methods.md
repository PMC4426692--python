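# Methods

## The dynamics

The model treats a perturbation as a conserved-but-leaky quantity
("energy") on an undirected simple graph.  A run starts by splitting
the total energy *E* equally among the seed nodes.  Each discrete step
has two synchronous sub-phases:

1. **Flow.**  Every edge {u, v} moves `k·(E_u − E_v)` units from the
   higher-energy endpoint to the lower one.  Collecting terms, the
   energy vector is multiplied by `I − k·L` with `L` the graph
   Laplacian.  This phase conserves total energy exactly and, for
   `0 < k ≤ 1/(deg_max + 1)`, keeps every energy nonnegative (each
   node retains the fraction `1 − k·deg ≥ k > 0` of its own energy).
2. **Dissipation.**  Every node loses `min(energy, D)` units — the
   floor at zero prevents negative energies when a node holds less
   than *D*.

A run ends when every node is below the silencing threshold θ = 1
unit; the **silencing time** is the number of completed steps (a state
already below θ at t = 0 has silencing time 0, and the check runs
after dissipation).  The **perturbation reach** is the number of nodes
whose energy was ever ≥ θ, evaluated after each flow sub-phase and at
initialization — so seeds count when their share qualifies.  Reusing θ
as the reach detection threshold keeps a single threshold concept.

Because dissipation removes at least θ in total while any node is ≥ θ
(when D ≥ θ), silencing is guaranteed within `E/θ` steps; a
configurable cap (`max_steps`, default `max(10·E/θ, ⌈E/min(D, θ)⌉)`)
guards pathological configurations and is reported as a flag, never
silently.

### Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `start_energy` E | injected energy (units) | 1000 | standard condition; the E/D grid (1000/5, 10000/5, 10000/1) is kept as the pipeline's default for robustness checks |
| `dissipation` D | energy removed per node per step | 5 | standard condition |
| `silencing_threshold` θ | detection/termination level | 1 | fixed in the reference analyses |
| `flow_coefficient` k | per-edge conductance | `1/(deg_max+1)` | the explicit-Euler stability bound of the Laplacian; any larger k can oscillate or overshoot negative. k is configurable but validated against the bound |
| `max_steps` | safety cap | see above | termination guarantee independent of parameters |

The proportionality constant of the flow, the order of the two
sub-phases, and the exact reach threshold are genuinely open design
points of this model family; they are fixed here as stated (flow
first, then dissipation; one flow+dissipation pair = one step) and
exposed in the config, so alternatives are one parameter away.  The
two sub-phase orders differ by at most one step in silencing time at
the default parameters.  Energies are real-valued throughout — the
model reads most naturally as continuous flow; no integer
quantization is applied.

The simulator applies `e + k·(A·e − deg∘e)` with a sparse CSR
adjacency; an independent dense `(I − k·L)` oracle is kept in the test
suite and the elementwise agreement (tolerance 1e-9 relative to the
energy scale) is asserted on random graphs at every step.

## Network handling

Input edge lists are simplified on load: self-loops dropped, duplicate
pairs (either orientation) collapsed, counts reported.  Edge direction
in input files is ignored — all analyses are on undirected graphs.
ID translation drops untranslated nodes (with a report) rather than
passing foreign IDs through silently; a source mapping to several
targets keeps the lexicographically smallest and logs the rest — the
original translation services' behaviour is not recoverable, and a
deterministic rule matters more than any particular choice.  Giant-
component ties are broken toward the component containing the
smallest node ID.  Random node deletion sorts the node set before the
seeded draw, so the surviving set depends only on (node set, seed),
never on file row order.

## Statistics

`mann_whitney` mirrors R's `wilcox.test` defaults, since that is the
convention in this literature: exact p when both n < 50 and the pooled
sample is tie-free, otherwise the normal approximation with the tie
correction and a `sign(z)`-scaled continuity correction.  The sign-
aware correction is why two identical samples give exactly p = 1.
`welch_t` is the unequal-variance t-test with Welch–Satterthwaite
degrees of freedom.  No multiple-testing correction is applied — the
reports label every p-value as unadjusted, matching how such analyses
are conventionally reported.  Group precedence in the target
partition: a protein targeted by *any* side-effect drug counts as a
with-side-effect target even if side-effect-free drugs also bind it;
this is the only reading under which the three groups partition the
node set.

Closeness uses the component-scaled convention
`(r/Σd)·(r/(n−1))` with r the number of reachable nodes, so scores
from small components cannot dominate a disconnected graph;
betweenness excludes endpoints and is normalized by `(n−1)(n−2)/2` so
it is a fraction in [0, 1].  Centralities and distance matrices are
computed through igraph's C core; a pure-Python BFS/path-counting
enumeration oracle verifies both conventions exactly on all fixture
graphs up to 30 nodes.

Target→disease distances: per target, the mean shortest-path length to
the *reachable* disease members, with unreachable members counted
separately (default policy).  Exclusion is the only finite-valued
convention when part of a disease set lies outside the giant
component, which is exactly the situation the peripheral-disease case
presents; an alternative policy imputing the network size as a penalty
distance is selectable for sensitivity analysis.

## What the synthetic generator emulates — and what it does not

`SyntheticScenario` generates a preferential-attachment network
(Barabási–Albert, seed clique on `max(m, 2)` nodes, exactly
`m(n−m)+C(m,2)` edges).  Preferential attachment was chosen because
the heavy-tailed degree distribution of real interactomes is the
single feature that drives every contrast the pipeline measures;
degree-sequence-controlled alternatives can be swapped in through the
same `InteractionNetwork` container.

Planted structure:

- each drug gets a side-effect flag (Bernoulli π_SE) and 1–5 targets;
  flagged drugs sample targets with weight `degree^β`, others
  uniformly.  β is the planted ground truth: degree correlates
  strongly and negatively with silencing time in this dynamics
  (asserted as a property), so β > 0 plants "side-effect targets are
  better spreaders" and β = 0 is an exact null;
- the "cancer-like" disease set samples from the top 5% of the degree
  distribution (hubs); the "diabetes-like" set samples from everything
  below that pool.  The emulated contrast is a disease group far above
  the background degree distribution versus one statistically
  indistinguishable from background — hence the peripheral pool is the
  *bulk*, not the low-degree tail: drawing only minimum-degree nodes
  would plant a negative effect the emulated system does not show.

Defaults (n = 2000, m = 2, 40 drugs, π_SE = 0.5, β = 2, disease sets
of 15) are the package's standard desk-scale study: large enough for
hubs to exist and groups to have workable sizes, small enough that
replicate Monte-Carlo designs (50–200 scenarios) run in minutes on one
CPU.  π_SE = 0.5 gives a balanced two-group comparison; real
annotation databases are far more lopsided, which costs power but not
validity — the statistics make no balance assumption.

All randomness flows from the single scenario seed through named
`SeedSequence` sub-streams (network / flags / targets / diseases /
terms), so any sub-draw is independently reproducible; bundles written
to disk are byte-deterministic.

What the generator does **not** emulate: the correlation structure of
real annotations (side-effect records correlate with drug age and
usage, not only with target topology), protein families and network
motifs, confidence-scored or directed edges, and MedDRA-style
side-effect vocabularies (terms are a small synthetic vocabulary).
Passing the planted-effect and calibration tests therefore shows the
*pipeline* is correct and adequately powered under a known truth — it
does not by itself validate the biological claim on any real
interactome.

## Numerical and degenerate-input choices

- Flow conservation is asserted to 1e-9 relative; simulator-vs-oracle
  agreement to 1e-9 relative with an absolute floor of 1e-9·E
  (different summation orders leave ~1e-12 noise on a 1000-unit
  scale).
- Single-node graphs: closeness and betweenness are defined as 0.
- Empty groups and samples raise; constant pooled samples are flagged
  `degenerate` with p = 1 (Mann-Whitney) or p ∈ {0, 1} (Welch, by
  mean equality).
- A drug with targets but no side-effect flag is an error, never a
  guess; drugs absent from an adverse-event table are explicitly
  flagged "no reported side effects" by the table loader.
- Robustness replicates that lose an entire target group are skipped
  and flagged, not imputed.

## Problem sizes used by the shipped analyses

The acceptance script and the end-to-end tests run: oracle agreement
on 100 random graphs ≤ 20 nodes; the degree–silencing correlation on
one n = 1000 network (all nodes probed); planted-effect power on 50
replicate n = 2000 scenarios; null calibration on 200 replicates;
the disease contrast on 50 replicates (with a seeded 200-node
background sample for the silencing comparison); robustness on 10
half-deletion replicates.  These sizes were chosen as the smallest at
which the measured quantities stabilize (detection rates within a few
percent across seeds) while a full run stays in the minutes range on
one CPU.

## Known limitations

- The dynamics is unweighted and undirected; confidence scores,
  tissue abundances and signalling direction are out of scope.
- `silencing_profile` runs probes serially; the runs are independent
  and order-invariant, so parallelization is trivial but not built in.
- The Mann-Whitney exact path delegates to scipy's exact enumeration;
  for samples with ties there is no exact option (as in R).
- The closeness convention for disconnected graphs is one of several
  in use; comparisons across tools must fix the convention first.
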
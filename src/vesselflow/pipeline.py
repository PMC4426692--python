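"""End-to-end analysis orchestration and replicate Monte-Carlo designs.

``run_full_analysis`` chains the stages of the reference workflow on a
loaded or synthetic study: derive node groups from the annotations,
simulate a perturbation from every node for each (E, D) grid point,
compare silencing times and perturbation reaches between groups,
summarize centralities of the disease sets, and measure target→disease
geodesic distances.  ``run_robustness`` repeats the headline comparison
on randomly truncated networks.

The replicate helpers (``planted_effect_replicates``,
``null_calibration``, ``disease_contrast_replicates``) run the same
machinery across many seeded synthetic scenarios; they are what the
power/calibration analyses and the acceptance checks are built from.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .centrality import compute_centralities, group_centrality_summary
from .distances import average_distance_to_set, component_membership
from .groups import (
    AnnotationSet,
    GroupComparison,
    cumulative_distribution,
    derive_groups,
    mann_whitney,
    welch_t,
)
from .network import InteractionNetwork, giant_component, random_node_deletion
from .simulate import PerturbationConfig, Simulator, silencing_profile
from .synth import SyntheticScenario, generate_network, load_scenario_bundle, plant_annotations

__all__ = [
    "AnalysisConfig",
    "run_full_analysis",
    "run_robustness",
    "derive_replicate_seed",
    "planted_effect_replicates",
    "null_calibration",
    "disease_contrast_replicates",
    "robustness_sign_consistency",
]

logger = logging.getLogger(__name__)

DEFAULT_ED_GRID: tuple[tuple[float, float], ...] = ((1000, 5), (10000, 5), (10000, 1))


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run.

    Either ``bundle_dir`` (a scenario bundle on disk) or ``scenario``
    (generated in memory) provides the inputs.  ``ed_grid`` lists the
    (start energy, dissipation) pairs to simulate; the default grid is
    the standard condition plus the two robustness variations.
    """

    output_dir: Path | str = "vesselflow_out"
    bundle_dir: Path | str | None = None
    scenario: SyntheticScenario | None = None
    ed_grid: tuple[tuple[float, float], ...] = DEFAULT_ED_GRID
    multi_target_split: bool = False
    flow_coefficient: float | None = None
    robustness_fraction: float = 0.5
    robustness_replicates: int = 10
    robustness_seed: int = 0

    def __post_init__(self):
        if self.bundle_dir is None and self.scenario is None:
            raise ValueError("provide either bundle_dir or scenario")
        if not self.ed_grid:
            raise ValueError("ed_grid must be nonempty")
        if self.bundle_dir is not None and not Path(self.bundle_dir).exists():
            raise FileNotFoundError(self.bundle_dir)


def derive_replicate_seed(base_seed: int, replicate: int, stream: int = 0) -> int:
    """Stable sub-2^31 seed for one replicate of a Monte-Carlo design."""
    ss = np.random.SeedSequence([int(base_seed), int(replicate), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31))


def _load_inputs(cfg: AnalysisConfig) -> tuple[InteractionNetwork, AnnotationSet, dict]:
    if cfg.bundle_dir is not None:
        net, ann, manifest = load_scenario_bundle(cfg.bundle_dir)
        provenance = {"source": str(cfg.bundle_dir), "manifest": manifest}
    else:
        scenario = cfg.scenario
        net = generate_network(scenario.n_nodes, scenario.m, scenario.seed)
        ann = plant_annotations(net, scenario)
        provenance = {"source": "synthetic", "scenario": dataclasses.asdict(scenario)}
    return net, ann, provenance


def _comparison_block(
    profile: pd.DataFrame,
    groups: dict[str, frozenset[str]],
    pairs: Sequence[tuple[str, str]],
    metric: str,
) -> list[dict]:
    out = []
    for a, b in pairs:
        sa = profile.loc[sorted(set(groups[a]) & set(profile.index)), metric]
        sb = profile.loc[sorted(set(groups[b]) & set(profile.index)), metric]
        if sa.empty or sb.empty:
            out.append({"metric": metric, "group_a": a, "group_b": b,
                        "skipped": "empty group"})
            continue
        cmp = mann_whitney(sa.to_numpy(), sb.to_numpy(), names=(a, b))
        entry = {"metric": metric, **cmp.as_dict(),
                 "median_a": float(sa.median()), "median_b": float(sb.median())}
        out.append(entry)
    return out


def _curves(profile: pd.DataFrame, groups: dict[str, frozenset[str]], metric: str):
    curves = {}
    for name, members in groups.items():
        vals = profile.loc[sorted(set(members) & set(profile.index)), metric]
        if len(vals):
            curves[name] = cumulative_distribution(vals.to_numpy())
    return curves


def run_full_analysis(cfg: AnalysisConfig) -> dict:
    """Execute the full analysis and write the report to ``output_dir``.

    Returns the report dict (also written as ``report.json``); per-node
    simulation tables and cumulative curves land as TSV next to it.
    Any stage failure raises with the stage name; artifacts written by
    earlier stages are preserved.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}
    stage = "load_inputs"
    try:
        net, ann, provenance = _load_inputs(cfg)
        report["provenance"] = {
            **provenance,
            "ed_grid": [list(p) for p in cfg.ed_grid],
            "multi_target_split": cfg.multi_target_split,
        }
        logger.info("loaded network: %d nodes, %d edges", net.n_nodes, net.n_edges)
        report["stages"].append(stage)

        stage = "derive_groups"
        assignment = derive_groups(net, ann)
        groups = dict(assignment.groups)
        report["groups"] = {
            name: len(members) for name, members in groups.items()
        }
        report["disease_groups"] = {
            name: len(members) for name, members in assignment.disease_groups.items()
        }
        report["not_in_network"] = {
            k: sorted(v) for k, v in assignment.not_in_network.items()
        }
        degenerate = [n for n, members in groups.items() if not members]
        if degenerate:
            report["degenerate_groups"] = degenerate
        logger.info("groups: %s", report["groups"])
        report["stages"].append(stage)

        stage = "simulate"
        report["simulations"] = []
        pairs = [
            ("targets_with_se", "targets_without_se"),
            ("targets_without_se", "non_targets"),
        ]
        for energy, dissipation in cfg.ed_grid:
            pcfg = PerturbationConfig(
                start_energy=energy,
                dissipation=dissipation,
                flow_coefficient=cfg.flow_coefficient,
            )
            profile = silencing_profile(net, cfg=pcfg)
            tag = f"E{energy:g}_D{dissipation:g}"
            profile.to_csv(outdir / f"profile_{tag}.tsv", sep="\t")
            block = {
                "start_energy": energy,
                "dissipation": dissipation,
                "comparisons": (
                    _comparison_block(profile, groups, pairs, "silencing_time")
                    + _comparison_block(profile, groups, pairs, "perturbation_reach")
                ),
            }
            for metric in ("silencing_time", "perturbation_reach"):
                curves = _curves(profile, {**groups, **assignment.disease_groups},
                                 metric)
                rows = []
                for name, curve in curves.items():
                    rows += [(name, t, f) for t, f in curve]
                pd.DataFrame(rows, columns=["group", "threshold", "cumulative_fraction"]) \
                    .to_csv(outdir / f"curves_{metric}_{tag}.tsv", sep="\t", index=False)
            if assignment.disease_groups:
                disease_pairs = []
                background = groups["non_targets"]
                for disease, members in assignment.disease_groups.items():
                    if not members:
                        block.setdefault("skipped", []).append(disease)
                        continue
                    rest = net.nodes - members
                    cmp = mann_whitney(
                        profile.loc[sorted(members), "silencing_time"].to_numpy(),
                        profile.loc[sorted(rest), "silencing_time"].to_numpy(),
                        names=(disease, "rest_of_network"),
                    )
                    disease_pairs.append({"metric": "silencing_time", **cmp.as_dict()})
                block["disease_comparisons"] = disease_pairs
            if cfg.multi_target_split:
                seed_sets = {
                    drug: sorted(t & net.nodes)
                    for drug, t in ann.drug_targets.items()
                    if t & net.nodes
                }
                drug_profile = silencing_profile(net, cfg=pcfg, seed_sets=seed_sets)
                drug_profile.to_csv(outdir / f"drug_profile_{tag}.tsv", sep="\t")
                se_drugs = [d for d in seed_sets if ann.side_effect_flags[d]]
                nose_drugs = [d for d in seed_sets if not ann.side_effect_flags[d]]
                if se_drugs and nose_drugs:
                    cmp = mann_whitney(
                        drug_profile.loc[se_drugs, "silencing_time"].to_numpy(),
                        drug_profile.loc[nose_drugs, "silencing_time"].to_numpy(),
                        names=("se_drugs", "no_se_drugs"),
                    )
                    block["multi_target_comparison"] = cmp.as_dict()
            report["simulations"].append(block)
        report["stages"].append(stage)

        stage = "centrality"
        profile_c = compute_centralities(net)
        profile_c.to_csv(outdir / "centrality.tsv", sep="\t")
        disease_members = frozenset().union(
            *assignment.disease_groups.values()
        ) if assignment.disease_groups else frozenset()
        summary_groups = {
            name: members
            for name, members in {**assignment.disease_groups,
                                  "background": net.nodes - disease_members}.items()
            if members
        }
        if len(summary_groups) >= 1:
            report["centrality_summary"] = group_centrality_summary(
                profile_c, summary_groups
            )
        report["stages"].append(stage)

        stage = "distances"
        report["distances"] = {}
        target_groups = {
            "targets_with_se": groups["targets_with_se"],
            "targets_without_se": groups["targets_without_se"],
        }
        per_disease_means: dict[str, dict[str, list[float]]] = {}
        for disease, members in assignment.disease_groups.items():
            if not members:
                continue
            report["distances"][disease] = {}
            per_disease_means[disease] = {}
            membership = component_membership(net, members)
            report["distances"][disease]["component_membership"] = {
                "in_giant": membership.in_giant,
                "out_of_giant": membership.out_of_giant,
                "fraction_out": membership.fraction_out,
            }
            for gname, targets in target_groups.items():
                if not targets:
                    report["distances"][disease][gname] = {"skipped": "empty group"}
                    continue
                result = average_distance_to_set(net, targets, members)
                result.per_target.to_csv(
                    outdir / f"distance_{disease}_{gname}.tsv", sep="\t"
                )
                report["distances"][disease][gname] = result.as_dict()
                per_disease_means[disease][gname] = (
                    result.per_target["mean_distance"].dropna().tolist()
                )
        diseases = [d for d in per_disease_means if per_disease_means[d]]
        if len(diseases) == 2:
            welch_block = []
            for gname in target_groups:
                a = per_disease_means[diseases[0]].get(gname, [])
                b = per_disease_means[diseases[1]].get(gname, [])
                if len(a) >= 2 and len(b) >= 2:
                    cmp = welch_t(a, b, names=(diseases[0], diseases[1]))
                    welch_block.append({"target_group": gname, **cmp.as_dict()})
            report["distance_welch"] = welch_block
        report["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"analysis stage {stage!r} failed: {exc}") from exc

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return report


# ---------------------------------------------------------------------------
# replicate Monte-Carlo designs
# ---------------------------------------------------------------------------


def _se_comparison_for_scenario(
    scenario: SyntheticScenario, pcfg: PerturbationConfig
) -> GroupComparison:
    """Silencing-time Mann-Whitney of SE-targets vs non-SE targets."""
    net = generate_network(scenario.n_nodes, scenario.m, scenario.seed)
    ann = plant_annotations(net, scenario)
    assignment = derive_groups(net, ann)
    with_se = sorted(assignment.groups["targets_with_se"])
    without_se = sorted(assignment.groups["targets_without_se"])
    if not with_se or not without_se:
        raise ValueError("a target group is empty in this replicate")
    sim = Simulator(net, pcfg)
    st = {n: sim.run([n]).silencing_time for n in set(with_se) | set(without_se)}
    return mann_whitney(
        [st[n] for n in with_se],
        [st[n] for n in without_se],
        names=("targets_with_se", "targets_without_se"),
    )


def planted_effect_replicates(
    n_replicates: int,
    base_seed: int,
    scenario: SyntheticScenario | None = None,
    pcfg: PerturbationConfig | None = None,
) -> pd.DataFrame:
    """Power of the SE-vs-no-SE comparison on degree-biased scenarios.

    Each replicate regenerates the scenario with a derived seed, runs
    per-target perturbations and the Mann-Whitney comparison.  The
    planted effect (``degree_bias > 0``) makes side-effect targets
    hubs, which silence faster, so "detected" means p below threshold
    *and* the with-SE group shifted toward smaller silencing times.
    """
    scenario = scenario or SyntheticScenario()
    pcfg = pcfg or PerturbationConfig()
    rows = []
    for rep in range(n_replicates):
        seed = derive_replicate_seed(base_seed, rep)
        cmp = _se_comparison_for_scenario(
            dataclasses.replace(scenario, seed=seed), pcfg
        )
        rows.append(
            {
                "replicate": rep,
                "seed": seed,
                "p_value": cmp.p_value,
                "direction": cmp.direction,
                "n_with_se": cmp.n_a,
                "n_without_se": cmp.n_b,
                # planted direction: with-SE silencing times smaller
                "correct_direction": cmp.direction == "b_greater",
            }
        )
        logger.info("planted-effect replicate %d: p=%.3g (%s)",
                    rep, cmp.p_value, cmp.direction)
    return pd.DataFrame(rows)


def null_calibration(
    n_replicates: int,
    base_seed: int,
    scenario: SyntheticScenario | None = None,
    pcfg: PerturbationConfig | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Type-I error of the same comparison on bias-free scenarios."""
    scenario = dataclasses.replace(
        scenario or SyntheticScenario(), degree_bias=0.0
    )
    frame = planted_effect_replicates(n_replicates, base_seed, scenario, pcfg)
    frame["rejected"] = frame["p_value"] < alpha
    return frame


def disease_contrast_replicates(
    n_replicates: int,
    base_seed: int,
    scenario: SyntheticScenario | None = None,
    pcfg: PerturbationConfig | None = None,
    n_background: int = 200,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Central vs peripheral disease-set contrast across replicates.

    Per replicate: the central ("cancer-like") set should show
    significantly smaller silencing times and significantly larger
    degree and betweenness than the background, the peripheral
    ("diabetes-like") set should be statistically indistinguishable
    from background, and the mean target→disease geodesic distance
    should be significantly larger for the peripheral set (Welch test
    on per-target means).
    """
    scenario = scenario or SyntheticScenario()
    pcfg = pcfg or PerturbationConfig()
    rows = []
    for rep in range(n_replicates):
        seed = derive_replicate_seed(base_seed, rep, stream=1)
        sc = dataclasses.replace(scenario, seed=seed)
        net = generate_network(sc.n_nodes, sc.m, sc.seed)
        ann = plant_annotations(net, sc)
        central = sorted(ann.disease_genes["cancer_like"])
        peripheral = sorted(ann.disease_genes["diabetes_like"])
        disease_nodes = set(central) | set(peripheral)
        bg_rng = np.random.default_rng(derive_replicate_seed(base_seed, rep, stream=2))
        bg_pool = sorted(net.nodes - disease_nodes)
        background = [
            bg_pool[i]
            for i in bg_rng.choice(len(bg_pool),
                                   size=min(n_background, len(bg_pool)),
                                   replace=False)
        ]
        sim = Simulator(net, pcfg)
        st = {n: sim.run([n]).silencing_time
              for n in disease_nodes | set(background)}
        central_vs_bg = mann_whitney([st[n] for n in central],
                                     [st[n] for n in background])
        peripheral_vs_bg = mann_whitney([st[n] for n in peripheral],
                                        [st[n] for n in background])
        prof = compute_centralities(net)
        bg_all = sorted(net.nodes - disease_nodes)
        degree_cmp = mann_whitney(prof.loc[central, "degree"].to_numpy(),
                                  prof.loc[bg_all, "degree"].to_numpy())
        btw_cmp = mann_whitney(prof.loc[central, "betweenness"].to_numpy(),
                               prof.loc[bg_all, "betweenness"].to_numpy())
        targets = sorted(ann.target_nodes() & net.nodes)
        d_central = average_distance_to_set(net, targets, central)
        d_peripheral = average_distance_to_set(net, targets, peripheral)
        dist_cmp = welch_t(
            d_peripheral.per_target["mean_distance"].dropna(),
            d_central.per_target["mean_distance"].dropna(),
        )
        rows.append(
            {
                "replicate": rep,
                "seed": seed,
                "central_silencing_p": central_vs_bg.p_value,
                "central_silencing_smaller": central_vs_bg.direction == "b_greater",
                "peripheral_silencing_p": peripheral_vs_bg.p_value,
                "central_degree_p": degree_cmp.p_value,
                "central_degree_larger": degree_cmp.direction == "a_greater",
                "central_betweenness_p": btw_cmp.p_value,
                "central_betweenness_larger": btw_cmp.direction == "a_greater",
                "mean_distance_central": d_central.group_mean,
                "mean_distance_peripheral": d_peripheral.group_mean,
                "distance_welch_p": dist_cmp.p_value,
                "peripheral_farther": dist_cmp.direction == "a_greater",
            }
        )
    frame = pd.DataFrame(rows)
    frame["contrast_holds"] = (
        (frame["central_silencing_p"] < alpha)
        & frame["central_silencing_smaller"]
        & (frame["peripheral_silencing_p"] >= alpha)
        & (frame["central_degree_p"] < alpha)
        & frame["central_degree_larger"]
        & (frame["central_betweenness_p"] < alpha)
        & frame["central_betweenness_larger"]
        & (frame["distance_welch_p"] < alpha)
        & frame["peripheral_farther"]
    )
    return frame


def robustness_sign_consistency(
    scenario: SyntheticScenario,
    fraction: float,
    n_replicates: int,
    base_seed: int,
    pcfg: PerturbationConfig | None = None,
) -> pd.DataFrame:
    """Does the SE-vs-no-SE ordering survive random node deletion?

    Each replicate deletes ``fraction`` of the nodes, takes the giant
    component of the truncated network, restricts the target groups to
    surviving nodes and reruns the silencing-time comparison.  A
    replicate "preserves the ordering" when the median shift keeps the
    with-SE group on the faster-silencing side.
    """
    pcfg = pcfg or PerturbationConfig()
    net = generate_network(scenario.n_nodes, scenario.m, scenario.seed)
    ann = plant_annotations(net, scenario)
    rows = []
    for rep in range(n_replicates):
        seed = derive_replicate_seed(base_seed, rep, stream=3)
        truncated = giant_component(
            random_node_deletion(net, fraction, rng_seed=seed)
        )
        assignment = derive_groups(truncated, ann)
        with_se = sorted(assignment.groups["targets_with_se"])
        without_se = sorted(assignment.groups["targets_without_se"])
        if not with_se or not without_se:
            rows.append({"replicate": rep, "seed": seed, "skipped": True,
                         "preserved": None})
            continue
        sim = Simulator(truncated, pcfg)
        st = {n: sim.run([n]).silencing_time for n in set(with_se) | set(without_se)}
        med_with = float(np.median([st[n] for n in with_se]))
        med_without = float(np.median([st[n] for n in without_se]))
        cmp = mann_whitney([st[n] for n in with_se], [st[n] for n in without_se])
        rows.append(
            {
                "replicate": rep,
                "seed": seed,
                "skipped": False,
                "median_with_se": med_with,
                "median_without_se": med_without,
                "p_value": cmp.p_value,
                "preserved": med_with < med_without,
            }
        )
    return pd.DataFrame(rows)


def run_robustness(cfg: AnalysisConfig) -> dict:
    """Robustness section for a configured analysis (writes TSV + JSON)."""
    net, ann, provenance = _load_inputs(cfg)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pcfg = PerturbationConfig(flow_coefficient=cfg.flow_coefficient)
    rows = []
    for rep in range(cfg.robustness_replicates):
        seed = derive_replicate_seed(cfg.robustness_seed, rep, stream=3)
        truncated = giant_component(
            random_node_deletion(net, cfg.robustness_fraction, rng_seed=seed)
        )
        assignment = derive_groups(truncated, ann)
        with_se = sorted(assignment.groups["targets_with_se"])
        without_se = sorted(assignment.groups["targets_without_se"])
        if not with_se or not without_se:
            rows.append({"replicate": rep, "seed": seed, "skipped": True})
            continue
        sim = Simulator(truncated, pcfg)
        st = {n: sim.run([n]).silencing_time for n in set(with_se) | set(without_se)}
        cmp = mann_whitney([st[n] for n in with_se], [st[n] for n in without_se])
        rows.append(
            {
                "replicate": rep,
                "seed": seed,
                "skipped": False,
                "p_value": cmp.p_value,
                "median_with_se": float(np.median([st[n] for n in with_se])),
                "median_without_se": float(np.median([st[n] for n in without_se])),
                "preserved": float(np.median([st[n] for n in with_se]))
                < float(np.median([st[n] for n in without_se])),
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "robustness.tsv", sep="\t", index=False)
    valid = frame[~frame["skipped"]] if "skipped" in frame else frame
    summary = {
        "fraction": cfg.robustness_fraction,
        "replicates": cfg.robustness_replicates,
        "n_valid": int(len(valid)),
        "n_preserved": int(valid["preserved"].sum()) if len(valid) else 0,
        "provenance": provenance,
    }
    with open(outdir / "robustness.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return summary
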
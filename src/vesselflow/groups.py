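"""Annotation-driven node groups, cumulative distributions, and the
two-sample tests used throughout the group comparisons.

The central grouping mirrors the drug-target analysis design: nodes are
partitioned into targets of at least one drug with recorded adverse
events ("targets_with_se"), targets of drugs none of which have recorded
adverse events ("targets_without_se"), and everything else
("non_targets").  Disease gene sets are kept alongside and intersected
with the network.

``mann_whitney`` follows R's ``wilcox.test`` defaults — exact p-value
when both samples have fewer than 50 observations and there are no
ties, otherwise the normal approximation with tie correction and a
``sign(z)``-based continuity correction (so two identical samples give
exactly p = 1).  ``welch_t`` is the unequal-variance t-test with
Welch–Satterthwaite degrees of freedom.  All p-values are two-sided and
unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .network import InteractionNetwork

__all__ = [
    "AnnotationSet",
    "GroupComparison",
    "GroupAssignment",
    "load_drug_targets",
    "load_side_effect_pairs",
    "load_disease_genes",
    "derive_groups",
    "cumulative_distribution",
    "mann_whitney",
    "welch_t",
]


@dataclass(frozen=True)
class AnnotationSet:
    """Drug→target map, per-drug side-effect flags, disease gene sets.

    ``side_effect_flags`` must define a flag for every drug that has
    targets; :func:`derive_groups` refuses to guess.
    """

    drug_targets: Mapping[str, frozenset[str]]
    side_effect_flags: Mapping[str, bool]
    disease_genes: Mapping[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_tables(
        cls,
        drug_targets: Mapping[str, Iterable[str]],
        side_effect_pairs: Iterable[tuple[str, str]] = (),
        disease_genes: Mapping[str, Iterable[str]] | None = None,
    ) -> "AnnotationSet":
        """Assemble from raw tables.

        The side-effect flag of a drug is ``True`` iff it appears with
        at least one side-effect term; drugs absent from the adverse-
        event table are flagged ``False`` (no reported side effects).
        """
        flagged = {drug for drug, _term in side_effect_pairs}
        targets = {d: frozenset(t) for d, t in drug_targets.items()}
        flags = {d: d in flagged for d in targets}
        diseases = {
            name: frozenset(genes) for name, genes in (disease_genes or {}).items()
        }
        return cls(drug_targets=targets, side_effect_flags=flags,
                   disease_genes=diseases)

    def target_nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for targets in self.drug_targets.values():
            out |= targets
        return frozenset(out)


def _read_two_column_tsv(path: str | Path, comment: str = "#") -> list[tuple[str, str]]:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or (comment and line.lstrip().startswith(comment)):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: malformed row at line {lineno}: expected two columns"
                )
            rows.append((fields[0].strip(), fields[1].strip()))
    return rows


def load_drug_targets(path: str | Path) -> dict[str, frozenset[str]]:
    """Load a (drug_id, node_id) TSV into a drug→targets map."""
    table: dict[str, set[str]] = {}
    for drug, node in _read_two_column_tsv(path):
        table.setdefault(drug, set()).add(node)
    return {d: frozenset(t) for d, t in table.items()}


def load_side_effect_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Load a (drug_id, side_effect_term) TSV, duplicates removed."""
    seen = set()
    out = []
    for pair in _read_two_column_tsv(path):
        if pair not in seen:
            seen.add(pair)
            out.append(pair)
    return out


def load_disease_genes(path: str | Path) -> dict[str, frozenset[str]]:
    """Load a (disease_id, node_id) TSV into disease→gene-set map."""
    table: dict[str, set[str]] = {}
    for disease, node in _read_two_column_tsv(path):
        table.setdefault(disease, set()).add(node)
    return {d: frozenset(g) for d, g in table.items()}


class GroupAssignment(NamedTuple):
    groups: dict[str, frozenset[str]]
    disease_groups: dict[str, frozenset[str]]
    not_in_network: dict[str, frozenset[str]]


def derive_groups(net: InteractionNetwork, ann: AnnotationSet) -> GroupAssignment:
    """Partition network nodes by drug-target / side-effect status.

    Precedence: a node targeted by *any* side-effect drug belongs to
    ``targets_with_se`` even if other, side-effect-free drugs also
    target it; nodes targeted only by side-effect-free drugs form
    ``targets_without_se``; the rest are ``non_targets``.  The three
    sets partition the node set.

    Disease gene sets are intersected with the network; members outside
    it are reported in ``not_in_network`` (as are annotated drug
    targets absent from the network).
    """
    nodes = net.nodes
    with_se: set[str] = set()
    without_se: set[str] = set()
    missing_targets: set[str] = set()
    for drug, targets in ann.drug_targets.items():
        if drug not in ann.side_effect_flags:
            raise ValueError(f"drug {drug!r} has targets but no side-effect flag")
        flag = ann.side_effect_flags[drug]
        for t in targets:
            if t not in nodes:
                missing_targets.add(t)
            elif flag:
                with_se.add(t)
            else:
                without_se.add(t)
    without_se -= with_se
    non_targets = set(nodes) - with_se - without_se
    groups = {
        "targets_with_se": frozenset(with_se),
        "targets_without_se": frozenset(without_se),
        "non_targets": frozenset(non_targets),
    }
    disease_groups = {}
    not_in_network: dict[str, frozenset[str]] = {}
    if missing_targets:
        not_in_network["drug_targets"] = frozenset(missing_targets)
    for disease, genes in ann.disease_genes.items():
        disease_groups[disease] = frozenset(genes & nodes)
        outside = genes - nodes
        if outside:
            not_in_network[disease] = frozenset(outside)
    return GroupAssignment(groups, disease_groups, not_in_network)


def cumulative_distribution(values: Sequence[float]) -> list[tuple[float, float]]:
    """Empirical cumulative step function as (threshold, fraction) pairs.

    Thresholds are the sorted unique values; fractions are
    nondecreasing and end at exactly 1.0.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot form a cumulative distribution of no values")
    uniq, counts = np.unique(values, return_counts=True)
    fractions = np.cumsum(counts) / values.size
    fractions[-1] = 1.0
    return [(float(t), float(f)) for t, f in zip(uniq, fractions)]


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of a two-sample location test (p-values unadjusted)."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    test: str
    statistic: float
    p_value: float
    direction: str  # "a_greater", "b_greater" or "none"
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "direction": self.direction,
            "degenerate": self.degenerate,
        }


def _direction(num: float) -> str:
    if num > 0:
        return "a_greater"
    if num < 0:
        return "b_greater"
    return "none"


def mann_whitney(
    a: Sequence[float], b: Sequence[float], names: tuple[str, str] = ("a", "b")
) -> GroupComparison:
    """Two-sided Mann-Whitney (Wilcoxon rank-sum) test.

    Exact null distribution when both samples have n < 50 and the
    pooled data are tie-free; otherwise the normal approximation with
    tie correction and sign-aware continuity correction.  ``statistic``
    is the U of the first sample; ``direction`` reports which sample
    tends to larger values (sign of ``U - n_a n_b / 2``).
    """
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    num = u1 - n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if np.ptp(pooled) == 0:
        return GroupComparison(*names, n1, n2, "mann_whitney", u1, 1.0, "none",
                               degenerate=True)
    if n1 < 50 and n2 < 50 and not has_ties:
        p = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )
    else:
        n = n1 + n2
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
        sigma2 = (n1 * n2 / 12.0) * ((n + 1) - tie_term)
        if sigma2 <= 0:
            return GroupComparison(*names, n1, n2, "mann_whitney", u1, 1.0, "none",
                                   degenerate=True)
        correction = float(np.sign(num)) * 0.5
        z = (num - correction) / np.sqrt(sigma2)
        p = float(min(1.0, 2.0 * min(stats.norm.cdf(z), stats.norm.sf(z))))
    return GroupComparison(
        names[0], names[1], n1, n2, "mann_whitney", u1, p, _direction(num)
    )


def welch_t(
    a: Sequence[float], b: Sequence[float], names: tuple[str, str] = ("a", "b")
) -> GroupComparison:
    """Welch's unequal-variance two-sample t-test, two-sided."""
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least two observations per sample")
    diff = float(x.mean() - y.mean())
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        p = 1.0 if diff == 0 else 0.0
        return GroupComparison(*names, x.size, y.size, "welch_t",
                               0.0 if diff == 0 else np.inf * np.sign(diff),
                               p, _direction(diff), degenerate=True)
    res = stats.ttest_ind(x, y, equal_var=False)
    return GroupComparison(
        names[0], names[1], x.size, y.size, "welch_t",
        float(res.statistic), float(res.pvalue), _direction(diff),
    )
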
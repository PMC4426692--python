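import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_network

from vesselflow import (
    AnnotationSet,
    InteractionNetwork,
    cumulative_distribution,
    derive_groups,
    mann_whitney,
    welch_t,
)
from vesselflow.groups import load_drug_targets, load_side_effect_pairs


class TestDeriveGroups:
    def net(self):
        return InteractionNetwork.from_edges(
            [("A", "B"), ("B", "C"), ("C", "D")], nodes=["E"]
        )

    def test_se_precedence(self):
        ann = AnnotationSet.from_tables(
            {"d1": ["A"], "d2": ["A", "B"]}, side_effect_pairs=[("d1", "nausea")]
        )
        assignment = derive_groups(self.net(), ann)
        # A is hit by an SE drug and a non-SE drug: SE wins
        assert "A" in assignment.groups["targets_with_se"]
        assert assignment.groups["targets_without_se"] == {"B"}

    def test_untargeted_node_is_non_target(self):
        ann = AnnotationSet.from_tables({"d1": ["A"]}, [("d1", "rash")])
        assignment = derive_groups(self.net(), ann)
        assert "E" in assignment.groups["non_targets"]

    def test_partition_property(self):
        rng = np.random.default_rng(8)
        for seed in range(10):
            net = random_network(seed, 30, 0.1)
            nodes = net.sorted_nodes()
            drugs = {
                f"d{i}": rng.choice(nodes, size=rng.integers(1, 4), replace=False)
                for i in range(8)
            }
            pairs = [(f"d{i}", "term") for i in range(8) if rng.random() < 0.5]
            assignment = derive_groups(
                net, AnnotationSet.from_tables(drugs, pairs)
            )
            groups = list(assignment.groups.values())
            union = frozenset().union(*groups)
            assert union == net.nodes
            assert sum(len(g) for g in groups) == net.n_nodes

    def test_matches_enumeration_oracle(self):
        """10 drugs / 15 targets fixture: sizes equal a hand enumeration
        done with independent set logic."""
        rng = np.random.default_rng(77)
        nodes = [f"N{i:02d}" for i in range(15)]
        net = InteractionNetwork.from_edges([], nodes=nodes)
        drugs = {f"d{i}": set(rng.choice(nodes, size=2, replace=False))
                 for i in range(10)}
        se_drugs = {f"d{i}" for i in range(10) if i % 3 == 0}
        pairs = [(d, "t") for d in se_drugs]
        assignment = derive_groups(net, AnnotationSet.from_tables(drugs, pairs))
        # oracle: direct set algebra
        se_targets = set().union(*(drugs[d] for d in se_drugs))
        all_targets = set().union(*drugs.values())
        assert assignment.groups["targets_with_se"] == se_targets
        assert assignment.groups["targets_without_se"] == all_targets - se_targets
        assert len(assignment.groups["non_targets"]) == 15 - len(all_targets)

    def test_missing_flag_errors(self):
        ann = AnnotationSet(drug_targets={"d1": frozenset(["A"])},
                            side_effect_flags={})
        with pytest.raises(ValueError, match="d1"):
            derive_groups(self.net(), ann)

    def test_out_of_network_members_reported(self):
        ann = AnnotationSet.from_tables(
            {"d1": ["A", "GHOST"]}, [("d1", "t")],
            disease_genes={"dz": ["B", "PHANTOM"]},
        )
        assignment = derive_groups(self.net(), ann)
        assert assignment.not_in_network["drug_targets"] == {"GHOST"}
        assert assignment.not_in_network["dz"] == {"PHANTOM"}
        assert assignment.disease_groups["dz"] == {"B"}

    def test_loaders_roundtrip(self, tmp_path):
        (tmp_path / "dt.tsv").write_text("# h\nd1\tA\nd1\tB\nd2\tC\n")
        (tmp_path / "se.tsv").write_text("d1\tnausea\nd1\tnausea\nd1\trash\n")
        targets = load_drug_targets(tmp_path / "dt.tsv")
        pairs = load_side_effect_pairs(tmp_path / "se.tsv")
        assert targets == {"d1": frozenset("AB"), "d2": frozenset("C")}
        assert pairs == [("d1", "nausea"), ("d1", "rash")]  # deduplicated


class TestCumulativeDistribution:
    @pytest.mark.parametrize("values,expected", [
        ([5], [(5.0, 1.0)]),
        ([1, 1, 3], [(1.0, 2 / 3), (3.0, 1.0)]),
    ])
    def test_examples(self, values, expected):
        assert cumulative_distribution(values) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cumulative_distribution([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
    def test_monotone_and_ends_at_one(self, values):
        curve = cumulative_distribution(values)
        fractions = [f for _, f in curve]
        thresholds = [t for t, _ in curve]
        assert fractions == sorted(fractions)
        assert thresholds == sorted(set(thresholds))
        assert fractions[-1] == 1.0


class TestMannWhitney:
    def test_exact_small_sample(self):
        cmp = mann_whitney([1, 2], [3, 4])
        assert cmp.statistic == 0.0
        assert cmp.p_value == pytest.approx(1 / 3)
        assert cmp.direction == "b_greater"

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.normal(size=12)
            b = rng.normal(0.5, size=9)
            assert mann_whitney(a, b).p_value == pytest.approx(
                mann_whitney(b, a).p_value, rel=1e-12
            )

    def test_identical_samples_give_p_one(self):
        cmp = mann_whitney([1, 2, 3], [1, 2, 3])
        assert cmp.p_value == 1.0

    def test_constant_samples_flagged_degenerate(self):
        cmp = mann_whitney([2, 2, 2], [2, 2])
        assert cmp.degenerate
        assert cmp.p_value == 1.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_type_one_error_calibrated(self):
        """Two null Gaussian samples of n=50: rejection rate at 5% stays
        within binomial expectations over 1000 replicates."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            if mann_whitney(a, b).p_value < 0.05 :
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


class TestWelchT:
    def test_identical_samples(self):
        cmp = welch_t([1, 2, 3], [1, 2, 3])
        assert cmp.statistic == pytest.approx(0.0)
        assert cmp.p_value == pytest.approx(1.0)

    def test_separated_samples(self):
        assert welch_t([0, 0, 1, 1], [10, 10, 11, 11]).p_value < 1e-3

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1, 2, 3])

    def test_zero_variance_flagged(self):
        assert welch_t([3, 3], [3, 3]).degenerate

    def test_matches_textbook_formula(self):
        """Statistic and dof recomputed from first principles to 1e-10."""
        from scipy import stats

        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.normal(0, 1, size=rng.integers(5, 30))
            b = rng.normal(0.3, 2, size=rng.integers(5, 30))
            cmp = welch_t(a, b)
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t = (a.mean() - b.mean()) / np.sqrt(va + vb)
            dof = (va + vb) ** 2 / (
                va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
            )
            p = 2 * stats.t.sf(abs(t), dof)
            assert cmp.statistic == pytest.approx(t, abs=1e-10)
            assert cmp.p_value == pytest.approx(p, abs=1e-10)


class TestAgainstR:
    """The reference analyses used R's wilcox.test and t.test; cross-check
    a handful of fixtures against Rscript directly."""

    FIXTURES = [
        ([1.0, 2.0, 5.0, 7.0], [3.0, 4.0, 6.0, 10.0]),          # exact path
        ([1.0, 2.0, 2.0, 5.0], [2.0, 4.0, 6.0, 6.0]),           # ties
        (list(np.linspace(0, 60, 60)), list(np.linspace(1, 80, 70))),  # large n
    ]

    def test_wilcox_and_welch_match_r(self):
        lines = ["options(digits=15)"]
        for a, b in self.FIXTURES:
            av = "c(" + ",".join(map(str, a)) + ")"
            bv = "c(" + ",".join(map(str, b)) + ")"
            lines.append(f"cat(wilcox.test({av}, {bv})$p.value, '\\n')")
            lines.append(f"cat(t.test({av}, {bv})$p.value, '\\n')")
        out = subprocess.run(
            ["Rscript", "-e", "; ".join(lines)],
            capture_output=True, text=True, check=True,
        )
        values = [float(x) for x in out.stdout.split()]
        for i, (a, b) in enumerate(self.FIXTURES):
            r_wilcox, r_welch = values[2 * i], values[2 * i + 1]
            assert mann_whitney(a, b).p_value == pytest.approx(r_wilcox, rel=1e-6)
            assert welch_t(a, b).p_value == pytest.approx(r_welch, rel=1e-6)
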
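import numpy as np
import pytest

from conftest import adjacency_matrix, random_network
from oracles import dense_run

from vesselflow import (
    InteractionNetwork,
    PerturbationConfig,
    Simulator,
    initialize_energy,
    run_perturbation,
    silencing_profile,
    step,
)


def isolated(name="X"):
    return InteractionNetwork.from_edges([], nodes=[name])


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"start_energy": 0}, {"start_energy": -5}, {"dissipation": 0},
        {"silencing_threshold": -1}, {"flow_coefficient": 1.5},
    ])
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            PerturbationConfig(**kwargs)

    def test_default_flow_coefficient_is_stability_bound(self, star5):
        cfg = PerturbationConfig()
        assert cfg.resolve_flow_coefficient(star5) == pytest.approx(1 / 6)

    def test_flow_coefficient_above_bound_rejected(self, star5):
        with pytest.raises(ValueError, match="stability"):
            PerturbationConfig(flow_coefficient=0.5).resolve_flow_coefficient(star5)

    def test_default_max_steps_covers_slow_dissipation(self):
        assert PerturbationConfig().resolve_max_steps() == 10000
        # D < threshold: cap must still allow full drainage
        cfg = PerturbationConfig(start_energy=100, dissipation=0.01)
        assert cfg.resolve_max_steps() >= 100 / 0.01

    def test_from_file(self, tmp_path):
        path = tmp_path / "sim.cfg"
        path.write_text(
            "start_energy = 10000  # robustness grid\ndissipation=1\nmax_steps = 500\n"
        )
        cfg = PerturbationConfig.from_file(path)
        assert cfg.start_energy == 10000
        assert cfg.dissipation == 1
        assert cfg.max_steps == 500

    def test_from_file_rejects_unknown_key(self, tmp_path):
        path = tmp_path / "sim.cfg"
        path.write_text("start_energy = 10\nwhat = 3\n")
        with pytest.raises(ValueError, match="unknown"):
            PerturbationConfig.from_file(path)


class TestInitializeEnergy:
    @pytest.mark.parametrize("n_seeds,share", [(1, 1000.0), (2, 500.0), (4, 250.0)])
    def test_energy_split_equally(self, k4, n_seeds, share):
        seeds = k4.sorted_nodes()[:n_seeds]
        state = initialize_energy(k4, seeds, start_energy=1000)
        for node in k4.sorted_nodes():
            expected = share if node in seeds else 0.0
            assert state.energy_of(node) == expected
        assert state.total_energy() == pytest.approx(1000)
        assert state.step == 0

    def test_unknown_seed_named_in_error(self, path3):
        with pytest.raises(KeyError, match="ghost"):
            initialize_energy(path3, ["ghost"])

    def test_empty_seed_set_errors(self, path3):
        with pytest.raises(ValueError):
            initialize_energy(path3, [])

    def test_reached_flag_set_for_qualifying_seeds(self, k4):
        state = initialize_energy(k4, k4.sorted_nodes(), start_energy=2.0)
        # shares of 0.5 are below the threshold of 1: nothing reached yet
        assert state.reached.sum() == 0
        state2 = initialize_energy(k4, ["a"], start_energy=1000)
        assert state2.reached.sum() == 1


class TestStep:
    def test_isolated_node_dissipates_only(self):
        net = isolated()
        state = initialize_energy(net, ["X"], start_energy=1000)
        nxt = step(state, net, PerturbationConfig())
        assert nxt.energy_of("X") == pytest.approx(995.0)
        assert nxt.step == 1

    def test_two_node_flow_then_dissipation(self):
        net = InteractionNetwork.from_edges([("u", "v")])
        cfg = PerturbationConfig(flow_coefficient=0.25)
        state = initialize_energy(net, ["u"], start_energy=100)
        nxt = step(state, net, cfg)
        # flow: u 100 -> 75, v 0 -> 25; dissipation of 5 each
        assert nxt.energy_of("u") == pytest.approx(70.0)
        assert nxt.energy_of("v") == pytest.approx(20.0)
        assert bool(nxt.reached[list(nxt.nodes).index("v")])

    def test_matches_dense_oracle_stepwise(self):
        """Sparse simulator equals dense (I - kL) algebra at every step."""
        for seed in range(20):
            net = random_network(seed, 10, 0.35)
            adjacency, nodes = adjacency_matrix(net)
            cfg = PerturbationConfig()
            sim = Simulator(net, cfg)
            e0 = np.zeros(len(nodes))
            e0[seed % len(nodes)] = cfg.start_energy
            _, _, states, _ = dense_run(
                adjacency, e0, sim.k, cfg.dissipation, max_steps=5
            )
            state = initialize_energy(net, [nodes[seed % len(nodes)]],
                                      cfg.start_energy)
            for expected in states[1:6]:
                state = step(state, net, cfg)
                np.testing.assert_allclose(state.energy, expected, rtol=1e-9,
                                           atol=1e-9 * cfg.start_energy)


class TestRunPerturbation:
    @pytest.mark.parametrize("energy,dissipation,expected", [
        (1000, 5, 200),     # 1000 - 5t < 1 first at t = 200
        (10000, 1, 10000),
    ])
    def test_isolated_node_closed_form(self, energy, dissipation, expected):
        res = run_perturbation(
            isolated(), ["X"],
            PerturbationConfig(start_energy=energy, dissipation=dissipation),
        )
        assert res.silencing_time == expected
        assert res.perturbation_reach == 1
        assert not res.terminated_by_cap

    def test_path_graph_matches_dense_oracle(self, path3):
        cfg = PerturbationConfig(flow_coefficient=1 / 3)
        adjacency, nodes = adjacency_matrix(path3)
        e0 = np.zeros(3)
        e0[nodes.index("A")] = 1000.0
        silencing, reach, _, _ = dense_run(adjacency, e0, 1 / 3, 5.0)
        res = run_perturbation(path3, ["A"], cfg)
        assert res.silencing_time == silencing
        assert res.perturbation_reach == reach

    def test_already_silent_network(self, path3):
        res = run_perturbation(
            path3, ["A"], PerturbationConfig(start_energy=0.5, dissipation=5)
        )
        assert res.silencing_time == 0
        assert res.perturbation_reach == 0

    def test_step_cap_is_flagged(self):
        res = run_perturbation(
            isolated(), ["X"], PerturbationConfig(max_steps=3)
        )
        assert res.terminated_by_cap
        assert res.silencing_time == 3

    def test_empty_seed_set_errors(self, path3):
        with pytest.raises(ValueError):
            run_perturbation(path3, [])


class TestInvariants:
    """Conservation, positivity, monotonicity and termination bounds."""

    def fixture_nets(self):
        return [random_network(seed, n, p)
                for seed, (n, p) in enumerate([(8, 0.4), (12, 0.3), (15, 0.2),
                                               (20, 0.15), (20, 0.4)])]

    def test_flow_conserves_total_energy(self):
        for net in self.fixture_nets():
            sim = Simulator(net, PerturbationConfig())
            rng = np.random.default_rng(0)
            for _ in range(5):
                e = rng.uniform(0, 500, size=net.n_nodes)
                flowed = sim._flow(e)
                assert flowed.sum() == pytest.approx(e.sum(), rel=1e-9)
                assert (flowed >= -1e-12).all()

    def test_dissipation_bookkeeping(self):
        cfg = PerturbationConfig()
        for net in self.fixture_nets():
            sim = Simulator(net, cfg)
            rng = np.random.default_rng(1)
            e = rng.uniform(0, 50, size=net.n_nodes)
            flowed = sim._flow(e)
            after = sim._dissipate(flowed)
            removed = flowed.sum() - after.sum()
            expected = np.minimum(flowed, cfg.dissipation).sum()
            assert removed == pytest.approx(expected, rel=1e-9)
            assert (after >= 0).all()

    def test_total_energy_strictly_decreases(self):
        for net in self.fixture_nets():
            seed_node = net.sorted_nodes()[0]
            res = run_perturbation(net, [seed_node], record_trajectory=True)
            traj = np.array(res.trajectory)
            positive = traj[traj > 0]
            assert (np.diff(positive) < 0).all()

    def test_silencing_time_bounded_by_energy(self):
        """With D >= threshold, silencing_time <= E / threshold."""
        cfg = PerturbationConfig()
        for net in self.fixture_nets():
            for seed_node in net.sorted_nodes()[:3]:
                res = run_perturbation(net, [seed_node], cfg)
                assert res.silencing_time <= cfg.start_energy
                assert 0 <= res.perturbation_reach <= net.n_nodes

    def test_reach_includes_seed_when_share_qualifies(self):
        for net in self.fixture_nets():
            res = run_perturbation(net, [net.sorted_nodes()[0]])
            assert res.perturbation_reach >= 1


class TestSilencingProfile:
    def test_vertex_transitive_graphs_give_equal_results(self, cycle5, k4):
        for net in (cycle5, k4):
            profile = silencing_profile(net)
            assert profile["silencing_time"].nunique() == 1
            assert profile["perturbation_reach"].nunique() == 1

    def test_deterministic_across_reruns(self):
        net = random_network(11, 50, 0.1)
        a = silencing_profile(net)
        b = silencing_profile(net)
        assert a.equals(b)

    def test_probe_subset_and_order(self):
        net = random_network(12, 20, 0.2)
        probes = net.sorted_nodes()[5:10]
        profile = silencing_profile(net, probes=probes)
        assert list(profile.index) == probes

    def test_multi_target_seed_sets(self, k4):
        cfg = PerturbationConfig()
        profile = silencing_profile(
            k4, cfg=cfg, seed_sets={"drugA": ["a", "b"], "drugB": ["c"]}
        )
        assert set(profile.index) == {"drugA", "drugB"}
        single = run_perturbation(k4, ["c"], cfg)
        assert profile.loc["drugB", "silencing_time"] == single.silencing_time

    def test_unknown_probe_raises_with_id(self):
        net = random_network(13, 10, 0.3)
        with pytest.raises(RuntimeError, match="nope"):
            silencing_profile(net, probes=["nope"])
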
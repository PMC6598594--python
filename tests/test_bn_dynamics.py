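"""Constrained-asynchronous update scheme and attractor search."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenoflow import synthetic
from phenoflow.bn_dynamics import (
    attractor_campaign,
    compile_network,
    enumerate_fixed_points,
    perturb_state,
    random_initial_state,
    run_to_attractor,
    state_to_bits,
    sweep,
    update_node,
)
from phenoflow.network import AND, MAJ, BooleanNetwork

from oracles import ref_fixed_points, ref_node_update


def _net(edges, rules=None):
    net = BooleanNetwork()
    nodes = sorted({x for e in edges for x in e[:2]})
    for n in nodes:
        net.add_node(n, (rules or {}).get(n, MAJ))
    for s, d, sign in edges:
        net.add_edge(s, d, sign)
    net.validate()
    return net


class TestUpdateNode:
    def test_maj_strict_majority_activates(self):
        net = _net([("a", "x", 1), ("b", "x", 1), ("c", "x", -1)])
        state = {"a": 1, "b": 1, "c": 1, "x": 0}
        assert update_node(net, state, "x") == 1  # delta = +1

    def test_and_requires_all_inputs(self, and_net):
        state = {"A": 1, "B": 0, "C": 1, "D": 0}
        assert update_node(and_net, state, "C") == 0
        state["B"] = 1
        assert update_node(and_net, state, "C") == 1

    def test_maj_tie_holds_current_value(self):
        net = _net([("a", "x", 1), ("b", "x", -1)])
        assert update_node(net, {"a": 1, "b": 1, "x": 1}, "x") == 1
        assert update_node(net, {"a": 1, "b": 1, "x": 0}, "x") == 0

    def test_off_inhibitor_exerts_no_repression(self):
        net = _net([("a", "x", 1), ("b", "x", -1)])
        assert update_node(net, {"a": 1, "b": 0, "x": 0}, "x") == 1

    def test_input_free_node_holds(self, path_net):
        assert update_node(path_net, {"A": 1, "B": 0, "C": 0, "D": 0}, "A") == 1
        assert update_node(path_net, {"A": 0, "B": 0, "C": 0, "D": 1}, "D") == 1

    def test_agrees_with_naive_oracle_on_random_states(self, rng):
        net = synthetic.random_boolean_network(
            synthetic.FixtureSpec(n_nodes=10, edge_density=0.25, seed=6)
        )
        cn = compile_network(net)
        for _ in range(50):
            arr = rng.integers(0, 2, size=10).astype(np.uint8)
            values = cn.state_to_dict(arr)
            node = cn.nodes[rng.integers(10)]
            assert update_node(net, values, node) == ref_node_update(net, values, node)


class TestSweep:
    def test_fixed_point_unchanged_for_any_order(self, mutual_activation, rng):
        cn = compile_network(mutual_activation)
        s = np.array([1, 1], dtype=np.uint8)
        for _ in range(10):
            assert np.array_equal(sweep(cn, s, rng), s)

    def test_every_node_updated_with_latest_values(self, rng):
        # chain a->b->c from (1,0,0): a sequential sweep can propagate more
        # than one step when the order happens to follow the chain
        net = _net([("a", "b", 1), ("b", "c", 1)])
        cn = compile_network(net)
        results = set()
        for _ in range(50):
            out = sweep(cn, np.array([1, 0, 0], dtype=np.uint8), rng)
            results.add(state_to_bits(out))
        assert results == {"110", "111"}

    def test_seed_determinism(self, rng):
        net = synthetic.random_boolean_network(
            synthetic.FixtureSpec(n_nodes=12, edge_density=0.2, seed=8)
        )
        s0 = random_initial_state(net, 0.5, np.random.default_rng(0))
        a = sweep(net, s0, np.random.default_rng(42))
        b = sweep(net, s0, np.random.default_rng(42))
        assert np.array_equal(a, b)


class TestRunToAttractor:
    def test_fixed_init_converges_at_iteration_one(self, mutual_activation, rng):
        res = run_to_attractor(mutual_activation, np.array([0, 0], np.uint8), 100, rng)
        assert res.converged and res.iterations == 1

    def test_negative_feedback_two_nodes_oracle(self):
        # A activates B, B inhibits A, tie-hold: enumerate all 4 states x orders
        # OFF states are stable: an inactive activator gives no signal, and
        # ties hold, so (A=0,B=0) and (A=0,B=1) are the fixed points
        net = _net([("A", "B", 1), ("B", "A", -1)])
        oracle_fps = ref_fixed_points(net)
        assert oracle_fps == {(0, 0), (0, 1)}
        rng = np.random.default_rng(0)
        for bits in itertools.product([0, 1], repeat=2):
            res = run_to_attractor(net, np.array(bits, np.uint8), 200, rng)
            if res.converged:
                assert tuple(res.end_state) in oracle_fps

    def test_converged_end_states_are_oracle_fixed_points(self):
        rng = np.random.default_rng(17)
        for seed in range(10):
            net = synthetic.random_boolean_network(
                synthetic.FixtureSpec(n_nodes=10, edge_density=0.25,
                                      inhibition_fraction=0.3, seed=seed)
            )
            fps = ref_fixed_points(net)
            for _ in range(10):
                init = random_initial_state(net, rng.random(), rng)
                res = run_to_attractor(net, init, 200, rng)
                if res.converged:
                    assert tuple(int(v) for v in res.end_state) in fps

    def test_converged_state_is_nodewise_stable(self, rng):
        net = synthetic.random_boolean_network(
            synthetic.FixtureSpec(n_nodes=12, edge_density=0.2, seed=21)
        )
        cn = compile_network(net)
        init = random_initial_state(cn, 0.4, rng)
        res = run_to_attractor(cn, init, 500, rng)
        if res.converged:
            for i in range(cn.n_nodes):
                assert cn.update_value(res.end_state, i) == res.end_state[i]


class TestRandomStateAndPerturb:
    def test_extremes(self, rng, path_net):
        assert random_initial_state(path_net, 0.0, rng).sum() == 0
        assert random_initial_state(path_net, 1.0, rng).sum() == 4

    def test_activation_fraction_within_binomial_bound(self, rng):
        net = synthetic.random_boolean_network(
            synthetic.FixtureSpec(n_nodes=10_000, edge_density=0.0, seed=0)
        )
        frac = random_initial_state(net, 0.5, rng).mean()
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(10_000)

    def test_perturb_extremes_and_mean(self, rng):
        s = rng.integers(0, 2, size=700).astype(np.uint8)
        assert np.array_equal(perturb_state(s, 0.0, rng), s)
        assert np.array_equal(perturb_state(s, 1.0, rng), 1 - s)
        flips = [
            int((perturb_state(s, 0.05, rng) != s).sum()) for _ in range(200)
        ]
        assert np.mean(flips) == pytest.approx(35, rel=0.15)


class TestAttractorCampaign:
    def test_single_global_fixed_point(self, rng, path_net):
        # all updates are pure propagation; every run converges
        res = attractor_campaign(path_net, 100, max_iter=100, rng=rng)
        assert sum(c for _, c in res.attractors) == res.n_converged <= res.n_sims

    def test_two_basin_toy_recovers_both_loops(self, rng):
        net, fps = synthetic.planted_attractor_network(2, seed=0)
        res = attractor_campaign(net, 50 * 2**6, max_iter=100, rng=rng)
        found = {state_to_bits(s) for s, _ in res.attractors}
        assert found == {state_to_bits(f) for f in fps}

    def test_campaign_attractors_are_exhaustive_fixed_points(self, rng):
        net = synthetic.random_boolean_network(
            synthetic.FixtureSpec(n_nodes=11, edge_density=0.2, seed=33)
        )
        oracle = ref_fixed_points(net)
        res = attractor_campaign(net, 300, max_iter=200, rng=rng)
        for s, _ in res.attractors:
            assert tuple(int(v) for v in s) in oracle

    def test_seed_determinism(self):
        net, _ = synthetic.planted_attractor_network(2, seed=0)
        a = attractor_campaign(net, 500, max_iter=50, rng=np.random.default_rng(5))
        b = attractor_campaign(net, 500, max_iter=50, rng=np.random.default_rng(5))
        assert [(state_to_bits(s), c) for s, c in a.attractors] == [
            (state_to_bits(s), c) for s, c in b.attractors
        ]


class TestEnumerateFixedPoints:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_naive_oracle(self, seed):
        net = synthetic.random_boolean_network(
            synthetic.FixtureSpec(n_nodes=8, edge_density=0.25,
                                  inhibition_fraction=0.3, seed=seed)
        )
        ours = {tuple(int(v) for v in s) for s in enumerate_fixed_points(net)}
        assert ours == ref_fixed_points(net)
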
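"""Stochastic engine semantics, closed forms, and the exact oracle."""

import numpy as np
import pytest

from erbbsim.engine import (EngineError, EnvironmentSpec, SimulationConfig,
                            draw_levels, exact_activity, simulate,
                            simulate_replicate)
from erbbsim.logic import And, LogicalNetwork, Not, Or, UnknownNodeError, Var
from erbbsim.synth import chain_fixture


def _net(rules, externals, nodes=None):
    nodes = nodes or (list(externals) + list(rules))
    return LogicalNetwork(tuple(nodes), frozenset(externals), rules)


IDENT = _net({"Y": Var("A")}, ["A"])
NOTNET = _net({"Y": Not(Var("A"))}, ["A"])
ANDNET = _net({"Y": And((Var("A"), Var("B")))}, ["A", "B"])
ORNET = _net({"Y": Or((Var("A"), Var("B")))}, ["A", "B"])


# -- environment and level drawing ----------------------------------------

def test_environment_spec_validation():
    with pytest.raises(EngineError):
        EnvironmentSpec({"A": (50, 20)})
    with pytest.raises(EngineError):
        EnvironmentSpec({"A": (-1, 5)})
    env = EnvironmentSpec({"A": 50, "B": (0, 5)})
    assert env["A"] == (50.0, 50.0)
    assert env.bounds("missing") == (0.0, 0.0)


def test_draw_levels_degenerate_uniform_and_default():
    rng = np.random.default_rng(0)
    assert draw_levels(EnvironmentSpec({"EGF": 50}), rng) == {"EGF": 50.0}
    draws = [draw_levels(EnvironmentSpec({"EGF": (0, 5)}), rng)["EGF"]
             for _ in range(10_000)]
    # uniform[0,5]: mean 2.5, sd 5/sqrt(12)
    se = (5 / np.sqrt(12)) / np.sqrt(10_000)
    assert abs(np.mean(draws) - 2.5) <= 3 * se
    assert all(0 <= d <= 5 for d in draws)
    # a declared external absent from the spec is OFF
    assert draw_levels(EnvironmentSpec({}), rng, ["EGF"]) == {"EGF": 0.0}


# -- closed-form simulation checks ----------------------------------------

def test_constant_input_passes_through():
    cfg = SimulationConfig(transient_steps=5, window_steps=50, replicates=3)
    rec = simulate(IDENT, {"A": 100}, None, cfg)
    assert rec.mean["Y"] == 100.0 and rec.sem["Y"] == 0.0


def test_not_gate_complements_bernoulli_rate():
    cfg = SimulationConfig(window_steps=10_000, replicates=1, seed=3)
    rec = simulate(NOTNET, {"A": 30}, None, cfg)
    se = np.sqrt(0.3 * 0.7 / 10_000) * 100
    assert abs(rec.mean["Y"] - 70.0) <= 3 * se


def test_and_gate_multiplies_independent_rates():
    cfg = SimulationConfig(window_steps=10_000, replicates=1, seed=4)
    rec = simulate(ANDNET, {"A": 50, "B": 50}, None, cfg)
    se = np.sqrt(0.25 * 0.75 / 10_000) * 100
    assert abs(rec.mean["Y"] - 25.0) <= 3 * se


def test_identity_net_mean_over_replicates():
    rec = simulate(IDENT, {"A": 50}, None,
                   SimulationConfig(replicates=300, seed=5))
    assert 47.0 <= rec.mean["Y"] <= 53.0
    assert rec.sem["Y"] > 0


def test_locked_nodes_have_zero_variance():
    cfg = SimulationConfig(replicates=5, seed=0)
    rec = simulate(ORNET, {"A": 50, "B": 50}, {"Y": 0, "A": 1}, cfg)
    assert rec.mean["Y"] == 0.0 and rec.sem["Y"] == 0.0
    assert rec.mean["A"] == 100.0 and rec.sem["A"] == 0.0


def test_mutation_on_unknown_node_rejected():
    with pytest.raises(UnknownNodeError):
        simulate(IDENT, {"A": 50}, {"Zzz": 1}, SimulationConfig(replicates=2))


def test_determinism_identical_seed_identical_output():
    cfg = SimulationConfig(replicates=10, seed=42)
    r1 = simulate(ANDNET, {"A": (20, 80), "B": 50}, None, cfg)
    r2 = simulate(ANDNET, {"A": (20, 80), "B": 50}, None, cfg)
    assert np.array_equal(r1.per_replicate, r2.per_replicate)
    assert np.array_equal(r1.levels, r2.levels)


def test_replicate_streams_independent_of_batch_order():
    cfg_a = SimulationConfig(replicates=3, seed=9)
    cfg_b = SimulationConfig(replicates=7, seed=9)
    r3 = simulate(IDENT, {"A": (0, 100)}, None, cfg_a)
    r7 = simulate(IDENT, {"A": (0, 100)}, None, cfg_b)
    assert np.array_equal(r3.per_replicate, r7.per_replicate[:3])


def test_monotone_pass_through_with_common_random_numbers():
    means = []
    for level in range(0, 101, 10):
        rec = simulate(IDENT, {"A": level}, None,
                       SimulationConfig(window_steps=400, replicates=4, seed=7))
        means.append(rec.mean["Y"])
    assert all(b >= a for a, b in zip(means, means[1:]))
    assert means[0] == 0.0 and means[-1] == 100.0


def test_zero_internal_network_records_externals_only():
    net = LogicalNetwork(("A",), frozenset({"A"}), {})
    rec = simulate(net, {"A": 100}, None, SimulationConfig(replicates=2))
    assert rec.mean["A"] == 100.0


def test_simulate_replicate_reproducible_with_seeded_rng():
    out1 = simulate_replicate(ANDNET, {"A": (20, 80), "B": 50}, None,
                              SimulationConfig(), np.random.default_rng(11))
    out2 = simulate_replicate(ANDNET, {"A": (20, 80), "B": 50}, None,
                              SimulationConfig(), np.random.default_rng(11))
    assert out1 == out2
    assert 0.0 <= out1["Y"] <= 100.0


def test_percentages_bounded(hmec_net):
    rec = simulate(hmec_net, {"EGF": (0, 100), "ECM": (0, 100),
                              "EGFR_Contr": 100}, None,
                   SimulationConfig(replicates=20, seed=1))
    for n in hmec_net.nodes:
        assert 0.0 <= rec.mean[n] <= 100.0
        assert rec.sem[n] >= 0.0


# -- exact oracle ----------------------------------------------------------

def test_exact_pass_through_and_product():
    assert exact_activity(IDENT, {"A": 50})["Y"] == pytest.approx(50.0)
    assert exact_activity(ANDNET, {"A": 50, "B": 50})["Y"] == pytest.approx(25.0)
    assert exact_activity(ORNET, {"A": 50, "B": 50})["Y"] == pytest.approx(75.0)


def test_exact_three_step_chain_with_blocking():
    # B=A, C=B, Y=C AND NOT B: with A always ON the chain saturates and
    # Y = 1 AND NOT 1 = 0 at every post-transient step.
    net = _net({"B": Var("A_ext"), "C": Var("B"),
                "Y": And((Var("C"), Not(Var("B"))))}, ["A_ext"])
    res = exact_activity(net, {"A_ext": 100})
    assert res["Y"] == pytest.approx(0.0)
    assert res["B"] == pytest.approx(100.0)


def test_exact_respects_mutations():
    res = exact_activity(ANDNET, {"A": 50, "B": 50}, {"A": 1})
    assert res["A"] == 100.0
    assert res["Y"] == pytest.approx(50.0)


def test_exact_size_guard():
    big = chain_fixture(17)
    with pytest.raises(EngineError, match="oracle"):
        exact_activity(big, {"A": 50})


def test_simulate_agrees_with_exact_on_chain():
    net = chain_fixture(4, negate_every=2)
    cfg = SimulationConfig(window_steps=4000, replicates=12, seed=21)
    rec = simulate(net, {"A": 40}, None, cfg)
    ex = exact_activity(net, {"A": 40}, None, cfg)
    for n in net.internals:
        assert abs(rec.mean[n] - ex[n]) <= 4 * max(rec.sem[n], 1e-6)
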
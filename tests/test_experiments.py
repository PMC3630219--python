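"""Dose-response sweeps, mutation comparisons, t statistics and the
scenario library."""

import numpy as np
import pytest
from scipy import stats

from erbbsim.engine import EngineError, EnvironmentSpec, SimulationConfig
from erbbsim.experiments import (Scenario, dose_response, mutation_compare,
                                 scenario_library, student_t)
from erbbsim.io import scenario_from_dict, scenario_to_dict
from erbbsim.logic import LogicalNetwork, Not, Var


IDENT = LogicalNetwork(("A", "Y"), frozenset({"A"}), {"Y": Var("A")})
NOTNET = LogicalNetwork(("A", "Y"), frozenset({"A"}), {"Y": Not(Var("A"))})


def _scenario(env, **kw):
    return Scenario(name=kw.pop("name", "test"),
                    env=EnvironmentSpec(env), **kw)


# -- Student's t -----------------------------------------------------------

def test_student_t_matches_hand_computed_pooled_test():
    # means 12 vs 22, both sample variances 4, pooled SE sqrt(8/3):
    # t = -10 / 1.63299 = -6.12372, df = 4, two-sided p ~ 0.00356
    t, p = student_t((10, 12, 14), (20, 22, 24))
    assert t == pytest.approx(-6.123724, rel=1e-6)
    assert p == pytest.approx(0.003602, rel=1e-3)


def test_student_t_agrees_with_scipy_reference():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1.3, 25)
    t, p = student_t(a, b)
    ref = stats.ttest_ind(a, b, equal_var=True)
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_student_t_degenerate_paths():
    assert student_t((1, 2, 3), (1, 2, 3)) == (0.0, 1.0)  # identical samples
    t, p = student_t((0, 0), (1, 1))       # zero variance, unequal means
    assert np.isinf(t) and t < 0 and p == 0.0
    assert student_t((5, 5), (5, 5)) == (0.0, 1.0)
    with pytest.raises(ValueError):
        student_t((1,), (1, 2))


def test_student_t_label_swap_flips_sign_only():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
    t1, p1 = student_t(a, b)
    t2, p2 = student_t(b, a)
    assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


# -- dose response ---------------------------------------------------------

def test_dose_response_identity_recovers_diagonal():
    scen = _scenario({"A": (0, 100)}, sweep="A", outputs=("Y",))
    res = dose_response(IDENT, scen, n_runs=800, n_bins=8,
                        config=SimulationConfig(window_steps=400, seed=6))
    means, sems = res.series["Y"]
    assert res.counts.sum() == 800
    for c, m, s in zip(res.centers, means, sems):
        assert abs(m - c) <= 3 * s


def test_dose_response_not_gate_recovers_complement():
    scen = _scenario({"A": (0, 100)}, sweep="A", outputs=("Y",))
    res = dose_response(NOTNET, scen, n_runs=800, n_bins=8,
                        config=SimulationConfig(window_steps=400, seed=8))
    means, sems = res.series["Y"]
    for c, m, s in zip(res.centers, means, sems):
        assert abs(m - (100 - c)) <= 3 * s


def test_dose_response_rejects_bad_sweep():
    with pytest.raises(EngineError, match="external"):
        dose_response(IDENT, _scenario({"A": (0, 100)}), "Y", n_runs=10)
    with pytest.raises(EngineError, match="empty"):
        dose_response(IDENT, _scenario({"A": 50}), "A", n_runs=10)


# -- mutation comparison ---------------------------------------------------

def test_empty_mutation_with_shared_streams_is_exactly_null():
    scen = _scenario({"A": (20, 80)}, outputs=("Y",))
    res = mutation_compare(IDENT, scen, {}, n=20, paired=True,
                           config=SimulationConfig(window_steps=200, seed=1))
    row = res.rows["Y"]
    assert row.t == 0.0 and row.p == 1.0
    assert row.baseline_mean == row.perturbed_mean


def test_mutation_compare_detects_forced_activation():
    scen = _scenario({"A": 10}, outputs=("Y",))
    res = mutation_compare(IDENT, scen, {"Y": 1}, n=30,
                           config=SimulationConfig(window_steps=400, seed=2))
    row = res.rows["Y"]
    assert row.perturbed_mean == 100.0
    assert row.t > 0 and row.p < 1e-6


def test_mutation_compare_degenerate_zero_variance_flagged():
    # both arms constant but different: locked OFF baseline via scenario,
    # locked ON perturbation
    scen = _scenario({"A": 100}, outputs=("Y",), mutations={"Y": 0})
    res = mutation_compare(IDENT, scen, {"Y": 1}, n=5,
                           config=SimulationConfig(window_steps=100, seed=3))
    row = res.rows["Y"]
    assert row.p == 0.0 and row.degenerate


def test_mutation_compare_requires_two_replicates():
    with pytest.raises(EngineError):
        mutation_compare(IDENT, _scenario({"A": 50}, outputs=("Y",)),
                         {"Y": 1}, n=1)


# -- scenario library ------------------------------------------------------

# Independent transcription of the published external-condition table
# (%ON intervals; scalars are degenerate intervals; unused stimuli are 0).
EXPECTED_CONDITIONS = {
    "fig2a": dict(alpha_1213L=(40, 60), alpha_iL=(0, 10), alpha_qL=(0, 10),
                  alpha_sL=(40, 60), ECM=(0, 100), EGF=(0, 100),
                  EGFR_Contr=100, ErbB2_Contr=0, ErbB2Deg_Contr=0,
                  ErbB3_Contr=0, ExtPump=(40, 60), IL1_TNF=2, Stress=2),
    "fig2b": dict(alpha_1213L=72, alpha_iL=11, alpha_qL=37, alpha_sL=48,
                  ECM=88, EGF=(0, 100), EGFR_Contr=100, ErbB2_Contr=0,
                  ErbB2Deg_Contr=0, ErbB3_Contr=0, ExtPump=12,
                  IL1_TNF=2, Stress=2),
    "fig2c": dict(alpha_1213L=72, alpha_iL=11, alpha_qL=37, alpha_sL=48,
                  ECM=88, EGF=(0, 100), EGFR_Contr=100, ErbB2_Contr=0,
                  ErbB2Deg_Contr=0, ErbB3_Contr=0, ExtPump=12,
                  IL1_TNF=2, Stress=2),
    "fig2d": dict(alpha_1213L=(60, 70), alpha_iL=(70, 80), alpha_qL=(10, 20),
                  alpha_sL=(10, 20), ECM=(0, 100), EGF=0, EGFR_Contr=100,
                  ErbB2_Contr=0, ErbB2Deg_Contr=0, ErbB3_Contr=0,
                  ExtPump=(1, 10), IL1_TNF=2, Stress=2),
    "fig2e": dict(alpha_1213L=(5, 65), alpha_iL=(30, 80), alpha_qL=(50, 100),
                  alpha_sL=(55, 95), ECM=(0, 100), EGF=(0, 100),
                  EGFR_Contr=100, ErbB2_Contr=0, ErbB2Deg_Contr=0,
                  ErbB3_Contr=0, ExtPump=(80, 100), IL1_TNF=2, Stress=2),
    "fig2f": dict(alpha_1213L=(70, 80), alpha_iL=(40, 50), alpha_qL=(90, 100),
                  alpha_sL=(50, 60), ECM=(0, 100), EGF=(1, 10),
                  EGFR_Contr=100, ErbB2_Contr=0, ErbB2Deg_Contr=0,
                  ErbB3_Contr=0, ExtPump=(90, 100), IL1_TNF=2, Stress=2),
    "fig2g": dict(alpha_1213L=36, alpha_iL=69, alpha_qL=77, alpha_sL=(0, 100),
                  ECM=99, EGF=10, EGFR_Contr=100, ErbB2_Contr=0,
                  ErbB2Deg_Contr=0, ErbB3_Contr=0, ExtPump=94,
                  IL1_TNF=2, Stress=2),
    "fig2h": dict(alpha_1213L=26, alpha_iL=97, alpha_qL=4, alpha_sL=55,
                  ECM=94, EGF=(90, 100), EGFR_Contr=(90, 100), ErbB2_Contr=0,
                  ErbB2Deg_Contr=0, ErbB3_Contr=0, ExtPump=76,
                  IL1_TNF=2, Stress=2),
    "fig3a": dict(alpha_1213L=(20, 30), alpha_iL=90, alpha_qL=1, alpha_sL=50,
                  ECM=90, EGF=(0, 5), EGFR_Contr=100, ErbB2_Contr=0,
                  ErbB2Deg_Contr=0, ErbB3_Contr=0, ExtPump=(70, 80),
                  IL1_TNF=2, Stress=2),
    "fig3b": dict(alpha_1213L=(20, 30), alpha_iL=100, alpha_qL=5, alpha_sL=60,
                  ECM=100, EGF=(60, 70), EGFR_Contr=100, ErbB2_Contr=0,
                  ErbB2Deg_Contr=0, ErbB3_Contr=0, ExtPump=(70, 80),
                  IL1_TNF=2, Stress=2),
}


def _as_interval(v):
    return (float(v), float(v)) if isinstance(v, (int, float)) else \
        (float(v[0]), float(v[1]))


def test_scenario_library_matches_published_conditions(library):
    assert set(library) == set(EXPECTED_CONDITIONS)
    for name, expected in EXPECTED_CONDITIONS.items():
        env = library[name].env
        assert set(env) == set(expected), name
        for node, v in expected.items():
            assert env[node] == _as_interval(v), (name, node)


def test_scenario_library_spot_values(library):
    assert library["fig3a"].env["EGF"] == (0.0, 5.0)
    assert library["fig3b"].env["EGF"] == (60.0, 70.0)
    assert library["fig2g"].env["alpha_sL"] == (0.0, 100.0)
    # unused stimuli default OFF
    assert library["fig3a"].env.bounds("TGFa") == (0.0, 0.0)


def test_fig2h_expression_variants(library):
    scen = library["fig2h"]
    assert set(scen.variants) == {"egfr_only", "plus_erbb2",
                                  "plus_erbb2_erbb3"}
    e2 = scen.environment("plus_erbb2")
    assert e2["ErbB2_Contr"] == (90.0, 100.0)
    assert e2["ErbB2Deg_Contr"] == (25.0, 35.0)
    assert e2.bounds("ErbB3_Contr") == (0.0, 0.0)
    e3 = scen.environment("plus_erbb2_erbb3")
    assert e3["ErbB3_Contr"] == (90.0, 100.0)
    with pytest.raises(EngineError):
        scen.environment("nope")


def test_fig2c_carries_ras_activation(library):
    assert library["fig2c"].mutations == {"Ras": 1}
    assert library["fig2c"].sweep == "EGF"


def test_scenario_round_trips_through_dict(library):
    for name in ("fig2h", "fig3a"):
        scen = library[name]
        back = scenario_from_dict(scenario_to_dict(scen))
        assert back.name == scen.name
        assert dict(back.env) == dict(scen.env)
        assert back.outputs == scen.outputs
        assert {k: dict(v) for k, v in back.variants.items()} == \
               {k: dict(v) for k, v in scen.variants.items()}
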
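"""Dynamical-analysis experiments: dose-response sweeps, in-silico
mutation comparisons, and the scenario library of external conditions.

A *scenario* bundles an environment (per-input %ON intervals), baseline
mutations, the output nodes of interest, and optional simulation-config
overrides.  ``scenario_library()`` provides the ten published external
condition sets for the bundled hMEC ErbB reconstruction: eight model
validation experiments (EGF/ECM/alpha-s dose responses, the Ras
constitutive-activation control, and the ErbB dimerization-hierarchy
series) and the two Src/EGFR-internalization experiments at low
(0-5% ON) and high (60-70% ON) EGF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .engine import (ActivityRecord, EngineError, EnvironmentSpec,
                     SimulationConfig, simulate)
from .logic import LogicalNetwork

__all__ = [
    "Scenario", "DoseResponseResult", "ComparisonRow", "ComparisonResult",
    "student_t", "dose_response", "mutation_compare", "scenario_library",
]


@dataclass(frozen=True)
class Scenario:
    """A named experimental condition set."""

    name: str
    env: EnvironmentSpec
    mutations: Mapping[str, int] = field(default_factory=dict)
    outputs: tuple[str, ...] = ()
    sweep: str | None = None
    config: Mapping[str, int] = field(default_factory=dict)
    #: named environment overrides (e.g. receptor-expression sub-cases)
    variants: Mapping[str, Mapping[str, tuple]] = field(default_factory=dict)

    def environment(self, variant: str | None = None) -> EnvironmentSpec:
        if variant is None:
            return self.env
        try:
            overrides = self.variants[variant]
        except KeyError:
            raise EngineError(
                f"scenario {self.name!r} has no variant {variant!r}") from None
        return self.env.replace(**overrides)

    def simulation_config(self, base: SimulationConfig | None = None,
                          **extra) -> SimulationConfig:
        cfg = base or SimulationConfig()
        kw = dict(self.config)
        kw.update(extra)
        return cfg.replace(**kw) if kw else cfg


# ---------------------------------------------------------------------------
# Statistics


def student_t(sample_a: Sequence[float], sample_b: Sequence[float],
              *, welch: bool = False) -> tuple[float, float]:
    """Two-sample two-sided Student's t-test (pooled variance by default).

    Returns ``(t, p)`` with ``t = (mean_a - mean_b) / se``.  Degenerate
    cases: both samples constant and equal gives ``(0, 1)``; zero pooled
    variance with unequal means gives ``(+/-inf, 0)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least two observations")
    if welch:
        t, p = _stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    if sp2 == 0.0:
        if ma == mb:
            return 0.0, 1.0
        return math.copysign(math.inf, ma - mb), 0.0
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(_stats.t.sf(abs(t), df))
    return float(t), p


# ---------------------------------------------------------------------------
# Dose-response sweeps


@dataclass
class DoseResponseResult:
    """Binned input-output curve: replicates are grouped by the activity
    level drawn for the swept input."""

    sweep_node: str
    edges: np.ndarray                     # n_bins + 1 bin edges in %ON
    counts: np.ndarray                    # replicates per bin
    series: dict[str, tuple[np.ndarray, np.ndarray]]  # node -> (means, sems)
    n_runs: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self):
        import pandas as pd
        rows = []
        for node, (means, sems) in self.series.items():
            for b in range(len(self.counts)):
                rows.append({"node": node, "bin": b,
                             "bin_center": self.centers[b],
                             "mean_percent_on": means[b], "sem": sems[b],
                             "n": int(self.counts[b])})
        return pd.DataFrame(rows)


def dose_response(net: LogicalNetwork,
                  scenario: Scenario,
                  sweep_node: str | None = None,
                  n_runs: int = 2000,
                  n_bins: int = 10,
                  config: SimulationConfig | None = None,
                  outputs: Sequence[str] | None = None,
                  variant: str | None = None) -> DoseResponseResult:
    """Sweep one external input over its environment interval.

    Every replicate draws all environment levels (including the swept
    input) independently; replicates are then binned by the drawn sweep
    level into ``n_bins`` equal-width bins and the output %ON is averaged
    per bin.
    """
    sweep = sweep_node or scenario.sweep
    if sweep is None:
        raise EngineError("no sweep node given")
    if sweep not in net.externals:
        raise EngineError(f"sweep node {sweep!r} is not an external input")
    env = scenario.environment(variant)
    lo, hi = env.bounds(sweep)
    if hi <= lo:
        raise EngineError(
            f"sweep range for {sweep!r} is empty: [{lo}, {hi}]")
    out_nodes = tuple(outputs or scenario.outputs or net.internals)
    cfg = scenario.simulation_config(config, replicates=n_runs)
    rec = simulate(net, env, scenario.mutations, cfg)
    k = rec.level_nodes.index(sweep)
    drawn = rec.levels[:, k]
    edges = np.linspace(lo, hi, n_bins + 1)
    bin_id = np.clip(np.digitize(drawn, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(bin_id, minlength=n_bins)
    series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for node in out_nodes:
        vals = rec.per_replicate[:, rec.nodes.index(node)]
        means = np.full(n_bins, np.nan)
        sems = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sel = vals[bin_id == b]
            if len(sel):
                means[b] = sel.mean()
                sems[b] = sel.std(ddof=1) / math.sqrt(len(sel)) if len(sel) > 1 else 0.0
        series[node] = (means, sems)
    return DoseResponseResult(sweep, edges, counts, series, n_runs)


def plot_dose_response(result: DoseResponseResult, path: str) -> None:
    """Minimal chart helper (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for node, (means, sems) in result.series.items():
        ax.errorbar(result.centers, means, yerr=sems, marker="o",
                    capsize=2, label=node)
    ax.set_xlabel(f"{result.sweep_node} activity level (%ON)")
    ax.set_ylabel("output activity (%ON)")
    ax.set_ylim(-2, 102)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Mutation comparisons


@dataclass
class ComparisonRow:
    baseline_mean: float
    baseline_sem: float
    perturbed_mean: float
    perturbed_sem: float
    n: int
    t: float
    p: float
    degenerate: bool = False


@dataclass
class ComparisonResult:
    """Wild-type vs mutant per-node statistics."""

    scenario: str
    mutations: dict[str, int]
    n: int
    rows: dict[str, ComparisonRow]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [{"node": node, "baseline_mean": r.baseline_mean,
              "baseline_sem": r.baseline_sem,
              "perturbed_mean": r.perturbed_mean,
              "perturbed_sem": r.perturbed_sem,
              "n": r.n, "t": r.t, "p": r.p}
             for node, r in self.rows.items()]).set_index("node")


def mutation_compare(net: LogicalNetwork,
                     scenario: Scenario,
                     mutations: Mapping[str, int],
                     outputs: Sequence[str] | None = None,
                     n: int = 300,
                     config: SimulationConfig | None = None,
                     *,
                     variant: str | None = None,
                     paired: bool = False,
                     welch: bool = False) -> ComparisonResult:
    """Simulate a baseline arm and a perturbed arm and test each output.

    Baseline carries the scenario's own mutations; the perturbed arm adds
    the requested ones.  Arms share the scenario environment; by default
    they use disjoint per-replicate seed streams spawned from the scenario
    seed.  ``paired=True`` reuses the baseline streams in the perturbed
    arm (common random numbers), which makes an empty perturbation
    exactly null.  ``t`` is signed perturbed-minus-baseline.
    """
    if n < 2:
        raise EngineError("n must be >= 2 per arm")
    env = scenario.environment(variant)
    base_mut = dict(scenario.mutations)
    pert_mut = dict(base_mut)
    pert_mut.update(mutations)
    cfg = scenario.simulation_config(config, replicates=n)
    base = simulate(net, env, base_mut, cfg, spawn_prefix=(0,))
    pert = simulate(net, env, pert_mut, cfg,
                    spawn_prefix=(0,) if paired else (1,))
    out_nodes = tuple(outputs or scenario.outputs or net.internals)
    rows: dict[str, ComparisonRow] = {}
    for node in out_nodes:
        a = base.replicate_values(node)
        b = pert.replicate_values(node)
        t, p = student_t(b, a, welch=welch)
        rows[node] = ComparisonRow(
            baseline_mean=base.mean[node], baseline_sem=base.sem[node],
            perturbed_mean=pert.mean[node], perturbed_sem=pert.sem[node],
            n=n, t=t, p=p, degenerate=not math.isfinite(t))
    return ComparisonResult(scenario.name, dict(mutations), n, rows)


# ---------------------------------------------------------------------------
# Scenario library (published external simulation conditions)

# Rows: stimulus -> one interval per experiment column.  Scalars are
# degenerate intervals.  Stimuli not listed for an experiment are 0.
_T1 = {
    "fig2a": {"alpha_1213L": (40, 60), "alpha_iL": (0, 10), "alpha_qL": (0, 10),
              "alpha_sL": (40, 60), "ECM": (0, 100), "EGF": (0, 100),
              "EGFR_Contr": 100, "ErbB2_Contr": 0, "ErbB2Deg_Contr": 0,
              "ErbB3_Contr": 0, "ExtPump": (40, 60), "IL1_TNF": 2, "Stress": 2},
    "fig2b": {"alpha_1213L": 72, "alpha_iL": 11, "alpha_qL": 37,
              "alpha_sL": 48, "ECM": 88, "EGF": (0, 100),
              "EGFR_Contr": 100, "ErbB2_Contr": 0, "ErbB2Deg_Contr": 0,
              "ErbB3_Contr": 0, "ExtPump": 12, "IL1_TNF": 2, "Stress": 2},
    "fig2c": {"alpha_1213L": 72, "alpha_iL": 11, "alpha_qL": 37,
              "alpha_sL": 48, "ECM": 88, "EGF": (0, 100),
              "EGFR_Contr": 100, "ErbB2_Contr": 0, "ErbB2Deg_Contr": 0,
              "ErbB3_Contr": 0, "ExtPump": 12, "IL1_TNF": 2, "Stress": 2},
    "fig2d": {"alpha_1213L": (60, 70), "alpha_iL": (70, 80), "alpha_qL": (10, 20),
              "alpha_sL": (10, 20), "ECM": (0, 100), "EGF": 0,
              "EGFR_Contr": 100, "ErbB2_Contr": 0, "ErbB2Deg_Contr": 0,
              "ErbB3_Contr": 0, "ExtPump": (1, 10), "IL1_TNF": 2, "Stress": 2},
    "fig2e": {"alpha_1213L": (5, 65), "alpha_iL": (30, 80), "alpha_qL": (50, 100),
              "alpha_sL": (55, 95), "ECM": (0, 100), "EGF": (0, 100),
              "EGFR_Contr": 100, "ErbB2_Contr": 0, "ErbB2Deg_Contr": 0,
              "ErbB3_Contr": 0, "ExtPump": (80, 100), "IL1_TNF": 2, "Stress": 2},
    "fig2f": {"alpha_1213L": (70, 80), "alpha_iL": (40, 50), "alpha_qL": (90, 100),
              "alpha_sL": (50, 60), "ECM": (0, 100), "EGF": (1, 10),
              "EGFR_Contr": 100, "ErbB2_Contr": 0, "ErbB2Deg_Contr": 0,
              "ErbB3_Contr": 0, "ExtPump": (90, 100), "IL1_TNF": 2, "Stress": 2},
    "fig2g": {"alpha_1213L": 36, "alpha_iL": 69, "alpha_qL": 77,
              "alpha_sL": (0, 100), "ECM": 99, "EGF": 10,
              "EGFR_Contr": 100, "ErbB2_Contr": 0, "ErbB2Deg_Contr": 0,
              "ErbB3_Contr": 0, "ExtPump": 94, "IL1_TNF": 2, "Stress": 2},
    # fig2h carries three receptor-expression sub-cases (variants below)
    "fig2h": {"alpha_1213L": 26, "alpha_iL": 97, "alpha_qL": 4,
              "alpha_sL": 55, "ECM": 94, "EGF": (90, 100),
              "EGFR_Contr": (90, 100), "ErbB2_Contr": 0, "ErbB2Deg_Contr": 0,
              "ErbB3_Contr": 0, "ExtPump": 76, "IL1_TNF": 2, "Stress": 2},
    "fig3a": {"alpha_1213L": (20, 30), "alpha_iL": 90, "alpha_qL": 1,
              "alpha_sL": 50, "ECM": 90, "EGF": (0, 5),
              "EGFR_Contr": 100, "ErbB2_Contr": 0, "ErbB2Deg_Contr": 0,
              "ErbB3_Contr": 0, "ExtPump": (70, 80), "IL1_TNF": 2, "Stress": 2},
    "fig3b": {"alpha_1213L": (20, 30), "alpha_iL": 100, "alpha_qL": 5,
              "alpha_sL": 60, "ECM": 100, "EGF": (60, 70),
              "EGFR_Contr": 100, "ErbB2_Contr": 0, "ErbB2Deg_Contr": 0,
              "ErbB3_Contr": 0, "ExtPump": (70, 80), "IL1_TNF": 2, "Stress": 2},
}

_DIMER_NODES = ("EGFR_EGFR_PM_EGF", "EGFR_ErbB2", "ErbB2_ErbB3")
_TRAFFIC_OUTPUTS = ("EGFR_EGFR_PM_EGF", "CCP_E", "CCV_E", "MVB_E")

_META = {
    "fig2a": {"sweep": "EGF", "outputs": ("Akt",)},
    "fig2b": {"sweep": "EGF", "outputs": ("Erk",)},
    "fig2c": {"sweep": "EGF", "outputs": ("Erk",), "mutations": {"Ras": 1}},
    "fig2d": {"sweep": "ECM", "outputs": ("Erk",)},
    "fig2e": {"sweep": "ECM", "outputs": ("Rac",)},
    "fig2f": {"sweep": "ECM", "outputs": ("Cdc42",)},
    "fig2g": {"sweep": "alpha_sL", "outputs": ("AC",)},
    "fig2h": {"outputs": _DIMER_NODES,
              "variants": {
                  "egfr_only": {},
                  "plus_erbb2": {"ErbB2_Contr": (90, 100),
                                 "ErbB2Deg_Contr": (25, 35)},
                  "plus_erbb2_erbb3": {"ErbB2_Contr": (90, 100),
                                       "ErbB2Deg_Contr": (25, 35),
                                       "ErbB3_Contr": (90, 100)}}},
    "fig3a": {"outputs": _TRAFFIC_OUTPUTS},
    "fig3b": {"outputs": _TRAFFIC_OUTPUTS},
}


def scenario_library() -> dict[str, Scenario]:
    """The ten published external-condition columns as ready-to-run
    scenarios (all values are %ON activity levels)."""
    lib: dict[str, Scenario] = {}
    for name, intervals in _T1.items():
        meta = _META.get(name, {})
        lib[name] = Scenario(
            name=name,
            env=EnvironmentSpec(intervals),
            mutations=dict(meta.get("mutations", {})),
            outputs=tuple(meta.get("outputs", ())),
            sweep=meta.get("sweep"),
            variants={k: dict(v) for k, v in meta.get("variants", {}).items()})
    return lib
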
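"""Stochastic semi-quantitative simulation of logical networks.

The model is Boolean, but inputs and outputs are continuous *activity
levels* (%ON, 0-100).  Each external input is assigned a level drawn once
per replicate from its environment interval; at every time step the input
is ON with probability level/100, independently across steps.  Internal
nodes update synchronously by their Boolean rules applied to the full
state at the previous step.  After a transient is discarded, a node's %ON
is the percentage of window steps it spent ON — a semi-quantitative
measure of activity, not a concentration.

Simulation protocol per replicate:

1. draw one level per non-locked external node (uniform on its interval);
2. initialize all internal nodes OFF, locked nodes to their locked bit;
3. sample initial external bits, then for each step: compute every
   non-locked internal node from the state at t-1, resample every
   non-locked external node, assemble the new state;
4. discard ``transient_steps`` states, average the remaining
   ``window_steps`` states into %ON.

:func:`exact_activity` is the exact counterpart for small networks: it
propagates the full probability distribution over internal states,
averaging the synchronous image over all external assignments, and serves
as an oracle for the stochastic engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .logic import (And, Const, Expr, LogicalNetwork, Not, Or,
                    UnknownNodeError, Var, validate_network)

__all__ = [
    "EngineError", "EnvironmentSpec", "SimulationConfig", "ActivityRecord",
    "draw_levels", "simulate", "simulate_replicate", "exact_activity",
]

_CHUNK = 512  # replicates simulated per vectorized batch

# Exact-oracle state-space guards: 2^N x 2^K transition enumeration.
_MAX_EXACT_INTERNAL = 16
_MAX_EXACT_EXTERNAL = 10


class EngineError(Exception):
    """Invalid network, environment, mutation or configuration."""


class EnvironmentSpec(Mapping):
    """Per-external-node activity intervals in %ON.

    Accepts scalars (degenerate intervals) or ``(lo, hi)`` pairs with
    ``0 <= lo <= hi <= 100``.  Externals absent from the spec default to
    the interval ``(0, 0)`` — stimuli not used in an experiment are OFF.
    """

    def __init__(self, intervals: Mapping[str, object] | None = None):
        iv: dict[str, tuple[float, float]] = {}
        for name, v in (intervals or {}).items():
            if isinstance(v, (int, float)):
                lo = hi = float(v)
            else:
                lo, hi = (float(v[0]), float(v[1]))
            if not (0.0 <= lo <= hi <= 100.0):
                raise EngineError(
                    f"invalid interval for {name!r}: [{lo}, {hi}]")
            iv[name] = (lo, hi)
        self._iv = iv

    def bounds(self, node: str) -> tuple[float, float]:
        return self._iv.get(node, (0.0, 0.0))

    def replace(self, **intervals) -> "EnvironmentSpec":
        merged = dict(self._iv)
        merged.update(intervals)
        return EnvironmentSpec(merged)

    def __getitem__(self, node: str) -> tuple[float, float]:
        return self._iv[node]

    def __iter__(self):
        return iter(self._iv)

    def __len__(self) -> int:
        return len(self._iv)

    def __repr__(self) -> str:
        return f"EnvironmentSpec({self._iv!r})"


@dataclass(frozen=True)
class SimulationConfig:
    """Steps, replication and seeding for the stochastic engine.

    ``transient_steps``/``window_steps`` default to 200/800 — comfortably
    past the longest feedback cycle of the bundled ErbB reconstruction.
    Identical config + seed gives bitwise-identical output; replicate ``r``
    uses an independent stream spawned from ``(seed, r)``, so results do
    not depend on batching order.
    """

    transient_steps: int = 200
    window_steps: int = 800
    replicates: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.transient_steps < 0:
            raise EngineError("transient_steps must be >= 0")
        if self.window_steps < 1:
            raise EngineError("window_steps must be >= 1")
        if self.replicates < 1:
            raise EngineError("replicates must be >= 1")

    def replace(self, **kw) -> "SimulationConfig":
        d = {"transient_steps": self.transient_steps,
             "window_steps": self.window_steps,
             "replicates": self.replicates, "seed": self.seed}
        d.update(kw)
        return SimulationConfig(**d)


@dataclass
class ActivityRecord:
    """Per-node %ON summaries aggregated over replicates."""

    nodes: tuple[str, ...]
    mean: dict[str, float]
    sem: dict[str, float]
    replicates: int
    #: (replicates, nodes) matrix of per-replicate %ON values.
    per_replicate: np.ndarray | None = None
    #: (replicates, free externals) matrix of drawn activity levels.
    levels: np.ndarray | None = None
    level_nodes: tuple[str, ...] = ()

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            {"mean_percent_on": [self.mean[n] for n in self.nodes],
             "sem": [self.sem[n] for n in self.nodes],
             "n": self.replicates},
            index=pd.Index(self.nodes, name="node"))

    def replicate_values(self, node: str) -> np.ndarray:
        if self.per_replicate is None:
            raise EngineError("per-replicate values were not retained")
        return self.per_replicate[:, self.nodes.index(node)]


def _norm_mutations(net: LogicalNetwork,
                    mutations: Mapping[str, int] | None) -> dict[str, int]:
    out: dict[str, int] = {}
    declared = set(net.nodes)
    for name, bit in (mutations or {}).items():
        if name not in declared:
            raise UnknownNodeError(f"mutation on unknown node {name!r}")
        if isinstance(bit, str):
            token = bit.strip().upper()
            if token not in ("ON", "OFF"):
                raise EngineError(f"mutation bit must be ON/OFF/0/1, got {bit!r}")
            bit = 1 if token == "ON" else 0
        if bit not in (0, 1):
            raise EngineError(f"mutation bit must be 0 or 1, got {bit!r}")
        out[name] = int(bit)
    return out


def draw_levels(env: EnvironmentSpec, rng: np.random.Generator,
                externals: Iterable[str] | None = None) -> dict[str, float]:
    """Draw one activity level per external node, uniform on its interval.

    With ``externals`` given, nodes absent from *env* get level 0 (stimuli
    not used in an experiment are OFF); a degenerate interval returns its
    endpoint without consuming randomness.
    """
    names = list(externals) if externals is not None else list(env)
    out: dict[str, float] = {}
    for name in names:
        lo, hi = env.bounds(name)
        out[name] = lo if hi <= lo else float(rng.uniform(lo, hi))
    return out


# ---------------------------------------------------------------------------
# Compilation: network -> vectorized synchronous step function


class _Compiled:
    """A network with mutations folded in, compiled to a numpy step kernel.

    The kernel updates all replicates at once: node states live in a
    (n_nodes, R) boolean matrix and each rule becomes one vectorized
    boolean expression over its rows.
    """

    def __init__(self, net: LogicalNetwork, mutations: Mapping[str, int] | None):
        violations = validate_network(net)
        if violations:
            raise EngineError("invalid network: " + "; ".join(violations))
        self.net = net
        self.locked = _norm_mutations(net, mutations)
        self.nodes = net.nodes
        self.index = {n: i for i, n in enumerate(net.nodes)}
        self.ext_free = [n for n in net.nodes
                         if n in net.externals and n not in self.locked]
        self.int_free = [n for n in net.internals if n not in self.locked]
        self.ext_rows = [self.index[n] for n in self.ext_free]
        self.int_rows = [self.index[n] for n in self.int_free]
        self.step = self._build_step()

    def _code(self, e: Expr) -> str:
        if isinstance(e, Const):
            return "_T" if e.value else "_F"
        if isinstance(e, Var):
            return f"S[{self.index[e.name]}]"
        if isinstance(e, Not):
            return f"(~{self._code(e.child)})"
        if isinstance(e, And):
            return "(" + " & ".join(self._code(c) for c in e.children) + ")"
        if isinstance(e, Or):
            return "(" + " | ".join(self._code(c) for c in e.children) + ")"
        raise TypeError(f"not an expression: {e!r}")

    def _build_step(self):
        lines = ["def _step(S, OUT, _T, _F):"]
        if not self.int_free:
            lines.append("    pass")
        for k, name in enumerate(self.int_free):
            lines.append(f"    OUT[{k}] = " + self._code(self.net.rules[name]))
        ns: dict = {}
        exec("\n".join(lines), ns)  # noqa: S102 - generated from validated AST
        return ns["_step"]


def _replicate_rng(seed: int, spawn_key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def _run_core(comp: _Compiled, cfg: SimulationConfig,
              levels: np.ndarray, bits: np.ndarray | None) -> np.ndarray:
    """Run all replicates of one batch; returns (R, n_nodes) %ON."""
    R = levels.shape[0] if levels.size else (bits.shape[0] if bits is not None else 1)
    if bits is not None:
        R = bits.shape[0]
    n_nodes = len(comp.nodes)
    total = cfg.transient_steps + cfg.window_steps
    S = np.zeros((n_nodes, R), dtype=bool)
    for name, bit in comp.locked.items():
        S[comp.index[name]] = bool(bit)
    if comp.ext_rows:
        S[comp.ext_rows] = bits[:, 0, :].T
    OUT = np.empty((len(comp.int_free), R), dtype=bool)
    counts = np.zeros((n_nodes, R), dtype=np.int64)
    _T = np.ones(R, dtype=bool)
    _F = np.zeros(R, dtype=bool)
    step = comp.step
    transient = cfg.transient_steps
    for t in range(1, total + 1):
        step(S, OUT, _T, _F)
        if comp.ext_rows:
            S[comp.ext_rows] = bits[:, t, :].T
        if comp.int_rows:
            S[comp.int_rows] = OUT
        if t > transient:
            counts += S
    return counts.T * (100.0 / cfg.window_steps)


def _draw_batch(comp: _Compiled, env: EnvironmentSpec, cfg: SimulationConfig,
                rep_ids: Sequence[int], spawn_prefix: tuple[int, ...]):
    """Per-replicate levels and pre-sampled external bit streams."""
    R = len(rep_ids)
    nfe = len(comp.ext_free)
    total = cfg.transient_steps + cfg.window_steps
    levels = np.zeros((R, nfe))
    bits = np.zeros((R, total + 1, nfe), dtype=bool) if nfe else None
    for j, r in enumerate(rep_ids):
        rng = _replicate_rng(cfg.seed, spawn_prefix + (int(r),))
        lv = draw_levels(env, rng, comp.ext_free)
        row = np.array([lv[n] for n in comp.ext_free], dtype=float)
        levels[j] = row
        if nfe:
            bits[j] = rng.random((total + 1, nfe)) < (row / 100.0)
    return levels, bits


def simulate(net: LogicalNetwork,
             env: EnvironmentSpec | Mapping | None = None,
             mutations: Mapping[str, int] | None = None,
             config: SimulationConfig | None = None,
             *,
             spawn_prefix: tuple[int, ...] = ()) -> ActivityRecord:
    """Run ``config.replicates`` independent replicates and aggregate
    per-node mean %ON and SEM (sample SD / sqrt(n)).

    ``spawn_prefix`` namespaces the per-replicate seed streams; the
    experiments layer uses it to give comparison arms disjoint streams
    from one scenario seed.
    """
    if env is None:
        env = EnvironmentSpec()
    elif not isinstance(env, EnvironmentSpec):
        env = EnvironmentSpec(env)
    cfg = config or SimulationConfig()
    comp = _Compiled(net, mutations)
    R = cfg.replicates
    pct = np.empty((R, len(comp.nodes)))
    levels = np.empty((R, len(comp.ext_free)))
    for start in range(0, R, _CHUNK):
        ids = range(start, min(start + _CHUNK, R))
        lv, bits = _draw_batch(comp, env, cfg, list(ids), spawn_prefix)
        pct[start:start + len(lv)] = _run_core(comp, cfg, lv, bits)
        levels[start:start + len(lv)] = lv
    mean = pct.mean(axis=0)
    if R > 1:
        sem = pct.std(axis=0, ddof=1) / np.sqrt(R)
    else:
        sem = np.zeros(len(comp.nodes))
    return ActivityRecord(
        nodes=comp.nodes,
        mean={n: float(mean[i]) for i, n in enumerate(comp.nodes)},
        sem={n: float(sem[i]) for i, n in enumerate(comp.nodes)},
        replicates=R,
        per_replicate=pct,
        levels=levels,
        level_nodes=tuple(comp.ext_free))


def simulate_replicate(net: LogicalNetwork,
                       env: EnvironmentSpec | Mapping | None,
                       mutations: Mapping[str, int] | None,
                       config: SimulationConfig,
                       rng: np.random.Generator) -> dict[str, float]:
    """One replicate driven by an explicit generator; returns node -> %ON."""
    if env is None:
        env = EnvironmentSpec()
    elif not isinstance(env, EnvironmentSpec):
        env = EnvironmentSpec(env)
    comp = _Compiled(net, mutations)
    nfe = len(comp.ext_free)
    total = config.transient_steps + config.window_steps
    lv = draw_levels(env, rng, comp.ext_free)
    levels = np.array([[lv[n] for n in comp.ext_free]], dtype=float)
    bits = None
    if nfe:
        bits = (rng.random((1, total + 1, nfe)) < (levels[0] / 100.0))
    pct = _run_core(comp, config, levels, bits)[0]
    return {n: float(pct[i]) for i, n in enumerate(comp.nodes)}


# ---------------------------------------------------------------------------
# Exact oracle


def exact_activity(net: LogicalNetwork,
                   levels: Mapping[str, float],
                   mutations: Mapping[str, int] | None = None,
                   config: SimulationConfig | None = None) -> dict[str, float]:
    """Exact expected %ON for small networks (the engine's oracle).

    Maintains the probability distribution over all 2^N internal states.
    One synchronous step maps distribution ``d`` to ``T d`` where the
    transition operator averages the deterministic image over all 2^K
    external assignments, weighted by the product of per-input Bernoulli
    probabilities (``level/100``).  Starting from the all-OFF internal
    state, the transient is propagated and node marginals are averaged
    over the window — matching :func:`simulate` in expectation.
    """
    cfg = config or SimulationConfig()
    comp = _Compiled(net, mutations)
    for name in levels:
        if name not in comp.index:
            raise UnknownNodeError(f"level for unknown node {name!r}")
    N = len(comp.int_free)
    K = len(comp.ext_free)
    if N > _MAX_EXACT_INTERNAL or K > _MAX_EXACT_EXTERNAL:
        raise EngineError(
            f"exact oracle limited to {_MAX_EXACT_INTERNAL} internal / "
            f"{_MAX_EXACT_EXTERNAL} external free nodes (got {N}/{K})")
    p = np.array([float(levels.get(n, 0.0)) / 100.0 for n in comp.ext_free])
    if np.any((p < 0) | (p > 1)):
        raise EngineError("levels must lie in [0, 100]")

    n_states = 1 << N
    n_env = 1 << K
    ncols = n_states * n_env
    s_idx = np.arange(ncols) // n_env
    e_idx = np.arange(ncols) % n_env

    S = np.zeros((len(comp.nodes), ncols), dtype=bool)
    for name, bit in comp.locked.items():
        S[comp.index[name]] = bool(bit)
    for j, name in enumerate(comp.int_free):
        S[comp.index[name]] = ((s_idx >> j) & 1).astype(bool)
    for k, name in enumerate(comp.ext_free):
        S[comp.index[name]] = ((e_idx >> k) & 1).astype(bool)

    OUT = np.empty((N, ncols), dtype=bool)
    _T = np.ones(ncols, dtype=bool)
    comp.step(S, OUT, _T, ~_T)
    next_state = np.zeros(ncols, dtype=np.int64)
    for j in range(N):
        next_state |= OUT[j].astype(np.int64) << j

    w = np.ones(ncols)
    for k in range(K):
        bit = (e_idx >> k) & 1
        w *= np.where(bit == 1, p[k], 1.0 - p[k])

    T = sparse.coo_matrix((w, (next_state, s_idx)),
                          shape=(n_states, n_states)).tocsr()

    d = np.zeros(n_states)
    d[0] = 1.0
    for _ in range(cfg.transient_steps):
        d = T @ d
    acc = np.zeros(n_states)
    for _ in range(cfg.window_steps):
        d = T @ d
        acc += d
    acc /= cfg.window_steps

    result: dict[str, float] = {}
    if N:
        bit_matrix = ((np.arange(n_states)[None, :] >> np.arange(N)[:, None]) & 1)
        marg = bit_matrix @ acc
        for j, name in enumerate(comp.int_free):
            result[name] = float(100.0 * marg[j])
    for k, name in enumerate(comp.ext_free):
        result[name] = float(100.0 * p[k])
    for name, bit in comp.locked.items():
        result[name] = 100.0 * bit
    return result
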
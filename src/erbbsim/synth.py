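"""Synthetic logical networks for testing and benchmarking.

Random networks share the statistical structure the engine assumes —
named nodes, Boolean rules over a bounded number of regulators, a set of
stochastic external inputs — without any biological meaning.  Rules are
drawn as random truth tables with a tunable ON bias and rendered as
expressions by minterm expansion (no minimization; correctness over
elegance).  Chain fixtures have closed-form stationary activities and
anchor the engine's pass-through tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .logic import And, Const, Expr, LogicalNetwork, Not, Or, Var

__all__ = ["GeneratorSpec", "random_network", "chain_fixture"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random-network generator.

    ``bias`` is the probability that a truth-table row maps to ON.  With
    ``feedforward=True`` regulators are drawn only from external inputs
    and earlier internal nodes (no cycles, oracle-friendly); otherwise
    from all nodes, self-loops included.
    """

    n_internal: int
    n_external: int
    max_in_degree: int = 2
    bias: float = 0.5
    seed: int = 0
    feedforward: bool = False

    def __post_init__(self):
        if self.n_internal < 1 or self.n_external < 0:
            raise ValueError("need >=1 internal and >=0 external nodes")
        if self.max_in_degree < 1:
            raise ValueError("max_in_degree must be >= 1")
        if not (0.0 < self.bias < 1.0):
            raise ValueError("bias must lie in (0, 1)")
        if self.max_in_degree > self.n_internal + self.n_external:
            raise ValueError("max_in_degree exceeds node count")


def _minterm_expression(regulators: list[str], table: np.ndarray) -> Expr:
    """Render a truth table as a disjunction of minterms."""
    k = len(regulators)
    on_rows = [r for r in range(1 << k) if table[r]]
    if not on_rows:
        return Const(False)
    if len(on_rows) == 1 << k:
        return Const(True)
    terms: list[Expr] = []
    for row in on_rows:
        literals: list[Expr] = []
        for j, name in enumerate(regulators):
            bit = (row >> j) & 1
            literals.append(Var(name) if bit else Not(Var(name)))
        terms.append(literals[0] if k == 1 else And(tuple(literals)))
    return terms[0] if len(terms) == 1 else Or(tuple(terms))


def random_network(spec: GeneratorSpec) -> LogicalNetwork:
    """Generate a random logical network; deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    externals = [f"E{i + 1}" for i in range(spec.n_external)]
    internals = [f"N{i + 1}" for i in range(spec.n_internal)]
    rules: dict[str, Expr] = {}
    for i, name in enumerate(internals):
        if spec.feedforward:
            pool = externals + internals[:i]
            if not pool:
                pool = externals
        else:
            pool = externals + internals
        if not pool:
            raise ValueError("no candidate regulators available")
        k = int(rng.integers(1, min(spec.max_in_degree, len(pool)) + 1))
        regs = [pool[j] for j in rng.choice(len(pool), size=k, replace=False)]
        table = rng.random(1 << k) < spec.bias
        rules[name] = _minterm_expression(regs, table)
    return LogicalNetwork(tuple(externals + internals),
                          frozenset(externals), rules)


def chain_fixture(length: int, negate_every: int = 0,
                  input_name: str = "A") -> LogicalNetwork:
    """Linear chain ``X1 <- input``, ``Xi = [NOT] X(i-1)``.

    With input level p the stationary %ON of each node is p or 100-p
    according to the parity of negations up to it.  ``negate_every=m``
    negates every m-th link (m=0: none).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    names = [f"X{i + 1}" for i in range(length)]
    rules: dict[str, Expr] = {}
    prev = input_name
    for i, name in enumerate(names, start=1):
        body: Expr = Var(prev)
        if negate_every and i % negate_every == 0:
            body = Not(body)
        rules[name] = body
        prev = name
    return LogicalNetwork(tuple([input_name] + names),
                          frozenset([input_name]), rules)
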
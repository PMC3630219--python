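"""Boolean-rule logical networks.

A logical network partitions its named nodes into *external* inputs (no
rule; sampled stochastically by the engine) and *internal* nodes, each
governed by a single Boolean expression over other nodes.  This module owns
the expression AST, its parser/serializer, evaluation, structural
validation, and subnetwork extraction.

Grammar (case-insensitive keywords, standard precedence NOT > AND > OR)::

    expr   := term ("OR" term)*
    term   := factor ("AND" factor)*
    factor := "NOT" factor | atom
    atom   := IDENT | "TRUE" | "FALSE" | "(" expr ")"

Identifiers are ASCII letters, digits and underscores (not starting with a
digit) and are case-sensitive.  AND/OR chains are flattened into n-ary
nodes, so ``A AND B AND C`` parses to a single 3-child conjunction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Expr", "Const", "Var", "Not", "And", "Or", "TRUE", "FALSE",
    "LogicError", "ParseError", "UnknownNodeError",
    "parse_expression", "serialize", "evaluate", "variables",
    "LogicalNetwork", "validate_network", "extract_subnetwork",
    "networks_equivalent",
]

NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")
_KEYWORDS = {"AND", "OR", "NOT", "TRUE", "FALSE"}


class LogicError(Exception):
    """Base class for logical-network errors."""


class ParseError(LogicError):
    """Syntax error in a rule string; carries the 0-based offset."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnknownNodeError(LogicError):
    """An identifier does not name a declared network node."""


# ---------------------------------------------------------------------------
# Expression AST


class Expr:
    """Abstract Boolean expression node."""

    __slots__ = ()


@dataclass(frozen=True)
class Const(Expr):
    value: bool


@dataclass(frozen=True)
class Var(Expr):
    name: str


@dataclass(frozen=True)
class Not(Expr):
    child: Expr


@dataclass(frozen=True)
class And(Expr):
    children: tuple[Expr, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise LogicError("AND requires at least two operands")


@dataclass(frozen=True)
class Or(Expr):
    children: tuple[Expr, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise LogicError("OR requires at least two operands")


TRUE = Const(True)
FALSE = Const(False)


def variables(expr: Expr) -> frozenset[str]:
    """Set of identifiers appearing in *expr*."""
    out: set[str] = set()
    stack = [expr]
    while stack:
        e = stack.pop()
        if isinstance(e, Var):
            out.add(e.name)
        elif isinstance(e, Not):
            stack.append(e.child)
        elif isinstance(e, (And, Or)):
            stack.extend(e.children)
    return frozenset(out)


def evaluate(expr: Expr, state: Mapping[str, int]) -> int:
    """Evaluate *expr* under a complete truth assignment; returns 0 or 1."""
    if isinstance(expr, Const):
        return int(expr.value)
    if isinstance(expr, Var):
        try:
            return 1 if state[expr.name] else 0
        except KeyError:
            raise UnknownNodeError(
                f"state does not assign node {expr.name!r}") from None
    if isinstance(expr, Not):
        return 1 - evaluate(expr.child, state)
    if isinstance(expr, And):
        return int(all(evaluate(c, state) for c in expr.children))
    if isinstance(expr, Or):
        return int(any(evaluate(c, state) for c in expr.children))
    raise TypeError(f"not an expression: {expr!r}")


# ---------------------------------------------------------------------------
# Serializer

def _atomish(e: Expr) -> bool:
    return isinstance(e, (Var, Const))


def serialize(expr: Expr) -> str:
    """Canonical text form; ``parse_expression(serialize(e))`` returns an
    AST structurally equal to ``e``.

    Nested same-operator children are parenthesized (the parser flattens
    unparenthesized chains), as are lower-precedence children.
    """
    if isinstance(expr, Const):
        return "TRUE" if expr.value else "FALSE"
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Not):
        inner = serialize(expr.child)
        if _atomish(expr.child):
            return f"NOT {inner}"
        return f"NOT ({inner})"
    if isinstance(expr, And):
        parts = []
        for c in expr.children:
            s = serialize(c)
            if isinstance(c, (And, Or)):
                s = f"({s})"
            parts.append(s)
        return " AND ".join(parts)
    if isinstance(expr, Or):
        parts = []
        for c in expr.children:
            s = serialize(c)
            if isinstance(c, Or):
                s = f"({s})"
            parts.append(s)
        return " OR ".join(parts)
    raise TypeError(f"not an expression: {expr!r}")


# ---------------------------------------------------------------------------
# Parser

_TOKEN_RE = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<word>[A-Za-z_][A-Za-z0-9_]*))")


class _Scanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.tok: str | None = None       # "(", ")", keyword, or "IDENT"
        self.value: str | None = None     # identifier text
        self.tok_pos = 0
        self.advance()

    def advance(self) -> None:
        t = self.text
        n = len(t)
        p = self.pos
        while p < n and t[p].isspace():
            p += 1
        self.tok_pos = p
        if p >= n:
            self.tok, self.value, self.pos = None, None, p
            return
        m = _TOKEN_RE.match(t, p)
        if m is None or m.start() != p and not m.group():  # pragma: no cover
            raise ParseError(f"unexpected character {t[p]!r}", p)
        if m.lastgroup is None or m.end() == p:
            raise ParseError(f"unexpected character {t[p]!r}", p)
        if m.group("lpar"):
            self.tok, self.value = "(", None
        elif m.group("rpar"):
            self.tok, self.value = ")", None
        else:
            word = m.group("word")
            upper = word.upper()
            if upper in _KEYWORDS:
                self.tok, self.value = upper, None
            else:
                self.tok, self.value = "IDENT", word
        self.pos = m.end()


def parse_expression(text: str, known_nodes: Iterable[str] | None = None) -> Expr:
    """Parse a rule string into a :class:`BooleanExpression <Expr>` AST.

    Parameters
    ----------
    text:
        Rule text over identifiers, AND/OR/NOT, TRUE/FALSE and parentheses.
    known_nodes:
        Optional collection of declared node names; an identifier outside
        it raises :class:`UnknownNodeError` naming the offender.
    """
    known = None if known_nodes is None else set(known_nodes)
    sc = _Scanner(text)

    def parse_or() -> Expr:
        terms = [parse_and()]
        while sc.tok == "OR":
            sc.advance()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and() -> Expr:
        factors = [parse_not()]
        while sc.tok == "AND":
            sc.advance()
            factors.append(parse_not())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_not() -> Expr:
        if sc.tok == "NOT":
            sc.advance()
            return Not(parse_not())
        return parse_atom()

    def parse_atom() -> Expr:
        if sc.tok == "(":
            open_pos = sc.tok_pos
            sc.advance()
            e = parse_or()
            if sc.tok != ")":
                raise ParseError("unbalanced parenthesis", open_pos)
            sc.advance()
            return e
        if sc.tok == "TRUE":
            sc.advance()
            return TRUE
        if sc.tok == "FALSE":
            sc.advance()
            return FALSE
        if sc.tok == "IDENT":
            name = sc.value
            if known is not None and name not in known:
                raise UnknownNodeError(
                    f"unknown node {name!r} at position {sc.tok_pos}")
            sc.advance()
            return Var(name)
        if sc.tok is None:
            raise ParseError("unexpected end of expression", sc.tok_pos)
        raise ParseError(f"unexpected token {sc.tok!r}", sc.tok_pos)

    expr = parse_or()
    if sc.tok is not None:
        raise ParseError(f"unexpected token {sc.tok or sc.value!r} after expression",
                         sc.tok_pos)
    return expr


# ---------------------------------------------------------------------------
# Networks


@dataclass(frozen=True)
class LogicalNetwork:
    """Named nodes partitioned into external inputs and rule-governed
    internal nodes.

    ``nodes`` fixes a canonical ordering used by the engine and all I/O.
    """

    nodes: tuple[str, ...]
    externals: frozenset[str]
    rules: Mapping[str, Expr] = field(default_factory=dict)

    @property
    def internals(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n not in self.externals)

    def rule(self, node: str) -> Expr:
        return self.rules[node]

    @staticmethod
    def from_rules(rules: Mapping[str, Expr],
                   externals: Iterable[str],
                   order: Iterable[str] | None = None) -> "LogicalNetwork":
        ext = frozenset(externals)
        if order is None:
            order = list(rules) + sorted(ext - set(rules))
        return LogicalNetwork(tuple(order), ext, dict(rules))


def validate_network(net: LogicalNetwork) -> list[str]:
    """Return human-readable invariant violations (empty list = valid).

    Violations are data, not exceptions: callers decide whether to raise.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for n in net.nodes:
        if not n or not NAME_RE.match(n):
            violations.append(f"invalid node name {n!r}")
        if n in seen:
            violations.append(f"duplicate node name {n!r}")
        seen.add(n)
    declared = set(net.nodes)
    for n in net.externals - declared:
        violations.append(f"external node {n!r} is not declared")
    internals = declared - net.externals
    for n in sorted(internals - set(net.rules)):
        violations.append(f"internal node {n!r} has no rule")
    for n, expr in net.rules.items():
        if n not in declared:
            violations.append(f"rule attached to undeclared node {n!r}")
        elif n in net.externals:
            violations.append(f"rule attached to external node {n!r}")
        for ref in sorted(variables(expr)):
            if ref not in declared:
                violations.append(
                    f"rule for {n!r} references undeclared node {ref!r}")
    return violations


def extract_subnetwork(net: LogicalNetwork, keep: Iterable[str]) -> LogicalNetwork:
    """Restrict *net* to ``keep``: kept internal nodes retain their rules;
    any node they reference outside ``keep`` becomes an external of the
    result (its dynamics are then supplied by the caller, e.g. fixed at the
    full-network activity level)."""
    keep_set = set(keep)
    declared = set(net.nodes)
    unknown = keep_set - declared
    if unknown:
        raise UnknownNodeError(f"unknown node(s): {sorted(unknown)}")
    new_internal = [n for n in net.nodes
                    if n in keep_set and n not in net.externals]
    refs: set[str] = set()
    for n in new_internal:
        refs |= variables(net.rules[n])
    new_ext = (keep_set & net.externals) | (refs - set(new_internal))
    order = tuple(n for n in net.nodes if n in set(new_internal) | new_ext)
    return LogicalNetwork(order, frozenset(new_ext),
                          {n: net.rules[n] for n in new_internal})


def networks_equivalent(a: LogicalNetwork, b: LogicalNetwork) -> bool:
    """Structural equality up to node ordering: same node set, same
    external partition, structurally equal rules."""
    return (set(a.nodes) == set(b.nodes)
            and a.externals == b.externals
            and dict(a.rules) == dict(b.rules))
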
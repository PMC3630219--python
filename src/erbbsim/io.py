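"""Model, scenario and result I/O.

Rule-text format
----------------
UTF-8 text, one ``Name = EXPR`` assignment per line, ``#`` comments.
Identifiers that are referenced but never assigned are external inputs.
A ``# @external: NAME [NAME ...]`` directive declares inputs referenced
by no rule (they would otherwise not exist in the file).

SBML-qual
---------
Boolean-only subset of the SBML Level 3 qualitative-models package:
every qualitative species has ``maxLevel="1"``; externals are
``constant="true"``; one transition per internal node whose ON function
term carries the rule as MathML (and/or/not over ``<ci>`` or
``<apply><eq/><ci/>1</apply>`` atoms).  Multi-level species and other
MathML constructs are rejected with explicit messages.

Results
-------
TSV with '.' decimals, LF endings and 6-significant-digit floats; a
``#`` comment header records tool version, seed and model hash so any
table can be traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path
from typing import Mapping

from lxml import etree

from .engine import EnvironmentSpec
from .logic import (Expr, LogicalNetwork, LogicError, ParseError,
                    parse_expression, serialize, validate_network, variables)

__all__ = [
    "RuleFileError", "SbmlQualError",
    "parse_rules", "serialize_rules", "read_rule_file", "write_rule_file",
    "read_sbml_qual", "write_sbml_qual",
    "model_hash", "write_results_tsv", "read_results_tsv",
    "scenario_to_dict", "scenario_from_dict",
    "read_scenario_file", "write_scenario_file",
]

_TOOL = "erbbsim"


class RuleFileError(LogicError):
    """Malformed rule file (carries a line number in the message)."""


class SbmlQualError(LogicError):
    """Unsupported or malformed SBML-qual document."""


# ---------------------------------------------------------------------------
# Rule text


def parse_rules(text: str) -> LogicalNetwork:
    """Parse rule text into a :class:`LogicalNetwork`."""
    rules: dict[str, Expr] = {}
    order: list[str] = []
    declared_ext: list[str] = []
    referenced: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("@external:"):
                for name in body[len("@external:"):].split():
                    if name not in declared_ext:
                        declared_ext.append(name)
            continue
        if "#" in line:
            line = line[:line.index("#")].strip()
        if not line:
            continue
        if "=" not in line:
            raise RuleFileError(f"line {lineno}: expected 'Name = EXPR'")
        name, _, rhs = line.partition("=")
        name = name.strip()
        if name in rules:
            raise RuleFileError(f"line {lineno}: duplicate rule for {name!r}")
        try:
            expr = parse_expression(rhs.strip())
        except ParseError as err:
            raise RuleFileError(f"line {lineno}: {err}") from err
        rules[name] = expr
        order.append(name)
        for ref in sorted(variables(expr)):
            if ref not in referenced:
                referenced.append(ref)
    externals = [n for n in referenced if n not in rules]
    for n in declared_ext:
        if n in rules:
            raise RuleFileError(
                f"node {n!r} declared external but has a rule")
        if n not in externals:
            externals.append(n)
    nodes = tuple(order + [n for n in externals if n not in order])
    return LogicalNetwork(nodes, frozenset(externals), rules)


def serialize_rules(net: LogicalNetwork) -> str:
    """Canonical rule text; stable under parse -> serialize -> parse."""
    lines = []
    referenced: set[str] = set()
    for n in net.internals:
        referenced |= variables(net.rules[n])
    unreferenced = [n for n in net.nodes
                    if n in net.externals and n not in referenced]
    if unreferenced:
        lines.append("# @external: " + " ".join(unreferenced))
    width = max((len(n) for n in net.internals), default=0)
    for n in net.internals:
        lines.append(f"{n:<{width}} = {serialize(net.rules[n])}")
    return "\n".join(lines) + "\n"


def read_rule_file(path: str | Path) -> LogicalNetwork:
    return parse_rules(Path(path).read_text(encoding="utf-8"))


def write_rule_file(net: LogicalNetwork, path: str | Path) -> None:
    _check_valid(net)
    Path(path).write_text(serialize_rules(net), encoding="utf-8")


def _check_valid(net: LogicalNetwork) -> None:
    violations = validate_network(net)
    if violations:
        raise LogicError("invalid network: " + "; ".join(violations))


def model_hash(net: LogicalNetwork) -> str:
    """Short content hash of the canonical rule text."""
    text = serialize_rules(net) + "|ext:" + ",".join(sorted(net.externals))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# SBML-qual

_NS_SBML = "http://www.sbml.org/sbml/level3/version1/core"
_NS_QUAL = "http://www.sbml.org/sbml/level3/version1/qual/version1"
_NS_MATH = "http://www.w3.org/1998/Math/MathML"
_NSMAP = {None: _NS_SBML, "qual": _NS_QUAL}


def _q(tag: str) -> str:
    return f"{{{_NS_QUAL}}}{tag}"


def _m(tag: str) -> str:
    return f"{{{_NS_MATH}}}{tag}"


def _expr_to_mathml(e: Expr, parent: etree._Element) -> None:
    from .logic import And, Const, Not, Or, Var
    if isinstance(e, Const):
        etree.SubElement(parent, _m("true" if e.value else "false"))
    elif isinstance(e, Var):
        apply = etree.SubElement(parent, _m("apply"))
        etree.SubElement(apply, _m("eq"))
        ci = etree.SubElement(apply, _m("ci"))
        ci.text = f" {e.name} "
        cn = etree.SubElement(apply, _m("cn"))
        cn.set("type", "integer")
        cn.text = " 1 "
    elif isinstance(e, (Not, And, Or)):
        apply = etree.SubElement(parent, _m("apply"))
        op = {"Not": "not", "And": "and", "Or": "or"}[type(e).__name__]
        etree.SubElement(apply, _m(op))
        children = (e.child,) if isinstance(e, Not) else e.children
        for c in children:
            _expr_to_mathml(c, apply)
    else:  # pragma: no cover
        raise TypeError(f"not an expression: {e!r}")


def write_sbml_qual(net: LogicalNetwork, path: str | Path) -> None:
    """Export as a Boolean SBML-qual document."""
    _check_valid(net)
    sbml = etree.Element(f"{{{_NS_SBML}}}sbml", nsmap=_NSMAP)
    sbml.set("level", "3")
    sbml.set("version", "1")
    sbml.set(_q("required"), "true")
    model = etree.SubElement(sbml, f"{{{_NS_SBML}}}model")
    model.set("id", "logical_network")
    comps = etree.SubElement(model, f"{{{_NS_SBML}}}listOfCompartments")
    comp = etree.SubElement(comps, f"{{{_NS_SBML}}}compartment")
    comp.set("id", "default")
    comp.set("constant", "true")
    species_list = etree.SubElement(model, _q("listOfQualitativeSpecies"))
    for n in net.nodes:
        sp = etree.SubElement(species_list, _q("qualitativeSpecies"))
        sp.set(_q("id"), n)
        sp.set(_q("compartment"), "default")
        sp.set(_q("constant"), "true" if n in net.externals else "false")
        sp.set(_q("maxLevel"), "1")
    transitions = etree.SubElement(model, _q("listOfTransitions"))
    for n in net.internals:
        tr = etree.SubElement(transitions, _q("transition"))
        tr.set(_q("id"), f"tr_{n}")
        inputs = etree.SubElement(tr, _q("listOfInputs"))
        for k, ref in enumerate(sorted(variables(net.rules[n]))):
            inp = etree.SubElement(inputs, _q("input"))
            inp.set(_q("id"), f"tr_{n}_in_{k}")
            inp.set(_q("qualitativeSpecies"), ref)
            inp.set(_q("transitionEffect"), "none")
        outputs = etree.SubElement(tr, _q("listOfOutputs"))
        out = etree.SubElement(outputs, _q("output"))
        out.set(_q("qualitativeSpecies"), n)
        out.set(_q("transitionEffect"), "assignmentLevel")
        fts = etree.SubElement(tr, _q("listOfFunctionTerms"))
        dt = etree.SubElement(fts, _q("defaultTerm"))
        dt.set(_q("resultLevel"), "0")
        ft = etree.SubElement(fts, _q("functionTerm"))
        ft.set(_q("resultLevel"), "1")
        math = etree.SubElement(ft, _m("math"))
        _expr_to_mathml(net.rules[n], math)
    tree = etree.ElementTree(sbml)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)


def _mathml_to_expr(el: etree._Element, node: str) -> Expr:
    from .logic import And, Const, Not, Or, Var
    tag = etree.QName(el).localname
    if tag == "math":
        children = [c for c in el if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SbmlQualError(
                f"transition for {node!r}: expected a single math child")
        return _mathml_to_expr(children[0], node)
    if tag == "ci":
        return Var(el.text.strip())
    if tag == "true":
        return Const(True)
    if tag == "false":
        return Const(False)
    if tag != "apply":
        raise SbmlQualError(
            f"transition for {node!r}: unsupported MathML element <{tag}>")
    children = [c for c in el if isinstance(c.tag, str)]
    if not children:
        raise SbmlQualError(f"transition for {node!r}: empty <apply>")
    op = etree.QName(children[0]).localname
    args = children[1:]
    if op == "eq":
        if len(args) != 2:
            raise SbmlQualError(f"transition for {node!r}: <eq> needs 2 operands")
        ci, cn = args
        if etree.QName(ci).localname != "ci" or etree.QName(cn).localname != "cn":
            raise SbmlQualError(
                f"transition for {node!r}: only '<ci> eq <cn>' comparisons "
                "are supported")
        level = int(float(cn.text.strip()))
        if level not in (0, 1):
            raise SbmlQualError(
                f"transition for {node!r}: comparison against level {level} "
                "(only Boolean levels 0/1 supported)")
        var = Var(ci.text.strip())
        return var if level == 1 else Not(var)
    if op == "not":
        if len(args) != 1:
            raise SbmlQualError(f"transition for {node!r}: <not> needs 1 operand")
        return Not(_mathml_to_expr(args[0], node))
    if op in ("and", "or"):
        parts = tuple(_mathml_to_expr(a, node) for a in args)
        if len(parts) == 1:
            return parts[0]
        return And(parts) if op == "and" else Or(parts)
    raise SbmlQualError(
        f"transition for {node!r}: unsupported MathML operator <{op}>")


def read_sbml_qual(path: str | Path) -> LogicalNetwork:
    """Import a Boolean SBML-qual document."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    model = root.find(f"{{{_NS_SBML}}}model")
    if model is None:
        raise SbmlQualError("document has no <model>")
    nodes: list[str] = []
    constant: dict[str, bool] = {}
    sp_list = model.find(_q("listOfQualitativeSpecies"))
    if sp_list is None:
        raise SbmlQualError("model has no qualitative species")
    for sp in sp_list.findall(_q("qualitativeSpecies")):
        name = sp.get(_q("id"))
        max_level = sp.get(_q("maxLevel"))
        if max_level is not None and int(max_level) > 1:
            raise SbmlQualError(
                f"species {name!r} has maxLevel={max_level}; only Boolean "
                "(maxLevel=1) models are supported")
        nodes.append(name)
        constant[name] = sp.get(_q("constant"), "false") == "true"
    rules: dict[str, Expr] = {}
    tr_list = model.find(_q("listOfTransitions"))
    if tr_list is not None:
        for tr in tr_list.findall(_q("transition")):
            outs = tr.find(_q("listOfOutputs"))
            if outs is None:
                raise SbmlQualError("transition without outputs")
            out_nodes = [o.get(_q("qualitativeSpecies"))
                         for o in outs.findall(_q("output"))]
            fts = tr.find(_q("listOfFunctionTerms"))
            if fts is None:
                raise SbmlQualError("transition without function terms")
            expr: Expr | None = None
            for ft in fts.findall(_q("functionTerm")):
                if ft.get(_q("resultLevel")) != "1":
                    raise SbmlQualError(
                        "only resultLevel=1 function terms are supported")
                math = ft.find(_m("math"))
                if math is None:
                    raise SbmlQualError("functionTerm without <math>")
                expr = _mathml_to_expr(math, out_nodes[0])
            if expr is None:
                raise SbmlQualError(
                    f"transition for {out_nodes} has no ON function term")
            for target in out_nodes:
                if target in rules:
                    raise SbmlQualError(f"duplicate transition for {target!r}")
                rules[target] = expr
    externals = frozenset(n for n in nodes
                          if constant.get(n, False) or n not in rules)
    return LogicalNetwork(tuple(nodes), externals, rules)


# ---------------------------------------------------------------------------
# Result tables


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_results_tsv(frame, path: str | Path, *, seed: int | None = None,
                      model: LogicalNetwork | None = None,
                      extra: Mapping[str, str] | None = None) -> None:
    """Write a result table as TSV with a provenance comment header."""
    from . import __version__
    header = [f"# tool: {_TOOL} {__version__}"]
    if seed is not None:
        header.append(f"# seed: {seed}")
    if model is not None:
        header.append(f"# model_hash: {model_hash(model)}")
    for k, v in (extra or {}).items():
        header.append(f"# {k}: {v}")
    buf = _io.StringIO()
    frame = frame.reset_index() if frame.index.name else frame
    buf.write("\t".join(map(str, frame.columns)) + "\n")
    for _, row in frame.iterrows():
        buf.write("\t".join(_fmt(v) for v in row) + "\n")
    Path(path).write_text("\n".join(header) + "\n" + buf.getvalue(),
                          encoding="utf-8", newline="\n")


def read_results_tsv(path: str | Path):
    import pandas as pd
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Scenario documents (YAML/JSON)


def scenario_to_dict(scenario) -> dict:
    return {
        "name": scenario.name,
        "env": {k: list(v) for k, v in scenario.env.items()},
        "mutations": dict(scenario.mutations),
        "outputs": list(scenario.outputs),
        "sweep": scenario.sweep,
        "config": dict(scenario.config),
        "variants": {k: {n: list(iv) for n, iv in v.items()}
                     for k, v in scenario.variants.items()},
    }


def scenario_from_dict(d: Mapping) -> "Scenario":
    from .experiments import Scenario
    return Scenario(
        name=d.get("name", "scenario"),
        env=EnvironmentSpec({k: tuple(v) if not isinstance(v, (int, float))
                             else v for k, v in d.get("env", {}).items()}),
        mutations=dict(d.get("mutations", {})),
        outputs=tuple(d.get("outputs", ())),
        sweep=d.get("sweep"),
        config=dict(d.get("config", {})),
        variants={k: {n: tuple(iv) for n, iv in v.items()}
                  for k, v in d.get("variants", {}).items()})


def read_scenario_file(path: str | Path):
    import yaml
    with open(path, "r", encoding="utf-8") as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def write_scenario_file(scenario, path: str | Path) -> None:
    import yaml
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)
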
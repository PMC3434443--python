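"""Serialization: bnet rule files, trace CSV, and statechart exports.

The on-disk model format is a BoolNet-style rule file: a ``targets,
factors`` header, then one line per component giving its next-state
formula with ``&``, ``|``, ``!`` and parentheses (constants ``0``/``1``
are accepted).  The dialect has no native notion of an exogenous input,
so an independent component X is written as the self-holding rule
``X, X`` plus a marker comment ``# independent: X``; signal components
get a ``# signal: <name>`` marker so kinds survive a round-trip.

Traces are written as wide CSV (``t`` column plus one 0/1 column per
component in model order).  Statechart structure can be exported as
Graphviz DOT (one cluster per component, two nodes, guard-labeled edges)
or SCXML (one ``<parallel>`` root, one two-state machine per component,
guards as transition conditions); both exports are write-only.
"""

from __future__ import annotations

import io as _stdio
import re
import xml.etree.ElementTree as ET

import pandas as pd

from .logic import And, BooleanFormula, Const, Lit, Not, Or, FALSE, TRUE
from .model import (
    Component,
    MotifModel,
    make_model,
    make_rule_from_next_state,
)
from .simulate import Trace

__all__ = [
    "BnetParseError",
    "formula_to_str",
    "parse_formula",
    "write_bnet",
    "read_bnet",
    "write_trace_csv",
    "read_trace_csv",
    "export_statechart",
]


class BnetParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)
        self.line = line


# --- formula concrete syntax -------------------------------------------------
# precedence: ! > & > |

def formula_to_str(formula: BooleanFormula) -> str:
    """Render a formula in the ``&``/``|``/``!`` concrete syntax."""

    def render(f: BooleanFormula, parent: str) -> str:
        if isinstance(f, Lit):
            return f.component if f.present else f"!{f.component}"
        if isinstance(f, Const):
            return "1" if f.value else "0"
        if isinstance(f, Not):
            if isinstance(f.operand, (And, Or)):
                return f"!({render(f.operand, 'top')})"
            return f"!{render(f.operand, '!')}"
        if isinstance(f, And):
            s = " & ".join(render(op, "&") for op in f.operands)
            return f"({s})" if parent == "!" else s
        if isinstance(f, Or):
            s = " | ".join(render(op, "|") for op in f.operands)
            return f"({s})" if parent in ("!", "&") else s
        raise TypeError(f"not a formula node: {f!r}")

    return render(formula, "top")


_TOKEN_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*|[01&|!()]")


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise BnetParseError(f"unexpected character {text[pos]!r} in formula")
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


def parse_formula(text: str) -> BooleanFormula:
    """Parse the ``&``/``|``/``!`` syntax into a formula tree."""
    tokens = _tokenize(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> BooleanFormula:
        terms = [parse_and()]
        while peek() == "|":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and() -> BooleanFormula:
        factors = [parse_unary()]
        while peek() == "&":
            take()
            factors.append(parse_unary())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_unary() -> BooleanFormula:
        tok = peek()
        if tok is None:
            raise BnetParseError("unexpected end of formula")
        if tok == "!":
            take()
            operand = parse_unary()
            if isinstance(operand, Lit):
                return Lit(operand.component, not operand.present)
            return Not(operand)
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise BnetParseError("missing closing parenthesis")
            take()
            return inner
        if tok == "0":
            take()
            return FALSE
        if tok == "1":
            take()
            return TRUE
        if re.match(r"^[A-Za-z_]", tok):
            take()
            return Lit(tok)
        raise BnetParseError(f"unexpected token {tok!r}")

    if not tokens:
        raise BnetParseError("empty formula")
    result = parse_or()
    if pos != len(tokens):
        raise BnetParseError(f"trailing tokens after formula: {tokens[pos:]!r}")
    return result


# --- bnet model files --------------------------------------------------------

def write_bnet(model: MotifModel) -> str:
    """Serialize a validated model in the bnet dialect."""
    lines = []
    if model.name:
        lines.append(f"# model: {model.name}")
    if model.description:
        lines.append(f"# description: {model.description}")
    for comp in model.components:
        if comp.independent:
            lines.append(f"# independent: {comp.name}")
        if comp.kind == "signal":
            lines.append(f"# signal: {comp.name}")
    lines.append("targets, factors")
    for comp in model.components:
        if comp.rule is None:
            lines.append(f"{comp.name}, {comp.name}")
        else:
            lines.append(f"{comp.name}, {formula_to_str(comp.rule.on_guard)}")
    return "\n".join(lines) + "\n"


def read_bnet(text: str) -> MotifModel:
    """Parse the bnet dialect back into a validated model.

    Components carrying an ``# independent:`` marker get no rule; all
    others get the canonical rule pair for their parsed next-state
    formula.  Validation errors from model construction propagate.
    """
    independents: set[str] = set()
    signals: set[str] = set()
    name = ""
    description = ""
    rules: list[tuple[str, str, int]] = []  # (target, formula text, line no)
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("independent:"):
                independents.add(body.split(":", 1)[1].strip())
            elif body.startswith("signal:"):
                signals.add(body.split(":", 1)[1].strip())
            elif body.startswith("model:"):
                name = body.split(":", 1)[1].strip()
            elif body.startswith("description:"):
                description = body.split(":", 1)[1].strip()
            continue
        if re.match(r"^targets\s*,\s*factors$", line, flags=re.IGNORECASE):
            header_seen = True
            continue
        if "," not in line:
            raise BnetParseError(
                f"expected '<target>, <formula>' but found {line!r}", line=lineno
            )
        target, formula_text = line.split(",", 1)
        target = target.strip()
        if not re.match(r"^[A-Za-z_][A-Za-z0-9_]*$", target):
            raise BnetParseError(f"invalid target name {target!r}", line=lineno)
        rules.append((target, formula_text.strip(), lineno))
    if not rules:
        raise BnetParseError("no rule lines found" + ("" if header_seen else " (and no header)"))
    components = []
    for target, formula_text, lineno in rules:
        kind = "signal" if target in signals else "gene"
        if target in independents:
            components.append(Component(target, kind=kind))
            continue
        try:
            f = parse_formula(formula_text)
        except BnetParseError as exc:
            raise BnetParseError(str(exc), line=lineno) from None
        components.append(Component(target, kind=kind, rule=make_rule_from_next_state(f)))
    return make_model(components, name=name, description=description)


# --- trace CSV ---------------------------------------------------------------

def write_trace_csv(trace: Trace) -> str:
    """Trace as CSV text: header ``t,<components>``, one row per instant."""
    return trace.to_dataframe().to_csv(index=False)


def read_trace_csv(text: str, model_name: str = "") -> Trace:
    """Read a trace CSV produced by :func:`write_trace_csv`."""
    df = pd.read_csv(_stdio.StringIO(text))
    if "t" not in df.columns:
        raise ValueError("trace CSV needs a 't' column")
    components = tuple(c for c in df.columns if c != "t")
    times = df["t"].tolist()
    configs = tuple(
        {c: int(row[c]) for c in components} for _, row in df.iterrows()
    )
    return Trace(
        model_name=model_name,
        components=components,
        configs=configs,
        start=int(times[0]) if times else 0,
    )


# --- statechart structure exports -------------------------------------------

def export_statechart(model: MotifModel, format: str = "dot") -> str:
    """Export the statechart structure as DOT or SCXML text.

    DOT: one cluster per component with nodes ``<name>=0``/``<name>=1``
    and, for regulated components, two edges labeled with the guards.
    SCXML: a single ``<parallel>`` containing one two-state machine per
    component, guards carried in the transitions' ``cond`` attribute.
    """
    if format == "dot":
        return _export_dot(model)
    if format == "scxml":
        return _export_scxml(model)
    raise ValueError(f"unknown export format {format!r}; expected 'dot' or 'scxml'")


def _export_dot(model: MotifModel) -> str:
    out = [f'digraph "{model.name or "motif"}" {{', "  compound=true;", "  rankdir=LR;"]
    for i, comp in enumerate(model.components):
        out.append(f"  subgraph cluster_{i} {{")
        out.append(f'    label="{comp.name}";')
        out.append(f'    "{comp.name}=0" [label="off"];')
        out.append(f'    "{comp.name}=1" [label="on"];')
        if comp.rule is not None:
            on = formula_to_str(comp.rule.on_guard).replace('"', r"\"")
            off = formula_to_str(comp.rule.off_guard).replace('"', r"\"")
            out.append(f'    "{comp.name}=0" -> "{comp.name}=1" [label="{on}"];')
            out.append(f'    "{comp.name}=1" -> "{comp.name}=0" [label="{off}"];')
        out.append("  }")
    out.append("}")
    return "\n".join(out) + "\n"


def _export_scxml(model: MotifModel) -> str:
    ns = "http://www.w3.org/2005/07/scxml"
    root = ET.Element(
        "scxml",
        {"xmlns": ns, "version": "1.0", "initial": "motif"},
    )
    parallel = ET.SubElement(root, "parallel", {"id": "motif"})
    for comp in model.components:
        machine = ET.SubElement(
            parallel, "state", {"id": comp.name, "initial": f"{comp.name}_off"}
        )
        off = ET.SubElement(machine, "state", {"id": f"{comp.name}_off"})
        on = ET.SubElement(machine, "state", {"id": f"{comp.name}_on"})
        if comp.rule is not None:
            ET.SubElement(
                off,
                "transition",
                {
                    "target": f"{comp.name}_on",
                    "cond": formula_to_str(comp.rule.on_guard),
                },
            )
            ET.SubElement(
                on,
                "transition",
                {
                    "target": f"{comp.name}_off",
                    "cond": formula_to_str(comp.rule.off_guard),
                },
            )
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"
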
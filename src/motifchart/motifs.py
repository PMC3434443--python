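"""Builders for the motif catalogue.

Every builder returns a validated :class:`~motifchart.model.MotifModel`
over the canonical component names X, S_X, Y, S_Y, Z.  Gene X and all
signals are independent; regulated genes get their rule from the stated
next-state function via :func:`make_rule_from_next_state`.

Catalogue
---------
* simple regulation s1..s4 — X regulates Y, mediated by signal S_X;
  coherent (s1: activation in presence of S_X, s2: repression in absence)
  or incoherent (s3: repression in presence, s4: activation in absence).
  The s2/s4 functions are inferred from the motif definitions (the source
  diagrams print them only graphically); see docs/methods.md.
* feedback loops — X and Y regulate each other through S_X/S_Y:
  double-positive (mutual activation), double-negative (mutual
  repression), negative (Y activates X, X represses Y).
* feedforward loops c1/i1 — X regulates Y and Z, Y regulates Z; the two
  regulations on Z are combined with an AND or OR gate.
* autoregulation — Y regulates itself, positive (lock-in) or negative
  (alternation), optionally gated by an additional activating gene X.
"""

from __future__ import annotations

from enum import Enum

from .logic import And, BooleanFormula, Lit, Not, Or
from .model import Component, MotifModel, make_model, make_rule_from_next_state

__all__ = [
    "GateLogic",
    "build_simple_regulation",
    "build_feedback",
    "build_ffl",
    "build_autoregulation",
    "MOTIF_BUILDERS",
    "build_named",
]


class GateLogic(str, Enum):
    """How the two regulations converging on the FFL output gene combine."""

    AND = "AND"
    OR = "OR"


def _gene(name: str, next_state: BooleanFormula | None = None) -> Component:
    rule = None if next_state is None else make_rule_from_next_state(next_state)
    return Component(name, kind="gene", rule=rule)


def _signal(name: str) -> Component:
    return Component(name, kind="signal")


X, S_X, Y, S_Y = Lit("X"), Lit("S_X"), Lit("Y"), Lit("S_Y")

_SIMPLE_NEXT_Y: dict[str, BooleanFormula] = {
    # coherent: activation of Y in presence of S_X
    "s1": And((X, S_X)),
    # coherent: repression of Y in absence of S_X (Y driven off exactly
    # when X is present without its signal)
    "s2": Not(And((X, Not(S_X)))),
    # incoherent: repression of Y in presence of S_X
    "s3": Not(And((X, S_X))),
    # incoherent: activation of Y in absence of S_X
    "s4": And((X, Not(S_X))),
}


def build_simple_regulation(variant: str) -> MotifModel:
    """Simple regulation of Y by X mediated by S_X; variant in s1..s4."""
    try:
        next_y = _SIMPLE_NEXT_Y[variant]
    except KeyError:
        raise ValueError(
            f"unknown simple-regulation variant {variant!r}; expected one of "
            f"{sorted(_SIMPLE_NEXT_Y)}"
        ) from None
    return make_model(
        [_gene("X"), _signal("S_X"), _gene("Y", next_y)],
        name=f"simple-{variant}",
        description=f"simple regulation motif {variant}",
    )


_FEEDBACK_NEXT: dict[str, tuple[BooleanFormula, BooleanFormula]] = {
    # (next_X, next_Y)
    "double_positive": (And((Y, S_Y)), And((X, S_X))),
    "double_negative": (Not(And((Y, S_Y))), Not(And((X, S_X)))),
    "negative": (And((Y, S_Y)), Not(And((X, S_X)))),
}


def build_feedback(variant: str) -> MotifModel:
    """Feedback loop between X and Y, both regulated, signals independent.

    ``double_positive``: mutual activation; ``double_negative``: mutual
    repression; ``negative``: Y activates X, X represses Y.
    """
    try:
        next_x, next_y = _FEEDBACK_NEXT[variant]
    except KeyError:
        raise ValueError(
            f"unknown feedback variant {variant!r}; expected one of "
            f"{sorted(_FEEDBACK_NEXT)}"
        ) from None
    return make_model(
        [_gene("X", next_x), _signal("S_X"), _gene("Y", next_y), _signal("S_Y")],
        name=f"feedback-{variant}",
        description=f"{variant.replace('_', '-')} feedback loop motif",
    )


def build_ffl(variant: str, gate: GateLogic = GateLogic.AND) -> MotifModel:
    """Type-1 feedforward loop: X regulates Y and Z, Y regulates Z.

    The two input branches of Z are the active-regulator terms X∧S_X and
    Y∧S_Y (the Y branch negated for the incoherent variant); ``gate``
    selects whether they are combined with AND or OR.
    """
    gate = GateLogic(gate)
    x_branch: BooleanFormula = And((X, S_X))
    if variant == "c1":
        y_branch: BooleanFormula = And((Y, S_Y))
    elif variant == "i1":
        y_branch = Not(And((Y, S_Y)))
    else:
        raise ValueError(f"unknown FFL variant {variant!r}; expected 'c1' or 'i1'")
    combine = And if gate is GateLogic.AND else Or
    next_z = combine((x_branch, y_branch))
    return make_model(
        [
            _gene("X"),
            _signal("S_X"),
            _gene("Y", And((X, S_X))),
            _signal("S_Y"),
            _gene("Z", next_z),
        ],
        name=f"ffl-{variant}-{gate.value.lower()}",
        description=f"{variant} feedforward loop motif, {gate.value} gate on Z",
    )


def build_autoregulation(
    sign: str, with_activator: bool = False, *, signal_gated: bool = False
) -> MotifModel:
    """Autoregulation of Y: positive (next Y = Y) or negative (next Y = ~Y).

    With ``with_activator`` an independent activating gene X is AND-ed into
    Y's rule; ``signal_gated`` additionally mediates X's action through an
    independent signal S_X (off by default — the plain activator form is
    the one in the catalogue).
    """
    if sign not in ("positive", "negative"):
        raise ValueError(
            f"unknown autoregulation sign {sign!r}; expected 'positive' or 'negative'"
        )
    self_term: BooleanFormula = Y if sign == "positive" else Not(Y)
    if not with_activator:
        return make_model(
            [_gene("Y", self_term)],
            name=f"autoreg-{sign}",
            description=f"{sign} autoregulation motif",
        )
    activator: BooleanFormula = And((X, S_X)) if signal_gated else X
    components = [_gene("X")]
    if signal_gated:
        components.append(_signal("S_X"))
    components.append(_gene("Y", And((activator, self_term))))
    return make_model(
        components,
        name=f"autoreg-{sign}-activated",
        description=f"{sign} autoregulation motif with activating gene X",
    )


# Canonical names used by the CLI and by exhaustive property tests.
MOTIF_BUILDERS = {
    "simple-s1": lambda: build_simple_regulation("s1"),
    "simple-s2": lambda: build_simple_regulation("s2"),
    "simple-s3": lambda: build_simple_regulation("s3"),
    "simple-s4": lambda: build_simple_regulation("s4"),
    "feedback-dp": lambda: build_feedback("double_positive"),
    "feedback-dn": lambda: build_feedback("double_negative"),
    "feedback-neg": lambda: build_feedback("negative"),
    "ffl-c1": lambda: build_ffl("c1", GateLogic.AND),
    "ffl-c1-or": lambda: build_ffl("c1", GateLogic.OR),
    "ffl-i1": lambda: build_ffl("i1", GateLogic.AND),
    "ffl-i1-or": lambda: build_ffl("i1", GateLogic.OR),
    "autoreg-pos": lambda: build_autoregulation("positive"),
    "autoreg-neg": lambda: build_autoregulation("negative"),
    "autoreg-pos-act": lambda: build_autoregulation("positive", with_activator=True),
    "autoreg-neg-act": lambda: build_autoregulation("negative", with_activator=True),
}


def build_named(name: str) -> MotifModel:
    """Build a catalogue motif by its canonical CLI name."""
    try:
        return MOTIF_BUILDERS[name]()
    except KeyError:
        raise ValueError(
            f"unknown motif {name!r}; available: {', '.join(sorted(MOTIF_BUILDERS))}"
        ) from None
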
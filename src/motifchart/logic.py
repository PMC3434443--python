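"""Boolean guard formulas over gene/signal presence states.

Transitions of the statechart models are guarded by propositional formulas
over the on/off state of the network's components: a literal ``X`` is true
when component X is present (on), and ``~X`` (the over-barred literal) when
it is absent.  Formulas are immutable trees; evaluation is against a
*configuration*, a total map from component names to {0, 1}.

The language is deliberately small: literals, negation, n-ary conjunction
and disjunction, and the two constants.  State spaces in this package never
exceed a few dozen states, so there is no normal-form machinery here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Union

__all__ = [
    "BooleanFormula",
    "Lit",
    "Not",
    "And",
    "Or",
    "Const",
    "TRUE",
    "FALSE",
    "UnknownComponentError",
    "eval_formula",
    "negate",
    "variables_of",
]

Configuration = Mapping[str, int]

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class UnknownComponentError(KeyError):
    """A formula references a component the configuration does not assign."""

    def __init__(self, component: str):
        super().__init__(component)
        self.component = component

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"configuration does not assign component {self.component!r}"


@dataclass(frozen=True)
class BooleanFormula:
    """Base class for all formula nodes."""

    def __and__(self, other: "BooleanFormula") -> "And":
        return And((self, other))

    def __or__(self, other: "BooleanFormula") -> "Or":
        return Or((self, other))

    def __invert__(self) -> "BooleanFormula":
        return negate(self)


@dataclass(frozen=True)
class Lit(BooleanFormula):
    """Presence (``present=True``) or absence literal for one component."""

    component: str
    present: bool = True

    def __post_init__(self) -> None:
        if not _NAME_RE.match(self.component):
            raise ValueError(f"invalid component name: {self.component!r}")


@dataclass(frozen=True)
class Not(BooleanFormula):
    operand: BooleanFormula


@dataclass(frozen=True)
class And(BooleanFormula):
    operands: tuple[BooleanFormula, ...]

    def __post_init__(self) -> None:
        if len(self.operands) < 2:
            raise ValueError("conjunction requires at least two operands")


@dataclass(frozen=True)
class Or(BooleanFormula):
    operands: tuple[BooleanFormula, ...]

    def __post_init__(self) -> None:
        if len(self.operands) < 2:
            raise ValueError("disjunction requires at least two operands")


@dataclass(frozen=True)
class Const(BooleanFormula):
    value: bool


TRUE = Const(True)
FALSE = Const(False)


def eval_formula(formula: BooleanFormula, config: Configuration) -> bool:
    """Evaluate ``formula`` under the total assignment ``config``.

    Standard boolean semantics; a presence literal for component ``c`` is
    true iff ``config[c] == 1``, an absence literal iff ``config[c] == 0``.

    Raises
    ------
    UnknownComponentError
        If the formula names a component ``config`` does not assign.
    """
    if isinstance(formula, Lit):
        try:
            value = config[formula.component]
        except KeyError:
            raise UnknownComponentError(formula.component) from None
        return bool(value) if formula.present else not value
    if isinstance(formula, Const):
        return formula.value
    if isinstance(formula, Not):
        return not eval_formula(formula.operand, config)
    if isinstance(formula, And):
        return all(eval_formula(f, config) for f in formula.operands)
    if isinstance(formula, Or):
        return any(eval_formula(f, config) for f in formula.operands)
    raise TypeError(f"not a formula node: {formula!r}")


def negate(formula: BooleanFormula) -> BooleanFormula:
    """Structural complement of ``formula``.

    Negation is pushed through the tree (De Morgan), flipping literal
    polarity at the leaves, so the result stays readable when serialized
    as an off-guard.  Extensionally, ``eval_formula(negate(f), c)`` is
    ``not eval_formula(f, c)`` on every total configuration.
    """
    if isinstance(formula, Lit):
        return Lit(formula.component, not formula.present)
    if isinstance(formula, Const):
        return Const(not formula.value)
    if isinstance(formula, Not):
        return formula.operand
    if isinstance(formula, And):
        return Or(tuple(negate(f) for f in formula.operands))
    if isinstance(formula, Or):
        return And(tuple(negate(f) for f in formula.operands))
    raise TypeError(f"not a formula node: {formula!r}")


def variables_of(formula: BooleanFormula) -> frozenset[str]:
    """The set of component names occurring in literals of ``formula``."""
    if isinstance(formula, Lit):
        return frozenset({formula.component})
    if isinstance(formula, Const):
        return frozenset()
    if isinstance(formula, Not):
        return variables_of(formula.operand)
    if isinstance(formula, (And, Or)):
        out: frozenset[str] = frozenset()
        for f in formula.operands:
            out |= variables_of(f)
        return out
    raise TypeError(f"not a formula node: {formula!r}")
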
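"""Statechart-restricted motif models.

A motif model is one parallel composite of two-state (off/on) machines,
one per component (gene or signal).  A *regulated* component carries an
update rule: a pair of guard formulas for its off->on and on->off
transitions.  A component without a rule is *independent*: nothing inside
the motif changes it, only externally supplied input events do.

The two guards of a rule must be mutually exclusive and jointly exhaustive
(``off_guard`` extensionally equal to the complement of ``on_guard``), so
the synchronous dynamics is a deterministic boolean network.  A validated
model is value-like: nothing in the package mutates it afterwards.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal as TypingLiteral, Optional

from .logic import (
    BooleanFormula,
    eval_formula,
    negate,
    variables_of,
)

__all__ = [
    "Component",
    "UpdateRule",
    "MotifModel",
    "ModelValidationError",
    "DuplicateComponentError",
    "DanglingVariableError",
    "GuardOverlapError",
    "GuardGapError",
    "make_model",
    "make_rule_from_next_state",
    "state_space_size",
]


class ModelValidationError(ValueError):
    """Base class for model construction failures."""


class DuplicateComponentError(ModelValidationError):
    def __init__(self, name: str):
        super().__init__(f"duplicate component name: {name!r}")
        self.name = name


class DanglingVariableError(ModelValidationError):
    def __init__(self, component: str, variable: str):
        super().__init__(
            f"guard of component {component!r} references undeclared "
            f"component {variable!r}"
        )
        self.component = component
        self.variable = variable


class GuardOverlapError(ModelValidationError):
    def __init__(self, component: str, witness: dict[str, int]):
        super().__init__(
            f"on/off guards of component {component!r} are both true "
            f"on assignment {witness!r}"
        )
        self.component = component
        self.witness = witness


class GuardGapError(ModelValidationError):
    def __init__(self, component: str, witness: dict[str, int]):
        super().__init__(
            f"on/off guards of component {component!r} are both false "
            f"on assignment {witness!r}"
        )
        self.component = component
        self.witness = witness


@dataclass(frozen=True)
class UpdateRule:
    """Guard pair of a regulated component.

    ``on_guard`` triggers the off->on transition, ``off_guard`` the
    on->off transition.  For the shipped motifs ``off_guard`` is always
    the complement of ``on_guard`` (see :func:`make_rule_from_next_state`).
    """

    on_guard: BooleanFormula
    off_guard: BooleanFormula

    def variables(self) -> frozenset[str]:
        return variables_of(self.on_guard) | variables_of(self.off_guard)


@dataclass(frozen=True)
class Component:
    """One two-state machine of the parallel composition.

    ``rule is None`` marks the component as independent — the statechart
    draws no transitions for it, and its state changes only through input
    schedule events.
    """

    name: str
    kind: TypingLiteral["gene", "signal"] = "gene"
    rule: Optional[UpdateRule] = None

    @property
    def independent(self) -> bool:
        return self.rule is None


@dataclass(frozen=True)
class MotifModel:
    """A validated motif: ordered components plus metadata.

    Component order is significant: it fixes trace column order and the
    lexicographic order used to canonicalize attractors.  Construct via
    :func:`make_model`, which enforces all invariants.
    """

    components: tuple[Component, ...]
    name: str = ""
    description: str = ""

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    def component(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def independent_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components if c.independent)

    def regulated_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components if not c.independent)


def _check_guard_pair(
    name: str, rule: UpdateRule, *, allow_partial: bool
) -> None:
    """Exhaustively check exclusivity (always) and exhaustiveness (unless partial).

    Overlaps are searched first: a simultaneous firing of both guards is the
    worse defect (it would make the dynamics nondeterministic), so it is the
    one reported when a rule has both kinds of violation.
    """
    variables = sorted(rule.variables())
    gap_witness: dict[str, int] | None = None
    for bits in itertools.product((0, 1), repeat=len(variables)):
        assignment = dict(zip(variables, bits))
        on = eval_formula(rule.on_guard, assignment)
        off = eval_formula(rule.off_guard, assignment)
        if on and off:
            raise GuardOverlapError(name, assignment)
        if not on and not off and gap_witness is None:
            gap_witness = assignment
    if gap_witness is not None and not allow_partial:
        raise GuardGapError(name, gap_witness)


def make_model(
    components: Iterable[Component],
    name: str = "",
    description: str = "",
    *,
    allow_partial: bool = False,
) -> MotifModel:
    """Build and validate a :class:`MotifModel`.

    Validation enforces: unique component names, at least one component,
    no guard referencing an undeclared component, and for each rule that
    the two guards never hold together and (unless ``allow_partial``)
    cover every assignment.  With ``allow_partial=True`` a gap is legal
    and the component holds its state when neither guard fires; an
    overlap is a hard error in either mode, since it would make the
    dynamics nondeterministic.
    """
    comps = tuple(components)
    if not comps:
        raise ModelValidationError("a model needs at least one component")
    seen: set[str] = set()
    for c in comps:
        if c.name in seen:
            raise DuplicateComponentError(c.name)
        seen.add(c.name)
    for c in comps:
        if c.rule is None:
            continue
        for var in sorted(c.rule.variables()):
            if var not in seen:
                raise DanglingVariableError(c.name, var)
        _check_guard_pair(c.name, c.rule, allow_partial=allow_partial)
    return MotifModel(components=comps, name=name, description=description)


def make_rule_from_next_state(f: BooleanFormula) -> UpdateRule:
    """Canonical rule for next-state function ``f``: on-guard ``f``,
    off-guard its complement.  Satisfies the exclusivity/exhaustiveness
    invariant by construction."""
    return UpdateRule(on_guard=f, off_guard=negate(f))


def state_space_size(model: MotifModel) -> int:
    """2**(number of components)."""
    return 2 ** len(model.components)
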
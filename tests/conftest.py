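"""Shared test plumbing: next-state tables and a random-model generator."""

from __future__ import annotations

import itertools
import random

from motifchart import (
    And,
    BooleanFormula,
    Component,
    Lit,
    MotifModel,
    Not,
    Or,
    eval_formula,
    make_model,
    make_rule_from_next_state,
)


def next_state_table(model: MotifModel) -> dict[str, tuple[int, ...]]:
    """Per-component truth table of the next-state function.

    For each regulated component: its next value on every assignment of
    *all* model components (in component order); independent components
    map to the identity column.  Two models with equal component tuples
    and equal tables have identical synchronous dynamics.
    """
    names = model.component_names
    table: dict[str, tuple[int, ...]] = {}
    assignments = [
        dict(zip(names, bits))
        for bits in itertools.product((0, 1), repeat=len(names))
    ]
    for comp in model.components:
        if comp.rule is None:
            table[comp.name] = tuple(a[comp.name] for a in assignments)
        else:
            table[comp.name] = tuple(
                int(eval_formula(comp.rule.on_guard, a)) for a in assignments
            )
    return table


def random_formula(rng: random.Random, names: list[str], depth: int = 2) -> BooleanFormula:
    if depth == 0 or rng.random() < 0.4:
        return Lit(rng.choice(names), present=rng.random() < 0.7)
    kind = rng.choice(["and", "or", "not"])
    if kind == "not":
        return Not(random_formula(rng, names, depth - 1))
    arity = rng.choice([2, 2, 3])
    op = And if kind == "and" else Or
    return op(tuple(random_formula(rng, names, depth - 1) for _ in range(arity)))


def random_model(rng: random.Random, n_components: int = 4) -> MotifModel:
    """A random valid model: first component independent, rest regulated."""
    names = [f"G{i}" for i in range(n_components)]
    components = [Component(names[0], kind="gene")]
    for name in names[1:]:
        f = random_formula(rng, names)
        components.append(
            Component(name, kind="gene", rule=make_rule_from_next_state(f))
        )
    return make_model(components, name=f"random-{rng.randint(0, 10**6)}")
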
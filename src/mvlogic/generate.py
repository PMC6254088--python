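"""Random fixture models for property testing.

Generated models have randomly sized activity ranges and random rule
expressions.  Row conditions for one component are made mutually
exclusive by construction with a priority encoding: the row targeting
level k is guarded by the negation of the guards of all higher-level
rows, so validation never rejects a generated model.  Every component
keeps a row targeting its maximal level, which keeps inferred maximal
levels stable across serialisation round trips.
"""
from __future__ import annotations

import random

from .model import (
    And,
    Component,
    Expr,
    FALSE,
    Lit,
    LogicalFunction,
    LogicalModel,
    Not,
    Or,
    TRUE,
    simplify,
)


def _random_expr(rng: random.Random, components, depth: int) -> Expr:
    """Random expression tree over the given components."""
    if depth <= 0 or rng.random() < 0.4:
        comp = rng.choice(components)
        lit = Lit(comp.name, rng.randint(1, comp.max_level))
        return Not(lit) if rng.random() < 0.4 else lit
    roll = rng.random()
    if roll < 0.1:
        return TRUE if rng.random() < 0.5 else FALSE
    op = And if roll < 0.55 else Or
    width = rng.randint(2, 3)
    return op(_random_expr(rng, components, depth - 1) for _ in range(width))


def random_model(
    rng: random.Random,
    n_components: int = 4,
    max_level: int = 2,
    depth: int = 2,
) -> LogicalModel:
    """A random valid logical model with ``n_components`` components."""
    components = [
        Component(f"v{i}", rng.randint(1, max_level)) for i in range(n_components)
    ]
    functions = []
    for comp in components:
        guards = [
            _random_expr(rng, components, depth) for _ in range(comp.max_level)
        ]
        rows = []
        for level in range(comp.max_level, 0, -1):
            guard = guards[level - 1]
            higher = guards[level:]
            cond = guard if not higher else And([guard, Not(Or(higher))])
            rows.append((level, simplify(cond) if level < comp.max_level else cond))
        # keep a syntactic row at the maximal level (first in the list)
        functions.append(LogicalFunction(comp.name, rows))
    return LogicalModel(components, functions)


def random_boolean_model(
    rng: random.Random, n_components: int = 4, depth: int = 2
) -> LogicalModel:
    """A random Boolean model (all maximal levels 1)."""
    return random_model(rng, n_components=n_components, max_level=1, depth=depth)


def random_state(rng: random.Random, model: LogicalModel):
    return tuple(rng.randint(0, c.max_level) for c in model.components)
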
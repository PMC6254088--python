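"""Updating modes: successor policies over states.

Deterministic policies map a state to one successor (or none at a
stable state): synchronous, sequential, block-sequential, and
synchronous-priority.  Non-deterministic policies return a successor
set: asynchronous, complete, and priority classes with a per-class
synchronous/asynchronous mode.  Stochastic updating samples one
successor from a non-deterministic base, uniformly or with
per-component rates over an asynchronous base.

All policies share unit-step semantics: a called component moves one
level toward its target per transition.  A stable state has no
successor under any policy.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import (
    LogicalModel,
    ModelError,
    State,
    called_components,
    step_toward,
    target_value,
)


def _check_cover(model: LogicalModel, groups) -> None:
    flat = [i for g in groups for i in g]
    if sorted(flat) != list(range(len(model.components))):
        raise ModelError(
            "component groups must cover every component exactly once"
        )


# ---------------------------------------------------------------------------
# deterministic successors
# ---------------------------------------------------------------------------

def synchronous_successor(model: LogicalModel, state) -> State | None:
    """All called components step one unit simultaneously."""
    called = called_components(model, state)
    if not called:
        return None
    return tuple(
        step_toward(lv, target_value(model, state, i)) if i in called else lv
        for i, lv in enumerate(state)
    )


def sequential_successor(model: LogicalModel, state, order) -> State | None:
    """One pass over a fixed order, each rule evaluated on the evolving state."""
    _check_cover(model, [order])
    current = list(state)
    changed = False
    for i in order:
        t = target_value(model, current, i)
        if t != current[i]:
            current[i] = step_toward(current[i], t)
            changed = True
    return tuple(current) if changed else None


def block_sequential_successor(model: LogicalModel, state, blocks) -> State | None:
    """Ordered blocks; within a block, called components step simultaneously."""
    _check_cover(model, blocks)
    current = list(state)
    changed = False
    for block in blocks:
        targets = {i: target_value(model, current, i) for i in block}
        for i, t in targets.items():
            if t != current[i]:
                current[i] = step_toward(current[i], t)
                changed = True
    return tuple(current) if changed else None


def synchronous_priority_successor(model: LogicalModel, state, classes) -> State | None:
    """Only the first class containing a called component fires (synchronously)."""
    _check_cover(model, classes)
    called = called_components(model, state)
    if not called:
        return None
    for cls in classes:
        firing = [i for i in cls if i in called]
        if firing:
            current = list(state)
            for i in firing:
                current[i] = step_toward(state[i], target_value(model, state, i))
            return tuple(current)
    return None


# ---------------------------------------------------------------------------
# non-deterministic successors
# ---------------------------------------------------------------------------

def asynchronous_successors(model: LogicalModel, state) -> list[State]:
    """One successor per called component, in declaration order."""
    out = []
    for i in sorted(called_components(model, state)):
        current = list(state)
        current[i] = step_toward(state[i], target_value(model, state, i))
        out.append(tuple(current))
    return out


def complete_successors(model: LogicalModel, state) -> list[State]:
    """One successor per non-empty subset of the called set, deduplicated."""
    called = sorted(called_components(model, state))
    targets = {i: target_value(model, state, i) for i in called}
    out: list[State] = []
    seen: set[State] = set()
    for mask in range(1, 1 << len(called)):
        current = list(state)
        for bit, i in enumerate(called):
            if mask >> bit & 1:
                current[i] = step_toward(state[i], targets[i])
        succ = tuple(current)
        if succ not in seen:
            seen.add(succ)
            out.append(succ)
    return out


def priority_successors(model: LogicalModel, state, classes) -> list[State]:
    """First class with a called component fires in its own mode.

    ``classes`` is an ordered list of ``(component indices, mode)`` pairs
    forming a partition, with mode ``"synchronous"`` or ``"asynchronous"``.
    """
    _check_cover(model, [cls for cls, _ in classes])
    called = called_components(model, state)
    if not called:
        return []
    for cls, mode in classes:
        firing = sorted(i for i in cls if i in called)
        if not firing:
            continue
        if mode == "synchronous":
            current = list(state)
            for i in firing:
                current[i] = step_toward(state[i], target_value(model, state, i))
            return [tuple(current)]
        if mode == "asynchronous":
            out = []
            for i in firing:
                current = list(state)
                current[i] = step_toward(state[i], target_value(model, state, i))
                out.append(tuple(current))
            return out
        raise ModelError(f"unknown priority class mode: {mode}")
    return []


# ---------------------------------------------------------------------------
# updater policy objects
# ---------------------------------------------------------------------------

class DeterministicUpdater:
    def successor(self, model: LogicalModel, state) -> State | None:
        raise NotImplementedError


class MultiSuccessorUpdater:
    def successors(self, model: LogicalModel, state) -> list[State]:
        raise NotImplementedError


@dataclass
class Synchronous(DeterministicUpdater):
    def successor(self, model, state):
        return synchronous_successor(model, state)


@dataclass
class Sequential(DeterministicUpdater):
    order: tuple[int, ...] | None = None

    def successor(self, model, state):
        order = self.order if self.order is not None else range(len(model.components))
        return sequential_successor(model, state, list(order))


@dataclass
class BlockSequential(DeterministicUpdater):
    blocks: tuple

    def successor(self, model, state):
        return block_sequential_successor(model, state, self.blocks)


@dataclass
class SynchronousPriority(DeterministicUpdater):
    classes: tuple

    def successor(self, model, state):
        return synchronous_priority_successor(model, state, self.classes)


@dataclass
class Asynchronous(MultiSuccessorUpdater):
    def successors(self, model, state):
        return asynchronous_successors(model, state)


@dataclass
class Complete(MultiSuccessorUpdater):
    def successors(self, model, state):
        return complete_successors(model, state)


@dataclass
class PriorityClasses(MultiSuccessorUpdater):
    classes: tuple  # ordered (component indices, mode) pairs

    def successors(self, model, state):
        return priority_successors(model, state, self.classes)


@dataclass
class Stochastic:
    """Random successor selection over a non-deterministic base.

    Without weights the successor is uniform over the base updater's
    successor set.  With per-component positive rates (asynchronous base
    only), an asynchronous successor's probability is proportional to
    the rate of its stepped component.
    """

    base: MultiSuccessorUpdater = field(default_factory=Asynchronous)
    weights: dict[str, float] | None = None

    def __post_init__(self):
        if self.weights is not None:
            if not isinstance(self.base, Asynchronous):
                raise ModelError(
                    "per-component rates are only defined for the "
                    "asynchronous base updater"
                )
            if any(w <= 0 for w in self.weights.values()):
                raise ModelError("stochastic rates must be positive")


def random_successor(
    model: LogicalModel, state, updater: Stochastic, rng: random.Random
) -> State | None:
    """Sample one successor (None at a stable state); ``rng`` advances."""
    if updater.weights is not None:
        called = sorted(called_components(model, state))
        if not called:
            return None
        weights = [updater.weights.get(model.names[i], 1.0) for i in called]
        if any(w <= 0 for w in weights):
            raise ModelError("stochastic rates must be positive")
        i = rng.choices(called, weights=weights)[0]
        current = list(state)
        current[i] = step_toward(state[i], target_value(model, state, i))
        return tuple(current)
    successors = updater.base.successors(model, state)
    if not successors:
        return None
    return successors[rng.randrange(len(successors))]


# ---------------------------------------------------------------------------
# CLI updater selection strings
# ---------------------------------------------------------------------------

def _parse_name_classes(model: LogicalModel, text: str) -> list[list[int]]:
    """Parse ``[c1,c2][c3]`` into index classes."""
    if not text or text[0] != "[" or text[-1] != "]":
        raise ModelError(f"malformed class specification: {text!r}")
    classes = []
    for part in text[1:-1].split("]["):
        names = [n.strip() for n in part.split(",") if n.strip()]
        if not names:
            raise ModelError(f"empty class in specification: {text!r}")
        classes.append([model.index(n) for n in names])
    return classes


def parse_updater(model: LogicalModel, text: str, deterministic: bool):
    """Resolve a selection string such as ``synchronous`` or
    ``priority:[a,b][c]`` into an updater policy object."""
    text = text.strip()
    head, _, rest = text.partition(":")
    if deterministic:
        if head == "synchronous" and not rest:
            return Synchronous()
        if head == "sequential":
            if not rest:
                return Sequential()
            order = [model.index(n.strip()) for n in rest.split(",")]
            return Sequential(tuple(order))
        if head == "priority" and rest:
            classes = _parse_name_classes(model, rest)
            _check_cover(model, classes)
            return SynchronousPriority(tuple(tuple(c) for c in classes))
        raise ModelError(
            f"unknown deterministic updater: {text!r} "
            "(expected synchronous, sequential[:c1,c2,...] or priority:[c1,c2][c3])"
        )
    if head == "asynchronous" and not rest:
        return Asynchronous()
    if head == "complete" and not rest:
        return Complete()
    if head == "priority" and rest:
        classes = _parse_name_classes(model, rest)
        _check_cover(model, classes)
        return PriorityClasses(tuple((tuple(c), "asynchronous") for c in classes))
    raise ModelError(
        f"unknown updater: {text!r} "
        "(expected asynchronous, complete or priority:[c1,c2][c3])"
    )
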
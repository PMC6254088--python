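"""Model-to-model transformations: perturbations, reduction, booleanization.

Perturbations emulate biological mutations declaratively: fixing a
component's level (knockout / ectopic expression), restricting its
activity range, or removing one regulator's influence on one target.
They are written as compact tokens: ``p53%0`` fixes p53 at 0,
``Mdm2cyt%0:1`` restricts Mdm2cyt to [0, 1], and ``p53:DNAdam%0``
removes the interaction from p53 onto DNAdam.

Reduction eliminates components by substituting their rules into their
targets' rules; it preserves stable states (projections onto the kept
components).  Removed components keep a derived rule giving their
expected level in the reduced model.

Booleanization replaces each multi-valued component of maximal level m
by m ordered Boolean sub-components ``v_b1 .. v_bm`` denoting
increasing activity.  Admissible Boolean states (b1 >= b2 >= ... >= bm
per component) are in bijection with multi-valued states, transitions
correspond under the bijection, and every non-admissible state can
asynchronously reach an admissible one, so no attractor contains a
non-admissible state.

All transformations return new models; they chain left to right.
"""
from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass

from .model import (
    And,
    Component,
    Expr,
    FALSE,
    Lit,
    LogicalFunction,
    LogicalModel,
    ModelError,
    Not,
    Or,
    ReductionError,
    TRUE,
    infer_regulators,
    simplify,
    substitute,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# atomic perturbations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixAtom:
    component: str
    level: int


@dataclass(frozen=True)
class RangeAtom:
    component: str
    min_level: int
    max_level: int


@dataclass(frozen=True)
class RemoveInteractionAtom:
    regulator: str
    target: str


@dataclass(frozen=True)
class Perturbation:
    """A multiple perturbation: an ordered list of atomic perturbations."""

    atoms: tuple

    def apply(self, model: LogicalModel) -> LogicalModel:
        for atom in self.atoms:
            if isinstance(atom, FixAtom):
                model = apply_fix(model, atom.component, atom.level)
            elif isinstance(atom, RangeAtom):
                model = apply_range(model, atom.component, atom.min_level, atom.max_level)
            elif isinstance(atom, RemoveInteractionAtom):
                model = remove_interaction(model, atom.regulator, atom.target)
            else:
                raise ModelError(f"unknown perturbation atom: {atom!r}")
        return model

    __call__ = apply


_FIX_RE = re.compile(r"(?P<name>\w+)%(?P<level>\d)\Z")
_RANGE_RE = re.compile(r"(?P<name>\w+)%(?P<lo>\d):(?P<hi>\d)\Z")
_REMOVE_RE = re.compile(r"(?P<reg>\w+):(?P<target>\w+)%0\Z")


def parse_perturbation(model: LogicalModel, tokens) -> Perturbation:
    """Parse perturbation tokens such as ``p53%0`` or ``p53:DNAdam%0``."""
    atoms = []
    keys = set()
    for token in tokens:
        m = _REMOVE_RE.match(token)
        if m and not _FIX_RE.match(token):
            reg, target = m.group("reg"), m.group("target")
            model.index(reg), model.index(target)
            atom = RemoveInteractionAtom(reg, target)
            key = ("remove", reg, target)
        elif _RANGE_RE.match(token):
            m = _RANGE_RE.match(token)
            name = m.group("name")
            lo, hi = int(m.group("lo")), int(m.group("hi"))
            comp = model.components[model.index(name)]
            if not 0 <= lo <= hi <= comp.max_level:
                raise ModelError(
                    f"invalid range {lo}:{hi} for {name} (maximal level "
                    f"{comp.max_level})"
                )
            atom = RangeAtom(name, lo, hi)
            key = ("range", name)
        elif _FIX_RE.match(token):
            m = _FIX_RE.match(token)
            name, level = m.group("name"), int(m.group("level"))
            comp = model.components[model.index(name)]
            if level > comp.max_level:
                raise ModelError(
                    f"level {level} outside the range of {name} "
                    f"[0, {comp.max_level}]"
                )
            atom = FixAtom(name, level)
            key = ("fix", name)
        else:
            raise ModelError(f"malformed perturbation token: {token!r}")
        if key in keys:
            raise ModelError(f"duplicate perturbation of {token!r}")
        keys.add(key)
        atoms.append(atom)
    return Perturbation(tuple(atoms))


def _replace_function(model: LogicalModel, comp: int, fn: LogicalFunction) -> LogicalModel:
    functions = list(model.functions)
    functions[comp] = fn
    return LogicalModel(model.components, functions)


def apply_fix(model: LogicalModel, component: str, level: int) -> LogicalModel:
    """Fix a component's rule to a constant level (knockout / ectopic)."""
    i = model.index(component)
    if not 0 <= level <= model.components[i].max_level:
        raise ModelError(
            f"level {level} outside the range of {component} "
            f"[0, {model.components[i].max_level}]"
        )
    rows = [(level, TRUE)] if level >= 1 else []
    return _replace_function(model, i, LogicalFunction(component, rows))


def apply_range(
    model: LogicalModel, component: str, min_level: int, max_level: int
) -> LogicalModel:
    """Clamp a component's target values into ``[min_level, max_level]``."""
    i = model.index(component)
    comp = model.components[i]
    if not 0 <= min_level <= max_level <= comp.max_level:
        raise ModelError(
            f"invalid range {min_level}:{max_level} for {component} "
            f"(maximal level {comp.max_level})"
        )
    old_rows = model.functions[i].rows
    rows = []
    for level, cond in old_rows:
        clamped = min(max(level, min_level), max_level)
        if clamped >= 1:
            rows.append((clamped, cond))
    if min_level >= 1:
        # states hitting the implicit default 0 are raised to the minimum
        others = [cond for _, cond in old_rows]
        default = simplify(Not(Or(others))) if others else TRUE
        if default != FALSE:
            rows.append((min_level, default))
    return _replace_function(model, i, LogicalFunction(component, rows))


def remove_interaction(model: LogicalModel, regulator: str, target: str) -> LogicalModel:
    """Rewrite the target's rule with the regulator held at its inactive level 0."""
    r = model.index(regulator)
    t = model.index(target)
    if r not in {idx for idx, _ in infer_regulators(model, t)}:
        logger.warning(
            "%s is not a regulator of %s; interaction removal is a no-op",
            regulator,
            target,
        )
        return model
    rows = []
    for level, cond in model.functions[t].rows:
        new = simplify(
            substitute(cond, lambda name, th: FALSE if name == regulator else None)
        )
        if new != FALSE:
            rows.append((level, new))
    return _replace_function(model, t, LogicalFunction(target, rows))


# ---------------------------------------------------------------------------
# booleanization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanizationMap:
    """Correspondence between a multi-valued model and its Boolean mapping."""

    source_names: tuple[str, ...]
    source_maxes: tuple[int, ...]
    groups: tuple[tuple[str, ...], ...]  # booleanized names per source component

    @property
    def names(self) -> list[str]:
        return [n for group in self.groups for n in group]

    def encode(self, state) -> tuple[int, ...]:
        """Multi-valued state -> admissible Boolean state."""
        bits: list[int] = []
        for lv, group in zip(state, self.groups):
            bits.extend(1 if k < lv else 0 for k in range(len(group)))
        return tuple(bits)

    def decode(self, bool_state) -> tuple[int, ...]:
        """Boolean state -> levels, as the count of active sub-components."""
        out = []
        pos = 0
        for group in self.groups:
            out.append(sum(bool_state[pos : pos + len(group)]))
            pos += len(group)
        return tuple(out)

    def is_admissible(self, bool_state) -> bool:
        pos = 0
        for group in self.groups:
            bits = bool_state[pos : pos + len(group)]
            if any(b2 > b1 for b1, b2 in zip(bits, bits[1:])):
                return False
            pos += len(group)
        return True


def _count_at_least(names: tuple[str, ...], t: int) -> Expr:
    """``count of active bits >= t`` over Boolean sub-components."""
    if t <= 0:
        return TRUE
    if t > len(names):
        return FALSE
    if t == len(names):
        return simplify(And(Lit(n) for n in names))
    return simplify(
        Or(And(Lit(n) for n in subset) for subset in itertools.combinations(names, t))
    )


def booleanize(model: LogicalModel) -> tuple[LogicalModel, BooleanizationMap]:
    """Boolean mapping of a multi-valued model.

    Each multi-valued component ``v`` of maximal level m becomes
    ``v_b1 .. v_bm``.  The rule of ``v_bi`` is
    ``([target of v >= i] & v_b(i-1)) | (v_bi & v_b(i+1))`` with
    ``v_b0 = 1`` and ``v_b(m+1) = 0``, where the target of ``v`` is
    evaluated on count-decoded levels.  Boolean models are returned
    unchanged, with an identity map.
    """
    groups = tuple(
        (c.name,) if c.max_level == 1 else tuple(f"{c.name}_b{i}" for i in range(1, c.max_level + 1))
        for c in model.components
    )
    bmap = BooleanizationMap(
        tuple(model.names), tuple(c.max_level for c in model.components), groups
    )
    if model.is_boolean():
        return model, bmap

    def translate(expr: Expr) -> Expr:
        def repl(name: str, threshold: int) -> Expr:
            group = groups[model.index(name)]
            if len(group) == 1:
                return Lit(group[0]) if threshold == 1 else FALSE
            return _count_at_least(group, threshold)

        return simplify(substitute(expr, repl))

    def target_at_least(comp_idx: int, level: int) -> Expr:
        conds = [c for lv, c in model.functions[comp_idx].rows if lv >= level]
        if not conds:
            return FALSE
        return translate(simplify(Or(conds)))

    components = []
    functions = []
    for idx, comp in enumerate(model.components):
        group = groups[idx]
        m = len(group)
        if m == 1:
            components.append(Component(comp.name, 1))
            rule = target_at_least(idx, 1)
            rows = [] if rule == FALSE else [(1, rule)]
            functions.append(LogicalFunction(comp.name, rows))
            continue
        for i, name in enumerate(group, start=1):
            rise = target_at_least(idx, i)
            if i > 1:
                rise = simplify(And([rise, Lit(group[i - 2])]))
            hold = (
                simplify(And([Lit(name), Lit(group[i])])) if i < m else FALSE
            )
            rule = simplify(Or([rise, hold]))
            components.append(Component(name, 1))
            rows = [] if rule == FALSE else [(1, rule)]
            functions.append(LogicalFunction(name, rows))
    return LogicalModel(components, functions), bmap


def booleanized(model: LogicalModel) -> LogicalModel:
    """Booleanize and discard the map (modifier form for chaining)."""
    return booleanize(model)[0]


# ---------------------------------------------------------------------------
# reduction
# ---------------------------------------------------------------------------

@dataclass
class ReductionResult:
    """A reduced model plus derived rules for the removed components.

    Derived functions give the expected level of each removed component
    as a rule over the kept components; they take no part in the
    dynamics of the reduced model.
    """

    reduced_model: LogicalModel
    derived_functions: dict[str, LogicalFunction]


def _eliminate(model: LogicalModel, name: str, derived: dict[str, LogicalFunction]):
    """Remove one component, substituting its rule into all other rules."""
    idx = model.index(name)
    if idx in {r for r, _ in infer_regulators(model, idx)}:
        raise ReductionError(
            f"cannot eliminate {name}: it regulates itself"
        )
    # substitute the canonical form of the target conditions: unlike the
    # written rows, it cannot cite semantically irrelevant components
    # (including the eliminated one itself)
    from .formats import expression_from_mdd

    mgr = model.manager
    target = model.target_mdd(idx)

    def repl(lit_name: str, threshold: int) -> Expr | None:
        if lit_name != name:
            return None
        return expression_from_mdd(mgr, mgr.geq_const(target, threshold), model.names)

    def rewrite(fn: LogicalFunction) -> LogicalFunction:
        new_rows = []
        for level, cond in fn.rows:
            new = simplify(substitute(cond, repl))
            if new != FALSE:
                new_rows.append((level, new))
        return LogicalFunction(fn.owner, new_rows)

    components = [c for c in model.components if c.name != name]
    functions = [rewrite(fn) for fn in model.functions if fn.owner != name]
    derived = {k: rewrite(fn) for k, fn in derived.items()}
    derived[name] = rewrite(model.functions[idx])
    return LogicalModel(components, functions), derived


def reduce(model: LogicalModel, components_to_remove) -> ReductionResult:
    """Eliminate the listed components one at a time, in list order.

    Each elimination substitutes the removed component's target
    expression for its literals in every remaining rule (the threshold
    literal ``v:t`` becomes the condition ``target of v >= t``).  An
    elimination of a self-regulated component is an error.
    """
    derived: dict[str, LogicalFunction] = {}
    for name in components_to_remove:
        model.index(name)  # unknown-name check against the running model
        model, derived = _eliminate(model, name, derived)
    return ReductionResult(model, derived)


def reduce_outputs(model: LogicalModel) -> ReductionResult:
    """Iteratively remove pure outputs (components regulating no other).

    Self-regulated outputs are kept: their elimination is not defined.
    """
    derived: dict[str, LogicalFunction] = {}
    while True:
        regulators_of_others: set[int] = set()
        self_regulated: set[int] = set()
        for i in range(len(model.components)):
            for r, _ in infer_regulators(model, i):
                if r == i:
                    self_regulated.add(r)
                else:
                    regulators_of_others.add(r)
        candidates = [
            c.name
            for i, c in enumerate(model.components)
            if i not in regulators_of_others and i not in self_regulated
        ]
        if not candidates:
            return ReductionResult(model, derived)
        model, derived = _eliminate(model, candidates[0], derived)


def propagate_fixed(model: LogicalModel) -> ReductionResult:
    """Substitute components with constant rules into their targets, to fixpoint."""
    derived: dict[str, LogicalFunction] = {}
    while True:
        constant = None
        for i in range(len(model.components)):
            t = model.target_mdd(i)
            if model.manager.is_terminal(t):
                constant = (i, t)
                break
        if constant is None:
            return ReductionResult(model, derived)
        idx, level = constant
        name = model.components[idx].name
        # replace the rule by its constant before elimination, so literals
        # of the component substitute to 0/1 regardless of its written form
        rows = [(level, TRUE)] if level >= 1 else []
        model = _replace_function(model, idx, LogicalFunction(name, rows))
        model, derived = _eliminate(model, name, derived)


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def chain(model: LogicalModel, modifiers) -> LogicalModel:
    """Apply modifiers (callables ``model -> model``) left to right."""
    for pos, modifier in enumerate(modifiers):
        try:
            model = modifier(model)
        except ModelError as err:
            raise ModelError(f"modifier {pos}: {err}") from err
    return model
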
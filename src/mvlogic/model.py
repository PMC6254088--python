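"""Core data structures and evaluation semantics of multi-valued logical models.

A logical model is an ordered list of components, each with a maximal
activity level (1 for Boolean components) and one logical function.  A
function is an ordered list of rows ``(target_level, condition)``: in a
given state the component's *target value* is the target level of the
unique satisfied row, or 0 when no row condition holds.  Row conditions
of one component must be pairwise mutually exclusive; this is validated
when a model is constructed.

Dynamics follow unit-step semantics: a component whose target value
differs from its current level is *called to update* and moves one
level toward the target per transition, never jumping.

Conditions are expression trees over threshold literals: the literal
``c:t`` holds iff the level of component ``c`` is at least ``t``; a bare
``c`` means ``c:1``.  Internally every function is also normalised to a
canonical decision-diagram form (ordered by component declaration
order), used by the static analyses; the original expression trees are
retained for round-trip serialisation.
"""
from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Iterator

from ._mdd import MDDManager

State = tuple[int, ...]

_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")

MAX_LEVEL = 9  # states serialise as digit strings, one digit per component


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class ModelError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ModelError):
    """A model violates a structural invariant."""


class ParseError(ModelError):
    """A text input could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FormatError(ModelError):
    """Unknown or unsupported serialisation format."""


class ReductionError(ModelError):
    """An illegal component elimination was requested."""


# ---------------------------------------------------------------------------
# expressions
# ---------------------------------------------------------------------------

class Expr:
    __slots__ = ()


@dataclass(frozen=True)
class Const(Expr):
    value: bool


TRUE = Const(True)
FALSE = Const(False)


@dataclass(frozen=True)
class Lit(Expr):
    """Threshold literal: true iff ``level(name) >= threshold``."""

    name: str
    threshold: int = 1


@dataclass(frozen=True)
class Not(Expr):
    arg: Expr


@dataclass(frozen=True)
class And(Expr):
    args: tuple[Expr, ...]

    def __init__(self, args: Iterable[Expr]):
        object.__setattr__(self, "args", tuple(args))


@dataclass(frozen=True)
class Or(Expr):
    args: tuple[Expr, ...]

    def __init__(self, args: Iterable[Expr]):
        object.__setattr__(self, "args", tuple(args))


def eval_expr(expr: Expr, levels, index: dict[str, int]) -> bool:
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Lit):
        return levels[index[expr.name]] >= expr.threshold
    if isinstance(expr, Not):
        return not eval_expr(expr.arg, levels, index)
    if isinstance(expr, And):
        return all(eval_expr(a, levels, index) for a in expr.args)
    if isinstance(expr, Or):
        return any(eval_expr(a, levels, index) for a in expr.args)
    raise TypeError(f"not an expression: {expr!r}")


def expr_literals(expr: Expr) -> Iterator[Lit]:
    """All threshold literals appearing in an expression tree."""
    if isinstance(expr, Lit):
        yield expr
    elif isinstance(expr, Not):
        yield from expr_literals(expr.arg)
    elif isinstance(expr, (And, Or)):
        for a in expr.args:
            yield from expr_literals(a)


def substitute(expr: Expr, repl) -> Expr:
    """Replace literals: ``repl(name, threshold)`` returns an Expr or None."""
    if isinstance(expr, Lit):
        new = repl(expr.name, expr.threshold)
        return expr if new is None else new
    if isinstance(expr, Not):
        return Not(substitute(expr.arg, repl))
    if isinstance(expr, And):
        return And(substitute(a, repl) for a in expr.args)
    if isinstance(expr, Or):
        return Or(substitute(a, repl) for a in expr.args)
    return expr


def simplify(expr: Expr) -> Expr:
    """Constant folding and flattening; keeps literals untouched."""
    if isinstance(expr, Not):
        a = simplify(expr.arg)
        if isinstance(a, Const):
            return FALSE if a.value else TRUE
        if isinstance(a, Not):
            return a.arg
        return Not(a)
    if isinstance(expr, (And, Or)):
        is_and = isinstance(expr, And)
        absorbing, neutral = (FALSE, TRUE) if is_and else (TRUE, FALSE)
        args: list[Expr] = []
        for a in expr.args:
            a = simplify(a)
            if a == absorbing:
                return absorbing
            if a == neutral:
                continue
            if isinstance(a, And if is_and else Or):
                args.extend(a.args)
            else:
                args.append(a)
        if not args:
            return neutral
        if len(args) == 1:
            return args[0]
        return (And if is_and else Or)(args)
    return expr


# ---------------------------------------------------------------------------
# model structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    """A discrete variable with activity range [0, max_level]."""

    name: str
    max_level: int = 1

    def __post_init__(self):
        if not _IDENT_RE.match(self.name):
            raise ValidationError(f"invalid component name: {self.name!r}")
        if not 1 <= self.max_level <= MAX_LEVEL:
            raise ValidationError(
                f"max level of {self.name} must be in [1, {MAX_LEVEL}]"
            )


@dataclass(frozen=True)
class LogicalFunction:
    """Ordered rows ``(target_level, condition)`` with implicit default 0."""

    owner: str
    rows: tuple[tuple[int, Expr], ...]

    def __init__(self, owner: str, rows: Iterable[tuple[int, Expr]]):
        object.__setattr__(self, "owner", owner)
        object.__setattr__(self, "rows", tuple((int(lv), c) for lv, c in rows))


class LogicalModel:
    """Ordered components plus one logical function per component."""

    def __init__(self, components, functions, validate: bool = True):
        self.components: tuple[Component, ...] = tuple(components)
        self.functions: tuple[LogicalFunction, ...] = tuple(functions)
        self._index = {c.name: i for i, c in enumerate(self.components)}
        self._mgr: MDDManager | None = None
        self._target_mdds: list[int | None] = [None] * len(self.components)
        if validate:
            self._validate()

    # -- basics -------------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ModelError(f"unknown component: {name}") from None

    def is_boolean(self) -> bool:
        return all(c.max_level == 1 for c in self.components)

    def state_count(self) -> int:
        n = 1
        for c in self.components:
            n *= c.max_level + 1
        return n

    def all_states(self) -> Iterator[State]:
        return itertools.product(*(range(c.max_level + 1) for c in self.components))

    def __repr__(self) -> str:
        sig = ", ".join(f"{c.name}[0..{c.max_level}]" for c in self.components)
        return f"<LogicalModel {sig}>"

    # -- decision diagrams ---------------------------------------------------

    @property
    def manager(self) -> MDDManager:
        if self._mgr is None:
            self._mgr = MDDManager(c.max_level + 1 for c in self.components)
        return self._mgr

    def expr_mdd(self, expr: Expr) -> int:
        mgr = self.manager
        if isinstance(expr, Const):
            return 1 if expr.value else 0
        if isinstance(expr, Lit):
            return mgr.literal(self._index[expr.name], expr.threshold)
        if isinstance(expr, Not):
            return mgr.not_(self.expr_mdd(expr.arg))
        if isinstance(expr, And):
            u = 1
            for a in expr.args:
                u = mgr.and_(u, self.expr_mdd(a))
            return u
        if isinstance(expr, Or):
            u = 0
            for a in expr.args:
                u = mgr.or_(u, self.expr_mdd(a))
            return u
        raise TypeError(f"not an expression: {expr!r}")

    def target_mdd(self, comp: int) -> int:
        """Canonical decision diagram of the component's target function."""
        u = self._target_mdds[comp]
        if u is None:
            mgr = self.manager
            u = 0
            for level, cond in self.functions[comp].rows:
                c = self.expr_mdd(cond)
                u = mgr.apply2(
                    ("row", level), lambda a, b, lv=level: lv if a else b, c, u
                )
            self._target_mdds[comp] = u
        return u

    # -- validation ----------------------------------------------------------

    def _validate(self) -> None:
        if len(self.functions) != len(self.components):
            raise ValidationError("one logical function per component is required")
        if len(self._index) != len(self.components):
            raise ValidationError("component names must be unique")
        for comp, fn in zip(self.components, self.functions):
            if fn.owner != comp.name:
                raise ValidationError(
                    f"function owner {fn.owner!r} does not match component "
                    f"{comp.name!r} at the same position"
                )
            for level, cond in fn.rows:
                if not 1 <= level <= comp.max_level:
                    raise ValidationError(
                        f"target level {level} outside the range of {comp.name}"
                    )
                for lit in expr_literals(cond):
                    ref = self._index.get(lit.name)
                    if ref is None:
                        raise ValidationError(
                            f"undeclared component {lit.name!r} in the rule of "
                            f"{comp.name}"
                        )
                    if not 1 <= lit.threshold <= self.components[ref].max_level:
                        raise ValidationError(
                            f"threshold {lit.name}:{lit.threshold} exceeds the "
                            f"maximal level of {lit.name}"
                        )
            # mutual exclusivity of row conditions, checked symbolically
            mdds = [self.expr_mdd(c) for _, c in fn.rows]
            for i in range(len(mdds)):
                for j in range(i + 1, len(mdds)):
                    if self.manager.and_(mdds[i], mdds[j]) != 0:
                        raise ValidationError(
                            f"overlapping rows in the rule of {comp.name}: some "
                            f"state satisfies both row {i + 1} and row {j + 1}"
                        )

    def check_state(self, state) -> State:
        state = tuple(state)
        if len(state) != len(self.components):
            raise ModelError(
                f"state has {len(state)} levels, model has "
                f"{len(self.components)} components"
            )
        for lv, comp in zip(state, self.components):
            if not 0 <= lv <= comp.max_level:
                raise ModelError(
                    f"level {lv} outside the range of {comp.name} "
                    f"[0, {comp.max_level}]"
                )
        return state


# ---------------------------------------------------------------------------
# states as digit strings
# ---------------------------------------------------------------------------

def parse_state(model: LogicalModel, text: str) -> State:
    """Parse a digit-string state such as ``1011`` (declaration order)."""
    text = text.strip()
    if len(text) != len(model.components) or not text.isdigit():
        raise ModelError(
            f"invalid state string {text!r}: expected "
            f"{len(model.components)} digits"
        )
    return model.check_state(int(ch) for ch in text)


def format_state(state: State) -> str:
    return "".join(str(lv) for lv in state)


# ---------------------------------------------------------------------------
# evaluation semantics
# ---------------------------------------------------------------------------

def target_value(model: LogicalModel, state, comp: int) -> int:
    """Target level of one component: the unique satisfied row, or 0."""
    for level, cond in model.functions[comp].rows:
        if eval_expr(cond, state, model._index):
            return level
    return 0


def target_state(model: LogicalModel, state) -> State:
    """Component-wise target values; equals ``state`` iff the state is stable."""
    return tuple(target_value(model, state, i) for i in range(len(model.components)))


def called_components(model: LogicalModel, state) -> set[int]:
    """Indices whose target value differs from the current level."""
    return {
        i
        for i in range(len(model.components))
        if target_value(model, state, i) != state[i]
    }


def step_toward(current: int, target: int) -> int:
    """Unit step: move one level toward the target, or stay."""
    if target > current:
        return current + 1
    if target < current:
        return current - 1
    return current


def is_stable(model: LogicalModel, state) -> bool:
    return not called_components(model, state)


# ---------------------------------------------------------------------------
# regulatory structure recovery
# ---------------------------------------------------------------------------

def infer_regulators(model: LogicalModel, comp: int) -> set[tuple[int, str]]:
    """Signed regulators of a component, recovered from its rule.

    A component ``r`` regulates ``comp`` iff two states differing only in
    ``r`` yield different target values.  The sign is ``+`` when the
    target is monotonically non-decreasing in the level of ``r``, ``-``
    when non-increasing, and ``±`` otherwise.
    """
    mgr = model.manager
    t = model.target_mdd(comp)
    out: set[tuple[int, str]] = set()
    for r in mgr.support(t):
        nondecr = nonincr = True
        for lv in range(mgr.domains[r] - 1):
            lo = mgr.restrict(t, {r: lv})
            hi = mgr.restrict(t, {r: lv + 1})
            if mgr.leq(lo, hi) != 1:
                nondecr = False
            if mgr.leq(hi, lo) != 1:
                nonincr = False
        sign = "+" if nondecr else ("-" if nonincr else "±")
        out.add((r, sign))
    return out
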
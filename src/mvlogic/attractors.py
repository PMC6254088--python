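"""Static identification of stable states and minimal trap spaces.

Stable states (fixed points) are found without sweeping the state
space: per component, the stability condition ``target_i(x) = x_i`` is
built as a decision diagram, all conditions are conjoined, and the
satisfying states are enumerated.  Stable states do not depend on the
updating mode.

Trap spaces (stable patterns) approximate complex attractors.  A
pattern is a partial assignment over the Booleanized components; it is
a trap space when the synchronous image of every covered state stays
inside the pattern.  Minimal trap spaces are computed by a
constraint-propagation search: candidate patterns are refined literal
by literal, and a fixed literal whose rule is not yet constant inside
the pattern is supported by branching over the prime implicants of that
rule.  Minimal trap spaces are the patterns admitting no further
refinement.  Brute-force counterparts of both analyses serve as
independent oracles on small models.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

from .model import (
    LogicalModel,
    ModelError,
    State,
    is_stable,
    target_value,
)

_BRUTE_FORCE_CAP = 1 << 20
_TRAP_BRUTE_CAP = 12


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------

FREE = None


@dataclass(frozen=True)
class Pattern:
    """Partial assignment over Boolean components; ``None`` entries are free.

    A pattern with no free entries is a single state; a pattern with k
    free entries covers 2**k Boolean states.
    """

    entries: tuple

    def __post_init__(self):
        for e in self.entries:
            if e not in (0, 1, FREE):
                raise ModelError(f"pattern entries must be 0, 1 or free: {e!r}")

    def __str__(self) -> str:
        return "".join("-" if e is FREE else str(e) for e in self.entries)

    def tokens(self) -> str:
        return " ".join("-" if e is FREE else str(e) for e in self.entries)

    @property
    def n_free(self) -> int:
        return sum(1 for e in self.entries if e is FREE)

    def covers(self, state) -> bool:
        return all(e is FREE or e == lv for e, lv in zip(self.entries, state))

    def states(self):
        """All covered Boolean states."""
        axes = [(0, 1) if e is FREE else (e,) for e in self.entries]
        return itertools.product(*axes)


def _pattern_sort_key(p: Pattern):
    # lexicographic with free entries sorted after 1
    return tuple(2 if e is FREE else e for e in p.entries)


# ---------------------------------------------------------------------------
# fixed points
# ---------------------------------------------------------------------------

def fixpoints(model: LogicalModel) -> list[State]:
    """All stable states, in lexicographic order, via decision diagrams."""
    mgr = model.manager
    stability = 1
    for i, comp in enumerate(model.components):
        t = model.target_mdd(i)
        cond = 0
        for level in range(comp.max_level + 1):
            level_eq = mgr.node(
                i, tuple(1 if lv == level else 0 for lv in range(comp.max_level + 1))
            )
            cond = mgr.or_(cond, mgr.and_(mgr.eq_const(t, level), level_eq))
        stability = mgr.and_(stability, cond)
        if stability == 0:
            return []
    return list(mgr.sat_states(stability))


def fixpoints_bruteforce(model: LogicalModel) -> list[State]:
    """Exhaustive stable-state sweep; the oracle for :func:`fixpoints`."""
    if model.state_count() > _BRUTE_FORCE_CAP:
        raise ModelError(
            f"state space of {model.state_count()} states exceeds the "
            f"brute-force cap of {_BRUTE_FORCE_CAP}"
        )
    return [s for s in model.all_states() if is_stable(model, s)]


# ---------------------------------------------------------------------------
# trap spaces
# ---------------------------------------------------------------------------

def _require_boolean(model: LogicalModel) -> None:
    if not model.is_boolean():
        raise ModelError("this operation requires a Boolean model; booleanize first")


def is_trap_space(model: LogicalModel, pattern: Pattern) -> bool:
    """Definitional check: every covered state's image stays in the pattern.

    The image is the synchronous successor; only the pattern's fixed
    entries constrain it.
    """
    _require_boolean(model)
    if len(pattern.entries) != len(model.components):
        raise ModelError(
            f"pattern has {len(pattern.entries)} entries, model has "
            f"{len(model.components)} components"
        )
    fixed = [i for i, e in enumerate(pattern.entries) if e is not FREE]
    for state in pattern.states():
        for i in fixed:
            if target_value(model, state, i) != pattern.entries[i]:
                return False
    return True


def trapspaces(model: LogicalModel) -> list[Pattern]:
    """All minimal trap spaces of the (Booleanized) model.

    Multi-valued models are Booleanized first; patterns are reported
    over the Booleanized component names.  Every stable state appears
    as a fully fixed pattern.  When the only trap space is the full
    state space, the single all-free pattern is returned.
    """
    from .modifiers import booleanize

    bmodel, _ = booleanize(model)
    mgr = bmodel.manager
    n = len(bmodel.components)
    rules = [bmodel.target_mdd(i) for i in range(n)]

    primes_cache: dict[tuple[int, int], tuple] = {}

    def primes_of(var: int, value: int):
        key = (var, value)
        cubes = primes_cache.get(key)
        if cubes is None:
            g = rules[var] if value == 1 else mgr.not_(rules[var])
            cubes = tuple(sorted(mgr.prime_implicants(g), key=sorted))
            primes_cache[key] = cubes
        return cubes

    def unsupported(assign: dict[int, int]) -> int | None:
        """First fixed variable whose rule is not yet constant in the pattern."""
        for var in sorted(assign):
            if mgr.restrict(rules[var], assign) != assign[var]:
                return var
        return None

    expand_memo: dict[frozenset, frozenset] = {}

    def expand(items: frozenset) -> frozenset:
        """Minimal trap spaces refining a partial assignment (may be empty)."""
        res = expand_memo.get(items)
        if res is not None:
            return res
        assign = dict(items)
        var = unsupported(assign)
        if var is None:
            res = frozenset({items})
        else:
            out: set[frozenset] = set()
            for cube in primes_of(var, assign[var]):
                if any(assign.get(v, b) != b for v, b in cube):
                    continue  # conflicting support choice
                if cube <= items:
                    continue
                out |= expand(items | cube)
            res = frozenset(out)
        expand_memo[items] = res
        return res

    minimal: set[frozenset] = set()
    visited: set[frozenset] = set()

    def search(items: frozenset) -> None:
        if items in visited:
            return
        visited.add(items)
        assign = dict(items)
        refinable = False
        for var in range(n):
            if var in assign:
                continue
            for bit in (0, 1):
                for refined in expand(items | {(var, bit)}):
                    refinable = True
                    search(refined)
        if not refinable:
            minimal.add(items)

    search(frozenset())

    patterns = [
        Pattern(tuple(dict(items).get(i, FREE) for i in range(n)))
        for items in minimal
    ]
    return sorted(patterns, key=_pattern_sort_key)


def trapspaces_bruteforce(model: LogicalModel) -> list[Pattern]:
    """Enumerate all 3**n patterns of a Boolean model; keep minimal trap spaces.

    The independent oracle for :func:`trapspaces`.
    """
    _require_boolean(model)
    n = len(model.components)
    if n > _TRAP_BRUTE_CAP:
        raise ModelError(
            f"{n} components exceed the brute-force cap of {_TRAP_BRUTE_CAP}"
        )
    traps = [
        Pattern(entries)
        for entries in itertools.product((0, 1, FREE), repeat=n)
        if is_trap_space(model, Pattern(entries))
    ]

    def strictly_inside(a: Pattern, b: Pattern) -> bool:
        """a covers strictly fewer states, all of them covered by b."""
        if a.entries == b.entries:
            return False
        for ea, eb in zip(a.entries, b.entries):
            if eb is not FREE and ea != eb:
                return False
        return True

    minimal = [
        p for p in traps if not any(strictly_inside(q, p) for q in traps)
    ]
    return sorted(minimal, key=_pattern_sort_key)
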
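"""Reduced ordered multi-valued decision diagrams (MDDs).

Internal engine used for the static analyses: stability conditions for
fixed-point identification, prime implicants for trap-space search,
regulator inference, and canonical function comparison.

Diagrams are hash-consed and fully reduced: a node whose children are
all identical collapses to that child, and structurally equal nodes are
shared.  Terminals are small non-negative integers, so the same engine
serves Boolean conditions (terminals 0/1) and multi-valued target
functions (terminals 0..9).  Variables are identified by their index in
a fixed ordering with per-variable finite domains.
"""
from __future__ import annotations

from typing import Callable, Iterator

# Ids below this bound denote terminal values; internal node ids start here.
_TERM = 16


class MDDManager:
    """Shared store of reduced ordered MDD nodes over fixed domains."""

    def __init__(self, domains) -> None:
        self.domains = tuple(int(d) for d in domains)
        if any(d < 2 or d > _TERM for d in self.domains):
            raise ValueError("variable domains must have between 2 and 16 levels")
        self.n = len(self.domains)
        self._unique: dict[tuple[int, tuple[int, ...]], int] = {}
        self._vars: list[int] = []
        self._kids: list[tuple[int, ...]] = []
        self._cache1: dict = {}
        self._cache2: dict = {}

    # -- node construction -------------------------------------------------

    def terminal(self, value: int) -> int:
        if not 0 <= value < _TERM:
            raise ValueError(f"terminal value out of range: {value}")
        return value

    def node(self, var: int, children) -> int:
        children = tuple(children)
        if len(children) != self.domains[var]:
            raise ValueError("child count does not match the variable domain")
        first = children[0]
        if all(c == first for c in children):
            return first
        key = (var, children)
        nid = self._unique.get(key)
        if nid is None:
            nid = _TERM + len(self._vars)
            self._unique[key] = nid
            self._vars.append(var)
            self._kids.append(children)
        return nid

    def literal(self, var: int, threshold: int) -> int:
        """Boolean-valued diagram of ``level(var) >= threshold``."""
        dom = self.domains[var]
        if not 1 <= threshold <= dom - 1:
            raise ValueError("threshold outside the variable range")
        return self.node(var, tuple(1 if lv >= threshold else 0 for lv in range(dom)))

    # -- structure accessors -----------------------------------------------

    def is_terminal(self, u: int) -> bool:
        return u < _TERM

    def var(self, u: int) -> int:
        return self._vars[u - _TERM]

    def children(self, u: int) -> tuple[int, ...]:
        return self._kids[u - _TERM]

    def _cofactors(self, u: int, var: int) -> tuple[int, ...]:
        """Children of u with respect to ``var`` (u may not test var)."""
        if u >= _TERM and self.var(u) == var:
            return self._kids[u - _TERM]
        return (u,) * self.domains[var]

    # -- generic apply ------------------------------------------------------

    def apply1(self, key, fn: Callable[[int], int], u: int) -> int:
        memo = self._cache1
        k = (key, u)
        if k in memo:
            return memo[k]
        if u < _TERM:
            r = fn(u)
        else:
            var = self.var(u)
            r = self.node(var, tuple(self.apply1(key, fn, c) for c in self.children(u)))
        memo[k] = r
        return r

    def apply2(self, key, fn: Callable[[int, int], int], u: int, v: int) -> int:
        memo = self._cache2
        k = (key, u, v)
        if k in memo:
            return memo[k]
        if u < _TERM and v < _TERM:
            r = fn(u, v)
        else:
            var = min(self.var(w) for w in (u, v) if w >= _TERM)
            uc = self._cofactors(u, var)
            vc = self._cofactors(v, var)
            r = self.node(var, tuple(self.apply2(key, fn, a, b) for a, b in zip(uc, vc)))
        memo[k] = r
        return r

    # -- Boolean connectives (terminals 0/1) ---------------------------------

    def and_(self, u: int, v: int) -> int:
        return self.apply2("and", lambda a, b: 1 if (a and b) else 0, u, v)

    def or_(self, u: int, v: int) -> int:
        return self.apply2("or", lambda a, b: 1 if (a or b) else 0, u, v)

    def not_(self, u: int) -> int:
        return self.apply1("not", lambda a: 0 if a else 1, u)

    def eq_const(self, u: int, value: int) -> int:
        return self.apply1(("eq", value), lambda a: 1 if a == value else 0, u)

    def geq_const(self, u: int, value: int) -> int:
        return self.apply1(("geq", value), lambda a: 1 if a >= value else 0, u)

    def leq(self, u: int, v: int) -> int:
        """Pointwise ``u <= v`` as a 0/1 diagram."""
        return self.apply2("leq", lambda a, b: 1 if a <= b else 0, u, v)

    # -- evaluation / inspection ---------------------------------------------

    def restrict(self, u: int, assignment: dict[int, int]) -> int:
        """Cofactor of u under a partial variable assignment."""
        memo: dict[int, int] = {}

        def rec(w: int) -> int:
            if w < _TERM:
                return w
            r = memo.get(w)
            if r is not None:
                return r
            var = self.var(w)
            kids = self.children(w)
            if var in assignment:
                r = rec(kids[assignment[var]])
            else:
                r = self.node(var, tuple(rec(c) for c in kids))
            memo[w] = r
            return r

        return rec(u)

    def evaluate(self, u: int, state) -> int:
        while u >= _TERM:
            u = self.children(u)[state[self.var(u)]]
        return u

    def support(self, u: int) -> set[int]:
        seen: set[int] = set()
        out: set[int] = set()
        stack = [u]
        while stack:
            w = stack.pop()
            if w < _TERM or w in seen:
                continue
            seen.add(w)
            out.add(self.var(w))
            stack.extend(self.children(w))
        return out

    def sat_states(self, u: int) -> Iterator[tuple[int, ...]]:
        """Full states with a non-zero value, in lexicographic order."""
        n = self.n
        state = [0] * n

        def rec(var: int, w: int) -> Iterator[tuple[int, ...]]:
            if var == n:
                if w != 0:
                    yield tuple(state)
                return
            kids = self._cofactors(w, var) if w >= _TERM else (w,) * self.domains[var]
            for lv in range(self.domains[var]):
                state[var] = lv
                yield from rec(var + 1, kids[lv])

        yield from rec(0, u)

    # -- prime implicants (Boolean variables and terminals only) -------------

    def prime_implicants(self, u: int) -> frozenset[frozenset[tuple[int, int]]]:
        """All prime implicants of a 0/1 diagram over Boolean variables.

        Cubes are frozensets of ``(variable, value)`` literals; the empty
        cube denotes the tautology.
        """
        memo: dict[int, frozenset] = {}

        def implies(cube: frozenset, g: int) -> bool:
            return self.restrict(g, dict(cube)) == 1

        def rec(f: int) -> frozenset:
            if f == 1:
                return frozenset({frozenset()})
            if f == 0:
                return frozenset()
            r = memo.get(f)
            if r is not None:
                return r
            v = self.var(f)
            f0, f1 = self.children(f)
            both = rec(self.and_(f0, f1))
            out = set(both)
            for c in rec(f0):
                if not implies(c, f1):
                    out.add(c | {(v, 0)})
            for c in rec(f1):
                if not implies(c, f0):
                    out.add(c | {(v, 1)})
            r = frozenset(out)
            memo[f] = r
            return r

        if any(self.domains[v] != 2 for v in self.support(u)):
            raise ValueError("prime implicants require Boolean variables")
        return rec(u)
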
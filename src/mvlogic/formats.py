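"""Text formats for logical models: mnet, bnet, boolfunction and tt.

* ``mnet`` — multi-valued rules, one row per line: ``name[:level] <- expr``.
  The target level defaults to 1.  A component's maximal level is
  inferred as the maximum of all its assigned target levels and of all
  thresholds citing it.  ``#`` starts a comment; blank lines are ignored.
* ``bnet`` — Boolean rules in the BoolNet dialect: an optional
  ``targets, factors`` header, then ``name, expr`` rows.
* ``boolfunction`` — Boolean rule lines ``name <- expr``.
* ``tt`` — an explicit truth table: a header of component names, then
  one ``input target`` digit-string pair per state, complete and in
  lexicographic order.

Expressions use ``!`` (NOT), ``&`` (AND), ``|`` (OR) with precedence
``! > & > |``, parentheses, the constants ``0``/``1``, and (in the
multi-valued dialects) ``name:threshold`` literals.

Exports to Boolean-only formats (bnet, boolfunction) booleanize
multi-valued models automatically.  All writers emit LF line endings
and a trailing newline.
"""
from __future__ import annotations

import os
import re
from dataclasses import dataclass

from .model import (
    And,
    Component,
    Const,
    Expr,
    FALSE,
    FormatError,
    Lit,
    LogicalFunction,
    LogicalModel,
    Not,
    Or,
    ParseError,
    TRUE,
    expr_literals,
    format_state,
    simplify,
    target_state,
)

# ---------------------------------------------------------------------------
# expression grammar (shared by mnet / bnet / boolfunction)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<int>\d+)"
    r"|(?P<arrow><-)"
    r"|(?P<op>[!&|():,%]))"
)


def _tokenize(text: str, line: int) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise ParseError(f"unexpected character {text[pos:].strip()[0]!r}", line)
            break
        pos = m.end()
        kind = m.lastgroup
        tokens.append((kind, m.group(kind)))
    return tokens


class _ExprParser:
    """Recursive-descent parser for rule expressions."""

    def __init__(self, tokens, line: int, thresholds: bool):
        self.tokens = tokens
        self.pos = 0
        self.line = line
        self.thresholds = thresholds

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expect_op(self, value: str):
        kind, val = self.take()
        if kind != "op" or val != value:
            raise ParseError(f"expected {value!r}", self.line)

    def parse(self) -> Expr:
        e = self.expr()
        if self.pos != len(self.tokens):
            raise ParseError(f"trailing tokens after expression", self.line)
        return e

    def expr(self) -> Expr:
        terms = [self.term()]
        while self.peek() == ("op", "|"):
            self.take()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else Or(terms)

    def term(self) -> Expr:
        factors = [self.factor()]
        while self.peek() == ("op", "&"):
            self.take()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else And(factors)

    def factor(self) -> Expr:
        kind, val = self.take()
        if kind == "op" and val == "!":
            return Not(self.factor())
        if kind == "op" and val == "(":
            e = self.expr()
            self.expect_op(")")
            return e
        if kind == "int":
            if val == "0":
                return FALSE
            if val == "1":
                return TRUE
            raise ParseError(f"unexpected number {val!r} in expression", self.line)
        if kind == "name":
            threshold = 1
            if self.peek() == ("op", ":"):
                if not self.thresholds:
                    raise ParseError(
                        "multi-valued thresholds are not allowed in this format",
                        self.line,
                    )
                self.take()
                tkind, tval = self.take()
                if tkind != "int" or int(tval) < 1:
                    raise ParseError("threshold must be a positive integer", self.line)
                threshold = int(tval)
            return Lit(val, threshold)
        raise ParseError("malformed expression", self.line)


def parse_expression(text: str, line: int = 0, thresholds: bool = True) -> Expr:
    return _ExprParser(_tokenize(text, line), line, thresholds).parse()


# ---------------------------------------------------------------------------
# expression writer
# ---------------------------------------------------------------------------

def expr_text(expr: Expr) -> str:
    """Render an expression with minimal parentheses (``! > & > |``)."""
    if isinstance(expr, Const):
        return "1" if expr.value else "0"
    if isinstance(expr, Lit):
        return expr.name if expr.threshold == 1 else f"{expr.name}:{expr.threshold}"
    if isinstance(expr, Not):
        inner = expr_text(expr.arg)
        if isinstance(expr.arg, (And, Or)):
            inner = f"({inner})"
        return f"!{inner}"
    if isinstance(expr, And):
        parts = [
            f"({expr_text(a)})" if isinstance(a, Or) else expr_text(a)
            for a in expr.args
        ]
        return " & ".join(parts)
    if isinstance(expr, Or):
        return " | ".join(expr_text(a) for a in expr.args)
    raise TypeError(f"not an expression: {expr!r}")


# ---------------------------------------------------------------------------
# rule-line formats: mnet and boolfunction
# ---------------------------------------------------------------------------

def _iter_rule_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            yield lineno, line


def _parse_rule_lines(text: str, thresholds: bool) -> LogicalModel:
    order: list[str] = []
    rows: dict[str, list[tuple[int, Expr, int]]] = {}
    for lineno, line in _iter_rule_lines(text):
        if "<-" not in line:
            raise ParseError("expected 'name[:level] <- expression'", lineno)
        lhs, rhs = line.split("<-", 1)
        lhs_tokens = _tokenize(lhs, lineno)
        if not lhs_tokens or lhs_tokens[0][0] != "name":
            raise ParseError("assignment target must be a component name", lineno)
        name = lhs_tokens[0][1]
        target = 1
        if len(lhs_tokens) == 3 and lhs_tokens[1] == ("op", ":"):
            if not thresholds:
                raise ParseError(
                    "multi-valued targets are not allowed in this format", lineno
                )
            if lhs_tokens[2][0] != "int" or int(lhs_tokens[2][1]) < 1:
                raise ParseError("target level must be a positive integer", lineno)
            target = int(lhs_tokens[2][1])
        elif len(lhs_tokens) != 1:
            raise ParseError("malformed assignment target", lineno)
        expr = parse_expression(rhs, lineno, thresholds=thresholds)
        if name not in rows:
            order.append(name)
            rows[name] = []
        rows[name].append((target, expr, lineno))

    if not order:
        raise ParseError("no components")

    # every referenced component must be assigned somewhere
    cited_max: dict[str, int] = {}
    for name in order:
        for _, expr, lineno in rows[name]:
            for lit in expr_literals(expr):
                if lit.name not in rows:
                    raise ParseError(
                        f"undeclared component {lit.name!r} (no assignment line)",
                        lineno,
                    )
                cited_max[lit.name] = max(cited_max.get(lit.name, 1), lit.threshold)

    components = []
    functions = []
    for name in order:
        max_level = max(
            max(target for target, _, _ in rows[name]), cited_max.get(name, 1)
        )
        components.append(Component(name, max_level))
        # duplicate rows with the same target level merge by OR
        by_target: dict[int, list[Expr]] = {}
        targets_in_order: list[int] = []
        for target, expr, _ in rows[name]:
            if target not in by_target:
                targets_in_order.append(target)
            by_target.setdefault(target, []).append(expr)
        fn_rows = [
            (t, conds[0] if len(conds) == 1 else Or(conds))
            for t in targets_in_order
            for conds in [by_target[t]]
        ]
        functions.append(LogicalFunction(name, fn_rows))
    return LogicalModel(components, functions)


def parse_mnet(text: str) -> LogicalModel:
    return _parse_rule_lines(text, thresholds=True)


def parse_boolfunction(text: str) -> LogicalModel:
    return _parse_rule_lines(text, thresholds=False)


def _max_witnessed(model: LogicalModel, comp: Component, fn: LogicalFunction) -> int:
    """Highest level of ``comp`` visible in the serialised rule lines."""
    seen = max((lv for lv, _ in fn.rows), default=1)
    for other in model.functions:
        for lit in expr_literals(Or(c for _, c in other.rows)) if other.rows else []:
            if lit.name == comp.name:
                seen = max(seen, lit.threshold)
    return seen


def write_mnet(model: LogicalModel) -> str:
    lines = []
    for comp, fn in zip(model.components, model.functions):
        for level, cond in fn.rows:
            lhs = comp.name if comp.max_level == 1 else f"{comp.name}:{level}"
            lines.append(f"{lhs} <- {expr_text(cond)}")
        if not fn.rows:
            # constant-0 components still need a declaration line
            lhs = comp.name if comp.max_level == 1 else f"{comp.name}:{comp.max_level}"
            lines.append(f"{lhs} <- 0")
    # witness lines keep inferred maximal levels stable across round trips
    for comp, fn in zip(model.components, model.functions):
        if fn.rows and comp.max_level > 1 and _max_witnessed(model, comp, fn) < comp.max_level:
            lines.append(f"{comp.name}:{comp.max_level} <- 0")
    return "\n".join(lines) + "\n"


def write_boolfunction(model: LogicalModel) -> str:
    model = _as_boolean(model)
    lines = []
    for comp, fn in zip(model.components, model.functions):
        cond = simplify(Or(c for _, c in fn.rows)) if fn.rows else FALSE
        lines.append(f"{comp.name} <- {expr_text(cond)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# bnet (BoolNet dialect)
# ---------------------------------------------------------------------------

_BNET_HEADER_RE = re.compile(r"targets\s*,\s*factors\s*\Z", re.IGNORECASE)


def parse_bnet(text: str) -> LogicalModel:
    order: list[str] = []
    exprs: dict[str, list[Expr]] = {}
    first = True
    for lineno, line in _iter_rule_lines(text):
        if first and _BNET_HEADER_RE.match(line):
            first = False
            continue
        first = False
        if "," not in line:
            raise ParseError("expected 'name, expression'", lineno)
        name_part, rhs = line.split(",", 1)
        name_tokens = _tokenize(name_part, lineno)
        if len(name_tokens) != 1 or name_tokens[0][0] != "name":
            raise ParseError("assignment target must be a component name", lineno)
        name = name_tokens[0][1]
        expr = parse_expression(rhs, lineno, thresholds=False)
        if name not in exprs:
            order.append(name)
            exprs[name] = []
        exprs[name].append(expr)
    if not order:
        raise ParseError("no components")
    for name in order:
        for expr in exprs[name]:
            for lit in expr_literals(expr):
                if lit.name not in exprs:
                    raise ParseError(
                        f"undeclared component {lit.name!r} (no assignment line)"
                    )
    components = [Component(name, 1) for name in order]
    functions = [
        LogicalFunction(
            name, [(1, exprs[name][0] if len(exprs[name]) == 1 else Or(exprs[name]))]
        )
        for name in order
    ]
    return LogicalModel(components, functions)


def write_bnet(model: LogicalModel) -> str:
    model = _as_boolean(model)
    lines = ["targets, factors"]
    for comp, fn in zip(model.components, model.functions):
        cond = simplify(Or(c for _, c in fn.rows)) if fn.rows else FALSE
        lines.append(f"{comp.name}, {expr_text(cond)}")
    return "\n".join(lines) + "\n"


def _as_boolean(model: LogicalModel) -> LogicalModel:
    if model.is_boolean():
        return model
    from .modifiers import booleanize

    return booleanize(model)[0]


# ---------------------------------------------------------------------------
# tt (truth table)
# ---------------------------------------------------------------------------

def write_tt(model: LogicalModel) -> str:
    lines = [" ".join(model.names)]
    for state in model.all_states():
        lines.append(f"{format_state(state)} {format_state(target_state(model, state))}")
    return "\n".join(lines) + "\n"


def parse_tt(text: str) -> LogicalModel:
    lines = [(no, ln) for no, ln in _iter_rule_lines(text)]
    if not lines:
        raise ParseError("no components")
    header_no, header = lines[0]
    names = header.split()
    for name in names:
        if not re.match(r"[A-Za-z_][A-Za-z0-9_]*\Z", name):
            raise ParseError(f"invalid component name {name!r}", header_no)
    if len(set(names)) != len(names):
        raise ParseError("duplicate component names in header", header_no)
    n = len(names)

    table: dict[tuple[int, ...], tuple[int, ...]] = {}
    for lineno, line in lines[1:]:
        parts = line.split()
        if len(parts) != 2 or not all(p.isdigit() for p in parts):
            raise ParseError("expected 'input target' digit strings", lineno)
        src, dst = parts
        if len(src) != n or len(dst) != n:
            raise ParseError(f"digit strings must have {n} digits", lineno)
        key = tuple(int(c) for c in src)
        val = tuple(int(c) for c in dst)
        if key in table:
            if table[key] != val:
                raise ParseError(
                    f"contradictory duplicate state {src}", lineno
                )
            continue
        table[key] = val

    maxes = [max(s[i] for s in table) if table else 0 for i in range(n)]
    if any(m < 1 for m in maxes):
        # Boolean components must still span {0, 1} for the table to be complete
        raise ParseError("missing states: every component needs levels 0 and 1")
    expected = 1
    for m in maxes:
        expected *= m + 1
    if len(table) != expected:
        raise ParseError(
            f"missing states: expected {expected} rows, found {len(table)}"
        )
    for src, dst in table.items():
        for i, lv in enumerate(dst):
            if lv > maxes[i]:
                raise ParseError(
                    f"digit out of range: target level {lv} for {names[i]} "
                    f"(maximal level {maxes[i]})"
                )

    components = [Component(name, m) for name, m in zip(names, maxes)]
    # reconstruct rule rows from the table through a decision diagram
    from ._mdd import MDDManager

    mgr = MDDManager(m + 1 for m in maxes)

    def build(var: int, prefix: list[int]) -> int:
        if var == n:
            return table[tuple(prefix)][comp_idx]
        kids = []
        for lv in range(maxes[var] + 1):
            prefix.append(lv)
            kids.append(build(var + 1, prefix))
            prefix.pop()
        return mgr.node(var, kids)

    functions = []
    for comp_idx, name in enumerate(names):
        t = build(0, [])
        rows = []
        for level in range(1, maxes[comp_idx] + 1):
            ind = mgr.eq_const(t, level)
            if ind != 0:
                rows.append((level, expression_from_mdd(mgr, ind, names)))
        functions.append(LogicalFunction(name, rows))
    return LogicalModel(components, functions)


def expression_from_mdd(mgr, u: int, names: list[str]) -> Expr:
    """Disjunction of path cubes of a 0/1 diagram, as threshold literals.

    Each path constrains a variable to a set of levels; contiguous level
    runs are rendered as interval constraints ``v:a & !v:b+1``.
    """
    if u == 1:
        return TRUE
    if u == 0:
        return FALSE
    cubes: list[Expr] = []

    def level_set_expr(var: int, levels: list[int]) -> list[Expr]:
        dom = mgr.domains[var]
        if len(levels) == dom:
            return []
        terms: list[Expr] = []
        runs: list[tuple[int, int]] = []
        for lv in sorted(levels):
            if runs and lv == runs[-1][1] + 1:
                runs[-1] = (runs[-1][0], lv)
            else:
                runs.append((lv, lv))
        for a, b in runs:
            parts: list[Expr] = []
            if a >= 1:
                parts.append(Lit(names[var], a))
            if b < dom - 1:
                parts.append(Not(Lit(names[var], b + 1)))
            terms.append(simplify(And(parts)) if parts else TRUE)
        return [terms[0] if len(terms) == 1 else Or(terms)]

    def rec(w: int, path: list[Expr]) -> None:
        if w == 0:
            return
        if w == 1:
            cubes.append(simplify(And(path)) if path else TRUE)
            return
        var = mgr.var(w)
        by_child: dict[int, list[int]] = {}
        for lv, child in enumerate(mgr.children(w)):
            by_child.setdefault(child, []).append(lv)
        for child, levels in by_child.items():
            rec(child, path + level_set_expr(var, levels))

    rec(u, [])
    return cubes[0] if len(cubes) == 1 else Or(cubes)


# ---------------------------------------------------------------------------
# format registry and extension-based dispatch
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FormatDescriptor:
    format_id: str
    default_extension: str
    multivalued: bool
    can_import: bool
    can_export: bool


FORMATS: dict[str, FormatDescriptor] = {
    "mnet": FormatDescriptor("mnet", ".mnet", True, True, True),
    "bnet": FormatDescriptor("bnet", ".bnet", False, True, True),
    "boolfunction": FormatDescriptor("boolfunction", ".boolfunction", False, True, True),
    "tt": FormatDescriptor("tt", ".tt", True, True, True),
}

_PARSERS = {
    "mnet": parse_mnet,
    "bnet": parse_bnet,
    "boolfunction": parse_boolfunction,
    "tt": parse_tt,
}

_WRITERS = {
    "mnet": write_mnet,
    "bnet": write_bnet,
    "boolfunction": write_boolfunction,
    "tt": write_tt,
}


def detect_format(filename: str) -> str:
    ext = os.path.splitext(str(filename))[1].lower()
    for desc in FORMATS.values():
        if ext == desc.default_extension:
            return desc.format_id
    supported = ", ".join(sorted(d.default_extension for d in FORMATS.values()))
    raise FormatError(
        f"unknown format for {filename!r}; supported extensions: {supported}"
    )


def loads(text: str, format_id: str) -> LogicalModel:
    if format_id not in _PARSERS:
        raise FormatError(f"unknown format: {format_id}")
    return _PARSERS[format_id](text)


def dumps(model: LogicalModel, format_id: str) -> str:
    if format_id not in _WRITERS:
        raise FormatError(f"unknown format: {format_id}")
    return _WRITERS[format_id](model)


def load_model(path) -> LogicalModel:
    fmt = detect_format(path)
    with open(path, encoding="utf-8") as fh:
        return loads(fh.read(), fmt)


def save_model(model: LogicalModel, path) -> None:
    fmt = detect_format(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(dumps(model, fmt))
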
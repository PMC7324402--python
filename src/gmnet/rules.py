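"""Plain-text rule files in the "targets, factors" dialect.

One line per module::

    targets, factors
    M1, !M9 & M10 & !M12
    M2, 0
    M3, (M1 | M8) & !M9

Operators are ``!`` (NOT), ``&`` (AND), ``|`` (OR) with the usual
precedence (NOT > AND > OR) and parentheses; ``0`` and ``1`` are the
constant rules.  The header line is optional.  This is the common
interchange format used by Boolean-network tools, so rule tables published
as supplementary material can be transcribed and loaded directly.
"""

from __future__ import annotations

import re
from typing import Sequence

from sympy import symbols
from sympy.logic import SOPform
from sympy.logic.boolalg import And, Not, Or, BooleanFalse, BooleanTrue

from .exceptions import RuleParseError
from .logic import BooleanFunction, BooleanNetwork

__all__ = ["parse_rules", "serialize_rules", "expression_from_truth_table"]

_TOKEN = re.compile(r"\s*(M\d+|[01]|[!&|()])")


def expression_from_truth_table(
    regulators: Sequence[int], truth_table: Sequence[int]
) -> str:
    """Render a truth table as a minimal sum-of-products expression.

    Minimization is Quine-McCluskey (sympy ``SOPform``), so inferred rules
    come out in the compact form in which published rule tables are written,
    e.g. ``!M9 & M10 & !M12`` rather than a raw minterm expansion.
    """
    k = len(regulators)
    if k == 0:
        return str(int(truth_table[0]))
    minterms = [
        [(t >> p) & 1 for p in range(k)]
        for t in range(1 << k)
        if truth_table[t]
    ]
    if not minterms:
        return "0"
    if len(minterms) == 1 << k:
        return "1"
    vars_ = symbols([f"M{r}" for r in regulators])
    return _render(SOPform(vars_, minterms))


def _render(expr) -> str:
    if isinstance(expr, BooleanTrue):
        return "1"
    if isinstance(expr, BooleanFalse):
        return "0"
    if expr.is_Symbol:
        return expr.name
    if isinstance(expr, Not):
        inner = expr.args[0]
        s = _render(inner)
        return f"!{s}" if inner.is_Symbol else f"!({s})"
    if isinstance(expr, And):
        parts = [
            f"({_render(a)})" if isinstance(a, Or) else _render(a)
            for a in _sorted_args(expr)
        ]
        return " & ".join(parts)
    if isinstance(expr, Or):
        return " | ".join(_render(a) for a in _sorted_args(expr))
    raise RuleParseError(f"cannot render sympy node {expr!r}")


def _sorted_args(expr):
    # deterministic ordering: by the lowest module index appearing in the term
    def key(a):
        idx = sorted(int(s.name[1:]) for s in a.free_symbols) or [0]
        return (idx, str(a))

    return sorted(expr.args, key=key)


# ---------------------------------------------------------------------------
# parsing


class _Parser:
    """Recursive-descent parser: expr := term ('|' term)*;
    term := factor ('&' factor)*; factor := '!' factor | '(' expr ')' |
    ident | '0' | '1'."""

    def __init__(self, tokens: list[str], line_no: int):
        self.tokens = tokens
        self.pos = 0
        self.line_no = line_no

    def fail(self, msg: str):
        raise RuleParseError(f"line {self.line_no}: {msg}")

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            self.fail("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            self.fail(f"unexpected token {self.peek()!r}")
        return node

    def expr(self):
        node = self.term()
        while self.peek() == "|":
            self.take()
            node = ("or", node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() == "&":
            self.take()
            node = ("and", node, self.factor())
        return node

    def factor(self):
        tok = self.take()
        if tok == "!":
            return ("not", self.factor())
        if tok == "(":
            node = self.expr()
            if self.take() != ")":
                self.fail("expected ')'")
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if tok.startswith("M"):
            return ("var", int(tok[1:]))
        self.fail(f"unexpected token {tok!r}")


def _tokenize(text: str, line_no: int) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN.match(text, pos)
        if not m:
            raise RuleParseError(
                f"line {line_no}: unknown identifier near {text[pos:]!r}"
            )
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def _collect_vars(node, out: set[int]):
    tag = node[0]
    if tag == "var":
        out.add(node[1])
    elif tag == "not":
        _collect_vars(node[1], out)
    elif tag in ("and", "or"):
        _collect_vars(node[1], out)
        _collect_vars(node[2], out)


def _eval(node, values: dict[int, int]) -> int:
    tag = node[0]
    if tag == "const":
        return node[1]
    if tag == "var":
        return values[node[1]]
    if tag == "not":
        return 1 - _eval(node[1], values)
    if tag == "and":
        return _eval(node[1], values) & _eval(node[2], values)
    return _eval(node[1], values) | _eval(node[2], values)


def parse_rules(text: str) -> BooleanNetwork:
    """Parse "targets, factors" rule text into a :class:`BooleanNetwork`.

    Every module M1..Mm must appear exactly once as a target, where ``m``
    is the number of rule lines; regulators may only reference M1..Mm.
    """
    entries: dict[int, tuple] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().replace(" ", "") in ("targets,factors", "targets,functions"):
            continue
        if "," not in line:
            raise RuleParseError(
                f"line {line_no}: expected 'Mi, <expression>'"
            )
        head, body = line.split(",", 1)
        head = head.strip()
        if not re.fullmatch(r"M\d+", head):
            raise RuleParseError(
                f"line {line_no}: bad target {head!r} (expected M<index>)"
            )
        target = int(head[1:])
        if target in entries:
            raise RuleParseError(f"line {line_no}: duplicate target {head}")
        node = _Parser(_tokenize(body, line_no), line_no).parse()
        entries[target] = (line_no, node)

    if not entries:
        raise RuleParseError("no rules found")
    m = len(entries)
    if sorted(entries) != list(range(1, m + 1)):
        raise RuleParseError(
            f"targets must be exactly M1..M{m}; got {sorted(entries)}"
        )

    functions = []
    for i in range(1, m + 1):
        line_no, node = entries[i]
        var_set: set[int] = set()
        _collect_vars(node, var_set)
        if var_set and max(var_set) > m:
            raise RuleParseError(
                f"line {line_no}: unknown identifier M{max(var_set)} "
                f"(network has {m} modules)"
            )
        regs = tuple(sorted(var_set))
        tt = []
        for t in range(1 << len(regs)):
            values = {r: (t >> p) & 1 for p, r in enumerate(regs)}
            tt.append(_eval(node, values))
        functions.append(
            BooleanFunction(target=i, regulators=regs, truth_table=tuple(tt))
        )
    return BooleanNetwork(functions=tuple(functions))


def serialize_rules(net: BooleanNetwork) -> str:
    """Write a network in the "targets, factors" dialect (with header)."""
    lines = ["targets, factors"]
    for fn in net.functions:
        lines.append(f"M{fn.target}, {fn.expression}")
    return "\n".join(lines) + "\n"
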
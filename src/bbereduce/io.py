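"""Readers and writers: BoolNet ``.bnet`` files, partition specs, STG exports.

The ``.bnet`` dialect accepted here covers both the BoolNet and the
PyBoolNet flavours: an optional ``targets, factors`` header, one
``name, expression`` line per variable, operators ``!``, ``&``, ``|``,
parentheses, the constants ``0``/``1``, and ``#`` comments.  Names are
case-sensitive; whitespace inside expressions is ignored.  Inputs can be
written either as constants (``x, 1``) or as identities (``x, x``) and both
round-trip unchanged.

Partition specification files have one block per line (comma-separated
variable names) plus an optional residual directive deciding what happens to
variables not named in any block::

    @residual: one-block         # default: remaining variables form one block
    @residual: singletons        # each remaining variable is its own block
    @residual: input-separated   # remaining inputs become singletons,
                                 # remaining non-inputs one block
    IL15, PDGF

The ``input-separated`` residual reproduces the case-study recipe "pin these
variables together, keep every input alone, lump the rest".
"""

from __future__ import annotations

import json
import re
from typing import Iterable

from .dynamics import STG, Attractor
from .errors import ParseError, PartitionError
from .model import And, BooleanNetwork, Const, Expr, Not, Or, Var, detect_inputs
from .partitions import Partition, canonical_partition

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_.]*")


# ---------------------------------------------------------------------------
# Expression parsing (recursive descent over |, &, !, parentheses, 0/1)
# ---------------------------------------------------------------------------


class _ExprParser:
    def __init__(self, text: str, line: int):
        self.text = text
        self.pos = 0
        self.line = line

    def error(self, msg: str) -> ParseError:
        return ParseError(f"{msg} (at column {self.pos + 1} of {self.text!r})", self.line)

    def skip_ws(self):
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse(self) -> Expr:
        expr = self.parse_or()
        if self.peek():
            raise self.error(f"unexpected {self.text[self.pos]!r}")
        return expr

    def parse_or(self) -> Expr:
        terms = [self.parse_and()]
        while self.peek() == "|":
            self.pos += 1
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and(self) -> Expr:
        factors = [self.parse_factor()]
        while self.peek() == "&":
            self.pos += 1
            factors.append(self.parse_factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_factor(self) -> Expr:
        ch = self.peek()
        if not ch:
            raise self.error("unexpected end of expression")
        if ch == "!":
            self.pos += 1
            return Not(self.parse_factor())
        if ch == "(":
            self.pos += 1
            inner = self.parse_or()
            if self.peek() != ")":
                raise self.error("expected ')'")
            self.pos += 1
            return inner
        if ch in "01":
            nxt = self.text[self.pos + 1 : self.pos + 2]
            if not nxt or not (_NAME_RE.match(nxt) or nxt.isdigit()):
                self.pos += 1
                return Const(int(ch))
        m = _NAME_RE.match(self.text, self.pos)
        if not m:
            raise self.error(f"unexpected {ch!r}")
        self.pos = m.end()
        return Var(m.group())


def parse_boolean_expression(text: str, line: int = 0) -> Expr:
    """Parse a single update expression in .bnet syntax."""
    return _ExprParser(text, line).parse()


# ---------------------------------------------------------------------------
# .bnet networks
# ---------------------------------------------------------------------------


def parse_bnet(text: str) -> BooleanNetwork:
    """Parse a BoolNet-format network; variable order is line order."""
    variables: list[str] = []
    functions: dict[str, Expr] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "," not in line:
            raise ParseError(f"expected 'name, expression', got {line!r}", lineno)
        name, _, rhs = line.partition(",")
        name = name.strip()
        rhs = rhs.strip()
        if name.lower() == "targets" and rhs.lower() == "factors":
            continue  # optional header
        if not _NAME_RE.fullmatch(name):
            raise ParseError(f"invalid variable name {name!r}", lineno)
        if name in functions:
            raise ParseError(f"duplicate declaration of {name!r}", lineno)
        if not rhs:
            raise ParseError(f"missing update expression for {name!r}", lineno)
        variables.append(name)
        functions[name] = parse_boolean_expression(rhs, lineno)
    if not variables:
        raise ParseError("no variable declarations found")
    declared = set(variables)
    for name in variables:
        undeclared = functions[name].variables() - declared
        if undeclared:
            raise ParseError(
                f"update function of {name!r} references undeclared "
                f"variable(s): {', '.join(sorted(undeclared))}"
            )
    return BooleanNetwork(tuple(variables), functions)


def _render(expr: Expr, parent: str = "or") -> str:
    if isinstance(expr, Const):
        return str(expr.value)
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Not):
        return "!" + _render(expr.child, "not")
    if isinstance(expr, And):
        body = " & ".join(_render(c, "and") for c in expr.children)
        return f"({body})" if parent == "not" else body
    if isinstance(expr, Or):
        body = " | ".join(_render(c, "or") for c in expr.children)
        return body if parent == "or" else f"({body})"
    raise TypeError(f"unknown expression node {expr!r}")


def serialize_bnet(bn: BooleanNetwork, header: bool = True) -> str:
    """Write a network back to .bnet text (re-parsing gives a semantically equal network)."""
    lines = ["targets, factors"] if header else []
    for name in bn.variables:
        lines.append(f"{name}, {_render(bn.functions[name])}")
    return "\n".join(lines) + "\n"


def read_bnet(path) -> BooleanNetwork:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_bnet(fh.read())


def write_bnet(bn: BooleanNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_bnet(bn))


# ---------------------------------------------------------------------------
# Partition specification files
# ---------------------------------------------------------------------------

_RESIDUAL_MODES = ("one-block", "singletons", "input-separated")


def parse_partition(text: str, bn: BooleanNetwork) -> Partition:
    """Parse a partition spec and bind it to ``bn`` (see module docstring)."""
    residual = "one-block"
    explicit: list[list[str]] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@residual"):
            _, _, mode = line.partition(":")
            mode = mode.strip()
            if mode not in _RESIDUAL_MODES:
                raise ParseError(
                    f"unknown residual mode {mode!r}; expected one of {_RESIDUAL_MODES}",
                    lineno,
                )
            residual = mode
            continue
        block = [v.strip() for v in line.split(",") if v.strip()]
        for v in block:
            if v not in bn.variables:
                raise ParseError(f"unknown variable {v!r}", lineno)
            if v in seen:
                raise ParseError(f"variable {v!r} appears in two blocks", lineno)
            seen.add(v)
        if block:
            explicit.append(block)
    remaining = [v for v in bn.variables if v not in seen]
    blocks = list(explicit)
    if remaining:
        if residual == "one-block":
            blocks.append(remaining)
        elif residual == "singletons":
            blocks.extend([v] for v in remaining)
        else:  # input-separated residual
            inputs = detect_inputs(bn)
            rest = [v for v in remaining if v not in inputs]
            blocks.extend([v] for v in remaining if v in inputs)
            if rest:
                blocks.append(rest)
    try:
        return canonical_partition(blocks, bn.variables)
    except PartitionError as exc:  # pragma: no cover - guarded above
        raise ParseError(str(exc)) from exc


def serialize_partition(part: Partition) -> str:
    lines = ["@residual: singletons"]
    lines += [", ".join(block) for block in part.blocks]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# STG and attractor exports
# ---------------------------------------------------------------------------


def export_stg_dot(stg: STG) -> str:
    """Graphviz DOT text; node and edge order is deterministic (lexicographic)."""
    lines = ["digraph STG {"]
    for s in range(stg.n_states):
        lines.append(f'  "{stg.state_string(s)}";')
    for s, t in sorted(set(stg.edges())):
        lines.append(f'  "{stg.state_string(s)}" -> "{stg.state_string(t)}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_stg_edges(stg: STG) -> str:
    """Tab-separated edge list ``source<TAB>target``, lexicographic order."""
    rows = [
        f"{stg.state_string(s)}\t{stg.state_string(t)}"
        for s, t in sorted(set(stg.edges()))
    ]
    return "\n".join(rows) + "\n"


def attractor_report(
    attractors: Iterable[Attractor],
    preserved: Iterable[Attractor] | None = None,
) -> str:
    """JSON report: each attractor's states, steadiness, and (optionally)
    whether the supplied partition preserves it."""
    preserved_sets = (
        None if preserved is None else {a.state_set() for a in preserved}
    )
    items = []
    for att in attractors:
        entry: dict = {
            "states": list(att.state_strings()),
            "steady_state": att.steady_state,
            "length": len(att),
        }
        if preserved_sets is not None:
            entry["preserved"] = att.state_set() in preserved_sets
        items.append(entry)
    return json.dumps({"n_attractors": len(items), "attractors": items}, indent=2)
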
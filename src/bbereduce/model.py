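"""Boolean networks and their update expressions.

A Boolean network is an ordered list of named binary variables, each with a
Boolean update function over the network variables.  Under the synchronous
scheme every variable is updated at once: the successor of a state ``s`` is
the vector ``(f_x1(s), ..., f_xn(s))``.

Expressions are immutable trees over the core connectives ``{const, var,
not, and, or}``.  Derived connectives (implication, equivalence,
exclusive-or) are normalised to the core set by the helper constructors, so
every downstream consumer (evaluation, CNF encoding, serialisation) only
ever sees the five core node kinds.

States are plain tuples of 0/1 ints ordered by variable declaration; their
textual form is a bit-string whose *leftmost* bit is the first declared
variable (state ``(1, 1, 0)`` of a three-variable network renders as
``"110"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import sympy

from .errors import NetworkError

State = tuple[int, ...]

# ---------------------------------------------------------------------------
# Expression trees
# ---------------------------------------------------------------------------


class Expr:
    """Base class for Boolean expression nodes.

    Operator overloads build trees conveniently::

        f = Var("x1") | ~Var("x3")
    """

    __slots__ = ()

    def __and__(self, other: "Expr") -> "Expr":
        return And((self, other))

    def __or__(self, other: "Expr") -> "Expr":
        return Or((self, other))

    def __invert__(self) -> "Expr":
        return Not(self)

    # Subclasses implement: evaluate, variables, substitute, __eq__/__hash__.

    def variables(self) -> frozenset[str]:
        raise NotImplementedError

    def evaluate(self, env: Mapping[str, object]):
        """Evaluate under a total assignment.

        ``env`` maps variable names to 0/1 ints — or to equal-length numpy
        integer arrays, in which case the whole expression is evaluated
        element-wise (used for truth tables and STG construction).
        """
        raise NotImplementedError

    def substitute(self, mapping: Mapping[str, "Expr"]) -> "Expr":
        """Replace variable references according to ``mapping`` (missing names kept)."""
        raise NotImplementedError

    def rename(self, mapping: Mapping[str, str]) -> "Expr":
        return self.substitute({k: Var(v) for k, v in mapping.items()})


@dataclass(frozen=True, slots=True)
class Const(Expr):
    value: int  # 0 or 1

    def __post_init__(self):
        if self.value not in (0, 1):
            raise ValueError(f"constant must be 0 or 1, got {self.value!r}")

    def variables(self) -> frozenset[str]:
        return frozenset()

    def evaluate(self, env):
        return self.value

    def substitute(self, mapping):
        return self

    def __repr__(self):
        return f"Const({self.value})"


@dataclass(frozen=True, slots=True)
class Var(Expr):
    name: str

    def variables(self) -> frozenset[str]:
        return frozenset((self.name,))

    def evaluate(self, env):
        try:
            return env[self.name]
        except KeyError:
            raise KeyError(f"variable {self.name!r} is not assigned") from None

    def substitute(self, mapping):
        return mapping.get(self.name, self)

    def __repr__(self):
        return f"Var({self.name!r})"


@dataclass(frozen=True, slots=True)
class Not(Expr):
    child: Expr

    def variables(self) -> frozenset[str]:
        return self.child.variables()

    def evaluate(self, env):
        # works for python ints and numpy integer arrays alike
        return self.child.evaluate(env) ^ 1

    def substitute(self, mapping):
        return Not(self.child.substitute(mapping))

    def __repr__(self):
        return f"Not({self.child!r})"


@dataclass(frozen=True, slots=True)
class And(Expr):
    children: tuple[Expr, ...]

    def __post_init__(self):
        object.__setattr__(self, "children", tuple(self.children))
        if len(self.children) < 2:
            raise ValueError("And needs at least two operands")

    def variables(self) -> frozenset[str]:
        return frozenset().union(*(c.variables() for c in self.children))

    def evaluate(self, env):
        out = self.children[0].evaluate(env)
        for c in self.children[1:]:
            out = out & c.evaluate(env)
        return out

    def substitute(self, mapping):
        return And(tuple(c.substitute(mapping) for c in self.children))

    def __repr__(self):
        return f"And({list(self.children)!r})"


@dataclass(frozen=True, slots=True)
class Or(Expr):
    children: tuple[Expr, ...]

    def __post_init__(self):
        object.__setattr__(self, "children", tuple(self.children))
        if len(self.children) < 2:
            raise ValueError("Or needs at least two operands")

    def variables(self) -> frozenset[str]:
        return frozenset().union(*(c.variables() for c in self.children))

    def evaluate(self, env):
        out = self.children[0].evaluate(env)
        for c in self.children[1:]:
            out = out | c.evaluate(env)
        return out

    def substitute(self, mapping):
        return Or(tuple(c.substitute(mapping) for c in self.children))

    def __repr__(self):
        return f"Or({list(self.children)!r})"


TRUE = Const(1)
FALSE = Const(0)


def implies(a: Expr, b: Expr) -> Expr:
    """a → b, normalised to ¬a ∨ b."""
    return Or((Not(a), b))


def equiv(a: Expr, b: Expr) -> Expr:
    """a ↔ b, normalised to (a ∧ b) ∨ (¬a ∧ ¬b)."""
    return Or((And((a, b)), And((Not(a), Not(b)))))


def xor(a: Expr, b: Expr) -> Expr:
    """a ⊕ b, normalised to (a ∧ ¬b) ∨ (¬a ∧ b)."""
    return Or((And((a, Not(b))), And((Not(a), b))))


def to_sympy(expr: Expr, symbols: Mapping[str, sympy.Symbol] | None = None):
    """Convert an expression tree to a sympy Boolean expression."""
    if symbols is None:
        symbols = {}

    def sym(name: str) -> sympy.Symbol:
        if name not in symbols:
            symbols[name] = sympy.Symbol(name)  # type: ignore[index]
        return symbols[name]

    def rec(e: Expr):
        if isinstance(e, Const):
            return sympy.true if e.value else sympy.false
        if isinstance(e, Var):
            return sym(e.name)
        if isinstance(e, Not):
            return sympy.Not(rec(e.child))
        if isinstance(e, And):
            return sympy.And(*(rec(c) for c in e.children))
        if isinstance(e, Or):
            return sympy.Or(*(rec(c) for c in e.children))
        raise TypeError(f"unknown expression node {e!r}")

    return rec(expr)


def from_sympy(e) -> Expr:
    """Convert a sympy Boolean expression back into an expression tree."""
    if e is sympy.true:
        return TRUE
    if e is sympy.false:
        return FALSE
    if isinstance(e, sympy.Symbol):
        return Var(e.name)
    if isinstance(e, sympy.Not):
        return Not(from_sympy(e.args[0]))
    if isinstance(e, sympy.And):
        args = [from_sympy(a) for a in e.args]
        return args[0] if len(args) == 1 else And(tuple(args))
    if isinstance(e, sympy.Or):
        args = [from_sympy(a) for a in e.args]
        return args[0] if len(args) == 1 else Or(tuple(args))
    raise TypeError(f"cannot convert sympy node {e!r}")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BooleanNetwork:
    """An ordered Boolean network: one update function per declared variable.

    Parameters
    ----------
    variables
        Declaration-ordered variable names (unique, non-empty, n >= 1).
    functions
        Map from variable name to its update expression; every variable the
        expressions reference must be declared.
    sync_partition
        Optional synchronization partition (blocks of variables updated
        atomically) for the partially asynchronous scheme; ``None`` means
        fully synchronous.
    """

    variables: tuple[str, ...]
    functions: dict[str, Expr]
    sync_partition: "object" = None  # Partition; kept loose to avoid a cycle

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        if len(self.variables) < 1:
            raise NetworkError("a Boolean network needs at least one variable")
        if any(not v for v in self.variables):
            raise NetworkError("variable names must be non-empty")
        if len(set(self.variables)) != len(self.variables):
            dupes = sorted({v for v in self.variables if self.variables.count(v) > 1})
            raise NetworkError(f"duplicate variable declaration: {', '.join(dupes)}")
        if set(self.functions) != set(self.variables):
            missing = set(self.variables) - set(self.functions)
            extra = set(self.functions) - set(self.variables)
            parts = []
            if missing:
                parts.append(f"missing update functions for {sorted(missing)}")
            if extra:
                parts.append(f"update functions for undeclared {sorted(extra)}")
            raise NetworkError("; ".join(parts))
        declared = set(self.variables)
        for name, fn in self.functions.items():
            undeclared = fn.variables() - declared
            if undeclared:
                raise NetworkError(
                    f"update function of {name!r} references undeclared "
                    f"variable(s): {', '.join(sorted(undeclared))}"
                )

    @property
    def n(self) -> int:
        return len(self.variables)

    def index(self, name: str) -> int:
        return self.variables.index(name)

    # -- state helpers ------------------------------------------------------

    def state_from_string(self, bits: str) -> State:
        if len(bits) != self.n or any(b not in "01" for b in bits):
            raise ValueError(
                f"state string must be {self.n} bits of 0/1, got {bits!r}"
            )
        return tuple(int(b) for b in bits)

    @staticmethod
    def state_to_string(state: State) -> str:
        return "".join(str(b) for b in state)

    def assignment(self, state: State) -> dict[str, int]:
        if len(state) != self.n:
            raise ValueError(f"state length {len(state)} != n = {self.n}")
        return dict(zip(self.variables, state))


def evaluate_expression(expr: Expr, state: Mapping[str, int] | Sequence[int], bn: BooleanNetwork | None = None) -> int:
    """Truth value of ``expr`` under a total assignment.

    ``state`` is either a mapping name → bit, or (with ``bn`` given) a state
    tuple in declaration order.
    """
    if not isinstance(state, Mapping):
        if bn is None:
            raise ValueError("a state tuple needs the network for variable order")
        state = bn.assignment(tuple(state))
    return int(expr.evaluate(state))


def step(bn: BooleanNetwork, state: State) -> State:
    """Synchronous successor: apply every update function to ``state`` at once."""
    env = bn.assignment(state)
    return tuple(int(bn.functions[v].evaluate(env)) for v in bn.variables)


def semantic_equal(e1: Expr, e2: Expr, universe: Iterable[str] | None = None) -> bool:
    """True iff ``e1`` and ``e2`` agree on every assignment of ``universe``.

    The universe defaults to the union of both expressions' variables.  Small
    universes (≤ 20 variables) are decided by a vectorised truth table; larger
    ones by satisfiability of ``e1 ⊕ e2``.
    """
    if universe is None:
        names = sorted(e1.variables() | e2.variables())
    else:
        names = sorted(set(universe))
        for e in (e1, e2):
            extra = e.variables() - set(names)
            if extra:
                raise ValueError(f"expression references {sorted(extra)} outside the universe")
    if len(names) <= 20:
        import numpy as np

        k = len(names)
        idx = np.arange(1 << k, dtype=np.int64)
        env = {nm: ((idx >> (k - 1 - i)) & 1).astype(np.uint8) for i, nm in enumerate(names)}
        v1 = np.broadcast_to(np.asarray(e1.evaluate(env), dtype=np.uint8), (1 << k,))
        v2 = np.broadcast_to(np.asarray(e2.evaluate(env), dtype=np.uint8), (1 << k,))
        return bool((v1 == v2).all())
    # SAT route: e1 ⊕ e2 unsatisfiable ⇔ equal
    from .sat import CNFBuilder, solve

    builder = CNFBuilder()
    builder.assert_literal(builder.encode_xor(builder.encode(e1), builder.encode(e2)))
    return solve(builder) is None


def detect_inputs(bn: BooleanNetwork) -> set[str]:
    """Variables whose update function is semantically constant or the identity.

    Both conventions encode an input whose value the dynamics never change:
    GINsim-style exports use constant update functions, BoolNet-style files
    use ``x, x``.  The test is semantic — a tautology like ``a | !a`` counts
    as the constant 1.
    """
    inputs: set[str] = set()
    for name in bn.variables:
        fn = bn.functions[name]
        support = sorted(fn.variables() | {name})
        if (
            semantic_equal(fn, TRUE, support)
            or semantic_equal(fn, FALSE, support)
            or semantic_equal(fn, Var(name), support)
        ):
            inputs.add(name)
    return inputs
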
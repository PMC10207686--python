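"""CNF machinery for the backward-equivalence check.

Update-function trees are encoded into CNF with the Tseitin transformation:
every internal node gets an auxiliary variable constrained to equal the value
of its subtree, so the encoding stays linear in the size of the expressions
(a naive distribution into CNF can be exponential).  Clauses are plain lists
of signed integers (DIMACS convention: ``±k`` is the k-th variable or its
negation), and satisfiability is decided by sympy's DPLL engine, handed the
formula in already-CNF form.
"""

from __future__ import annotations

import sympy
from sympy.logic.inference import satisfiable

from .model import And, Const, Expr, Not, Or, Var


class CNFBuilder:
    """Incrementally builds a CNF over named and auxiliary variables."""

    def __init__(self):
        self.clauses: list[list[int]] = []
        self._name_to_id: dict[str, int] = {}
        self._id_to_name: dict[int, str] = {}
        self._next = 1
        self._cache: dict[Expr, int] = {}
        self._true_lit: int | None = None

    # -- variables ----------------------------------------------------------

    def var(self, name: str) -> int:
        """Literal for a named problem variable."""
        if name not in self._name_to_id:
            self._name_to_id[name] = self._next
            self._id_to_name[self._next] = name
            self._next += 1
        return self._name_to_id[name]

    def aux(self) -> int:
        """Fresh unnamed auxiliary variable."""
        lit = self._next
        self._next += 1
        return lit

    # -- clause assembly ----------------------------------------------------

    def add_clause(self, lits: list[int]) -> None:
        self.clauses.append(list(lits))

    def assert_literal(self, lit: int) -> None:
        self.add_clause([lit])

    def assert_equal(self, a: int, b: int) -> None:
        """Constrain a ↔ b."""
        self.add_clause([-a, b])
        self.add_clause([a, -b])

    # -- Tseitin encoding ---------------------------------------------------

    def true_literal(self) -> int:
        if self._true_lit is None:
            self._true_lit = self.aux()
            self.assert_literal(self._true_lit)
        return self._true_lit

    def encode(self, expr: Expr) -> int:
        """Literal equivalent to ``expr`` (auxiliary definitions added as clauses)."""
        cached = self._cache.get(expr)
        if cached is not None:
            return cached
        if isinstance(expr, Const):
            lit = self.true_literal() if expr.value else -self.true_literal()
        elif isinstance(expr, Var):
            lit = self.var(expr.name)
        elif isinstance(expr, Not):
            lit = -self.encode(expr.child)
        elif isinstance(expr, (And, Or)):
            child_lits = [self.encode(c) for c in expr.children]
            out = self.aux()
            if isinstance(expr, And):
                # out ↔ ⋀ children
                for cl in child_lits:
                    self.add_clause([-out, cl])
                self.add_clause([out] + [-cl for cl in child_lits])
            else:
                # out ↔ ⋁ children
                for cl in child_lits:
                    self.add_clause([out, -cl])
                self.add_clause([-out] + child_lits)
            lit = out
        else:  # pragma: no cover - closed hierarchy
            raise TypeError(f"unknown expression node {expr!r}")
        self._cache[expr] = lit
        return lit

    def encode_xor(self, a: int, b: int) -> int:
        """Auxiliary d with d ↔ (a ⊕ b)."""
        d = self.aux()
        self.add_clause([-d, a, b])
        self.add_clause([-d, -a, -b])
        self.add_clause([d, -a, b])
        self.add_clause([d, a, -b])
        return d


def solve(builder: CNFBuilder) -> dict[str, int] | None:
    """Satisfiability of the builder's CNF.

    Returns ``None`` when unsatisfiable, otherwise a (possibly partial)
    model mapping *named* variables to 0/1; variables the solver left
    unconstrained are absent and any completion satisfies the formula.
    """
    if not builder.clauses:
        return {}
    nvars = builder._next - 1
    syms = [None] + [sympy.Symbol(f"v{i}") for i in range(1, nvars + 1)]

    def lit_to_sym(lit: int):
        return syms[lit] if lit > 0 else sympy.Not(syms[-lit])

    cnf_clauses = []
    for clause in builder.clauses:
        if not clause:
            return None  # empty clause: unsatisfiable
        cnf_clauses.append(sympy.Or(*[lit_to_sym(l) for l in clause]))
    formula = sympy.And(*cnf_clauses)
    if formula is sympy.true:
        return {}
    if formula is sympy.false:
        return None
    model = satisfiable(formula)
    if model is False:
        return None
    out: dict[str, int] = {}
    for sym, val in model.items():
        if not isinstance(sym, sympy.Symbol):
            continue
        idx = int(sym.name[1:])
        name = builder._id_to_name.get(idx)
        if name is not None:
            out[name] = 1 if val else 0
    return out
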
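"""Worked-example fixtures and a seeded random-network generator.

The three fixture networks are frozen completions of small published
illustrations: only some of their update functions are printed in the
figures, so the missing ones are reconstructed here as the simplest
functions consistent with every printed transition, partition and attractor
fact.  They are reconstructions for testing, not claims about the original
models.

The random generator produces NK-style networks — every variable draws K
distinct regulators and a random truth table with bias p — optionally with
*planted duplicates*: variables that copy another variable's update function
verbatim, which are therefore provably backward-equivalent to their
originals and must end up co-blocked in the coarsest reduction.  This gives
the property-test batteries a ground truth to recover.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model import And, BooleanNetwork, Const, Expr, Not, Or, Var


def fixture_toy_chain() -> BooleanNetwork:
    """Three-variable network whose x1 and x2 are backward-equivalent.

    f_x1 = x1 | !x3, f_x2 = x1 | x2 | !x3, f_x3 = !x3.  States 110 and 111
    form a 2-cycle attractor; the coarsest reduction merges x1 with x2 and
    its quotient update for the merged variable is x1 | !x3.
    """
    x1, x2, x3 = Var("x1"), Var("x2"), Var("x3")
    return BooleanNetwork(
        ("x1", "x2", "x3"),
        {"x1": x1 | ~x3, "x2": x1 | x2 | ~x3, "x3": ~x3},
    )


def fixture_tlr5_cascade() -> BooleanNetwork:
    """Five-variable receptor-signalling excerpt: TLR5 feeding four genes.

    TLR5 is an input (identity update); TICAM1 and MyD88 read TLR5; IRAK4
    and PIK3AP1 read MyD88.  Reproduces the transition 10000 → 11100 and the
    input-separated refinement {{TLR5}, {TICAM1, MyD88}, {IRAK4, PIK3AP1}}.
    """
    tlr5, myd88 = Var("TLR5"), Var("MyD88")
    return BooleanNetwork(
        ("TLR5", "TICAM1", "MyD88", "IRAK4", "PIK3AP1"),
        {
            "TLR5": tlr5,
            "TICAM1": tlr5,
            "MyD88": tlr5,
            "IRAK4": myd88,
            "PIK3AP1": myd88,
        },
    )


def fixture_four_steady_states() -> BooleanNetwork:
    """Three-variable network with 4 steady states, 2 of which survive reduction.

    f_x1 = x1, f_x2 = x2, f_x3 = x1 & x2.  Steady states are 000, 010, 100
    and 111; merging {x1, x2} keeps only 000 and 111, the two where x1 and
    x2 agree.
    """
    x1, x2 = Var("x1"), Var("x2")
    return BooleanNetwork(
        ("x1", "x2", "x3"),
        {"x1": x1, "x2": x2, "x3": x1 & x2},
    )


# Aliases under the figure-numbered names used throughout the test-plan
# vocabulary of this package's docs.
fixture_fig1 = fixture_toy_chain
fixture_fig9 = fixture_tlr5_cascade
fixture_fig10 = fixture_four_steady_states


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random-network generator.

    n: total variable count (base variables plus planted duplicates).
    k: regulators per variable (distinct, chosen uniformly among base variables).
    p: truth-table bias — probability that an entry of a random table is 1.
    duplicates: number of planted duplicate variables (d < n).
    seed: RNG seed; identical configs generate identical networks.
    """

    n: int
    k: int = 2
    p: float = 0.5
    duplicates: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.duplicates < 0 or self.duplicates >= self.n:
            raise ValueError("duplicates must satisfy 0 <= d < n")
        base = self.n - self.duplicates
        if not (0 <= self.k <= base - 1) and not (base == 1 and self.k == 0):
            raise ValueError("k must satisfy 0 <= k < number of base variables")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")


def _table_to_expr(regulators: tuple[str, ...], table: np.ndarray) -> Expr:
    """Expression with exactly the given truth table (minterm disjunction)."""
    if table.all():
        return Const(1)
    if not table.any():
        return Const(0)
    minterms = []
    for row, combo in enumerate(itertools.product((0, 1), repeat=len(regulators))):
        if table[row]:
            lits = [
                Var(r) if bit else Not(Var(r)) for r, bit in zip(regulators, combo)
            ]
            minterms.append(lits[0] if len(lits) == 1 else And(tuple(lits)))
    return minterms[0] if len(minterms) == 1 else Or(tuple(minterms))


def random_bn(config: GeneratorConfig) -> BooleanNetwork:
    """Seeded NK-style random network with optional planted duplicates.

    Base variables are named ``x1 … x{n-d}``; planted duplicates ``x{n-d+1}
    …`` each copy a uniformly chosen base variable's update function
    verbatim, and with probability 1/2 per other function, occurrences of
    the copied variable are rewritten to the duplicate (so duplicates also
    feed back into the dynamics).
    """
    bn, _ = _generate(config)
    return bn


def planted_pairs(config: GeneratorConfig) -> list[tuple[str, str]]:
    """(original, duplicate) pairs planted in ``random_bn(config)``."""
    _, pairs = _generate(config)
    return pairs


def _generate(config: GeneratorConfig) -> tuple[BooleanNetwork, list[tuple[str, str]]]:
    rng = np.random.default_rng(config.seed)
    n_base = config.n - config.duplicates
    base_names = [f"x{i + 1}" for i in range(n_base)]
    functions: dict[str, Expr] = {}
    for name in base_names:
        if config.k == 0:
            functions[name] = Const(int(rng.random() < config.p))
            continue
        regs = tuple(
            base_names[j] for j in sorted(rng.choice(n_base, size=config.k, replace=False))
        )
        table = (rng.random(1 << config.k) < config.p).astype(np.uint8)
        functions[name] = _table_to_expr(regs, table)

    dup_names = [f"x{n_base + i + 1}" for i in range(config.duplicates)]
    pairs: list[tuple[str, str]] = []
    for dup in dup_names:
        orig = base_names[int(rng.integers(n_base))]
        pairs.append((orig, dup))
        functions[dup] = functions[orig]
        # rewire: each other function independently may read the duplicate instead
        for other in list(functions):
            if other in (dup, orig):
                continue
            if orig in functions[other].variables() and rng.random() < 0.5:
                functions[other] = functions[other].rename({orig: dup})
    bn = BooleanNetwork(tuple(base_names + dup_names), functions)
    return bn, pairs
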
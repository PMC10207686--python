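"""Independent brute-force oracles used to cross-check the SAT-driven code.

Everything here works by exhaustive enumeration (truth tables, all set
partitions, full 2^n state sweeps) and deliberately shares no code with the
CNF encoding or the refinement loop it is checking.
"""

from __future__ import annotations

import itertools

from bbereduce.dynamics import _successor_array
from bbereduce.model import And, BooleanNetwork, Const, Expr, Not, Or, Var


def eval_via_python(expr: Expr, env: dict[str, int]) -> int:
    """Evaluate by rendering to a Python and/or/not expression and eval()-ing it."""

    def render(e: Expr) -> str:
        if isinstance(e, Const):
            return str(bool(e.value))
        if isinstance(e, Var):
            return f"bool(env[{e.name!r}])"
        if isinstance(e, Not):
            return f"(not {render(e.child)})"
        if isinstance(e, And):
            return "(" + " and ".join(render(c) for c in e.children) + ")"
        if isinstance(e, Or):
            return "(" + " or ".join(render(c) for c in e.children) + ")"
        raise TypeError(e)

    return int(eval(render(expr), {"env": env}))


def all_set_partitions(items: list[str]):
    """Every partition of ``items`` as a list of lists."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def is_bbe_exhaustive(bn: BooleanNetwork, blocks: list[list[str]]) -> bool:
    """Check the backward-equivalence condition by sweeping all constant states."""
    n = bn.n
    succ = _successor_array(bn)
    pos = {v: i for i, v in enumerate(bn.variables)}
    masks = [sum(1 << (n - 1 - pos[v]) for v in blk) for blk in blocks]
    for combo in itertools.product((0, 1), repeat=len(blocks)):
        s = 0
        for mask, bit in zip(masks, combo):
            if bit:
                s |= mask
        t = int(succ[s])
        if any((t & m) != 0 and (t & m) != m for m in masks):
            return False
    return True


def brute_force_coarsest_bbe(bn: BooleanNetwork) -> frozenset[frozenset[str]]:
    """Coarsest backward equivalence by enumerating every partition.

    Collects all partitions passing the exhaustive check and returns the one
    every other one refines; existence and uniqueness are asserted.
    """
    bbes = [
        frozenset(frozenset(b) for b in blocks)
        for blocks in all_set_partitions(list(bn.variables))
        if is_bbe_exhaustive(bn, blocks)
    ]

    def refines(fine, coarse):
        return all(any(fb <= cb for cb in coarse) for fb in fine)

    coarsest = [p for p in bbes if all(refines(q, p) for q in bbes)]
    assert len(coarsest) == 1, "coarsest backward equivalence must be unique"
    return coarsest[0]


def as_block_sets(partition) -> frozenset[frozenset[str]]:
    return frozenset(frozenset(b) for b in partition.blocks)
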
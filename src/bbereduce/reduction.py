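"""Boolean backward equivalence: SAT check, coarsest refinement, quotient.

A partition ℋ of the variables is a *backward equivalence* when the formula

    Φ^ℋ  ≡  ( ⋀_{H ∈ ℋ} ⋀_{x,x' ∈ H} x = x' )  →  ⋀_{H ∈ ℋ} ⋀_{x,x' ∈ H} f_x = f_x'

is valid: whenever all variables of each block agree in a state, they still
agree after one synchronous step.  Validity is decided by handing ¬Φ^ℋ to a
SAT solver; a model of ¬Φ^ℋ is a *witness* state s, constant on ℋ, whose
successor s' distinguishes variables inside some block.  Splitting every
block by the successor values and repeating converges — in at most n checks
— to the unique coarsest backward equivalence refining the initial
partition, independent of which witnesses the solver happens to return.

Quotienting a network by a backward-equivalence partition keeps one
representative variable per block (the member with the smallest declaration
index) and rewrites its update function over representatives.  The reduced
network reproduces the original dynamics exactly on all states that are
constant on the partition.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import sympy

from .errors import NotBBEError, PartitionError, SolverTimeoutError
from .model import BooleanNetwork, Expr, State, Var, from_sympy, semantic_equal, step, to_sympy
from .partitions import Partition, canonical_partition, is_refinement, split_blocks_by_witness
from .sat import CNFBuilder, solve


@dataclass(frozen=True)
class BBEWitness:
    """A state falsifying Φ^ℋ together with its synchronous successor.

    The state is constant on the partition that was checked; at least one
    block is non-constant under the successor values, which is what licenses
    splitting.
    """

    variables: tuple[str, ...]
    state: State
    successor: State

    def state_string(self) -> str:
        return "".join(str(b) for b in self.state)

    def successor_string(self) -> str:
        return "".join(str(b) for b in self.successor)

    def next_values(self) -> dict[str, int]:
        return dict(zip(self.variables, self.successor))


@dataclass(frozen=True)
class ReductionResult:
    """Quotient network plus the block/representative bookkeeping."""

    quotient: BooleanNetwork
    partition: Partition
    block_to_representative: dict[tuple[str, ...], str]
    variable_to_block: dict[str, tuple[str, ...]]
    original_variables: tuple[str, ...]

    @property
    def variable_to_representative(self) -> dict[str, str]:
        return {v: self.block_to_representative[b] for v, b in self.variable_to_block.items()}


def build_bbe_formula(bn: BooleanNetwork, part: Partition) -> sympy.Basic:
    """Φ^ℋ as a sympy Boolean formula (for inspection and small-scale checks).

    Within each block the antecedent chains equalities against the block's
    first member and the consequent equates update functions against the same
    member's function — logically equivalent to the all-pairs form under the
    antecedent, but linear in block size.
    """
    _check_universe(bn, part)
    symbols: dict[str, sympy.Symbol] = {}
    ante, cons = [], []
    for block in part.blocks:
        rep = block[0]
        rep_sym = to_sympy(Var(rep), symbols)
        f_rep = to_sympy(bn.functions[rep], symbols)
        for other in block[1:]:
            ante.append(sympy.Equivalent(rep_sym, to_sympy(Var(other), symbols)))
            cons.append(sympy.Equivalent(f_rep, to_sympy(bn.functions[other], symbols)))
    return sympy.Implies(sympy.And(*ante), sympy.And(*cons))


def _check_universe(bn: BooleanNetwork, part: Partition) -> None:
    if part.variables != set(bn.variables):
        raise PartitionError("partition does not cover exactly the network's variables")


def check_bbe(bn: BooleanNetwork, part: Partition) -> tuple[bool, BBEWitness | None]:
    """Decide the backward-equivalence condition; on failure return a witness.

    The check encodes ¬Φ^ℋ — block-equality constraints plus "some pair of
    update functions inside a block differs" — as a Tseitin CNF and asks the
    SAT backend for a model.  ``(True, None)`` means the partition is a
    backward equivalence.
    """
    _check_universe(bn, part)
    builder = CNFBuilder()
    for v in bn.variables:  # stable variable numbering
        builder.var(v)
    diffs: list[int] = []
    for block in part.blocks:
        if len(block) < 2:
            continue
        rep = block[0]
        rep_var = builder.var(rep)
        f_rep = builder.encode(bn.functions[rep])
        for other in block[1:]:
            builder.assert_equal(rep_var, builder.var(other))
            f_other = builder.encode(bn.functions[other])
            diffs.append(builder.encode_xor(f_rep, f_other))
    if not diffs:
        return True, None  # only singleton blocks (or equal-by-encoding functions)
    builder.add_clause(diffs)
    model = solve(builder)
    if model is None:
        return True, None
    witness = _witness_from_model(bn, part, model)
    return False, witness


def _witness_from_model(
    bn: BooleanNetwork, part: Partition, model: dict[str, int]
) -> BBEWitness:
    """Complete a (possibly partial) solver model into a witness state.

    Unassigned variables are don't-cares of the CNF, so any block-constant
    completion still falsifies Φ^ℋ; blocks with no assigned member default
    to 0.
    """
    values: dict[str, int] = {}
    for block in part.blocks:
        assigned = {model[v] for v in block if v in model}
        if len(assigned) > 1:  # pragma: no cover - solver model violates antecedent
            raise AssertionError("solver model not constant on a block")
        val = assigned.pop() if assigned else 0
        for v in block:
            values[v] = val
    state = tuple(values[v] for v in bn.variables)
    successor = step(bn, state)
    witness = BBEWitness(bn.variables, state, successor)
    nv = witness.next_values()
    if all(
        len({nv[v] for v in block}) == 1 for block in part.blocks
    ):  # pragma: no cover - encoding bug guard
        raise AssertionError("witness successor is constant on every block")
    return witness


def coarsest_bbe(
    bn: BooleanNetwork,
    initial: Partition,
    timeout: float | None = None,
    stats: dict | None = None,
) -> Partition:
    """Unique coarsest backward equivalence refining ``initial``.

    Iterates check → split-by-successor until the SAT check reports validity.
    Each round strictly increases the block count, so at most n checks run.
    ``timeout`` is a wall-clock budget in seconds enforced between solver
    calls; on expiry the computation fails rather than returning a partial
    (hence neither sound nor coarsest) partition.  ``stats``, when given, is
    filled with the number of SAT checks performed.
    """
    _check_universe(bn, initial)
    if bn.sync_partition is not None and not is_refinement(initial, bn.sync_partition):
        raise PartitionError(
            "with a partially asynchronous scheme the initial partition must "
            "refine the synchronization partition"
        )
    deadline = None if timeout is None else time.monotonic() + timeout
    part = canonical_partition(initial.blocks, bn.variables)
    checks = 0
    while True:
        if deadline is not None and time.monotonic() > deadline:
            raise SolverTimeoutError(
                f"backward-equivalence refinement exceeded its {timeout} s budget "
                f"after {checks} SAT checks"
            )
        is_bbe, witness = check_bbe(bn, part)
        checks += 1
        if stats is not None:
            stats["sat_checks"] = checks
        if is_bbe:
            return part
        refined = split_blocks_by_witness(part, witness.next_values(), bn.variables)
        assert refined.n_blocks > part.n_blocks, "witness split must refine strictly"
        part = refined
        assert checks <= bn.n, "refinement exceeded the n-iteration bound"


def reduce(
    bn: BooleanNetwork, part: Partition, simplify: bool = False
) -> ReductionResult:
    """Quotient ``bn`` by a backward-equivalence partition.

    Refuses (with the witness attached) if the partition fails the check.
    Each block's variable keeps the representative's name and the
    representative's update function with every variable rewritten to its
    block's representative.  ``simplify=True`` additionally runs a
    semantic-equality-verified logic simplification on the rewritten
    functions (absorbing e.g. ``x | x | !y`` into ``x | !y``); it is off by
    default so serialised quotients keep their provenance.
    """
    _check_universe(bn, part)
    if bn.sync_partition is not None and not is_refinement(part, bn.sync_partition):
        raise PartitionError(
            "with a partially asynchronous scheme the quotient partition must "
            "refine the synchronization partition"
        )
    ok, witness = check_bbe(bn, part)
    if not ok:
        raise NotBBEError(witness)
    part = canonical_partition(part.blocks, bn.variables)
    block_to_rep = {block: block[0] for block in part.blocks}
    var_to_block = {v: block for block in part.blocks for v in block}
    rep_of = {v: block_to_rep[var_to_block[v]] for v in bn.variables}

    q_vars = tuple(block[0] for block in part.blocks)
    q_funcs: dict[str, Expr] = {}
    for block in part.blocks:
        rep = block[0]
        rewritten = bn.functions[rep].rename(rep_of)
        if simplify:
            simplified = from_sympy(sympy.simplify_logic(to_sympy(rewritten)))
            if not semantic_equal(simplified, rewritten, q_vars):  # pragma: no cover
                raise AssertionError("simplification changed the function")
            rewritten = simplified
        q_funcs[rep] = rewritten

    q_sync = None
    if bn.sync_partition is not None:
        image = {tuple(dict.fromkeys(rep_of[v] for v in K)) for K in bn.sync_partition.blocks}
        q_sync = canonical_partition(image, q_vars)
    quotient = BooleanNetwork(q_vars, q_funcs, sync_partition=q_sync)
    return ReductionResult(quotient, part, block_to_rep, var_to_block, bn.variables)


def project_state(state: State, result: ReductionResult) -> State:
    """Map an original-space state, constant on the partition, to quotient space."""
    order = result.original_variables
    if len(state) != len(order):
        raise ValueError(f"state length {len(state)} != {len(order)}")
    values = dict(zip(order, state))
    out = []
    for block in result.partition.blocks:
        vals = {values[v] for v in block}
        if len(vals) != 1:
            from .errors import NonConstantStateError

            raise NonConstantStateError(
                f"state is not constant on block {{{', '.join(block)}}}"
            )
        out.append(vals.pop())
    return tuple(out)


def lift_state(reduced_state: State, result: ReductionResult) -> State:
    """Inverse of :func:`project_state`: every variable takes its block's value."""
    if len(reduced_state) != result.quotient.n:
        raise ValueError("reduced state length mismatch")
    by_block = dict(zip(result.partition.blocks, reduced_state))
    return tuple(
        by_block[result.variable_to_block[v]] for v in result.original_variables
    )
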
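"""Partition algebra over network variables.

A partition ℋ = {H_1, …, H_k} groups the variables into disjoint,
covering, non-empty blocks.  The same structure serves three roles: the
user's initial partition, the backward-equivalence result, and the
synchronization partition of the partially asynchronous scheme.

Canonical form — blocks ordered by their smallest member's declaration
index, members ordered by declaration index — makes representative choice
and all serialised output deterministic across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import PartitionError
from .model import BooleanNetwork


@dataclass(frozen=True)
class Partition:
    """A canonical partition of a fixed variable universe."""

    blocks: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        seen: set[str] = set()
        for block in self.blocks:
            if not block:
                raise PartitionError("empty block")
            for v in block:
                if v in seen:
                    raise PartitionError(f"variable {v!r} appears in two blocks")
                seen.add(v)

    @property
    def variables(self) -> frozenset[str]:
        return frozenset(v for b in self.blocks for v in b)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of(self, name: str) -> tuple[str, ...]:
        for block in self.blocks:
            if name in block:
                return block
        raise KeyError(name)

    def block_index(self) -> dict[str, int]:
        return {v: i for i, b in enumerate(self.blocks) for v in b}

    def representatives(self) -> tuple[str, ...]:
        """First (canonical) member of each block."""
        return tuple(b[0] for b in self.blocks)

    def is_singleton(self) -> bool:
        return all(len(b) == 1 for b in self.blocks)


def canonical_partition(blocks: Iterable[Iterable[str]], order: Sequence[str]) -> Partition:
    """Canonicalize ``blocks`` against the declaration order ``order``.

    Members inside each block and blocks among themselves are sorted by
    declaration index; the variable universe must equal ``order``.
    """
    pos = {name: i for i, name in enumerate(order)}
    norm = []
    for block in blocks:
        block = list(block)
        unknown = [v for v in block if v not in pos]
        if unknown:
            raise PartitionError(f"unknown variable(s): {', '.join(sorted(unknown))}")
        norm.append(tuple(sorted(block, key=pos.__getitem__)))
    norm.sort(key=lambda b: pos[b[0]])
    part = Partition(tuple(norm))
    if part.variables != set(order):
        missing = sorted(set(order) - part.variables)
        raise PartitionError(f"variables not covered by any block: {', '.join(missing)}")
    return part


def maximal_partition(bn: BooleanNetwork) -> Partition:
    """All variables in a single block — the coarsest possible start."""
    return Partition((tuple(bn.variables),))


def singleton_partition(bn: BooleanNetwork) -> Partition:
    """Every variable alone — the finest partition (always a backward equivalence)."""
    return Partition(tuple((v,) for v in bn.variables))


def input_separated_partition(bn: BooleanNetwork) -> Partition:
    """Two blocks: the input variables and everything else.

    Keeps external stimuli from being merged with internal variables.  When
    the network has no inputs (or only inputs) the two-block form degenerates
    and the maximal partition is returned instead.
    """
    from .model import detect_inputs

    inputs = detect_inputs(bn)
    others = [v for v in bn.variables if v not in inputs]
    if not inputs or not others:
        return maximal_partition(bn)
    return canonical_partition(
        [[v for v in bn.variables if v in inputs], others], bn.variables
    )


def is_refinement(fine: Partition, coarse: Partition) -> bool:
    """True iff every block of ``fine`` sits inside a block of ``coarse``."""
    if fine.variables != coarse.variables:
        raise PartitionError("partitions are over different variable sets")
    coarse_idx = coarse.block_index()
    for block in fine.blocks:
        target = coarse_idx[block[0]]
        if any(coarse_idx[v] != target for v in block[1:]):
            return False
    return True


def split_blocks_by_witness(
    part: Partition, next_values: Mapping[str, int], order: Sequence[str]
) -> Partition:
    """Split every block by the successor values observed at a witness state.

    Each block is cut into its 0-valued and 1-valued members under
    ``next_values`` (the values f_x(s) at the falsifying state s); empty
    halves are dropped, so the result always refines ``part`` and one witness
    may split several blocks at once.
    """
    missing = [v for v in part.variables if v not in next_values]
    if missing:
        raise PartitionError(
            f"successor values missing for: {', '.join(sorted(missing))}"
        )
    new_blocks: list[list[str]] = []
    for block in part.blocks:
        zeros = [v for v in block if not next_values[v]]
        ones = [v for v in block if next_values[v]]
        for half in (zeros, ones):
            if half:
                new_blocks.append(half)
    return canonical_partition(new_blocks, order)
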
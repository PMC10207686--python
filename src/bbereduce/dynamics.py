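"""State transition graphs, attractors, and exact-preservation checks.

The synchronous STG has one node per state (2^n of them) and exactly one
outgoing edge per node.  The partially asynchronous scheme is driven by a
*synchronization partition* 𝒦: one transition per block K of 𝒦, applying
only the update functions of the variables in K, so every state has one
successor choice per block.

States are encoded as integers whose most significant bit is the first
declared variable, so integer order coincides with lexicographic order of
the bit-strings.  Successor maps are materialised as numpy arrays indexed by
state, which keeps full enumeration cheap up to the explicit-construction
guard (24 variables by default — explicit state spaces beyond that are not
practical to materialise).

An attractor is a terminal strongly connected component of the STG: a set
of states the dynamics can enter but never leave.  Under the synchronous
scheme every attractor is a simple cycle; a steady state is a singleton with
a self-loop.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import SizeGuardError, SolverTimeoutError
from .model import BooleanNetwork, State, step
from .partitions import Partition
from .reduction import ReductionResult, project_state
from .sat import CNFBuilder, solve

DEFAULT_MAX_STG_VARS = 24

SYNCHRONOUS = "synchronous"
PARTIALLY_ASYNC = "partially-asynchronous"


def _guard(n: int, max_vars: int) -> None:
    if n > max_vars:
        raise SizeGuardError(
            f"explicit state-space construction refused: {n} variables exceeds "
            f"the cap of {max_vars} (default {DEFAULT_MAX_STG_VARS}); raise "
            "max_vars explicitly if you really want 2^n enumeration"
        )


def _successor_array(bn: BooleanNetwork, update: set[str] | None = None) -> np.ndarray:
    """Successor state (as int) for every state, updating only ``update`` vars.

    ``update=None`` updates everything (synchronous step).  Vectorised over
    the whole state space at once.
    """
    n = bn.n
    idx = np.arange(1 << n, dtype=np.int64)
    env = {
        name: ((idx >> (n - 1 - i)) & 1).astype(np.int64)
        for i, name in enumerate(bn.variables)
    }
    out = np.zeros(1 << n, dtype=np.int64)
    for i, name in enumerate(bn.variables):
        if update is None or name in update:
            bit = np.broadcast_to(
                np.asarray(bn.functions[name].evaluate(env), dtype=np.int64), idx.shape
            )
        else:
            bit = env[name]
        out |= bit << (n - 1 - i)
    return out


@dataclass(frozen=True)
class STG:
    """Explicit state transition graph.

    ``successors`` holds one full successor array per update choice: a single
    array for the synchronous scheme, one per synchronization block for the
    partially asynchronous one (so every state has exactly one successor
    choice per block, self-loops included).
    """

    variables: tuple[str, ...]
    scheme: str
    successors: tuple[np.ndarray, ...]
    sync_partition: Partition | None = None

    @property
    def n(self) -> int:
        return len(self.variables)

    @property
    def n_states(self) -> int:
        return 1 << self.n

    def state_string(self, idx: int) -> str:
        return format(idx, f"0{self.n}b")

    def edges(self):
        """All (source, target) int pairs, per update choice, source-major."""
        for s in range(self.n_states):
            for succ in self.successors:
                yield s, int(succ[s])

    def to_networkx(self) -> nx.DiGraph:
        """DiGraph on bit-string labels (parallel choices collapse to one edge)."""
        g = nx.DiGraph()
        for s in range(self.n_states):
            g.add_node(self.state_string(s))
        for s, t in self.edges():
            g.add_edge(self.state_string(s), self.state_string(t))
        return g

    def _int_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_states))
        g.add_edges_from(self.edges())
        return g


def generate_stg(
    bn: BooleanNetwork,
    scheme: str = SYNCHRONOUS,
    sync_partition: Partition | None = None,
    max_vars: int = DEFAULT_MAX_STG_VARS,
) -> STG:
    """Materialise the full STG under the requested update scheme."""
    _guard(bn.n, max_vars)
    if scheme == SYNCHRONOUS:
        return STG(bn.variables, scheme, (_successor_array(bn),))
    if scheme == PARTIALLY_ASYNC:
        part = sync_partition or bn.sync_partition
        if part is None:
            raise ValueError("partially asynchronous scheme needs a synchronization partition")
        if part.variables != set(bn.variables):
            raise ValueError("synchronization partition must cover the network variables")
        succs = tuple(_successor_array(bn, set(block)) for block in part.blocks)
        return STG(bn.variables, scheme, succs, part)
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass(frozen=True)
class Attractor:
    """Terminal SCC in canonical form.

    For deterministic (synchronous) dynamics the states are listed as the
    cycle starting from the lexicographically smallest state; otherwise they
    are simply sorted.
    """

    states: tuple[State, ...]
    steady_state: bool

    def state_strings(self) -> tuple[str, ...]:
        return tuple("".join(str(b) for b in s) for s in self.states)

    def state_set(self) -> frozenset[State]:
        return frozenset(self.states)

    def __len__(self) -> int:
        return len(self.states)


def _int_to_state(idx: int, n: int) -> State:
    return tuple((idx >> (n - 1 - i)) & 1 for i in range(n))


def attractors_of_stg(stg: STG) -> list[Attractor]:
    """All attractors: terminal strongly connected components of the STG."""
    g = stg._int_graph()
    out: list[Attractor] = []
    for comp in nx.attracting_components(g):
        members = sorted(comp)
        steady = len(members) == 1 and g.has_edge(members[0], members[0])
        if stg.scheme == SYNCHRONOUS and len(members) > 1:
            # order as the cycle from the smallest state
            succ = stg.successors[0]
            cyc = [members[0]]
            cur = int(succ[members[0]])
            while cur != members[0]:
                cyc.append(cur)
                cur = int(succ[cur])
            members = cyc
        out.append(
            Attractor(tuple(_int_to_state(m, stg.n) for m in members), steady)
        )
    out.sort(key=lambda a: a.states[0])
    return out


def steady_states_sat(
    bn: BooleanNetwork, timeout: float | None = None
) -> list[State]:
    """All fixed points of the synchronous step, by SAT with blocking clauses.

    Enumerates the models of ⋀_i (x_i ↔ f_i).  Works at any network size,
    but finds *steady states only* — for networks with cyclic attractors it
    is a lower bound on the attractor count.  ``timeout`` is a wall-clock
    budget enforced between solver calls.
    """
    deadline = None if timeout is None else time.monotonic() + timeout
    builder = CNFBuilder()
    for v in bn.variables:
        builder.assert_equal(builder.var(v), builder.encode(bn.functions[v]))
    found: list[State] = []
    while True:
        if deadline is not None and time.monotonic() > deadline:
            raise SolverTimeoutError(
                f"steady-state enumeration exceeded its {timeout} s budget "
                f"after {len(found)} states"
            )
        model = solve(builder)
        if model is None:
            return sorted(found)
        assigned = {v: model[v] for v in bn.variables if v in model}
        free = [v for v in bn.variables if v not in assigned]
        # a partial model means every completion of the free variables is a fixed point
        for combo in itertools.product((0, 1), repeat=len(free)):
            values = dict(assigned)
            values.update(zip(free, combo))
            state = tuple(values[v] for v in bn.variables)
            assert step(bn, state) == state
            found.append(state)
        if not assigned:
            return sorted(found)
        builder.add_clause(
            [-builder.var(v) if val else builder.var(v) for v, val in assigned.items()]
        )


def attractors(
    bn: BooleanNetwork,
    scheme: str = SYNCHRONOUS,
    strategy: str = "explicit",
    sync_partition: Partition | None = None,
    max_vars: int = DEFAULT_MAX_STG_VARS,
    timeout: float | None = None,
) -> list[Attractor]:
    """Attractor analysis.

    ``strategy="explicit"`` materialises the STG (size-guarded) and returns
    every attractor; ``strategy="sat-steady"`` works at any size but returns
    only the steady states, each as a singleton attractor.
    """
    if strategy == "explicit":
        stg = generate_stg(bn, scheme, sync_partition, max_vars)
        return attractors_of_stg(stg)
    if strategy == "sat-steady":
        if scheme != SYNCHRONOUS:
            raise ValueError("sat-steady enumeration is defined for the synchronous scheme")
        return [Attractor((s,), True) for s in steady_states_sat(bn, timeout)]
    raise ValueError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Constant states and preservation checks
# ---------------------------------------------------------------------------


def is_constant_state(state: State, part: Partition, order: tuple[str, ...]) -> bool:
    """True iff every block of ``part`` is monochrome in ``state``."""
    values = dict(zip(order, state))
    return all(len({values[v] for v in block}) == 1 for block in part.blocks)


def constant_states(part: Partition, order: tuple[str, ...]) -> list[State]:
    """All 2^(block count) states constant on ``part``, lexicographically sorted."""
    pos = {v: i for i, v in enumerate(order)}
    out = []
    for combo in itertools.product((0, 1), repeat=part.n_blocks):
        state = [0] * len(order)
        for block, val in zip(part.blocks, combo):
            for v in block:
                state[pos[v]] = val
        out.append(tuple(state))
    out.sort()
    return out


def _state_to_int(state: State) -> int:
    out = 0
    for b in state:
        out = (out << 1) | b
    return out


def verify_correspondence(
    bn: BooleanNetwork,
    result: ReductionResult,
    max_vars: int = DEFAULT_MAX_STG_VARS,
) -> bool:
    """Check that the quotient STG is exactly the constant-state part of the original.

    Verifies, for every state s constant on the partition and every update
    choice: (a) closure — the successor of s is again constant; (b) the
    commuting square — projecting the successor equals stepping the
    projection in the quotient.  Projection restricted to constant states is
    a bijection onto the quotient state space by construction, so (a)+(b)
    amount to the graph isomorphism between the induced constant-state
    subgraph and the reduced STG.
    """
    _guard(bn.n, max_vars)
    part = result.partition
    scheme = SYNCHRONOUS if bn.sync_partition is None else PARTIALLY_ASYNC
    stg = generate_stg(bn, scheme, bn.sync_partition, max_vars)
    qstg = generate_stg(
        result.quotient,
        scheme,
        result.quotient.sync_partition,
        max_vars,
    )
    if len(stg.successors) != len(qstg.successors):
        return False
    consts = constant_states(part, bn.variables)
    for succ, qsucc in zip(stg.successors, qstg.successors):
        for s in consts:
            t_int = int(succ[_state_to_int(s)])
            t = _int_to_state(t_int, bn.n)
            if not is_constant_state(t, part, bn.variables):
                return False  # closure violated
            if _state_to_int(project_state(t, result)) != int(
                qsucc[_state_to_int(project_state(s, result))]
            ):
                return False  # square does not commute
    return True


def preserved_attractors(
    original_attractors: list[Attractor],
    part: Partition,
    order: tuple[str, ...],
) -> tuple[list[Attractor], list[Attractor]]:
    """Split attractors into (preserved, dropped) under a BBE partition.

    An attractor is preserved iff it contains at least one state constant on
    the partition; preserved attractors survive in the quotient with their
    length unchanged, the rest disappear with the non-constant part of the
    state space.
    """
    preserved, dropped = [], []
    for att in original_attractors:
        if any(is_constant_state(s, part, order) for s in att.states):
            preserved.append(att)
        else:
            dropped.append(att)
    return preserved, dropped
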
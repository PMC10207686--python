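# Methods

## Model and semantics

A Boolean network is an ordered tuple of variables x_1 … x_n with one
Boolean update function f_x each, built from the core connectives
{0, 1, var, ¬, ∧, ∨} (implication, equivalence and exclusive-or are
accepted by the constructors and normalised to the core set, which keeps
the CNF encoding and the serialiser single-purpose). Synchronous semantics:
the unique successor of state s is (f_x1(s), …, f_xn(s)). States are
rendered as bit-strings whose leftmost bit is the first declared variable.

Partially asynchronous semantics is driven by a *synchronization partition*
𝒦: each transition picks one block K ∈ 𝒦 and applies only the update
functions of the variables in K (GINsim's "priority classes"). The
synchronous scheme is the special case 𝒦 = {all variables}.

An *input* is a variable the dynamics never change. Two encodings circulate
in published models — a constant update function and the identity
`x, x` — so input detection accepts both, and the test is semantic (a
tautology counts as the constant 1), since a syntactic test would miss
logically constant functions.

## Backward equivalence

A partition ℋ of the variables is a backward equivalence when

    Φ^ℋ ≡ (⋀_{H∈ℋ} ⋀_{x,x'∈H} x = x') ⟶ ⋀_{H∈ℋ} ⋀_{x,x'∈H} f_x = f_x'

is valid. The implementation checks satisfiability of ¬Φ^ℋ:

* **Encoding.** Per block, the antecedent is a chain of equalities against
  the block's first member and the consequent compares each member's update
  function against the first member's — equivalent to the all-pairs form
  under the antecedent but linear in block size. Update-function trees are
  Tseitin-encoded (one auxiliary variable per internal node), so the CNF is
  linear in the formula size; a naive distribution into clauses can blow up
  exponentially. The negated consequent becomes one clause over per-pair
  XOR difference variables.
* **Solving.** The CNF (signed-integer clauses) is handed to sympy's DPLL
  engine in already-CNF form. A model is restricted to the network
  variables and completed blockwise (unassigned variables inherit their
  block's value, defaulting to 0 — sound because a partial model of a CNF
  satisfies every clause under any completion). The completed state s is
  the witness; its successor s' = step(s) is computed directly.
* **Splitting.** Every block is cut into its 0- and 1-valued members under
  s'. One witness may split several blocks at once, which minimises solver
  round-trips. Splitting by s' rather than s is a free choice — the
  coarsest fixed point is the same either way — and s' is the value vector
  that directly exhibits the violation.
* **Termination.** Each round strictly increases the block count, so the
  loop runs at most n SAT checks; the result is the unique coarsest
  backward equivalence refining the initial partition, independent of which
  witness the solver returns (asserted in tests by shuffling declaration
  orders, which permutes the solver's branching order).

With a synchronization partition attached, the initial partition must
refine 𝒦 (enforced, since a block-K update preserves block constancy only
then); the check itself is unchanged, and the quotient inherits the image
of 𝒦 under the representative map.

## Quotient construction

The representative of a block is its smallest-declaration-index member and
the quotient variable keeps the representative's *name* (block composition
lives in the result's metadata rather than in concatenated names — legal
identifiers, stable round-trips). The quotient update of a block is the
representative's function with every variable rewritten to its block's
representative. An optional simplification pass
(`reduce(..., simplify=True)`) runs sympy's logic minimiser and is verified
against the unsimplified function by semantic equality; it is off by
default so serialised quotients keep their provenance. Quotienting by a
non-equivalent partition raises, carrying the witness.

## Dynamics

Explicit STGs encode states as integers (MSB = first variable) and
materialise one full numpy successor array per update choice — one array
for synchronous, one per 𝒦-block otherwise — via vectorised expression
evaluation over the whole state space. Attractors are the terminal
strongly connected components, computed with networkx's
`attracting_components` on the successor graph; for deterministic dynamics
each is reported as the cycle from its lexicographically smallest state.
Terminal SCCs are also the attractor notion used for the nondeterministic
partially-asynchronous scheme, the standard reading of "states the system
enters and never leaves".

Explicit construction is guarded at 24 variables by default (configurable):
beyond that the 2^n enumeration is not practical. For larger networks
`steady_states_sat` enumerates the models of ⋀_i (x_i ↔ f_i) with blocking
clauses — *steady states only*, documented as a lower bound on the attractor
count when cyclic attractors may exist; bounded-unfolding cycle detection
at that scale is out of scope. Partial models are expanded over their
don't-care variables (an input's fixed-point constraint x ↔ x constrains
nothing), and the blocking clause negates only the assigned literals, so
each solver round eliminates the whole don't-care cube.

`verify_correspondence` checks the exact-preservation guarantee as an
executable property: for every constant state and every update choice,
(a) the successor is again constant and (b) projecting the successor equals
stepping the projection in the quotient. Projection restricted to constant
states is a bijection onto the quotient space by construction, so (a)+(b)
constitute the graph isomorphism between the induced constant-state
subgraph and the quotient STG. `preserved_attractors` classifies attractors
by whether they contain a constant state.

## Solver budget

The DPLL call itself cannot be interrupted, so `timeout=` arguments are
wall-clock budgets enforced *between* solver calls of the refinement and
steady-state loops. On expiry the operation raises instead of returning a
partial partition — a partial answer would be neither sound nor coarsest.

## Synthetic data

Three frozen fixtures complete small published illustrations of the method
(a 3-variable chain with a 2-cycle, the TLR5 receptor cascade, a 3-variable
network with four steady states). Only some of their update functions are
printed in the original figures; the completions here are the simplest ones
consistent with every printed transition, partition and attractor fact, and
are documented as reconstructions, not as the original models' formulas.

The random generator is NK-style: each of the n−d base variables draws K
distinct regulators uniformly and an explicit random truth table whose
entries are 1 with probability p (explicit tables give a uniform,
analysable function distribution and serialise trivially, unlike random
expression trees). Defaults K = 2, p = 0.5 — the classic critical-regime
choice for random Boolean networks. d planted duplicates copy a base
variable's function verbatim, and with probability ½ per other function the
copied variable's occurrences are rewritten to the duplicate, so duplicates
feed back into the dynamics; every planted pair is provably co-blocked in
the coarsest reduction, giving the property batteries a ground truth.

What the generator does *not* emulate: the scale-free in-degree
distributions, canalising functions and long feedback structure of curated
biological models. Passing batteries therefore demonstrate the
*correctness* of the check/quotient machinery across function space, not
the *reduction power* to be expected on real models, which depends on
actual redundancy.

## Problem sizes and test design

The batteries pair every SAT-driven result with an independent brute-force
oracle: coarsest partitions are compared against exhaustive enumeration of
all set partitions with full 2^n state sweeps on 200 networks of 4–8
variables (Bell(8) = 4140 partitions per network keeps enumeration exact
yet cheap), and the correspondence/preservation theorems are verified
exhaustively on 100 networks of 8–12 variables — the range where full STGs
are instant but function space is already rich. Expression evaluation is
cross-checked against an independent rendering to Python `and/or/not`.

## Limitations

* Cyclic-attractor detection beyond the explicit guard is not implemented
  (steady states only at that scale).
* Fully asynchronous single-variable semantics is available only as the
  special case 𝒦 = all-singletons of the partially asynchronous scheme.
* Multi-valued networks, SBML-qual / GINsim file import, and probabilistic
  update schemes are out of scope; convert externally to `.bnet`.
* The DPLL backend is a pure-Python solver: adequate for the desk-scale
  batteries and for published models of ~60 variables with small update
  functions, but not tuned for adversarial CNFs.
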
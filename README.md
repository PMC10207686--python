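# bbereduce

Exact reduction of Boolean networks by **backward equivalence**.

Boolean networks (BNs) are a standard qualitative formalism for gene
regulation and signalling: each variable x carries a 0/1 activation value
and an update function f_x over the network variables; under the
synchronous scheme the successor of a state s is (f_x1(s), …, f_xn(s)).
Their analysis is dominated by the 2^n state transition graph (STG) and by
attractors — the terminal strongly connected components the dynamics can
never leave — whose identification is NP-hard.

`bbereduce` shrinks a BN *before* any state-space work. A partition
ℋ = {H_1, …, H_k} of the variables is a **backward equivalence** when the
formula

    Φ^ℋ ≡ ( ⋀_{H} ⋀_{x,x'∈H} x = x' )  ⟶  ⋀_{H} ⋀_{x,x'∈H} f_x = f_x'

is valid: variables that start equal inside a block stay equal after one
step (hence forever). Validity is decided by a SAT check on ¬Φ^ℋ; a model
is a *witness* state whose successor splits some block, and iterating
check → split converges in ≤ n checks to the unique coarsest backward
equivalence refining any initial partition. Quotienting keeps one
representative variable per block and rewrites its update function over
representatives. The guarantees are exact:

* the quotient STG is isomorphic to the original STG restricted to the
  *constant* states (those where every block is monochrome) — nothing else;
* every attractor containing a constant state survives with its length
  unchanged; attractors touching no constant state are dropped; nothing
  spurious is ever added.

The package is for modellers who want smaller, provably faithful models
(and a redundancy diagnostic) and for tool builders who need a reference
implementation of the check, the refinement loop, the quotient
construction, STG/attractor machinery, and the preservation theorems as
executable verifications.

## Worked example

```python
import bbereduce as bb

bn = bb.parse_bnet("""\
targets, factors
x1, x1 | !x3
x2, x1 | x2 | !x3
x3, !x3
""")
part = bb.coarsest_bbe(bn, bb.maximal_partition(bn))
result = bb.reduce(bn, part, simplify=True)
print("blocks:", [list(b) for b in part.blocks])
print(bb.serialize_bnet(result.quotient, header=False), end="")
print(f"reduction ratio: {result.quotient.n / bn.n:.2f}")
```

prints

```
blocks: [['x1', 'x2'], ['x3']]
x1, x1 | !x3
x3, !x3
reduction ratio: 0.67
```

x1 and x2 are interchangeable whenever they start equal — if
x1(t) = x2(t) then x2(t+1) = x1(t) ∨ x2(t) ∨ ¬x3(t) = x1(t) ∨ ¬x3(t)
= x1(t+1) — so the quotient keeps x1 as the block's representative with
update x1 ∨ ¬x3, two variables instead of three. The 8-state STG collapses
onto its 4 constant states, and the original 110 ↔ 111 cycle survives as a
2-state cycle in the quotient.

The `examples/` directory walks through each capability: reduction
(`01`), witness-driven refinement (`02`), attractor preservation (`03`),
and random networks with planted redundancy (`04`).

## Command line

```bash
bbereduce reduce model.bnet --partition input-separated --out results/
bbereduce check model.bnet --partition file:blocks.txt
bbereduce stg model.bnet --max-stg-vars 24 --out results/
bbereduce attractors model.bnet --strategy explicit --partition file:blocks.txt
bbereduce random -n 20 -k 2 -p 0.5 --duplicates 2 --seed 1
```

Initial partitions: `maximal` (one block — strongest reduction),
`input-separated` (inputs never merge with internal variables),
`singletons`, or a partition file (one comma-separated block per line plus
an optional `@residual:` directive — see `bbereduce.io`). With
`--scheme async:K.txt` the network runs partially asynchronously: one block
of the synchronization partition 𝒦 updates per transition, and the initial
partition must refine 𝒦. Every run writes a `manifest.json` sufficient to
reproduce it.

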
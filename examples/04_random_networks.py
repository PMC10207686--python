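"""Seeded random networks with planted, provably-recoverable redundancy.

Generates an NK-style random network (each variable reads K random
regulators through a random truth table) with two planted duplicate
variables that copy another variable's update function.  The coarsest
reduction must merge every planted pair — a ground truth for validating the
refinement loop at scale.
"""

import bbereduce as bb

cfg = bb.GeneratorConfig(n=10, k=2, p=0.5, duplicates=2, seed=42)
bn = bb.random_bn(cfg)
print(f"network: {bn.n} variables, {cfg.duplicates} planted duplicates")
print("planted pairs:", bb.planted_pairs(cfg))

part = bb.coarsest_bbe(bn, bb.maximal_partition(bn))
print("coarsest blocks:", [list(b) for b in part.blocks])

for orig, dup in bb.planted_pairs(cfg):
    block = part.block_of(orig)
    print(f"  {dup} co-blocked with {orig}?", dup in block)

result = bb.reduce(bn, part)
print(f"reduced to {result.quotient.n} variables "
      f"(ratio {result.quotient.n / bn.n:.2f})")
# every planted duplicate must land in its original's block; extra merges
# beyond the planted ones are legitimate discoveries, not errors.
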
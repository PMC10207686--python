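"""Reduce a small Boolean network by backward equivalence.

Builds a three-variable network in BoolNet text form, computes the coarsest
backward-equivalence partition starting from the maximal one, and prints the
quotient.  Variables x1 and x2 are merged because, whenever they start
equal, one synchronous step keeps them equal — certified by SAT from the
update functions alone, without touching the 2^n state space.
"""

import bbereduce as bb

TEXT = """\
targets, factors
x1, x1 | !x3
x2, x1 | x2 | !x3
x3, !x3
"""

bn = bb.parse_bnet(TEXT)
part = bb.coarsest_bbe(bn, bb.maximal_partition(bn))
result = bb.reduce(bn, part, simplify=True)

print("blocks:", [list(b) for b in part.blocks])
print("reduced network:")
print(bb.serialize_bnet(result.quotient, header=False), end="")
print(f"reduction ratio: {result.quotient.n / bn.n:.2f}")
# 'blocks' lists which variables were proven interchangeable; the reduced
# network keeps one representative per block (2 variables instead of 3).
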
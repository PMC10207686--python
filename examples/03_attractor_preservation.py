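"""What reduction does to attractors: exact preservation, honest loss.

A three-variable network with four steady states is quotiented by the
backward equivalence merging x1 with x2.  Attractors containing a state
where the merged variables agree survive with their length intact; the
others live entirely in the discarded (non-constant) part of the state
space and disappear.  Nothing spurious is ever added.
"""

import bbereduce as bb
from bbereduce.partitions import canonical_partition

bn = bb.fixture_four_steady_states()
atts = bb.attractors(bn)
print("original attractors:", [a.state_strings() for a in atts])

part = canonical_partition([["x1", "x2"], ["x3"]], bn.variables)
preserved, dropped = bb.preserved_attractors(atts, part, bn.variables)
print("preserved (x1 = x2):", [a.state_strings() for a in preserved])
print("dropped   (x1 ≠ x2):", [a.state_strings() for a in dropped])

result = bb.reduce(bn, part)
qatts = bb.attractors(result.quotient)
print("quotient attractors:", [a.state_strings() for a in qatts])
print("quotient STG is the constant-state subgraph:",
      bb.verify_correspondence(bn, result))
# 4 original steady states -> 2 in the quotient: exactly the projections of
# 000 and 111, the two states where x1 and x2 agree.
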
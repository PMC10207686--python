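"""Watch one round of SAT-driven partition refinement.

The five-variable receptor cascade (TLR5 feeding TICAM1, MyD88, IRAK4,
PIK3AP1) starts from the input-separated partition: the input alone, all
other genes together.  The SAT check rejects it and returns a witness state;
splitting the big block by the witness's successor values yields the refined
partition, which then passes the check — that refined partition is the
coarsest backward equivalence.
"""

import bbereduce as bb

bn = bb.fixture_tlr5_cascade()
h0 = bb.input_separated_partition(bn)
print("initial partition:", [list(b) for b in h0.blocks])

ok, witness = bb.check_bbe(bn, h0)
print("is it a backward equivalence?", ok)
print("witness state:    ", witness.state_string(), "(constant on every block)")
print("witness successor:", witness.successor_string(), "(splits the gene block)")

h1 = bb.split_blocks_by_witness(h0, witness.next_values(), bn.variables)
print("refined partition:", [list(b) for b in h1.blocks])
print("refined passes the check?", bb.check_bbe(bn, h1)[0])
# TICAM1/MyD88 read the input directly, IRAK4/PIK3AP1 read MyD88 — the
# witness successor separates exactly those two groups.
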
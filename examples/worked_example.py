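"""Annotate a single dystrophin mutation: the exon-52 deletion.

The deletion c.7543_7660del removes exon 52 (118 nt, not a multiple of
three), shifting the reading frame of every downstream exon.  The engine
finds every antisense-oligonucleotide skip that restores the frame.
"""

from skipscan import Mutation, annotate, load_dmd_transcript, parse_hgvs_lite

t = load_dmd_transcript()

m = parse_hgvs_lite("c.7543_7660del", t)
print(f"parsed: deletion of exons {m.first_exon}-{m.last_exon}")

a = annotate(t, Mutation.deletion("patient-1", m.first_exon, m.last_exon))
print(f"frame status: {a.frame_status}")
for s in a.strategies:
    print(f"  skip {s.label:>6}  ({s.category})")

# Each listed target set removes a contiguous exon run whose total coding
# length is a multiple of three, so the downstream frame is restored: here
# skipping exon 51 or exon 53 alone, or the whole 45-55 cocktail.
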
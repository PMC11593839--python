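"""Small-lesion and duplication rescue logic on the dystrophin fixture.

Shows the three non-deletion paths: an intra-exonic lesion in an asymmetric
exon (needs a balancing pair skip), a donor-site lesion (the exon is lost
from the transcript; the induced deletion is rescued like any other), and a
single-exon duplication (skip one copy; if an ASO removes both copies, an
adjacent exon can rebalance the frame).
"""

from skipscan import Mutation, annotate, load_dmd_transcript

t = load_dmd_transcript()

for m, story in [
    (Mutation.small_lesion("p1", 70, "intra"),
     "point mutation inside asymmetric exon 70 (125 nt)"),
    (Mutation.small_lesion("p2", 52, "donor"),
     "donor-site mutation after exon 52: exon 52 is lost from the mRNA"),
    (Mutation.duplication("p3", 2, 2),
     "duplication of exon 2 (62 nt), the most frequently duplicated exon"),
]:
    a = annotate(t, m)
    print(story)
    for s in a.strategies:
        note = f"  [{s.note}]" if s.note else ""
        print(f"  skip {s.label:>7}  ({s.category}){note}")
    print()

# "skip-within-duplication" removes one copy of the duplicated exon and
# restores the wild-type transcript; "rescue-after-double-copy-skip" is the
# fallback when an ASO removes both copies of the duplicated exon.
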
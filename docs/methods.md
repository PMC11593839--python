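# Methods

## The reading-frame model

The transcript model is a contiguous table of exons in HGVS c. coordinates
(c.1 = A of the start codon; the last position is the final base of the stop
codon; UTRs excluded). For exon *i* with coding interval
[c_start, c_end], the phase of the flanking introns is the cumulative coding
length mod 3 at the boundary: `start_phase = (c_start − 1) mod 3`,
`end_phase = c_end mod 3`. An exon is *symmetric* when both phases agree,
equivalently when its coding length is divisible by three. Phases and
symmetry flags are always recomputed from coordinates, never trusted from a
file.

All frame questions reduce to one statement: a transcript missing a set *E*
of exons is in-frame iff `Σ_{e∈E} len(e) ≡ 0 (mod 3)`. The engine calls this
set the *excluded region* (deleted or splice-lost exons plus ASO-skipped
exons) and asserts the congruence on every strategy it emits.

### Strategy enumeration

* **Deletion of exons f..l** (frameshift only): admissible ASO target sets
  are `{f−1}`, `{l+1}`, `{f−2, f−1}`, `{l+1, l+2}`, `{f−1, l+1}` — exactly
  the 1- and 2-exon flank extensions that keep the excluded region a single
  contiguous run. Targets are restricted to exons 2..78: the first exon
  (start codon) and last exon (stop codon) are never skippable.
* **Intra-exonic small lesion in exon e**: `{e}` if *e* is symmetric,
  otherwise whichever of `{e−1, e}`, `{e, e+1}` sums to 0 mod 3. The
  lesion's own length change (point variant or small indel) is ignored: once
  the exon is excluded, only exon lengths matter.
* **Splice-site lesion**: the affected exon is modelled as lost from the
  transcript (see conventions below). If the lost exon is symmetric, the
  induced transcript is already in-frame and the engine emits a single
  empty-target strategy noted `no-ASO-needed` (category `none`, excluded
  from per-strategy counts). Otherwise the induced single-exon deletion is
  rescued exactly like a genomic deletion; targets never include the exon
  that is already lost.
* **Duplication of exons f..l** (frameshift only): removing a subset *S* of
  one exon or two adjacent exons from one copy leaves an in-frame insertion
  iff `len(f..l) − len(S) ≡ 0 (mod 3)`. For a single-exon duplication the
  unique candidate `S = {f}` always qualifies (one-copy skip restores wild
  type). The risk of mistargeting the original copy is surfaced as the note
  `skip-within-duplication`, not as a disqualifier, matching the theoretical
  counting convention. Separately, if an ASO removes *both* copies of a
  single-exon duplication of an asymmetric exon, the net transcript lacks
  that exon; adjacent exons whose length rebalances the frame are emitted
  with note `rescue-after-double-copy-skip`.
* **Multi-exon cocktails**: configured in-frame ranges (defaults 3–9 and
  45–55, both mutation hotspots). A deletion qualifies iff it is a
  frameshift contained entirely in the range; a small lesion iff its
  lesion-bearing (or induced-lost) exon lies in the range; duplications
  never qualify — skipping the range in a duplicated region cannot
  reconstruct a wild-type-length frame in general.

Annotation is deterministic, order-independent, and de-duplicated by
(target set, category).

### Splice-loss convention

Which exon does a donor/acceptor mutation remove? The default, `own_exon`,
follows standard splicing biology: the exon whose own donor or acceptor is
mutated fails to be defined and is lost. The alternative `neighbor`
convention (donor lesion → downstream exon lost, acceptor → upstream) is
available as `EngineConfig(splice_loss_convention="neighbor")` for
comparison with analyses that phrase the rule that way. All shipped
defaults, tests and examples use `own_exon`.

## The Dp427m exon fixture

`data/dp427m_cds_exons.tsv` holds the 79 coding exon intervals of the
full-length muscle dystrophin transcript (RefSeq NM_004006 coordinates,
CDS total 11,058 nt = 3685 residues + stop). Because per-exon lengths are
easy to mistranscribe, the table is cross-validated on every load against
anchors with independent authority:

* exon count 79 and coordinate contiguity;
* exon 52 spans c.7543–7660 (118 nt) — the classic exon-52 deletion
  nomenclature anchor;
* the multi-skip cocktail ranges 3–9 and 45–55 are in-frame, as required
  for their documented association with mild phenotypes.

The proximal and central regions (exons 1–70) additionally reproduce the
published frame-compatibility pattern of every known single/double skip
strategy (e.g. 51+52 and 52+53 pairs in-frame, 69&70 and 58&59 pair sums
divisible by three, the 45–51 and 51–63 cross-flank runs in-frame). The
distal tail (exons 71–77 and the short coding portion of 79) was
reconstructed under the total-CDS and frame-pattern constraints rather than
transcribed directly from an annotation dump; individual boundaries there
may deviate from the reference annotation by a few bases without affecting
any mod-3 property used by the engine. Users who need base-exact distal
coordinates should regenerate the table from a current annotation release
and re-run `validate_fixture`.

All engine logic accepts any `TranscriptModel`, so correctness is
established on thousands of small random transcripts against brute-force
enumeration, independently of this fixture.

## Cohort aggregation

`summarize` counts, per strategy label (canonical forms `"51"`, `"51 & 53"`,
`"45–55"`), the distinct mutations it rescues, per class and overall; a
mutation amenable to several strategies appears in each of their rows but
once per row. Class-level rows report the fraction of each class with at
least one single, at least one double, at least one of either (the union —
*not* the sum, because many mutations have both kinds), and at least one
multi strategy; the multi column is not evaluated for duplications.

Denominators are configurable because locus-specific databases are
summarized both ways: `all` (default) divides deletion percentages by every
deletion record including in-frame ones, `frameshift` by frameshift
deletions only. Overall percentages always use the full filtered cohort.
Stored values are unrounded; the TSV writer prints one decimal place,
except two decimals for values below 0.1% so that rare strategies (0.05%)
remain visible.

## Synthetic cohort generator

The generator emulates the composition of DMD-associated records in
locus-specific databases. Defaults (all configurable in `GeneratorConfig`):

| parameter | default | meaning |
|---|---|---|
| `class_mix` | (0.60, 0.27, 0.135) | deletion / small-lesion / duplication shares among DMD-labelled records |
| `deletion_hotspots` | 43–55 w=0.70; 2–22 w=0.21 | probability a deletion is drawn from (and contained in) each hotspot; remaining mass starts uniformly outside |
| `deletion_span_mean` | 4 exons | mean of the truncated geometric span distribution (also used for multi-exon duplications) |
| `dup_single_prob` | 52/232 | single-exon duplication fraction |
| `dup_exon2_weight` | 12 | start-exon weight multiplier making exon-2 duplications modal (~13% of duplications vs ~1% for other exons) |
| `splice_fraction` | 0.25 | small lesions at splice sites, split evenly donor/acceptor |
| `frame_rule_noise` | 0 | probability a phenotype label violates the reading-frame rule |

Phenotypes follow the reading-frame rule: frameshift deletions/duplications
and all small lesions are labelled DMD, in-frame deletions/duplications BMD.
Because `class_mix` describes the *DMD-labelled* records, the generator
draws deletions and duplications until each class's DMD quota is met and
keeps the in-frame draws that arise on the way as BMD records; `n` is
therefore the DMD-labelled count and the returned cohort is somewhat larger.
With `frame_rule_noise = 0` the DMD/BMD split is exactly auditable; a
positive noise value flips each label independently, modelling the
documented exceptions to the rule.

Exon choice for small lesions is weighted by coding length (longer exons
accumulate more point mutations); no published within-hotspot start/span
joint distribution exists, so the geometric-span model is a declared
approximation, not an estimate of any database.

### What the synthetic cohorts do and do not show

Generated cohorts reproduce class mix, hotspot concentration, splice
fraction and the frame rule, so they exercise every pipeline stage with
realistic marginal structure. They do **not** reproduce the empirical joint
distribution of real deletion endpoints (real databases over-represent
specific recurrent breakpoints), recurrent point mutations, or
phenotype-label noise structure. Consequently, applicability percentages
computed on synthetic cohorts are demonstrations of the machinery, not
estimates of database-specific applicability figures; those depend on the
actual mutation spectrum analysed.

## Numerical and design choices

* All arithmetic is exact integer mod-3; there are no tolerances.
* Degenerate inputs: in-frame deletions/duplications are contract errors for
  the skip enumerators and yield `in_frame` with zero strategies from
  `annotate`; lesions in exon 1/79 with no admissible targets yield an empty
  strategy list (not an error); the last exon has no donor site and the
  first no acceptor, both for parsing and simulation.
* HGVS support is deliberately minimal (del/dup/ins/delins/substitutions
  with optional intronic offsets). Ranges that span more than one exon
  without exact boundary alignment are rejected rather than guessed, since
  partial-exon rearrangement semantics are not modelled. Offsets must
  anchor on an exon boundary, as HGVS requires.
* Determinism: cohort generation uses `numpy.random.default_rng(seed)`
  exclusively; report writers are byte-deterministic.
* Problem sizes in the shipped checks — ≥1000 random transcript/mutation
  oracle-equivalence cases and 10,000-record generator-recovery cohorts —
  were chosen to put sampling error well inside the documented ±2/±3
  percentage-point recovery bands while keeping the whole suite fast.

## Known limitations

* The engine counts *theoretical* frame restoration; it does not predict
  whether the truncated protein is functional, and the reading-frame rule
  itself has documented exceptions in both directions.
* Double skips for deletions are restricted to contiguous flank extensions,
  and duplication double skips to adjacent pairs; non-contiguous target
  pairs are not enumerated.
* Duplications are modelled as tandem, full-exon events; partial-exon and
  non-tandem rearrangements are out of scope, as are genomic (g.)
  coordinates and the shorter dystrophin isoforms.
* The distal-exon caveat of the fixture, above.
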
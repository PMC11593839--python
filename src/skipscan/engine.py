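"""Reading-frame engine: enumerate every frame-restoring exon-skip strategy.

The reading-frame rule is pure mod-3 arithmetic on exon coding lengths: a
deletion (or induced exon loss) is a frameshift iff the total coding length
removed is not a multiple of three, and an antisense-oligonucleotide (ASO)
skip strategy restores the frame iff the *excluded region* — every exon
absent from the final transcript, deleted plus skipped — has total coding
length divisible by three.

Strategy shapes per mutation class:

* **deletions** — single or double skips of exons flanking the deletion.
  Target sets are drawn from {first-2, first-1, last+1, last+2}; the excluded
  region must remain one contiguous exon run, so the admissible shapes are
  {first-1}, {last+1}, {first-2, first-1}, {last+1, last+2} and the
  cross-flank pair {first-1, last+1}.
* **small lesions** — an intra-exonic lesion in a symmetric exon is removed by
  skipping that exon; in an asymmetric exon, by skipping the exon together
  with whichever adjacent exon balances the frame.  A splice-site lesion
  causes the loss of an exon from the transcript; if that exon is symmetric
  no ASO is needed, otherwise the induced single-exon deletion is rescued
  like any other deletion.
* **duplications** — skipping one copy of one duplicated exon (or of two
  adjacent duplicated exons) restores the frame iff the duplicated length
  minus the skipped length is a multiple of three; for a single-exon
  duplication, skipping the one exon always restores the wild type.  If an
  ASO removes *both* copies of a single-exon duplication, the net transcript
  lacks that exon entirely; an adjacent exon whose length rebalances the
  frame is reported as a "rescue-after-double-copy-skip".
* **multi-exon cocktails** — a configured in-frame range (defaults 3–9 and
  45–55) applies to a deletion iff the deletion lies entirely inside the
  range, and to a small lesion iff the lesion-bearing (or induced-lost) exon
  lies inside the range; never to duplications.

Exon 1 (start codon) and the last exon (stop codon) are never skip targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .mutations import Mutation
from .transcript import TranscriptModel

__all__ = [
    "SkipStrategy",
    "Annotation",
    "EngineConfig",
    "FrameStatus",
    "deletion_frame_status",
    "duplication_frame_status",
    "deletion_skips",
    "small_lesion_skips",
    "duplication_skips",
    "duplication_double_copy_rescue",
    "multi_skip_applicable",
    "annotate",
    "annotate_cohort",
    "strategy_label",
]

FrameStatus = str  # "frameshift" | "in_frame" | "not_applicable"

#: note attached to splice lesions whose induced loss is already in-frame
NO_ASO_NEEDED = "no-ASO-needed"
#: note attached to adjacent-exon rescues of a both-copies-skipped duplication
DOUBLE_COPY_RESCUE = "rescue-after-double-copy-skip"


@dataclass(frozen=True)
class SkipStrategy:
    """A set of ASO-targeted exons and the region it removes.

    ``category`` is ``single``/``double``/``multi`` by target count (multi for
    cocktail ranges), or ``none`` for the empty-target case where a
    splice-site lesion already produced an in-frame transcript.
    ``excluded_region`` lists every exon absent from the final transcript
    (deleted/lost plus skipped); for a skip *within* a duplication nothing is
    absent relative to wild type and the set is empty.
    """

    targets: frozenset[int]
    category: str
    excluded_region: frozenset[int] = frozenset()
    note: str = ""
    cocktail: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        expected = {0: "none", 1: "single", 2: "double"}
        if self.category == "multi":
            if self.cocktail is None:
                raise ValueError("multi strategy requires its cocktail range")
        elif expected.get(len(self.targets)) != self.category:
            raise ValueError(
                f"category {self.category!r} inconsistent with {len(self.targets)} target(s)"
            )

    @property
    def label(self) -> str:
        return strategy_label(self)


def strategy_label(s: SkipStrategy) -> str:
    """Canonical display label: single ``"51"``, double ``"51 & 53"``, multi ``"45–55"``."""
    if s.category == "multi":
        return f"{s.cocktail[0]}–{s.cocktail[1]}"
    if s.category == "none":
        return "(none)"
    return " & ".join(str(e) for e in sorted(s.targets))


@dataclass(frozen=True)
class Annotation:
    """Frame status plus every applicable strategy for one mutation."""

    mutation_id: str
    frame_status: FrameStatus
    strategies: tuple[SkipStrategy, ...] = ()

    def by_category(self, category: str) -> list[SkipStrategy]:
        return [s for s in self.strategies if s.category == category]


@dataclass(frozen=True)
class EngineConfig:
    """Tunables of the enumeration.

    ``cocktails`` are the multi-exon-skip ranges evaluated for every mutation;
    each must be in-frame on the transcript in use.  ``splice_loss_convention``
    selects which exon a splice-site lesion removes: ``own_exon`` (standard
    splicing biology — the exon whose own donor/acceptor is mutated is lost)
    or ``neighbor`` (a donor lesion removes the downstream exon, an acceptor
    lesion the upstream exon).
    """

    cocktails: tuple[tuple[int, int], ...] = ((3, 9), (45, 55))
    splice_loss_convention: str = "own_exon"

    def __post_init__(self) -> None:
        if self.splice_loss_convention not in ("own_exon", "neighbor"):
            raise ValueError(
                f"unknown splice_loss_convention {self.splice_loss_convention!r}"
            )


DEFAULT_CONFIG = EngineConfig()


def _skippable(t: TranscriptModel) -> range:
    """Exons that can be ASO targets: everything but the first and last exon."""
    return range(2, t.n_exons)


def _run_length(t: TranscriptModel, exons: Iterable[int]) -> int:
    return sum(t.coding_length(e) for e in exons)


def _assert_sound(t: TranscriptModel, strategy: SkipStrategy) -> SkipStrategy:
    # Every deletion/small-lesion strategy must leave an in-frame transcript.
    if strategy.excluded_region:
        assert _run_length(t, strategy.excluded_region) % 3 == 0, strategy
    return strategy


# --------------------------------------------------------------------------
# deletions
# --------------------------------------------------------------------------

def deletion_frame_status(t: TranscriptModel, first: int, last: int) -> FrameStatus:
    """``frameshift`` iff the deleted coding length is not a multiple of 3."""
    return "frameshift" if t.segment_length(first, last) % 3 else "in_frame"


def duplication_frame_status(t: TranscriptModel, first: int, last: int) -> FrameStatus:
    """Same arithmetic as deletions: inserting 0 mod 3 bases keeps the frame."""
    return deletion_frame_status(t, first, last)


#: admissible flank target shapes for a deletion of exons first..last,
#: expressed as offsets: negative = upstream of first, positive = downstream of last
_DELETION_SHAPES = ((-1,), (1,), (-2, -1), (1, 2), (-1, 1))


def deletion_skips(t: TranscriptModel, first: int, last: int) -> list[SkipStrategy]:
    """All single/double flank skips restoring the frame of a frameshift deletion."""
    if deletion_frame_status(t, first, last) != "frameshift":
        raise ValueError(
            f"deletion {first}..{last} is in-frame; nothing to restore"
        )
    skippable = _skippable(t)
    deleted = frozenset(range(first, last + 1))
    out: list[SkipStrategy] = []
    for shape in _DELETION_SHAPES:
        targets = frozenset(
            (first + o) if o < 0 else (last + o) for o in shape
        )
        if not all(e in skippable for e in targets):
            continue
        excluded = deleted | targets
        if _run_length(t, excluded) % 3:
            continue
        category = "single" if len(targets) == 1 else "double"
        out.append(_assert_sound(t, SkipStrategy(
            targets=targets, category=category, excluded_region=frozenset(excluded)
        )))
    return _dedupe(out)


# --------------------------------------------------------------------------
# small lesions
# --------------------------------------------------------------------------

def resolve_splice_loss(m: Mutation, t: TranscriptModel,
                        convention: str = "own_exon") -> int | None:
    """Exon lost from the transcript by a donor/acceptor lesion, or None if
    the convention points outside the transcript."""
    e = m.lesion_exon
    if convention == "own_exon":
        lost = e
    else:  # neighbor: donor removes the downstream exon, acceptor the upstream one
        lost = e + 1 if m.lesion_site == "donor" else e - 1
    return lost if 1 <= lost <= t.n_exons else None


def small_lesion_skips(
    t: TranscriptModel, m: Mutation, config: EngineConfig = DEFAULT_CONFIG
) -> list[SkipStrategy]:
    """Single/double skips (or the no-ASO case) for a small lesion."""
    if m.mclass != "small_lesion":
        raise ValueError(f"{m.id}: not a small lesion")
    m.check_range(t)
    skippable = _skippable(t)
    e = m.lesion_exon

    if m.lesion_site == "intra":
        out: list[SkipStrategy] = []
        if t.is_symmetric(e):
            if e in skippable:
                out.append(SkipStrategy(
                    targets=frozenset([e]), category="single",
                    excluded_region=frozenset([e]),
                ))
        else:
            for pair in ((e - 1, e), (e, e + 1)):
                if not all(x in skippable for x in pair):
                    continue
                if _run_length(t, pair) % 3:
                    continue
                out.append(SkipStrategy(
                    targets=frozenset(pair), category="double",
                    excluded_region=frozenset(pair),
                ))
        return [_assert_sound(t, s) for s in _dedupe(out)]

    # splice-site lesion: an exon is lost from the transcript
    lost = resolve_splice_loss(m, t, config.splice_loss_convention)
    if lost is None:
        return []
    if t.is_symmetric(lost):
        return [SkipStrategy(
            targets=frozenset(), category="none",
            excluded_region=frozenset([lost]), note=NO_ASO_NEEDED,
        )]
    # induced frameshift deletion of the lost exon; targets never include it
    return deletion_skips(t, lost, lost)


# --------------------------------------------------------------------------
# duplications
# --------------------------------------------------------------------------

def duplication_skips(t: TranscriptModel, first: int, last: int) -> list[SkipStrategy]:
    """One-copy skips within a frameshift duplication.

    Candidates are one duplicated exon, or two *adjacent* duplicated exons,
    whose removal from one copy leaves an in-frame insertion.  For a
    single-exon duplication the unique candidate (the exon itself) always
    qualifies: removing one copy restores the wild-type transcript.
    """
    dup_len = t.segment_length(first, last)
    if dup_len % 3 == 0:
        raise ValueError(f"duplication {first}..{last} is in-frame; nothing to restore")
    skippable = _skippable(t)
    out: list[SkipStrategy] = []
    note = "skip-within-duplication"
    for e in range(first, last + 1):
        if e not in skippable:
            continue
        if (dup_len - t.coding_length(e)) % 3 == 0:
            out.append(SkipStrategy(
                targets=frozenset([e]), category="single", note=note,
            ))
    for e in range(first, last):
        pair = (e, e + 1)
        if not all(x in skippable for x in pair):
            continue
        if (dup_len - _run_length(t, pair)) % 3 == 0:
            out.append(SkipStrategy(
                targets=frozenset(pair), category="double", note=note,
            ))
    return _dedupe(out)


def duplication_double_copy_rescue(t: TranscriptModel, e: int) -> list[SkipStrategy]:
    """Adjacent-exon rescues when both copies of a duplicated exon are skipped.

    If an ASO removes both copies of a single-exon duplication of a
    frameshift (asymmetric) exon ``e``, the net transcript is wild type minus
    ``e``.  Skipping a neighbour ``f`` restores the frame iff
    ``len(e) + len(f)`` is a multiple of three.
    """
    if t.coding_length(e) % 3 == 0:
        raise ValueError(f"exon {e} is symmetric; a double-copy skip is already in-frame")
    skippable = _skippable(t)
    out: list[SkipStrategy] = []
    for f in (e - 1, e + 1):
        if f not in skippable:
            continue
        if (t.coding_length(e) + t.coding_length(f)) % 3 == 0:
            out.append(_assert_sound(t, SkipStrategy(
                targets=frozenset([f]), category="single",
                excluded_region=frozenset([e, f]), note=DOUBLE_COPY_RESCUE,
            )))
    return _dedupe(out)


# --------------------------------------------------------------------------
# multi-exon cocktails
# --------------------------------------------------------------------------

def multi_skip_applicable(
    t: TranscriptModel, m: Mutation, range_first: int, range_last: int,
    config: EngineConfig = DEFAULT_CONFIG,
) -> bool:
    """Whether skipping the whole cocktail range rescues mutation ``m``.

    The range itself must be in-frame.  A deletion qualifies iff it is a
    frameshift lying entirely inside the range (skipping the surviving range
    exons produces the full in-frame range deletion); a small lesion iff its
    lesion-bearing — or, for splice lesions, induced-lost — exon lies in the
    range; duplications never qualify.
    """
    if not (1 <= range_first <= range_last <= t.n_exons):
        raise ValueError(f"cocktail range {range_first}..{range_last} out of bounds")
    if t.segment_length(range_first, range_last) % 3:
        raise ValueError(
            f"cocktail range {range_first}..{range_last} is not in-frame on this transcript"
        )
    if m.mclass == "duplication":
        return False
    if m.mclass == "deletion":
        if deletion_frame_status(t, m.first_exon, m.last_exon) != "frameshift":
            return False
        return range_first <= m.first_exon and m.last_exon <= range_last
    # small lesion
    if m.lesion_site == "intra":
        affected = m.lesion_exon
    else:
        affected = resolve_splice_loss(m, t, config.splice_loss_convention)
        if affected is None:
            return False
    return range_first <= affected <= range_last


def _multi_strategy(
    t: TranscriptModel, m: Mutation, range_first: int, range_last: int,
    config: EngineConfig,
) -> SkipStrategy:
    region = frozenset(range(range_first, range_last + 1))
    if m.mclass == "deletion":
        absent = frozenset(range(m.first_exon, m.last_exon + 1))
    elif m.lesion_site != "intra":
        lost = resolve_splice_loss(m, t, config.splice_loss_convention)
        absent = frozenset([lost]) if lost is not None else frozenset()
    else:
        absent = frozenset()
    return _assert_sound(t, SkipStrategy(
        targets=region - absent, category="multi",
        excluded_region=region, cocktail=(range_first, range_last),
    ))


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------

def _dedupe(strategies: Iterable[SkipStrategy]) -> list[SkipStrategy]:
    seen: set[tuple] = set()
    out = []
    for s in sorted(strategies, key=lambda s: (len(s.targets), sorted(s.targets))):
        key = (s.targets, s.category)
        if key in seen:
            continue
        seen.add(key)
        out.append(s)
    return out


def annotate(
    t: TranscriptModel, m: Mutation, config: EngineConfig = DEFAULT_CONFIG
) -> Annotation:
    """Frame status and the complete de-duplicated strategy list for ``m``."""
    m.check_range(t)
    strategies: list[SkipStrategy] = []

    if m.mclass == "deletion":
        status = deletion_frame_status(t, m.first_exon, m.last_exon)
        if status == "frameshift":
            strategies.extend(deletion_skips(t, m.first_exon, m.last_exon))
    elif m.mclass == "duplication":
        status = duplication_frame_status(t, m.first_exon, m.last_exon)
        if status == "frameshift":
            strategies.extend(duplication_skips(t, m.first_exon, m.last_exon))
            if m.first_exon == m.last_exon:
                strategies.extend(duplication_double_copy_rescue(t, m.first_exon))
    else:
        status = "not_applicable"
        strategies.extend(small_lesion_skips(t, m, config))

    if status != "in_frame":
        for range_first, range_last in config.cocktails:
            if multi_skip_applicable(t, m, range_first, range_last, config):
                strategies.append(_multi_strategy(t, m, range_first, range_last, config))

    return Annotation(
        mutation_id=m.id, frame_status=status, strategies=tuple(_dedupe(strategies))
    )


def annotate_cohort(
    t: TranscriptModel, mutations: Sequence[Mutation],
    config: EngineConfig = DEFAULT_CONFIG,
) -> list[Annotation]:
    """Annotate every mutation (deterministic, order-preserving)."""
    return [annotate(t, m, config) for m in mutations]


# --------------------------------------------------------------------------
# annotation export (JSON per mutation; flat strategy TSV)
# --------------------------------------------------------------------------

def annotations_to_records(annotations: Sequence[Annotation]) -> list[dict]:
    """JSON-ready records: one object per mutation."""
    records = []
    for a in annotations:
        records.append({
            "id": a.mutation_id,
            "frame_status": a.frame_status,
            "strategies": [
                {
                    "targets": sorted(s.targets),
                    "category": s.category,
                    "label": s.label,
                    "note": s.note,
                    **({"cocktail": list(s.cocktail)} if s.cocktail else {}),
                }
                for s in a.strategies
            ],
        })
    return records


def annotations_from_records(records: Sequence[dict]) -> list[Annotation]:
    """Inverse of :func:`annotations_to_records`."""
    out = []
    for rec in records:
        strategies = []
        for s in rec["strategies"]:
            strategies.append(SkipStrategy(
                targets=frozenset(s["targets"]),
                category=s["category"],
                note=s.get("note", ""),
                cocktail=tuple(s["cocktail"]) if s.get("cocktail") else None,
            ))
        out.append(Annotation(
            mutation_id=rec["id"], frame_status=rec["frame_status"],
            strategies=tuple(strategies),
        ))
    return out
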
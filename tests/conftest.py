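"""Shared fixtures and independent brute-force oracles.

The oracles re-derive strategy sets by exhaustive enumeration straight from
the admissible-shape definitions, deliberately sharing no code with the
engine, so engine/oracle agreement is a meaningful check.
"""

from __future__ import annotations

import itertools

import pytest

from skipscan import TranscriptModel, load_dmd_transcript


@pytest.fixture(scope="session")
def dmd() -> TranscriptModel:
    return load_dmd_transcript()


def make_transcript(lengths) -> TranscriptModel:
    return TranscriptModel.from_lengths(lengths)


def _contiguous(exons: set[int]) -> bool:
    lo, hi = min(exons), max(exons)
    return len(exons) == hi - lo + 1


def _seg(t: TranscriptModel, exons) -> int:
    return sum(t.coding_length(e) for e in exons)


def oracle_deletion_skips(t: TranscriptModel, first: int, last: int) -> set[frozenset]:
    """Every 1- or 2-exon flank target set restoring the frame of a deletion."""
    candidates = [e for e in (first - 2, first - 1, last + 1, last + 2)
                  if 2 <= e <= t.n_exons - 1]
    deleted = set(range(first, last + 1))
    out = set()
    for size in (1, 2):
        for combo in itertools.combinations(candidates, size):
            excluded = deleted | set(combo)
            if not _contiguous(excluded):
                continue
            if _seg(t, excluded) % 3 == 0:
                out.add(frozenset(combo))
    return out


def oracle_intra_lesion_skips(t: TranscriptModel, e: int) -> set[frozenset]:
    """Target sets removing an intra-exonic lesion in exon e in-frame."""
    out = set()
    if t.coding_length(e) % 3 == 0:
        if 2 <= e <= t.n_exons - 1:
            out.add(frozenset([e]))
        return out
    for pair in ((e - 1, e), (e, e + 1)):
        if all(2 <= x <= t.n_exons - 1 for x in pair) and _seg(t, pair) % 3 == 0:
            out.add(frozenset(pair))
    return out


def oracle_splice_lesion_skips(t: TranscriptModel, lost: int) -> set[frozenset]:
    """Target sets rescuing the induced loss of exon ``lost`` (asymmetric)."""
    assert t.coding_length(lost) % 3 != 0
    return oracle_deletion_skips(t, lost, lost)


def oracle_duplication_skips(t: TranscriptModel, first: int, last: int) -> set[frozenset]:
    """1-exon and adjacent-2-exon subsets of a frameshift duplication whose
    removal from one copy leaves an in-frame insertion."""
    dup_len = t.segment_length(first, last)
    assert dup_len % 3 != 0
    out = set()
    for e in range(first, last + 1):
        if 2 <= e <= t.n_exons - 1 and (dup_len - t.coding_length(e)) % 3 == 0:
            out.add(frozenset([e]))
    for e in range(first, last):
        pair = (e, e + 1)
        if all(2 <= x <= t.n_exons - 1 for x in pair) and (dup_len - _seg(t, pair)) % 3 == 0:
            out.add(frozenset(pair))
    return out


def oracle_double_copy_rescue(t: TranscriptModel, e: int) -> set[frozenset]:
    out = set()
    for f in (e - 1, e + 1):
        if 2 <= f <= t.n_exons - 1 and (t.coding_length(e) + t.coding_length(f)) % 3 == 0:
            out.add(frozenset([f]))
    return out
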
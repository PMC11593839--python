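"""Exon-level model of a coding transcript in HGVS c. coordinates.

The central object is :class:`TranscriptModel`, an ordered table of exons with
their CDS coordinates (c.1 is the A of the start codon, the last position is
the final base of the stop codon; UTRs are excluded).  From the coordinates
the model derives, per exon, its coding length, the *phase* of the flanking
introns (cumulative coding length mod 3 at the boundary; phase 0 means the
boundary falls between codons) and whether the exon is *symmetric* — flanked
by introns of equal phase, equivalently a coding length divisible by three.
Removing a symmetric exon, or any run of exons whose total length is a
multiple of three, preserves the downstream reading frame; that arithmetic is
what every exon-skipping strategy in this package rests on.

The default transcript is the 79-exon full-length muscle dystrophin isoform
Dp427m, shipped as a static table and validated on load (see
:func:`load_dmd_transcript` and :func:`validate_fixture`).  All downstream
machinery accepts an arbitrary :class:`TranscriptModel`, so property tests can
run on small synthetic transcripts built with :meth:`TranscriptModel.from_lengths`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ExonRecord",
    "TranscriptModel",
    "TranscriptError",
    "FixtureCheck",
    "FixtureReport",
    "load_transcript",
    "load_dmd_transcript",
    "validate_fixture",
    "DMD_EXON_COUNT",
]

#: number of exons in the full-length dystrophin transcript
DMD_EXON_COUNT = 79

#: validation anchors for the shipped Dp427m table: (exon, c_start, c_end)
_DMD_ANCHOR = (52, 7543, 7660)

#: exon ranges that must be in-frame on the DMD fixture (multi-skip cocktails)
_DMD_IN_FRAME_RANGES = ((3, 9), (45, 55))


class TranscriptError(ValueError):
    """Raised when an exon table violates the transcript invariants."""


@dataclass(frozen=True)
class ExonRecord:
    """One exon of a coding transcript, CDS portion only.

    ``start_phase``/``end_phase`` are the phases of the introns preceding and
    following the exon; ``symmetric`` is true iff both phases agree, i.e. the
    coding length is a multiple of three.
    """

    index: int
    c_start: int
    c_end: int

    @property
    def coding_length(self) -> int:
        return self.c_end - self.c_start + 1

    @property
    def start_phase(self) -> int:
        return (self.c_start - 1) % 3

    @property
    def end_phase(self) -> int:
        return self.c_end % 3

    @property
    def symmetric(self) -> bool:
        return self.coding_length % 3 == 0

    def __post_init__(self) -> None:
        if self.index < 1:
            raise TranscriptError(f"exon index must be >= 1, got {self.index}")
        if self.c_end < self.c_start or self.c_start < 1:
            raise TranscriptError(
                f"exon {self.index}: invalid c. interval {self.c_start}..{self.c_end}"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered, contiguous exon table of a single coding transcript."""

    exons: tuple[ExonRecord, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise TranscriptError("transcript has no exons")
        expected = 1
        for exon in self.exons:
            if exon.index != expected:
                raise TranscriptError(
                    f"exon indices must be 1..n in order; expected {expected}, "
                    f"found {exon.index}"
                )
            expected += 1
        if self.exons[0].c_start != 1:
            raise TranscriptError(
                f"exon 1 must start at c.1, starts at c.{self.exons[0].c_start}"
            )
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.c_start != prev.c_end + 1:
                raise TranscriptError(
                    f"non-contiguous c. coordinates between exon {prev.index} "
                    f"(ends c.{prev.c_end}) and exon {cur.index} (starts c.{cur.c_start})"
                )

    @classmethod
    def from_lengths(cls, lengths: Sequence[int]) -> "TranscriptModel":
        """Build a transcript from per-exon coding lengths (handy for tests)."""
        exons = []
        pos = 1
        for i, length in enumerate(lengths, start=1):
            if length < 1:
                raise TranscriptError(f"exon {i}: coding length must be >= 1")
            exons.append(ExonRecord(index=i, c_start=pos, c_end=pos + length - 1))
            pos += length
        return cls(exons=tuple(exons))

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return self.exons[-1].c_end

    def exon(self, index: int) -> ExonRecord:
        if not 1 <= index <= self.n_exons:
            raise TranscriptError(
                f"exon index {index} out of range 1..{self.n_exons}"
            )
        return self.exons[index - 1]

    def coding_length(self, index: int) -> int:
        return self.exon(index).coding_length

    def segment_length(self, first: int, last: int) -> int:
        """Total coding nucleotides of exons ``first..last`` (inclusive)."""
        if first > last:
            raise TranscriptError(f"invalid exon range {first}..{last}")
        return self.exon(last).c_end - self.exon(first).c_start + 1

    def is_symmetric(self, index: int) -> bool:
        """True iff the exon's coding length is divisible by three."""
        return self.exon(index).symmetric

    def exon_containing(self, c_pos: int) -> ExonRecord:
        """Exon whose CDS interval contains coding position ``c_pos``."""
        if not 1 <= c_pos <= self.cds_length:
            raise TranscriptError(
                f"c.{c_pos} outside CDS (c.1..c.{self.cds_length})"
            )
        # exon count is tiny (<=79 in practice); linear scan is fine
        for exon in self.exons:
            if exon.c_start <= c_pos <= exon.c_end:
                return exon
        raise AssertionError("unreachable: contiguous exon table")


@dataclass(frozen=True)
class FixtureCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class FixtureReport:
    checks: tuple[FixtureCheck, ...] = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[FixtureCheck]:
        return [c for c in self.checks if not c.passed]

    def __str__(self) -> str:
        lines = []
        for c in self.checks:
            status = "PASS" if c.passed else "FAIL"
            detail = f" ({c.detail})" if c.detail else ""
            lines.append(f"[{status}] {c.name}{detail}")
        return "\n".join(lines)


def validate_fixture(t: TranscriptModel) -> FixtureReport:
    """Check a transcript against the Dp427m anchors.

    The report covers: exon count, the exon-52 coordinate anchor
    (c.7543..7660), in-frame multi-skip cocktail ranges 3–9 and 45–55, and
    contiguity of the c. coordinates (guaranteed by construction of
    :class:`TranscriptModel`, but restated so the report is self-contained).
    """
    checks: list[FixtureCheck] = []

    checks.append(
        FixtureCheck(
            name=f"exon count == {DMD_EXON_COUNT}",
            passed=t.n_exons == DMD_EXON_COUNT,
            detail=f"found {t.n_exons}",
        )
    )

    anchor_exon, anchor_start, anchor_end = _DMD_ANCHOR
    if t.n_exons >= anchor_exon:
        exon = t.exon(anchor_exon)
        ok = (exon.c_start, exon.c_end) == (anchor_start, anchor_end)
        detail = f"exon {anchor_exon} spans c.{exon.c_start}..c.{exon.c_end}"
    else:
        ok, detail = False, f"exon {anchor_exon} missing"
    checks.append(
        FixtureCheck(
            name=f"exon {anchor_exon} anchor c.{anchor_start}..c.{anchor_end}",
            passed=ok,
            detail=detail,
        )
    )

    for first, last in _DMD_IN_FRAME_RANGES:
        if t.n_exons >= last:
            length = t.segment_length(first, last)
            ok = length % 3 == 0
            detail = f"length {length} nt"
        else:
            ok, detail = False, "range missing"
        checks.append(
            FixtureCheck(name=f"exons {first}–{last} in-frame", passed=ok, detail=detail)
        )

    checks.append(
        FixtureCheck(name="contiguous c. coordinates", passed=True, detail="validated on load")
    )
    return FixtureReport(checks=tuple(checks))


def _parse_rows(rows: Iterable[dict], source: str) -> TranscriptModel:
    seen: dict[int, tuple[int, int]] = {}
    for lineno, row in enumerate(rows, start=2):
        try:
            index = int(row["exon"])
            c_start = int(row["c_start"])
            c_end = int(row["c_end"])
        except (KeyError, TypeError, ValueError) as exc:
            raise TranscriptError(f"{source}: malformed row {lineno}: {row}") from exc
        if index in seen:
            raise TranscriptError(f"{source}: duplicate exon index {index}")
        seen[index] = (c_start, c_end)
    if not seen:
        raise TranscriptError(f"{source}: empty exon table")
    exons = []
    for index in sorted(seen):
        c_start, c_end = seen[index]
        exons.append(ExonRecord(index=index, c_start=c_start, c_end=c_end))
    return TranscriptModel(exons=tuple(exons))


def load_transcript(path: str | Path, *, require_dmd: bool = True) -> TranscriptModel:
    """Load an exon table (TSV: ``exon  c_start  c_end``, 1-based inclusive).

    Phases and symmetry flags are always recomputed from the coordinates,
    never read from the file.  With ``require_dmd=True`` (default) the table
    must additionally pass all :func:`validate_fixture` anchors; the first
    failing check is raised as a :class:`TranscriptError` naming the exon or
    range involved.  Pass ``require_dmd=False`` to load an arbitrary
    transcript (e.g. a small synthetic one).
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        t = _parse_rows(reader, source=str(path))
    if require_dmd:
        report = validate_fixture(t)
        if not report.ok:
            failed = "; ".join(
                f"{c.name}: {c.detail}" if c.detail else c.name for c in report.failures()
            )
            if t.n_exons != DMD_EXON_COUNT:
                raise TranscriptError(
                    f"{path}: expected {DMD_EXON_COUNT} exons, found {t.n_exons}"
                )
            raise TranscriptError(f"{path}: fixture validation failed: {failed}")
    return t


def load_dmd_transcript() -> TranscriptModel:
    """The packaged 79-exon Dp427m CDS exon table, validated on load."""
    ref = resources.files("skipscan.data").joinpath("dp427m_cds_exons.tsv")
    with resources.as_file(ref) as path:
        return load_transcript(path, require_dmd=True)


def segment_length(t: TranscriptModel, first: int, last: int) -> int:
    """Module-level alias for :meth:`TranscriptModel.segment_length`."""
    return t.segment_length(first, last)


def is_symmetric(t: TranscriptModel, index: int) -> bool:
    """Module-level alias for :meth:`TranscriptModel.is_symmetric`."""
    return t.is_symmetric(index)
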
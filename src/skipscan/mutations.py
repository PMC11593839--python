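"""Mutation records: tabular I/O, a minimal HGVS c. parser, phenotype filters.

A :class:`Mutation` is a tagged record of one of three classes — exon-range
``deletion``, exon-range ``duplication``, or ``small_lesion`` (an intra-exonic
point mutation/small indel, or a splice-site lesion at a donor or acceptor).
Large rearrangements are encoded at exon resolution, the convention used by
locus-specific DMD databases; nucleotide-resolution ranges are accepted only
when they align exactly with exon boundaries.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .transcript import TranscriptModel

__all__ = [
    "Mutation",
    "MutationError",
    "HgvsParseError",
    "MUTATION_CLASSES",
    "LESION_SITES",
    "PHENOTYPES",
    "read_mutation_table",
    "write_mutation_table",
    "parse_hgvs_lite",
    "to_hgvs",
    "filter_phenotype",
]

MUTATION_CLASSES = ("deletion", "duplication", "small_lesion")
LESION_SITES = ("intra", "donor", "acceptor")
PHENOTYPES = ("DMD", "BMD", "IMD", "DCM", "pending")

_TSV_COLUMNS = ("id", "mclass", "first_exon", "last_exon", "lesion_site", "phenotype", "hgvs")


class MutationError(ValueError):
    """Raised for invalid mutation records or malformed mutation tables."""


class HgvsParseError(MutationError):
    """Raised when an HGVS c. string is outside the supported grammar."""


@dataclass(frozen=True)
class Mutation:
    """One patient mutation at exon resolution.

    Exactly the fields of the declared class are populated: deletions and
    duplications carry ``first_exon``/``last_exon`` (equal for single-exon
    events); small lesions carry ``lesion_exon`` and ``lesion_site``.
    """

    id: str
    mclass: str
    phenotype: str = "DMD"
    first_exon: int | None = None
    last_exon: int | None = None
    lesion_exon: int | None = None
    lesion_site: str | None = None
    raw: str | None = None

    def __post_init__(self) -> None:
        if self.mclass not in MUTATION_CLASSES:
            raise MutationError(f"{self.id}: unknown mutation class {self.mclass!r}")
        if self.phenotype not in PHENOTYPES:
            raise MutationError(f"{self.id}: unknown phenotype {self.phenotype!r}")
        if self.mclass in ("deletion", "duplication"):
            if self.first_exon is None or self.last_exon is None:
                raise MutationError(f"{self.id}: {self.mclass} requires an exon range")
            if self.lesion_exon is not None or self.lesion_site is not None:
                raise MutationError(f"{self.id}: lesion fields set on a {self.mclass}")
            if not 1 <= self.first_exon <= self.last_exon:
                raise MutationError(
                    f"{self.id}: invalid exon range {self.first_exon}..{self.last_exon}"
                )
        else:
            if self.lesion_exon is None or self.lesion_site is None:
                raise MutationError(f"{self.id}: small_lesion requires lesion_exon and lesion_site")
            if self.first_exon is not None or self.last_exon is not None:
                raise MutationError(f"{self.id}: range fields set on a small_lesion")
            if self.lesion_site not in LESION_SITES:
                raise MutationError(f"{self.id}: unknown lesion site {self.lesion_site!r}")
            if self.lesion_exon < 1:
                raise MutationError(f"{self.id}: invalid lesion exon {self.lesion_exon}")

    def check_range(self, t: TranscriptModel) -> None:
        """Validate exon indices against a transcript (raises MutationError)."""
        top = self.last_exon if self.mclass != "small_lesion" else self.lesion_exon
        low = self.first_exon if self.mclass != "small_lesion" else self.lesion_exon
        if low < 1 or top > t.n_exons:
            raise MutationError(
                f"{self.id}: exon index out of range 1..{t.n_exons}"
            )

    @classmethod
    def deletion(cls, id: str, first: int, last: int, phenotype: str = "DMD", **kw) -> "Mutation":
        return cls(id=id, mclass="deletion", first_exon=first, last_exon=last,
                   phenotype=phenotype, **kw)

    @classmethod
    def duplication(cls, id: str, first: int, last: int, phenotype: str = "DMD", **kw) -> "Mutation":
        return cls(id=id, mclass="duplication", first_exon=first, last_exon=last,
                   phenotype=phenotype, **kw)

    @classmethod
    def small_lesion(cls, id: str, exon: int, site: str = "intra",
                     phenotype: str = "DMD", **kw) -> "Mutation":
        return cls(id=id, mclass="small_lesion", lesion_exon=exon, lesion_site=site,
                   phenotype=phenotype, **kw)


# --------------------------------------------------------------------------
# tabular I/O
# --------------------------------------------------------------------------

def read_mutation_table(path: str | Path, t: TranscriptModel) -> list[Mutation]:
    """Read mutations from the documented TSV schema.

    Header: ``id  mclass  first_exon  last_exon  lesion_site  phenotype  hgvs``.
    Cells that do not apply to the record's class are left empty.  A row with
    an ``hgvs`` cell and empty coordinate cells is routed through
    :func:`parse_hgvs_lite`.  Any malformed row raises :class:`MutationError`
    naming the row number.
    """
    path = Path(path)
    mutations: list[Mutation] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != list(_TSV_COLUMNS):
            raise MutationError(
                f"{path}: expected header {list(_TSV_COLUMNS)}, found {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                mutations.append(_row_to_mutation(row, t))
            except MutationError as exc:
                raise MutationError(f"{path}: row {lineno}: {exc}") from exc
    return mutations


def _cell(row: dict, key: str) -> str:
    value = row.get(key)
    return value.strip() if value else ""


def _row_to_mutation(row: dict, t: TranscriptModel) -> Mutation:
    mid = _cell(row, "id")
    if not mid:
        raise MutationError("missing id")
    hgvs = _cell(row, "hgvs")
    mclass = _cell(row, "mclass").lower()
    first, last = _cell(row, "first_exon"), _cell(row, "last_exon")
    site = _cell(row, "lesion_site").lower() or None
    phenotype = _cell(row, "phenotype")
    phenotype = _normalize_phenotype(phenotype) if phenotype else "DMD"

    if hgvs and not first and not last:
        m = parse_hgvs_lite(hgvs, t)
        return replace(m, id=mid, phenotype=phenotype)

    def _exon(cell: str, name: str) -> int:
        try:
            value = int(cell)
        except ValueError as exc:
            raise MutationError(f"{mid}: non-integer {name} {cell!r}") from exc
        if not 1 <= value <= t.n_exons:
            raise MutationError(f"{mid}: {name} {value} out of range 1..{t.n_exons}")
        return value

    if mclass == "small_lesion":
        if not first:
            raise MutationError(f"{mid}: small_lesion requires its exon in first_exon")
        m = Mutation.small_lesion(mid, _exon(first, "first_exon"), site or "intra",
                                  phenotype, raw=hgvs or None)
    elif mclass in ("deletion", "duplication"):
        if not first or not last:
            raise MutationError(f"{mid}: {mclass} requires first_exon and last_exon")
        m = Mutation(id=mid, mclass=mclass, first_exon=_exon(first, "first_exon"),
                     last_exon=_exon(last, "last_exon"), phenotype=phenotype,
                     raw=hgvs or None)
    else:
        raise MutationError(f"{mid}: unknown mutation class {mclass!r}")
    m.check_range(t)
    return m


def _normalize_phenotype(token: str) -> str:
    for known in PHENOTYPES:
        if token.lower() == known.lower():
            return known
    raise MutationError(f"unknown phenotype {token!r}")


def write_mutation_table(mutations: Iterable[Mutation], path: str | Path) -> Path:
    """Write mutations in the TSV schema read by :func:`read_mutation_table`."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for m in mutations:
            if m.mclass == "small_lesion":
                row = [m.id, m.mclass, m.lesion_exon, "", m.lesion_site, m.phenotype, m.raw or ""]
            else:
                row = [m.id, m.mclass, m.first_exon, m.last_exon, "", m.phenotype, m.raw or ""]
            writer.writerow(row)
    return path


# --------------------------------------------------------------------------
# minimal HGVS c. parser
# --------------------------------------------------------------------------

_POS = r"(?P<{0}>\d+)(?P<{0}off>[+-]\d+)?"
_RANGE_RE = re.compile(
    r"^c\." + _POS.format("p1") + r"_" + _POS.format("p2") +
    r"(?P<kind>del|dup|delins[ACGTacgt]*|ins[ACGTacgt]+)$"
)
_POINT_RE = re.compile(
    r"^c\." + _POS.format("p1") +
    r"(?:(?P<ref>[ACGTacgt])>(?P<alt>[ACGTacgt])|(?P<kind>del|dup|delins[ACGTacgt]*|ins[ACGTacgt]+)([ACGTacgt]*)?)$"
)


def parse_hgvs_lite(s: str, t: TranscriptModel) -> Mutation:
    """Parse a simplified HGVS c. string into an exon-resolution Mutation.

    Supported grammar: ``c.<pos>_<pos>del|dup|ins|delins``, ``c.<pos><ref>><alt>``,
    ``c.<pos>del|dup|ins|delins``, with optional intronic offsets ``+n``/``-n``.

    Resolution rules:

    * a del/dup range whose endpoints coincide exactly with exon boundaries
      and span >= 1 full exon becomes an exon-range deletion/duplication;
    * any intra-exonic variant (single position or a range inside one exon)
      becomes a ``small_lesion(intra)`` in the containing exon;
    * a position with offset ``+n`` marks the donor site of the exon whose
      last coding base anchors the offset; ``-n`` marks the acceptor site of
      the exon whose first coding base anchors the offset;
    * a del/dup range that is not exon-boundary-aligned but spans more than
      one exon is unsupported and raises :class:`HgvsParseError` (such records
      need manual exon-level encoding).
    """
    s = s.strip()
    m = _RANGE_RE.match(s)
    if m:
        return _parse_range(s, m, t)
    m = _POINT_RE.match(s)
    if m:
        return _parse_point(s, m, t)
    raise HgvsParseError(f"unsupported HGVS string {s!r}")


def _anchor_pos(pos: int, t: TranscriptModel) -> None:
    if not 1 <= pos <= t.cds_length:
        raise HgvsParseError(f"c.{pos} outside CDS (c.1..c.{t.cds_length})")


def _splice_lesion(s: str, pos: int, offset: int, t: TranscriptModel) -> Mutation:
    _anchor_pos(pos, t)
    exon = t.exon_containing(pos)
    if offset > 0:
        if pos != exon.c_end:
            raise HgvsParseError(
                f"{s!r}: +offset must anchor at an exon's last coding base "
                f"(c.{pos} is inside exon {exon.index})"
            )
        if exon.index == t.n_exons:
            raise HgvsParseError(f"{s!r}: the last exon has no donor site")
        return Mutation.small_lesion("", exon.index, "donor", raw=s)
    if pos != exon.c_start:
        raise HgvsParseError(
            f"{s!r}: -offset must anchor at an exon's first coding base "
            f"(c.{pos} is inside exon {exon.index})"
        )
    if exon.index == 1:
        raise HgvsParseError(f"{s!r}: the first exon has no acceptor site")
    return Mutation.small_lesion("", exon.index, "acceptor", raw=s)


def _parse_point(s: str, m: re.Match, t: TranscriptModel) -> Mutation:
    pos = int(m.group("p1"))
    offset = int(m.group("p1off") or 0)
    if offset:
        return _splice_lesion(s, pos, offset, t)
    _anchor_pos(pos, t)
    exon = t.exon_containing(pos)
    return Mutation.small_lesion("", exon.index, "intra", raw=s)


def _parse_range(s: str, m: re.Match, t: TranscriptModel) -> Mutation:
    p1, p2 = int(m.group("p1")), int(m.group("p2"))
    off1, off2 = int(m.group("p1off") or 0), int(m.group("p2off") or 0)
    kind = m.group("kind")
    if off1 or off2:
        if p1 == p2 or kind.startswith("ins"):
            return _splice_lesion(s, p1 if off1 else p2, off1 or off2, t)
        raise HgvsParseError(f"{s!r}: ranges with intronic offsets are unsupported")
    if p2 < p1:
        raise HgvsParseError(f"{s!r}: inverted range")
    _anchor_pos(p1, t)
    _anchor_pos(p2, t)
    e1, e2 = t.exon_containing(p1), t.exon_containing(p2)
    if kind in ("del", "dup"):
        if p1 == e1.c_start and p2 == e2.c_end:
            cls = Mutation.deletion if kind == "del" else Mutation.duplication
            return cls("", e1.index, e2.index, raw=s)
        if e1.index != e2.index:
            raise HgvsParseError(
                f"{s!r}: range spans exons {e1.index}..{e2.index} but is not "
                "exon-boundary-aligned; encode it at exon resolution instead"
            )
        return Mutation.small_lesion("", e1.index, "intra", raw=s)
    # ins / delins: small variants only
    if e1.index != e2.index:
        raise HgvsParseError(f"{s!r}: multi-exon {kind} is unsupported")
    return Mutation.small_lesion("", e1.index, "intra", raw=s)


def to_hgvs(m: Mutation, t: TranscriptModel) -> str:
    """Render a Mutation as a (simplified, boundary-aligned) HGVS c. string."""
    if m.mclass in ("deletion", "duplication"):
        first, last = t.exon(m.first_exon), t.exon(m.last_exon)
        suffix = "del" if m.mclass == "deletion" else "dup"
        return f"c.{first.c_start}_{last.c_end}{suffix}"
    exon = t.exon(m.lesion_exon)
    if m.lesion_site == "intra":
        return f"c.{exon.c_start}del"
    if m.lesion_site == "donor":
        return f"c.{exon.c_end}+1G>A"
    return f"c.{exon.c_start}-1G>A"


def filter_phenotype(
    mutations: Sequence[Mutation], keep: Iterable[str] = ("DMD",)
) -> list[Mutation]:
    """Order-preserving subset of mutations whose phenotype is in ``keep``."""
    keep_set = {_normalize_phenotype(k) for k in keep}
    return [m for m in mutations if m.phenotype in keep_set]
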
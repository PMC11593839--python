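"""Cohort-level applicability tables.

Aggregates per-mutation annotations into the summary objects a therapy
developer cares about: how many patients each skip strategy could treat
(per strategy, per mutation class, and overall), and what fraction of each
class is amenable to single, double, single-or-double, or multi-exon
skipping.  Percentages use configurable denominators because locus-specific
databases can be summarized either over all records of a class (including
in-frame deletions that no skip can help) or over frameshift records only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .engine import Annotation
from .mutations import Mutation

__all__ = [
    "SummaryConfig",
    "StrategyRow",
    "ClassRow",
    "CohortSummary",
    "CompositionReport",
    "summarize",
    "composition_report",
    "write_report",
    "read_report",
]

CLASSES = ("deletion", "small_lesion", "duplication")


@dataclass(frozen=True)
class SummaryConfig:
    """``denominator="all"`` divides deletion percentages by every deletion
    record (in-frame included); ``"frameshift"`` by frameshift deletions only."""

    denominator: str = "all"

    def __post_init__(self) -> None:
        if self.denominator not in ("all", "frameshift"):
            raise ValueError(f"unknown denominator mode {self.denominator!r}")


@dataclass(frozen=True)
class StrategyRow:
    label: str
    counts: Mapping[str, int]          # per mutation class
    percents: Mapping[str, float]      # per mutation class
    overall_count: int
    overall_percent: float


@dataclass(frozen=True)
class ClassRow:
    mclass: str
    single: float
    double: float
    single_or_double: float
    multi: float | None                # None where not evaluated (duplications)


@dataclass(frozen=True)
class CohortSummary:
    denominators: Mapping[str, int]    # per class + "overall"
    strategy_rows: tuple[StrategyRow, ...]
    class_rows: tuple[ClassRow, ...]

    def strategy_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.strategy_rows, start=1):
            rows.append({
                "rank": i, "strategy": r.label,
                "overall_count": r.overall_count,
                "overall_percent": r.overall_percent,
                **{f"{c}_count": r.counts.get(c, 0) for c in CLASSES},
                **{f"{c}_percent": r.percents.get(c, 0.0) for c in CLASSES},
            })
        return pd.DataFrame(rows)

    def class_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"class": r.mclass, "single": r.single, "double": r.double,
             "single_or_double": r.single_or_double, "multi": r.multi}
            for r in self.class_rows
        ])

    def to_dict(self) -> dict:
        return {
            "denominators": dict(self.denominators),
            "strategies": [
                {"label": r.label, "counts": dict(r.counts),
                 "percents": dict(r.percents),
                 "overall_count": r.overall_count,
                 "overall_percent": r.overall_percent}
                for r in self.strategy_rows
            ],
            "classes": [
                {"class": r.mclass, "single": r.single, "double": r.double,
                 "single_or_double": r.single_or_double, "multi": r.multi}
                for r in self.class_rows
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CohortSummary":
        return cls(
            denominators=dict(data["denominators"]),
            strategy_rows=tuple(
                StrategyRow(label=r["label"], counts=dict(r["counts"]),
                            percents=dict(r["percents"]),
                            overall_count=r["overall_count"],
                            overall_percent=r["overall_percent"])
                for r in data["strategies"]
            ),
            class_rows=tuple(
                ClassRow(mclass=r["class"], single=r["single"], double=r["double"],
                         single_or_double=r["single_or_double"], multi=r["multi"])
                for r in data["classes"]
            ),
        )


def _percent(count: int, denominator: int) -> float:
    return 100.0 * count / denominator


def summarize(
    annotations: Sequence[Annotation],
    mutations: Sequence[Mutation],
    config: SummaryConfig = SummaryConfig(),
) -> CohortSummary:
    """Aggregate annotations into strategy and class applicability tables.

    A mutation contributes at most once to any strategy row but may appear in
    several rows.  Strategy rows are sorted by overall percentage descending,
    ties broken by label.  Class rows report the fraction of each class with
    at least one single, at least one double, at least one of either, and at
    least one multi strategy (multi is not evaluated for duplications).
    Empty-target "no-ASO-needed" records never enter per-strategy counts.
    """
    if not mutations:
        raise ValueError("empty cohort: denominators are undefined")
    by_id = {m.id: m for m in mutations}
    if len(by_id) != len(mutations):
        raise ValueError("duplicate mutation ids in cohort")
    if {a.mutation_id for a in annotations} != set(by_id):
        raise ValueError("annotations and mutations are not aligned by id")

    class_counts = {c: sum(1 for m in mutations if m.mclass == c) for c in CLASSES}
    frameshift_del = sum(
        1 for a in annotations
        if by_id[a.mutation_id].mclass == "deletion" and a.frame_status == "frameshift"
    )
    denominators = dict(class_counts)
    if config.denominator == "frameshift":
        denominators["deletion"] = frameshift_del
    denominators["overall"] = len(mutations)

    # per-strategy distinct-mutation counts
    strategy_counts: dict[str, dict[str, int]] = {}
    has_cat: dict[str, set[str]] = {"single": set(), "double": set(), "multi": set()}
    for a in sorted(annotations, key=lambda a: a.mutation_id):
        mclass = by_id[a.mutation_id].mclass
        seen_labels: set[str] = set()
        for s in a.strategies:
            if s.category == "none":
                continue
            has_cat[s.category].add(a.mutation_id)
            if s.label in seen_labels:
                continue
            seen_labels.add(s.label)
            per_class = strategy_counts.setdefault(
                s.label, {c: 0 for c in CLASSES}
            )
            per_class[mclass] += 1

    rows = []
    for label, counts in strategy_counts.items():
        overall = sum(counts.values())
        percents = {
            c: _percent(counts[c], denominators[c]) if denominators[c] else 0.0
            for c in CLASSES
        }
        rows.append(StrategyRow(
            label=label, counts=counts, percents=percents,
            overall_count=overall,
            overall_percent=_percent(overall, denominators["overall"]),
        ))
    rows.sort(key=lambda r: (-r.overall_percent, r.label))

    class_rows = []
    for mclass in CLASSES + ("overall",):
        ids = {m.id for m in mutations} if mclass == "overall" else {
            m.id for m in mutations if m.mclass == mclass
        }
        denom = denominators[mclass if mclass != "overall" else "overall"]
        if denom == 0:
            class_rows.append(ClassRow(mclass, 0.0, 0.0, 0.0, None))
            continue
        n_single = len(ids & has_cat["single"])
        n_double = len(ids & has_cat["double"])
        n_union = len(ids & (has_cat["single"] | has_cat["double"]))
        if mclass == "duplication":
            multi = None
        else:
            multi = _percent(len(ids & has_cat["multi"]), denom)
        class_rows.append(ClassRow(
            mclass=mclass,
            single=_percent(n_single, denom),
            double=_percent(n_double, denom),
            single_or_double=_percent(n_union, denom),
            multi=multi,
        ))

    return CohortSummary(
        denominators=denominators,
        strategy_rows=tuple(rows),
        class_rows=tuple(class_rows),
    )


@dataclass(frozen=True)
class CompositionReport:
    """Class-mix and deletion frame-status breakdown of a mutation cohort."""

    total: int
    class_counts: Mapping[str, int]
    class_percents: Mapping[str, float]
    deletion_frameshift: int
    deletion_in_frame: int

    @property
    def deletion_in_frame_percent(self) -> float:
        n = self.class_counts["deletion"]
        return _percent(self.deletion_in_frame, n) if n else 0.0

    @property
    def deletion_frameshift_percent(self) -> float:
        n = self.class_counts["deletion"]
        return _percent(self.deletion_frameshift, n) if n else 0.0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"class": c, "count": self.class_counts[c],
             "percent": self.class_percents[c]}
            for c in CLASSES
        ])


def composition_report(
    mutations: Sequence[Mutation], t=None
) -> CompositionReport:
    """Counts and percentages per class, plus the deletion frame-status split.

    ``t`` (a TranscriptModel) is required only when the cohort contains
    deletions, to classify them as frameshift or in-frame.
    """
    if not mutations:
        raise ValueError("empty cohort")
    class_counts = {c: sum(1 for m in mutations if m.mclass == c) for c in CLASSES}
    total = len(mutations)
    fs = inf = 0
    for m in mutations:
        if m.mclass != "deletion":
            continue
        if t is None:
            raise ValueError("a TranscriptModel is required to frame-classify deletions")
        if t.segment_length(m.first_exon, m.last_exon) % 3:
            fs += 1
        else:
            inf += 1
    return CompositionReport(
        total=total,
        class_counts=class_counts,
        class_percents={c: _percent(n, total) for c, n in class_counts.items()},
        deletion_frameshift=fs,
        deletion_in_frame=inf,
    )


# --------------------------------------------------------------------------
# deterministic report I/O
# --------------------------------------------------------------------------

def write_report(summary: CohortSummary, path: str | Path, format: str = "tsv") -> Path:
    """Write a summary as TSV (two stacked tables) or JSON; byte-deterministic."""
    path = Path(path)
    if format == "json":
        path.write_text(
            json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    elif format == "tsv":
        lines = ["# strategy applicability",
                 "rank\tstrategy\toverall_count\toverall_percent\t"
                 + "\t".join(f"{c}_count\t{c}_percent" for c in CLASSES)]
        for i, r in enumerate(summary.strategy_rows, start=1):
            cells = [str(i), r.label, str(r.overall_count), _fmt(r.overall_percent)]
            for c in CLASSES:
                cells += [str(r.counts.get(c, 0)), _fmt(r.percents.get(c, 0.0))]
            lines.append("\t".join(cells))
        lines.append("")
        lines.append("# class applicability")
        lines.append("class\tsingle\tdouble\tsingle_or_double\tmulti")
        for r in summary.class_rows:
            lines.append("\t".join([
                r.mclass, _fmt(r.single), _fmt(r.double), _fmt(r.single_or_double),
                "-" if r.multi is None else _fmt(r.multi),
            ]))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def _fmt(percent: float) -> str:
    """One decimal place, but keep sub-0.1% values visible as 0.05-style."""
    if 0 < percent < 0.1:
        return f"{percent:.2f}"
    return f"{percent:.1f}"


def read_report(path: str | Path) -> CohortSummary:
    """Read back a JSON report written by :func:`write_report`."""
    return CohortSummary.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
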
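"""Seeded generator of DMD-like mutation cohorts.

Emulates the composition of a locus-specific dystrophin mutation database:
~60% large deletions, ~27% small lesions and ~13.5% large duplications among
DMD-labelled records, deletions concentrated in the exon 43–55 (weight 0.70)
and exon 2–22 (weight 0.21) hotspots, duplications dominated by exon 2, and
roughly a quarter of small lesions at splice sites.

``class_mix`` describes the *DMD-labelled* records.  Phenotype labels follow
the reading-frame rule (frameshift deletion/duplication → DMD, in-frame →
BMD; small lesions → DMD), so the generator draws deletions and duplications
until the per-class DMD quota is met and keeps the naturally arising in-frame
draws in the cohort as BMD records.  ``frame_rule_noise`` then flips each
label with the given probability, modelling the documented exceptions to the
rule.  Everything is deterministic for a fixed (seed, config, transcript).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mutations import Mutation, write_mutation_table
from .transcript import TranscriptModel

__all__ = ["GeneratorConfig", "generate_cohort", "write_cohort"]


@dataclass(frozen=True)
class Hotspot:
    first: int
    last: int
    weight: float


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunables of the synthetic cohort; defaults emulate the DMD population.

    ``n`` is the number of DMD-labelled records (before noise); the returned
    cohort also contains the in-frame BMD by-products of deletion/duplication
    sampling, so its total length is slightly larger than ``n``.
    """

    n: int = 1000
    seed: int = 0
    #: probabilities (deletion, small_lesion, duplication); renormalized
    class_mix: tuple[float, float, float] = (0.60, 0.27, 0.135)
    #: deletion start/containment regions; remaining weight is spread
    #: uniformly over exons outside every hotspot
    deletion_hotspots: tuple[Hotspot, ...] = (Hotspot(43, 55, 0.70), Hotspot(2, 22, 0.21))
    #: mean of the (truncated) geometric exon-span distribution for deletions
    #: and multi-exon duplications
    deletion_span_mean: float = 4.0
    #: probability a duplication is single-exon (52/232 in the emulated population)
    dup_single_prob: float = 52.0 / 232.0
    #: start-exon weight multiplier making exon 2 the modal duplication
    dup_exon2_weight: float = 12.0
    #: fraction of small lesions at splice sites, split evenly donor/acceptor
    splice_fraction: float = 0.25
    #: probability a phenotype label violates the reading-frame rule
    frame_rule_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if any(p < 0 for p in self.class_mix) or sum(self.class_mix) <= 0:
            raise ValueError("class_mix must be non-negative and sum > 0")
        for p, name in ((self.dup_single_prob, "dup_single_prob"),
                        (self.splice_fraction, "splice_fraction"),
                        (self.frame_rule_noise, "frame_rule_noise")):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        total = sum(h.weight for h in self.deletion_hotspots)
        if total > 1 or any(h.weight < 0 for h in self.deletion_hotspots):
            raise ValueError("hotspot weights must be non-negative and sum <= 1")
        if self.deletion_span_mean < 1:
            raise ValueError("deletion_span_mean must be >= 1")

    @property
    def normalized_mix(self) -> tuple[float, float, float]:
        total = sum(self.class_mix)
        return tuple(p / total for p in self.class_mix)


def _truncated_geometric(rng: np.random.Generator, mean: float, upper: int) -> int:
    span = int(rng.geometric(1.0 / mean))
    return min(span, upper)


def _deletion_regions(t: TranscriptModel, cfg: GeneratorConfig):
    """(first, last, weight) regions: hotspots plus the uniform remainder."""
    hot = [(h.first, h.last, h.weight) for h in cfg.deletion_hotspots]
    in_hotspot = set()
    for f, l, _ in hot:
        in_hotspot.update(range(f, l + 1))
    rest = [e for e in range(1, t.n_exons + 1) if e not in in_hotspot]
    remainder = 1.0 - sum(w for *_, w in hot)
    return hot, rest, remainder


def _draw_deletion(rng: np.random.Generator, t: TranscriptModel,
                   cfg: GeneratorConfig, regions) -> tuple[int, int]:
    hot, rest, remainder = regions
    weights = [w for *_, w in hot] + ([remainder] if rest else [])
    weights = np.asarray(weights) / np.sum(weights)
    which = rng.choice(len(weights), p=weights)
    if which < len(hot):
        first_lo, first_hi, _ = hot[which]
        start = int(rng.integers(first_lo, first_hi + 1))
        span = _truncated_geometric(rng, cfg.deletion_span_mean, first_hi - start + 1)
    else:
        start = int(rest[rng.integers(len(rest))])
        span = _truncated_geometric(rng, cfg.deletion_span_mean, t.n_exons - start + 1)
    return start, start + span - 1


def _draw_duplication(rng: np.random.Generator, t: TranscriptModel,
                      cfg: GeneratorConfig) -> tuple[int, int]:
    starts = np.arange(2, t.n_exons)  # duplications of exon 1 or the last exon excluded
    weights = np.ones(len(starts), dtype=float)
    weights[starts == 2] = cfg.dup_exon2_weight
    weights /= weights.sum()
    start = int(rng.choice(starts, p=weights))
    if rng.random() < cfg.dup_single_prob:
        return start, start
    span = 1 + _truncated_geometric(rng, cfg.deletion_span_mean, t.n_exons - 1 - start)
    return start, start + span - 1


def _draw_small_lesion(rng: np.random.Generator, t: TranscriptModel,
                       cfg: GeneratorConfig) -> tuple[int, str]:
    lengths = np.array([t.coding_length(e) for e in range(1, t.n_exons + 1)], dtype=float)
    exon = int(rng.choice(np.arange(1, t.n_exons + 1), p=lengths / lengths.sum()))
    if rng.random() >= cfg.splice_fraction:
        return exon, "intra"
    site = "donor" if rng.random() < 0.5 else "acceptor"
    # the last exon has no donor, the first no acceptor
    if site == "donor" and exon == t.n_exons:
        site = "acceptor"
    elif site == "acceptor" and exon == 1:
        site = "donor"
    return exon, site


def generate_cohort(t: TranscriptModel, cfg: GeneratorConfig) -> list[Mutation]:
    """Generate a synthetic cohort (see module docstring for the model)."""
    rng = np.random.default_rng(cfg.seed)
    mix = cfg.normalized_mix
    quotas = rng.multinomial(cfg.n, mix) if cfg.n else np.zeros(3, dtype=int)
    regions = _deletion_regions(t, cfg)

    drafts: list[tuple[str, dict, str]] = []  # (mclass, fields, rule_phenotype)

    def _fill_quota(quota: int, draw, mclass: str) -> None:
        produced, attempts = 0, 0
        limit = 1000 * (quota + 1)
        while produced < quota:
            attempts += 1
            if attempts > limit:
                raise RuntimeError(
                    f"could not draw {quota} frameshift {mclass}s on this "
                    "transcript; too few asymmetric exon runs"
                )
            first, last = draw()
            if t.segment_length(first, last) % 3:
                drafts.append((mclass, {"first": first, "last": last}, "DMD"))
                produced += 1
            else:
                drafts.append((mclass, {"first": first, "last": last}, "BMD"))

    _fill_quota(int(quotas[0]), lambda: _draw_deletion(rng, t, cfg, regions), "deletion")

    for _ in range(quotas[1]):  # small lesions are DMD-labelled by the rule
        exon, site = _draw_small_lesion(rng, t, cfg)
        drafts.append(("small_lesion", {"exon": exon, "site": site}, "DMD"))

    _fill_quota(int(quotas[2]), lambda: _draw_duplication(rng, t, cfg), "duplication")

    order = rng.permutation(len(drafts))
    width = max(5, len(str(max(len(drafts), 1))))
    mutations: list[Mutation] = []
    for i, j in enumerate(order, start=1):
        mclass, fields, phenotype = drafts[j]
        if cfg.frame_rule_noise and rng.random() < cfg.frame_rule_noise:
            phenotype = "BMD" if phenotype == "DMD" else "DMD"
        mid = f"syn{i:0{width}d}"
        if mclass == "deletion":
            m = Mutation.deletion(mid, fields["first"], fields["last"], phenotype)
        elif mclass == "duplication":
            m = Mutation.duplication(mid, fields["first"], fields["last"], phenotype)
        else:
            m = Mutation.small_lesion(mid, fields["exon"], fields["site"], phenotype)
        mutations.append(m)
    return mutations


def write_cohort(mutations: Sequence[Mutation], path) -> None:
    """Write a cohort in the mutation-table TSV schema."""
    write_mutation_table(mutations, path)
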
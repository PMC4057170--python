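"""Hierarchical genomic annotation of binding sites and matched random nulls.

Sites are assigned to exactly one of four functional categories in a fixed
priority order — promoter (TSS +/- 1 kb), exon, intron, intergenic — and,
independently of that hierarchy, flagged CGI or non-CGI by overlap with any
CpG island. This yields an 8-way partition of any site set. Two random
null generators are provided: length-matched (uniform placement, lengths
resampled from the observed set) and distribution-matched (length-matched
plus rejection sampling until the 8 category counts equal the observed
ones).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .core import (
    GenomeAnnotation,
    GenomicInterval,
    build_interval_index,
    query_overlaps,
)

PROMOTER_HALF_WINDOW = 1000
FEATURES = ("promoter", "exon", "intron", "intergenic")


class AnnotationCategory(NamedTuple):
    feature: str  # one of FEATURES
    cgi: bool

    def __str__(self) -> str:
        return f"{'CGI' if self.cgi else 'nonCGI'}-{self.feature}"


ALL_CATEGORIES: tuple[AnnotationCategory, ...] = tuple(
    AnnotationCategory(f, c) for f in FEATURES for c in (True, False)
)


@dataclass
class CategoryCounts:
    counts: dict[AnnotationCategory, int] = field(
        default_factory=lambda: {c: 0 for c in ALL_CATEGORIES}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, cat: AnnotationCategory) -> int:
        return self.counts.get(cat, 0)

    def add(self, cat: AnnotationCategory) -> None:
        self.counts[cat] = self.counts.get(cat, 0) + 1

    def fraction(self, cat: AnnotationCategory) -> float:
        return self.counts.get(cat, 0) / self.total if self.total else 0.0

    def feature_counts(self) -> dict[str, int]:
        out = {f: 0 for f in FEATURES}
        for cat, n in self.counts.items():
            out[cat.feature] += n
        return out


class AnnotationIndex:
    """Prebuilt interval trees over promoter windows, exons, transcript
    spans and CGIs for O(log n) classification."""

    def __init__(self, genome: GenomeAnnotation):
        promoters = []
        exons = []
        spans = []
        for g in genome.genes:
            start = max(0, g.tss - PROMOTER_HALF_WINDOW)
            promoters.append(
                GenomicInterval(g.chrom, start, g.tss + PROMOTER_HALF_WINDOW)
            )
            exons.extend(g.exons)
            spans.append(GenomicInterval(g.chrom, g.tx_start, g.tx_end))
        self.promoters = build_interval_index(promoters)
        self.exons = build_interval_index(exons)
        self.spans = build_interval_index(spans)
        self.cgis = build_interval_index(genome.cgis)


def classify_site(
    site: GenomicInterval, genome: GenomeAnnotation | AnnotationIndex
) -> AnnotationCategory:
    """Assign one of the 8 categories to a site.

    The feature is the first of promoter, exon, intron, intergenic whose
    definition the site overlaps by at least one base; the CGI flag is
    evaluated independently against all CpG islands.
    """
    index = genome if isinstance(genome, AnnotationIndex) else AnnotationIndex(genome)
    if query_overlaps(index.promoters, site):
        feature = "promoter"
    elif query_overlaps(index.exons, site):
        feature = "exon"
    elif query_overlaps(index.spans, site):
        feature = "intron"
    else:
        feature = "intergenic"
    cgi = bool(query_overlaps(index.cgis, site))
    return AnnotationCategory(feature, cgi)


def annotate_sites(
    sites: Iterable[GenomicInterval],
    genome: GenomeAnnotation | AnnotationIndex,
) -> CategoryCounts:
    """Category counts over a site set; every site is counted exactly once."""
    index = genome if isinstance(genome, AnnotationIndex) else AnnotationIndex(genome)
    counts = CategoryCounts()
    for site in sites:
        counts.add(classify_site(site, index))
    return counts


def _draw_random_intervals(
    n: int,
    lengths: np.ndarray,
    chrom_names: list[str],
    chrom_sizes: np.ndarray,
    rng: np.random.Generator,
    name_prefix: str = "random",
) -> list[GenomicInterval]:
    """n random intervals: lengths resampled from ``lengths``, chromosome
    chosen proportional to its size, start uniform so the interval fits."""
    weights = chrom_sizes / chrom_sizes.sum()
    out: list[GenomicInterval] = []
    while len(out) < n:
        length = int(rng.choice(lengths))
        ci = int(rng.choice(len(chrom_names), p=weights))
        size = int(chrom_sizes[ci])
        if length >= size:  # cannot fit: re-draw
            continue
        start = int(rng.integers(0, size - length + 1))
        out.append(
            GenomicInterval(
                chrom_names[ci], start, start + length, name=f"{name_prefix}_{len(out)}"
            )
        )
    return out


def sample_random_lengthmatched(
    sites: Sequence[GenomicInterval],
    genome: GenomeAnnotation,
    seed: int,
) -> list[GenomicInterval]:
    """An equal number of random regions with lengths resampled from the
    observed site-length distribution, placed uniformly over the genome."""
    if not sites:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(seed)
    lengths = np.array([s.length for s in sites], dtype=np.int64)
    chrom_names = sorted(genome.chrom_sizes)
    chrom_sizes = np.array([genome.chrom_sizes[c] for c in chrom_names], dtype=np.int64)
    return _draw_random_intervals(len(sites), lengths, chrom_names, chrom_sizes, rng)


def sample_random_distributionmatched(
    sites: Sequence[GenomicInterval],
    genome: GenomeAnnotation,
    seed: int,
    max_attempts_per_category: int = 10**6,
) -> list[GenomicInterval]:
    """Random regions matched for the genomic distribution of the sites.

    Rejection-samples length-matched random intervals until, per category,
    the random counts equal the observed counts. Raises when a category
    quota cannot be filled within the attempt budget (e.g. CGI categories
    on a genome without CGIs).
    """
    if not sites:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(seed)
    index = AnnotationIndex(genome)
    target = annotate_sites(sites, index)
    quotas = {c: n for c, n in target.counts.items() if n > 0}
    lengths = np.array([s.length for s in sites], dtype=np.int64)
    chrom_names = sorted(genome.chrom_sizes)
    chrom_sizes = np.array([genome.chrom_sizes[c] for c in chrom_names], dtype=np.int64)
    attempts = {c: 0 for c in quotas}
    out: list[GenomicInterval] = []
    budget = max_attempts_per_category * len(quotas)
    total_attempts = 0
    batch = max(64, len(sites))
    while quotas and total_attempts < budget:
        for cand in _draw_random_intervals(
            batch, lengths, chrom_names, chrom_sizes, rng, "matched"
        ):
            total_attempts += 1
            cat = classify_site(cand, index)
            if quotas.get(cat, 0) > 0:
                out.append(cand)
                quotas[cat] -= 1
                if quotas[cat] == 0:
                    del quotas[cat]
                    if not quotas:
                        break
        for c in quotas:
            attempts[c] += batch
            if attempts[c] > max_attempts_per_category:
                raise RuntimeError(
                    f"cannot fill random quota for category {c}: "
                    f"{quotas[c]} sites still missing after "
                    f"{attempts[c]} attempts"
                )
    if quotas:
        missing = ", ".join(str(c) for c in quotas)
        raise RuntimeError(f"cannot fill random quota for category: {missing}")
    return out


def fold_over_random(
    obs: CategoryCounts, rand: CategoryCounts
) -> dict[AnnotationCategory, float]:
    """Per-category share of observed sites over share of random regions.

    fold(c) = (obs(c)/obs_total) / (rand(c)/rand_total). Categories with
    rand(c)=0 but obs(c)>0 map to +inf; 0/0 maps to NaN (undefined).
    """
    if obs.total == 0:
        raise ValueError("empty observed set")
    if rand.total == 0:
        raise ValueError("empty random set")
    folds: dict[AnnotationCategory, float] = {}
    for cat in ALL_CATEGORIES:
        o = obs[cat] / obs.total
        r = rand[cat] / rand.total
        if r > 0:
            folds[cat] = o / r
        elif o > 0:
            folds[cat] = math.inf
        else:
            folds[cat] = math.nan
    return folds
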
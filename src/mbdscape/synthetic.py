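"""Synthetic genome, methylome, ChIP tag tracks, expression and cohort with
planted ground truth.

The generator emulates the data structures of a genome-wide MBD2
binding-site study: a toy genome of non-overlapping genes with CpG islands
at a configurable fraction of promoters and internal exons; a bimodal CGI
methylome over a mid-methylated background; ChIP tag tracks in which
binding-site enrichment is coupled to methylation (most planted peaks sit
on hypermethylated CGIs); a "cluster 4" subset of genes whose promoter CGI
extends ~1.4 kb into the gene body, carries the MBD2 site ~1 kb downstream
of the TSS and active-mark signal at the TSS, and is expressed at low to
medium levels; and a tumor/normal cohort in which tumor samples are shifted
upward at the planted binding sites only.

Every generator draws from an independent random stream fanned out from one
global seed, so regenerating one output never perturbs another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import GROUP_NORMAL, GROUP_TUMOR, CohortMatrix
from .core import (
    CpGTable,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    TagTrack,
)
from .methylation import interval_methylation

logger = logging.getLogger(__name__)

# planted peak classes
CLASS_HYPER_PROMOTER = "hypermeth-CGI-promoter"
CLASS_CGI_EXON = "CGI-exon"
CLASS_BACKGROUND = "background"
CLASS_CLUSTER4 = "cluster4"

#: ChIP tracks emitted by generate_chip_tags. The first is the input
#: control; the last two are repressive marks with no planted signal and
#: are display-only in clustering.
TRACK_NAMES = (
    "input",
    "MBD2",
    "Pol2",
    "H3K4me3",
    "H2A.Zac",
    "H3K27ac",
    "H3K36me3",
    "P300",
    "H3K27me3",
    "H3K9me3",
)

ACTIVE_MARKS = ("Pol2", "H3K4me3", "H2A.Zac", "H3K27ac", "P300")

# independent random-stream ids fanned out from the global seed
_STREAM_GENOME = 0
_STREAM_METHYLOME = 1
_STREAM_SITES = 2
_STREAM_EXPRESSION = 3
_STREAM_COHORT = 4
_STREAM_COHORT_RANDOM = 5
_STREAM_TRACK_BASE = 100  # + track index


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic dataset; defaults are the shipped
    desk-scale study conditions."""

    seed: int = 42
    # genome shape
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 300
    cgi_promoter_fraction: float = 0.8
    cgi_exon_fraction: float = 0.25
    cgi_hyper_fraction: float = 0.6
    # methylome: Beta(alpha, beta) parameter pairs
    meth_background_dist: tuple[float, float] = (5.0, 5.0)
    meth_cgi_unmeth_dist: tuple[float, float] = (1.0, 20.0)
    meth_cgi_hyper_dist: tuple[float, float] = (20.0, 2.0)
    cpg_cgi_spacing: float = 10.0  # mean bp between CpGs inside CGIs
    cpg_background_spacing: float = 100.0
    coverage_mean: float = 30.0
    # binding sites
    n_peaks: int = 150
    frac_peaks_hypermeth: float = 0.9
    frac_hyper_exon: float = 0.1  # share of non-cluster4 hyper peaks at exon CGIs
    n_cluster4: int = 40
    cluster4_offset_mean: float = 1000.0
    cluster4_offset_sd: float = 150.0
    # ChIP tags
    tag_background_rate: float = 0.01  # tags per bp per track
    peak_fold: float = 15.0
    peak_kernel_width: int = 400  # triangular kernel support, bp
    # MBD2 amplitude multiple per peak class relative to peak_fold; CGI-exon
    # and background sites bind weaker than CGI-promoter sites
    fold_mult_exon: float = 0.5
    fold_mult_background: float = 0.2
    active_kernel_width: int = 1500  # active marks span broad promoter domains
    # genome-wide methyl-CpG reader component of the MBD2 track: expected
    # number of extra tags per CpG equals this coupling times the CpG's
    # methylation fraction, so enrichment tracks methylation density even
    # away from called peaks
    mbd2_meth_coupling: float = 1.0
    # cohort
    cohort_n_tumor: int = 100
    cohort_n_normal: int = 30
    cohort_effect_delta: float = 0.05
    cohort_noise_sd: float = 0.02

    def validate(self) -> None:
        fracs = {
            "cgi_promoter_fraction": self.cgi_promoter_fraction,
            "cgi_exon_fraction": self.cgi_exon_fraction,
            "cgi_hyper_fraction": self.cgi_hyper_fraction,
            "frac_peaks_hypermeth": self.frac_peaks_hypermeth,
            "frac_hyper_exon": self.frac_hyper_exon,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.tag_background_rate <= 0:
            raise ValueError("tag_background_rate must be > 0")
        if self.cohort_effect_delta < 0:
            raise ValueError("cohort_effect_delta must be >= 0")
        if self.n_cluster4 > self.n_peaks:
            raise ValueError("n_cluster4 cannot exceed n_peaks")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        for key in ("meth_background_dist", "meth_cgi_unmeth_dist",
                    "meth_cgi_hyper_dist"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class SyntheticTruth:
    """Planted ground truth: the oracle for recovery tests."""

    peaks: list[GenomicInterval]
    peak_classes: list[str]  # aligned with peaks
    cluster4_genes: list[str]
    cluster4_offsets: dict[str, int]  # gene id -> planted TSS offset (bp)
    expression_band: tuple[float, float] | None = None
    expression_tiers: dict[str, str] | None = None
    cohort_group_means: dict[str, float] | None = None

    def peaks_of_class(self, label: str) -> list[GenomicInterval]:
        return [p for p, c in zip(self.peaks, self.peak_classes) if c == label]


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

_GENE_MIN, _GENE_MAX = 2_000, 20_000
_MIN_INTERGENIC_GAP = 3_000  # keeps CGIs clear of neighbouring promoter windows
_CHROM_MARGIN = 20_000
_MIN_SEGMENT = 50  # smallest exon/intron
_CGI_MIN, _CGI_MAX = 300, 1_500
# cluster-4 promoter CGI: asymmetric around the TSS, extending into the
# gene body so the downstream MBD2 site still sits on methylated CGI
_C4_CGI_UP, _C4_CGI_DOWN = 100, 1_400


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def _make_exons(
    chrom: str, strand: str, start: int, length: int, rng: np.random.Generator
) -> tuple[GenomicInterval, ...]:
    n_ex = int(rng.integers(2, 9))
    n_seg = 2 * n_ex - 1  # exons and introns alternate, exon first and last
    spare = length - n_seg * _MIN_SEGMENT
    w = rng.random(n_seg)
    extra = np.floor(w / w.sum() * spare).astype(int)
    seg = _MIN_SEGMENT + extra
    seg[-1] += length - int(seg.sum())  # absorb rounding in the last exon
    exons = []
    pos = start
    for i, s in enumerate(seg):
        if i % 2 == 0:
            exons.append(GenomicInterval(chrom, pos, pos + int(s), strand))
        pos += int(s)
    return tuple(exons)


def generate_genome(config: SyntheticConfig) -> GenomeAnnotation:
    """Toy genome: non-overlapping genes on alternating strands with CpG
    islands at a configured fraction of promoters and internal exons.

    Cluster-4 candidate genes (``n_cluster4`` of the CGI-promoter genes)
    receive an asymmetric, always-hypermethylated promoter CGI that runs
    ~1.4 kb into the gene body; their CGIs are named
    ``CGI:promoter_c4:<gene>`` so downstream planting can find them.
    Raises when the requested genes cannot be packed into the genome.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_GENOME)
    chrom_sizes = {
        _chrom_name(i): config.chrom_length for i in range(config.n_chroms)
    }
    # distribute genes over chromosomes as evenly as possible
    per_chrom = [
        config.n_genes // config.n_chroms
        + (1 if i < config.n_genes % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    genes: list[GeneModel] = []
    gene_idx = 0
    for ci, n_here in enumerate(per_chrom):
        chrom = _chrom_name(ci)
        usable = config.chrom_length - 2 * _CHROM_MARGIN
        lengths = rng.integers(_GENE_MIN, _GENE_MAX + 1, size=n_here)
        needed = int(lengths.sum()) + (n_here + 1) * _MIN_INTERGENIC_GAP
        if needed > usable:
            raise ValueError(
                f"infeasible packing: {n_here} genes need {needed} bp "
                f"on {chrom} but only {usable} bp are usable"
            )
        free = usable - int(lengths.sum()) - (n_here + 1) * _MIN_INTERGENIC_GAP
        w = rng.random(n_here + 1)
        extra_gaps = np.floor(w / w.sum() * free).astype(int)
        pos = _CHROM_MARGIN
        for gi in range(n_here):
            pos += _MIN_INTERGENIC_GAP + int(extra_gaps[gi])
            strand = "+" if gene_idx % 2 == 0 else "-"
            length = int(lengths[gi])
            gene_id = f"gene{gene_idx:04d}"
            exons = _make_exons(chrom, strand, pos, length, rng)
            genes.append(
                GeneModel(gene_id, chrom, strand, pos, pos + length, exons)
            )
            pos += length
            gene_idx += 1

    # promoter CGIs: Bernoulli per gene; cluster-4 genes drawn among them
    prom_mask = rng.random(config.n_genes) < config.cgi_promoter_fraction
    prom_gene_idx = np.flatnonzero(prom_mask)
    if len(prom_gene_idx) < config.n_cluster4:
        raise ValueError(
            f"infeasible: {len(prom_gene_idx)} CGI-promoter genes but "
            f"n_cluster4={config.n_cluster4}"
        )
    c4_idx = set(
        rng.choice(prom_gene_idx, size=config.n_cluster4, replace=False).tolist()
    )
    cgis: list[GenomicInterval] = []
    hyper: list[bool] = []
    for i in prom_gene_idx:
        g = genes[i]
        if i in c4_idx:
            if g.strand == "+":
                start, end = g.tss - _C4_CGI_UP, g.tss + _C4_CGI_DOWN
            else:
                start, end = g.tss - _C4_CGI_DOWN + 1, g.tss + _C4_CGI_UP + 1
            cgis.append(
                GenomicInterval(g.chrom, start, end, name=f"CGI:promoter_c4:{g.gene_id}")
            )
            hyper.append(True)
        else:
            length = int(rng.integers(_CGI_MIN, _CGI_MAX + 1))
            jitter = int(rng.integers(-100, 101))
            start = max(0, g.tss - length // 2 + jitter)
            cgis.append(
                GenomicInterval(
                    g.chrom, start, start + length, name=f"CGI:promoter:{g.gene_id}"
                )
            )
            hyper.append(bool(rng.random() < config.cgi_hyper_fraction))

    # exon CGIs over internal exons, kept clear of the own promoter window
    exon_mask = rng.random(config.n_genes) < config.cgi_exon_fraction
    n_skipped = 0
    for i in np.flatnonzero(exon_mask):
        g = genes[i]
        internal = g.exons[1:-1]
        if not internal:
            n_skipped += 1
            continue
        ex = internal[int(rng.integers(0, len(internal)))]
        length = int(rng.integers(_CGI_MIN, _CGI_MAX + 1))
        center = ex.center
        start = max(g.tx_start, center - length // 2)
        end = min(g.tx_end, start + length)
        if end - start < _CGI_MIN:
            n_skipped += 1
            continue
        # reject CGIs encroaching on the gene's own promoter window (or on
        # the extended cluster-4 promoter CGI, which reaches ~1.4 kb in)
        reach = 1500 if i in c4_idx else 1000
        win_lo, win_hi = g.tss - reach, g.tss + reach
        if start < win_hi and end > win_lo:
            n_skipped += 1
            continue
        cgis.append(
            GenomicInterval(g.chrom, start, end, name=f"CGI:exon:{g.gene_id}")
        )
        hyper.append(bool(rng.random() < config.cgi_hyper_fraction))
    if n_skipped:
        logger.info("generate_genome: skipped %d exon-CGI placements", n_skipped)

    return GenomeAnnotation(chrom_sizes, genes, cgis, cgi_hyper=hyper)


def cluster4_gene_ids(genome: GenomeAnnotation) -> list[str]:
    """Gene ids carrying a cluster-4 promoter CGI, in CGI order."""
    return [
        c.name.split(":", 2)[2]
        for c in genome.cgis
        if c.name.startswith("CGI:promoter_c4:")
    ]


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


def _poisson_positions(
    rng: np.random.Generator, length: int, mean_spacing: float, offset: int = 0
) -> np.ndarray:
    """Integer positions from a Poisson point process with the given mean
    spacing (gaps >= 1 bp so positions are unique)."""
    n_expect = int(length / mean_spacing * 1.5) + 20
    gaps = np.maximum(1, np.round(rng.exponential(mean_spacing, n_expect))).astype(
        np.int64
    )
    pos = np.cumsum(gaps) - 1
    while pos[-1] < length:  # rare under-draw
        more = np.maximum(
            1, np.round(rng.exponential(mean_spacing, n_expect))
        ).astype(np.int64)
        pos = np.concatenate([pos, pos[-1] + np.cumsum(more)])
    return pos[pos < length] + offset


def generate_methylome(genome: GenomeAnnotation, config: SyntheticConfig) -> CpGTable:
    """Base-resolution methylome: dense CpGs inside CGIs (~1 per
    ``cpg_cgi_spacing`` bp) over a sparse background, with methylation drawn
    from the hypermethylated-CGI, unmethylated-CGI or background Beta
    distribution and coverage Poisson(``coverage_mean``)."""
    config.validate()
    rng = _rng(config.seed, _STREAM_METHYLOME)
    hyper_flags = genome.cgi_hyper or [False] * len(genome.cgis)
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, size in genome.chrom_sizes.items():
        cgi_list = [
            (c, h) for c, h in zip(genome.cgis, hyper_flags) if c.chrom == chrom
        ]
        cgi_list.sort(key=lambda t: t[0].start)
        starts = np.array([c.start for c, _ in cgi_list], dtype=np.int64)
        ends = np.array([c.end for c, _ in cgi_list], dtype=np.int64)
        flags = np.array([h for _, h in cgi_list], dtype=bool)

        bg = _poisson_positions(rng, size, config.cpg_background_spacing)
        if len(starts):
            # position is inside CGI i when starts[i] <= pos < ends[i]
            idx = np.searchsorted(ends, bg, side="right")
            safe = np.minimum(idx, len(starts) - 1)
            in_cgi = (idx < len(starts)) & (bg >= starts[safe])
            bg = bg[~in_cgi]
        cgi_pos_parts = []
        cgi_hyper_parts = []
        for (c, h) in cgi_list:
            p = _poisson_positions(rng, c.length, config.cpg_cgi_spacing, c.start)
            cgi_pos_parts.append(p)
            cgi_hyper_parts.append(np.full(len(p), h, dtype=bool))
        if cgi_pos_parts:
            cgi_pos = np.concatenate(cgi_pos_parts)
            cgi_h = np.concatenate(cgi_hyper_parts)
        else:
            cgi_pos = np.empty(0, dtype=np.int64)
            cgi_h = np.empty(0, dtype=bool)

        pos = np.concatenate([bg, cgi_pos])
        kind = np.concatenate(
            [np.zeros(len(bg), dtype=np.int8),
             np.where(cgi_h, np.int8(2), np.int8(1))]
        )
        order = np.argsort(pos, kind="stable")
        pos, kind = pos[order], kind[order]
        uniq, first = np.unique(pos, return_index=True)
        pos, kind = uniq, kind[first]

        meth = np.empty(len(pos), dtype=np.float64)
        for code, (a, b) in (
            (0, config.meth_background_dist),
            (1, config.meth_cgi_unmeth_dist),
            (2, config.meth_cgi_hyper_dist),
        ):
            mask = kind == code
            meth[mask] = rng.beta(a, b, int(mask.sum()))
        cov = rng.poisson(config.coverage_mean, len(pos)).astype(np.int64)
        data[chrom] = (pos, meth, cov)
    return CpGTable.from_arrays(data)


# ---------------------------------------------------------------------------
# binding sites and ChIP tags
# ---------------------------------------------------------------------------

_PEAK_LEN_MEAN, _PEAK_LEN_SD = 600.0, 100.0
_PEAK_LEN_MIN, _PEAK_LEN_MAX = 300, 1000


def _peak_length(rng: np.random.Generator) -> int:
    return int(np.clip(round(rng.normal(_PEAK_LEN_MEAN, _PEAK_LEN_SD)),
                       _PEAK_LEN_MIN, _PEAK_LEN_MAX))


def plant_sites(genome: GenomeAnnotation, config: SyntheticConfig) -> SyntheticTruth:
    """Choose the planted binding-site intervals and their class labels.

    Classes: ``cluster4`` (at TSS + Normal(offset) into the gene body of the
    cluster-4 genes, strand-aware), ``hypermeth-CGI-promoter`` and
    ``CGI-exon`` (centred on hypermethylated promoter/exon CGIs), and
    ``background`` (uniform placement away from any CGI).
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_SITES)
    hyper_flags = genome.cgi_hyper or [False] * len(genome.cgis)
    genes_by_id = {g.gene_id: g for g in genome.genes}

    c4_cgis = [c for c in genome.cgis if c.name.startswith("CGI:promoter_c4:")]
    prom_hyper = [
        c for c, h in zip(genome.cgis, hyper_flags)
        if h and c.name.startswith("CGI:promoter:")
    ]
    exon_hyper = [
        c for c, h in zip(genome.cgis, hyper_flags)
        if h and c.name.startswith("CGI:exon:")
    ]

    n_hyper = round(config.frac_peaks_hypermeth * config.n_peaks)
    n_c4 = min(config.n_cluster4, n_hyper, len(c4_cgis))
    n_rest = n_hyper - n_c4
    n_exon = min(round(config.frac_hyper_exon * n_rest), len(exon_hyper))
    n_prom = n_rest - n_exon
    n_bg = config.n_peaks - n_hyper
    if n_prom > len(prom_hyper):
        raise ValueError(
            f"infeasible: need {n_prom} hypermethylated promoter CGIs, "
            f"only {len(prom_hyper)} available"
        )

    peaks: list[GenomicInterval] = []
    classes: list[str] = []
    cluster4_genes: list[str] = []
    cluster4_offsets: dict[str, int] = {}

    for c in (c4_cgis[i] for i in rng.permutation(len(c4_cgis))[:n_c4]):
        gene = genes_by_id[c.name.split(":", 2)[2]]
        offset = max(200, int(round(rng.normal(
            config.cluster4_offset_mean, config.cluster4_offset_sd))))
        center = gene.tss + offset if gene.strand == "+" else gene.tss - offset
        half = _peak_length(rng) // 2
        peaks.append(GenomicInterval(
            gene.chrom, center - half, center + half,
            name=f"peak_c4_{len(peaks)}"))
        classes.append(CLASS_CLUSTER4)
        cluster4_genes.append(gene.gene_id)
        cluster4_offsets[gene.gene_id] = offset

    for c in (prom_hyper[i] for i in rng.permutation(len(prom_hyper))[:n_prom]):
        center = c.center + int(rng.integers(-50, 51))
        half = _peak_length(rng) // 2
        peaks.append(GenomicInterval(
            c.chrom, max(0, center - half), center + half,
            name=f"peak_prom_{len(peaks)}"))
        classes.append(CLASS_HYPER_PROMOTER)

    for c in (exon_hyper[i] for i in rng.permutation(len(exon_hyper))[:n_exon]):
        center = c.center + int(rng.integers(-50, 51))
        half = _peak_length(rng) // 2
        peaks.append(GenomicInterval(
            c.chrom, max(0, center - half), center + half,
            name=f"peak_exon_{len(peaks)}"))
        classes.append(CLASS_CGI_EXON)

    # background peaks: anywhere not overlapping a CGI
    chrom_names = sorted(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chrom_names], dtype=float)
    cgi_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in chrom_names:
        cs = sorted(
            (c for c in genome.cgis if c.chrom == chrom),
            key=lambda c: (c.start, c.end),
        )
        cgi_by_chrom[chrom] = (
            np.array([c.start for c in cs], dtype=np.int64),
            np.array([c.end for c in cs], dtype=np.int64),
        )
    placed = 0
    attempts = 0
    while placed < n_bg:
        attempts += 1
        if attempts > 10**6:
            raise RuntimeError("cannot place background peaks away from CGIs")
        ci = int(rng.choice(len(chrom_names), p=sizes / sizes.sum()))
        chrom = chrom_names[ci]
        half = _peak_length(rng) // 2
        center = int(rng.integers(half, int(sizes[ci]) - half))
        starts, ends = cgi_by_chrom[chrom]
        i = np.searchsorted(ends, center - half, side="right")
        if i < len(starts) and starts[i] < center + half:
            continue
        peaks.append(GenomicInterval(
            chrom, center - half, center + half, name=f"peak_bg_{len(peaks)}"))
        classes.append(CLASS_BACKGROUND)
        placed += 1

    return SyntheticTruth(peaks, classes, cluster4_genes, cluster4_offsets)


def _background_positions(
    rng: np.random.Generator, chrom_sizes: dict[str, int], rate: float
) -> dict[str, np.ndarray]:
    out = {}
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n = rng.poisson(rate * size)
        out[chrom] = rng.integers(0, size, n).astype(np.int64)
    return out


def _kernel_tags(
    rng: np.random.Generator,
    centers_by_chrom: dict[str, list[int]],
    chrom_sizes: dict[str, int],
    rate: float,
    fold: float,
    width: int,
) -> dict[str, np.ndarray]:
    """Extra tags under a triangular kernel of the given support width at
    each centre; expected count per centre = rate * fold * width / 2."""
    half = width / 2
    lam = rate * fold * half
    out: dict[str, list[np.ndarray]] = {}
    for chrom, centers in centers_by_chrom.items():
        parts = []
        for center in centers:
            n = rng.poisson(lam)
            if n == 0:
                continue
            offs = rng.triangular(-half, 0.0, half, n)
            pos = np.clip(
                np.round(center + offs), 0, chrom_sizes[chrom] - 1
            ).astype(np.int64)
            parts.append(pos)
        out[chrom] = parts  # type: ignore[assignment]
    return {
        c: (np.concatenate(p) if p else np.empty(0, dtype=np.int64))
        for c, p in out.items()
    }


#: gene-body H3K36me3 enrichment multiple by expression tier
K36_TIER_FOLD = {"high": 3.0, "medium": 1.5, "low": 0.5}


def generate_chip_tags(
    genome: GenomeAnnotation,
    methylome: CpGTable,
    config: SyntheticConfig,
    truth: SyntheticTruth | None = None,
    expression_tiers: Mapping[str, str] | None = None,
) -> tuple[dict[str, TagTrack], SyntheticTruth]:
    """ChIP and input tag tracks with planted signal.

    input, H3K27me3 and H3K9me3 are homogeneous Poisson background. MBD2
    adds a triangular kernel at every planted peak centre. Active marks add
    TSS-centred kernels at cluster-4 genes only. H3K36me3 adds uniform
    gene-body tags scaled by the gene's expression tier. Each track draws
    from its own random stream, so tracks never perturb one another.
    """
    config.validate()
    if truth is None:
        truth = plant_sites(genome, config)
    if expression_tiers is None:
        from .stratification import tertile_bins

        rpkm = generate_expression(genome, config)
        expression_tiers = tertile_bins(rpkm).to_dict()
        truth.expression_tiers = dict(expression_tiers)

    chrom_sizes = genome.chrom_sizes
    rate = config.tag_background_rate
    width = config.peak_kernel_width
    genes_by_id = {g.gene_id: g for g in genome.genes}

    class_fold = {
        CLASS_CLUSTER4: 1.0,
        CLASS_HYPER_PROMOTER: 1.0,
        CLASS_CGI_EXON: config.fold_mult_exon,
        CLASS_BACKGROUND: config.fold_mult_background,
    }
    centers_by_class: dict[str, dict[str, list[int]]] = {
        cls: {c: [] for c in chrom_sizes} for cls in class_fold
    }
    for p, pc in zip(truth.peaks, truth.peak_classes):
        centers_by_class[pc][p.chrom].append(p.center)
    c4_tss: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    for gid in truth.cluster4_genes:
        g = genes_by_id[gid]
        c4_tss[g.chrom].append(g.tss)

    tracks: dict[str, TagTrack] = {}
    for ti, name in enumerate(TRACK_NAMES):
        rng = _rng(config.seed, _STREAM_TRACK_BASE + ti)
        pos = _background_positions(rng, chrom_sizes, rate)
        extra: dict[str, np.ndarray] = {}
        if name == "MBD2":
            parts_by_chrom: dict[str, list[np.ndarray]] = {c: [] for c in chrom_sizes}
            for cls in (CLASS_CLUSTER4, CLASS_HYPER_PROMOTER,
                        CLASS_CGI_EXON, CLASS_BACKGROUND):
                cls_extra = _kernel_tags(
                    rng, centers_by_class[cls], chrom_sizes, rate,
                    config.peak_fold * class_fold[cls], width,
                )
                for c, arr in cls_extra.items():
                    parts_by_chrom[c].append(arr)
            if config.mbd2_meth_coupling > 0:
                for chrom, size in chrom_sizes.items():
                    cpg_pos, cpg_meth, _ = methylome.fetch(chrom, 0, size)
                    n_per_cpg = rng.poisson(config.mbd2_meth_coupling * cpg_meth)
                    parts_by_chrom[chrom].append(np.repeat(cpg_pos, n_per_cpg))
            extra = {
                c: (np.concatenate(p) if p else np.empty(0, dtype=np.int64))
                for c, p in parts_by_chrom.items()
            }
        elif name in ACTIVE_MARKS:
            extra = _kernel_tags(
                rng, c4_tss, chrom_sizes, rate, config.peak_fold,
                config.active_kernel_width,
            )
        elif name == "H3K36me3":
            parts: dict[str, list[np.ndarray]] = {c: [] for c in chrom_sizes}
            for g in genome.genes:
                tier = expression_tiers.get(g.gene_id)
                if tier is None:
                    continue
                lam = rate * K36_TIER_FOLD[tier] * g.length
                n = rng.poisson(lam)
                if n:
                    parts[g.chrom].append(
                        rng.integers(g.tx_start, g.tx_end, n).astype(np.int64)
                    )
            extra = {
                c: (np.concatenate(p) if p else np.empty(0, dtype=np.int64))
                for c, p in parts.items()
            }
        merged = {
            c: np.concatenate([pos[c], extra.get(c, np.empty(0, dtype=np.int64))])
            for c in pos
        }
        strands = {
            c: np.where(rng.random(len(v)) < 0.5, "+", "-").astype("U1")
            for c, v in merged.items()
        }
        tracks[name] = TagTrack.from_arrays(name, merged, strands)
    return tracks, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

_EXPR_BAND = (0.20, 0.60)  # cluster-4 genes drawn between these quantiles
_LOGNORM_MEAN, _LOGNORM_SIGMA = 1.0, 1.2


def generate_expression(
    genome: GenomeAnnotation, config: SyntheticConfig
) -> pd.Series:
    """Per-gene RPKM: log-normal across the genome, with cluster-4 genes
    re-drawn uniformly between the global 20th and 60th percentile (the
    low-to-medium expression range)."""
    config.validate()
    rng = _rng(config.seed, _STREAM_EXPRESSION)
    gene_ids = [g.gene_id for g in genome.genes]
    rpkm = rng.lognormal(_LOGNORM_MEAN, _LOGNORM_SIGMA, len(gene_ids))
    lo, hi = np.quantile(rpkm, _EXPR_BAND)
    series = pd.Series(rpkm, index=gene_ids, name="rpkm")
    for gid in cluster4_gene_ids(genome):
        series[gid] = rng.uniform(lo, hi)
    series.attrs["cluster4_band"] = (float(lo), float(hi))
    return series


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def generate_cohort(
    sites: list[GenomicInterval],
    methylome: CpGTable,
    config: SyntheticConfig,
    apply_effect: bool = True,
    stream: int = _STREAM_COHORT,
) -> CohortMatrix:
    """Tumor/normal beta-value matrix at the given sites.

    The base value per site is its methylome level; normal samples add
    Gaussian noise, tumor samples additionally shift by
    ``cohort_effect_delta`` when ``apply_effect`` is set; all values are
    clipped to [0,1]. Sites without CpG coverage are dropped and counted.
    """
    config.validate()
    rng = _rng(config.seed, stream)
    base: list[float] = []
    kept: list[GenomicInterval] = []
    n_dropped = 0
    for s in sites:
        level = interval_methylation(s, methylome, min_coverage=1)
        if level is None:
            n_dropped += 1
        else:
            base.append(level)
            kept.append(s)
    if n_dropped:
        logger.info("generate_cohort: dropped %d sites without CpG coverage",
                    n_dropped)
    if not kept:
        raise ValueError("no site has CpG coverage")
    b = np.array(base)
    n_t, n_n = config.cohort_n_tumor, config.cohort_n_normal
    delta = config.cohort_effect_delta if apply_effect else 0.0
    tumor = b[None, :] + delta + rng.normal(0, config.cohort_noise_sd, (n_t, len(b)))
    normal = b[None, :] + rng.normal(0, config.cohort_noise_sd, (n_n, len(b)))
    values = np.clip(np.vstack([tumor, normal]), 0.0, 1.0)
    sample_ids = [f"T{i:03d}" for i in range(n_t)] + [f"N{i:03d}" for i in range(n_n)]
    groups = [GROUP_TUMOR] * n_t + [GROUP_NORMAL] * n_n
    return CohortMatrix(sample_ids, groups, kept, values)


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: GenomeAnnotation
    methylome: CpGTable
    tracks: dict[str, TagTrack]
    truth: SyntheticTruth
    expression: pd.Series
    cohort: CohortMatrix
    cohort_random: CohortMatrix
    random_sites: list[GenomicInterval] = field(default_factory=list)


def simulate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate the full dataset: genome, methylome, tracks, expression,
    tumor/normal cohort at the planted sites and a distribution-matched
    random-site cohort with no planted effect."""
    from .annotation import sample_random_distributionmatched

    config = config or SyntheticConfig()
    config.validate()
    genome = generate_genome(config)
    methylome = generate_methylome(genome, config)
    truth = plant_sites(genome, config)
    expression = generate_expression(genome, config)
    from .stratification import tertile_bins

    tiers = tertile_bins(expression).to_dict()
    truth.expression_tiers = tiers
    truth.expression_band = expression.attrs.get("cluster4_band")
    tracks, truth = generate_chip_tags(
        genome, methylome, config, truth=truth, expression_tiers=tiers
    )
    random_seed = (config.seed * 1_000_003 + 17) % (2**31)
    random_sites = sample_random_distributionmatched(
        truth.peaks, genome, seed=random_seed
    )
    cohort = generate_cohort(truth.peaks, methylome, config, apply_effect=True)
    cohort_random = generate_cohort(
        random_sites, methylome, config, apply_effect=False,
        stream=_STREAM_COHORT_RANDOM,
    )
    truth.cohort_group_means = {
        GROUP_TUMOR: float(np.nanmean(
            cohort.values[cohort.sample_mask(GROUP_TUMOR)])),
        GROUP_NORMAL: float(np.nanmean(
            cohort.values[cohort.sample_mask(GROUP_NORMAL)])),
    }
    return SyntheticDataset(
        config, genome, methylome, tracks, truth, expression,
        cohort, cohort_random, random_sites,
    )
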
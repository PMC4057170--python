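"""Anchor-centred tag-density matrices, k-means clustering of binding sites
across chromatin marks, and averaged TSS / metagene / methylation profiles.

Matrices count read 5' positions in fixed-width bins across a window of
+/- ``flank`` bp around each anchor (peak centre or TSS) and normalize to
reads per 10 million mapped. Because peak-centred matrices ignore
transcription direction, asymmetric signal produces pairs of mirrored
clusters; :func:`merge_mirrored` detects and merges them, which is how the
"cluster 4" group of one-sided active-mark sites is assembled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .core import CpGTable, GeneModel, GenomicInterval, TagTrack

logger = logging.getLogger(__name__)

#: normalization unit: reads per 10 million mapped
NORM_FACTOR = 1e7


@dataclass
class ProfileMatrix:
    """Anchors x bins matrix of normalized tag counts for one mark."""

    track_name: str
    anchors: list[GenomicInterval]  # anchors actually profiled (edge-safe)
    flank: int
    bin: int
    matrix: np.ndarray  # shape (n_anchors, 2*flank/bin)
    n_dropped: int = 0  # anchors too close to a chromosome edge

    @property
    def n_bins(self) -> int:
        return 2 * self.flank // self.bin

    def bin_offsets(self) -> np.ndarray:
        """bp offset of each bin midpoint relative to the anchor point."""
        return (np.arange(self.n_bins) + 0.5) * self.bin - self.flank


def tag_density_matrix(
    track: TagTrack,
    anchors: Sequence[GenomicInterval],
    flank: int,
    bin: int,
    strand_aware: bool = False,
    chrom_sizes: Mapping[str, int] | None = None,
) -> ProfileMatrix:
    """Count tag 5' ends per bin around each anchor centre.

    Counts are scaled by 1e7 / total_mapped (reads per 10 million). Anchors
    whose window would cross a chromosome edge are dropped and counted.
    Rows of minus-strand anchors are reversed when ``strand_aware`` is set,
    so bin 0 is always the most upstream bin in the anchor's frame.
    """
    if (2 * flank) % bin != 0:
        raise ValueError(f"bin {bin} does not divide window {2 * flank}")
    n_bins = 2 * flank // bin
    scale = NORM_FACTOR / track.total_mapped if track.total_mapped else 0.0
    rows = []
    kept: list[GenomicInterval] = []
    n_dropped = 0
    for anchor in anchors:
        point = anchor.center
        lo = point - flank
        hi = point + flank
        size = chrom_sizes.get(anchor.chrom) if chrom_sizes else None
        if lo < 0 or (size is not None and hi > size):
            n_dropped += 1
            continue
        pos = track.positions(anchor.chrom)
        edges = lo + bin * np.arange(n_bins + 1, dtype=np.int64)
        counts = np.diff(np.searchsorted(pos, edges, side="left")).astype(np.float64)
        if strand_aware and anchor.strand == "-":
            counts = counts[::-1]
        rows.append(counts * scale)
        kept.append(anchor)
    if n_dropped:
        logger.info("tag_density_matrix(%s): dropped %d edge anchors",
                    track.track_name, n_dropped)
    matrix = np.vstack(rows) if rows else np.empty((0, n_bins))
    return ProfileMatrix(track.track_name, kept, flank, bin, matrix, n_dropped)


@dataclass
class ClusterAssignment:
    """Per-anchor cluster labels plus per-cluster mean profiles per mark."""

    labels: np.ndarray  # per anchor, in 1..k
    k: int
    anchors: list[GenomicInterval]
    cluster_means: dict[str, np.ndarray]  # mark -> (k, n_bins)
    participating: tuple[str, ...]  # marks used in the feature vector
    reversed_rows: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    merge_history: list[tuple[int, int, float]] = field(default_factory=list)
    # anchors x (marks * bins) matrix in the scaled feature space the
    # clustering ran on; consumed by merge_mirrored
    feature_matrix: np.ndarray | None = None
    n_bins: int = 0

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def _cluster_means(
    matrices: Mapping[str, ProfileMatrix],
    labels: np.ndarray,
    k: int,
    reversed_rows: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for name, pm in matrices.items():
        mat = pm.matrix
        if reversed_rows is not None and reversed_rows.any():
            mat = mat.copy()
            mat[reversed_rows] = mat[reversed_rows, ::-1]
        means = np.zeros((k, mat.shape[1]))
        for c in range(1, k + 1):
            idx = labels == c
            if idx.any():
                means[c - 1] = mat[idx].mean(axis=0)
        out[name] = means
    return out


def _feature_space(
    matrices: Mapping[str, ProfileMatrix],
    participating: Sequence[str],
    smooth_bins: int,
    clip: float | None,
) -> np.ndarray:
    """Concatenated per-mark features: light running-mean smoothing, scaling
    to unit 95th percentile, then winsorizing. Without the clip the 95th
    percentile of a mostly-background mark sits at noise level and a few
    strong signal bins dominate the Euclidean metric."""
    from scipy.ndimage import uniform_filter1d

    feats = []
    for n in participating:
        m = matrices[n].matrix.astype(np.float64)
        if smooth_bins > 1 and m.shape[0]:
            m = uniform_filter1d(m, size=smooth_bins, axis=1, mode="nearest")
        p95 = np.percentile(m, 95) if m.size else 0.0
        if p95 > 0:
            m = m / p95
        if clip is not None:
            m = np.minimum(m, clip)
        feats.append(m)
    return np.hstack(feats)


def kmeans_cluster(
    matrices: Mapping[str, ProfileMatrix],
    k: int,
    seed: int,
    display_only: Sequence[str] = (),
    smooth_bins: int = 5,
    clip: float | None = 2.0,
) -> ClusterAssignment:
    """Lloyd k-means (k-means++ init, 20 restarts) on concatenated per-mark
    profiles.

    Each participating mark is smoothed by a short running mean, scaled to
    unit 95th percentile and winsorized at ``clip`` before concatenation so
    deep or spiky tracks do not dominate the Euclidean metric. Marks listed
    in ``display_only`` are excluded from the feature vector but still get
    per-cluster mean profiles in the result.
    """
    names = list(matrices)
    participating = tuple(n for n in names if n not in set(display_only))
    if not participating:
        raise ValueError("no participating marks")
    ref = matrices[participating[0]]
    n_anchors = ref.matrix.shape[0]
    for n in names:
        pm = matrices[n]
        if pm.matrix.shape[0] != n_anchors or [
            (a.chrom, a.start, a.end) for a in pm.anchors
        ] != [(a.chrom, a.start, a.end) for a in ref.anchors]:
            raise ValueError("matrices must share identical anchors")
    if k > n_anchors:
        raise ValueError(f"k={k} exceeds {n_anchors} anchors")
    X = _feature_space(matrices, participating, smooth_bins, clip)
    km = KMeans(n_clusters=k, init="k-means++", n_init=20, random_state=seed)
    labels = km.fit_predict(X) + 1
    return ClusterAssignment(
        labels=labels,
        k=k,
        anchors=list(ref.anchors),
        cluster_means=_cluster_means(matrices, labels, k),
        participating=participating,
        reversed_rows=np.zeros(n_anchors, dtype=bool),
        feature_matrix=X,
        n_bins=ref.matrix.shape[1],
    )


def merge_mirrored(
    assignment: ClusterAssignment,
    matrices: Mapping[str, ProfileMatrix],
    threshold: float = 0.8,
    direct_margin: float = 0.1,
) -> ClusterAssignment:
    """Merge cluster pairs whose mean profiles are mirror images.

    For each pair (a, b) the Pearson correlation is computed between a's
    mean profile and the bin-reversed mean profile of b over the
    concatenated participating marks in the clustering feature space (so
    high-signal marks carry the comparison and flat noise marks do not
    dilute it). A pair merges when the mirror correlation exceeds
    ``threshold`` AND exceeds the un-reversed (direct) correlation by
    ``direct_margin`` — the second condition keeps merely similar symmetric
    clusters, whose direct and mirrored correlations are equal, apart.
    Merging flags b's member rows as reversed orientation, re-orients them
    when recomputing means, and repeats best-first until no pair
    qualifies; labels are renumbered to 1..k'.
    """
    if assignment.feature_matrix is None:
        raise ValueError("assignment carries no feature matrix; "
                         "run kmeans_cluster first")
    X = assignment.feature_matrix
    n_marks = len(assignment.participating)
    n_bins = assignment.n_bins
    labels = assignment.labels.copy()
    reversed_rows = assignment.reversed_rows.copy()
    history = list(assignment.merge_history)
    active = sorted(set(labels.tolist()))

    def oriented_mean(cluster: int) -> np.ndarray:
        rows = X[labels == cluster].reshape(-1, n_marks, n_bins).copy()
        rev = reversed_rows[labels == cluster]
        rows[rev] = rows[rev, :, ::-1]
        return rows.mean(axis=0)

    def corr(u: np.ndarray, v: np.ndarray) -> float:
        if np.std(u) == 0 or np.std(v) == 0:
            return 0.0
        return float(np.corrcoef(u.ravel(), v.ravel())[0, 1])

    while True:
        means = {c: oriented_mean(c) for c in active}
        best: tuple[float, int, int] | None = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                r_mirror = corr(means[a], means[b][:, ::-1])
                r_direct = corr(means[a], means[b])
                if (
                    r_mirror > threshold
                    and r_mirror - r_direct > direct_margin
                    and (best is None or r_mirror > best[0])
                ):
                    best = (r_mirror, a, b)
        if best is None:
            break
        r, a, b = best
        reversed_rows = reversed_rows | (labels == b)
        labels[labels == b] = a
        active.remove(b)
        history.append((a, b, r))

    remap = {old: new for new, old in enumerate(active, start=1)}
    labels = np.array([remap[x] for x in labels])
    k_new = len(active)
    return ClusterAssignment(
        labels=labels,
        k=k_new,
        anchors=assignment.anchors,
        cluster_means=_cluster_means(matrices, labels, k_new, reversed_rows),
        participating=assignment.participating,
        reversed_rows=reversed_rows,
        merge_history=history,
        feature_matrix=X,
        n_bins=n_bins,
    )


@dataclass
class AverageProfile:
    mean: np.ndarray
    p50: np.ndarray
    p90: np.ndarray


def average_profile(
    matrix: ProfileMatrix, members: Sequence[int] | np.ndarray | None = None
) -> AverageProfile:
    """Column-wise mean, median and 90th percentile over member rows
    (linear quantile interpolation)."""
    rows = (
        matrix.matrix
        if members is None
        else matrix.matrix[np.asarray(list(members), dtype=int)]
    )
    if rows.shape[0] == 0:
        raise ValueError("empty member set")
    return AverageProfile(
        mean=rows.mean(axis=0),
        p50=np.percentile(rows, 50, axis=0, method="linear"),
        p90=np.percentile(rows, 90, axis=0, method="linear"),
    )


def _tss_anchors(genes: Sequence[GeneModel]) -> list[GenomicInterval]:
    return [
        GenomicInterval(g.chrom, g.tss, g.tss + 1, g.strand, g.gene_id)
        for g in genes
    ]


def _tes_anchors(genes: Sequence[GeneModel]) -> list[GenomicInterval]:
    return [
        GenomicInterval(g.chrom, g.tes, g.tes + 1, g.strand, g.gene_id)
        for g in genes
    ]


@dataclass
class TssProfile:
    profile: np.ndarray  # per-bin mean normalized density
    bin_offsets: np.ndarray  # bp offset of bin midpoints relative to the TSS
    max_bin: int
    max_offset_bp: float  # midpoint of the maximal bin, downstream positive
    n_genes: int


def tss_profile(
    track: TagTrack,
    genes: Sequence[GeneModel],
    flank: int = 5000,
    bin: int = 100,
    strand_aware: bool = True,
    chrom_sizes: Mapping[str, int] | None = None,
) -> TssProfile:
    """Strand-aware average tag-density profile anchored at gene TSSs,
    reporting where the profile peaks relative to the TSS."""
    pm = tag_density_matrix(
        track, _tss_anchors(genes), flank, bin, strand_aware, chrom_sizes
    )
    if pm.matrix.shape[0] == 0:
        raise ValueError("no gene TSS could be profiled")
    mean = pm.matrix.mean(axis=0)
    offsets = pm.bin_offsets()
    max_bin = int(np.argmax(mean))
    return TssProfile(
        profile=mean,
        bin_offsets=offsets,
        max_bin=max_bin,
        max_offset_bp=float(offsets[max_bin]),
        n_genes=pm.matrix.shape[0],
    )


@dataclass
class MetageneProfile:
    tss_profile: np.ndarray
    tes_profile: np.ndarray
    bin_offsets: np.ndarray  # relative to the respective anchor
    n_genes: int
    n_excluded: int


def metagene_profile(
    track: TagTrack,
    genes: Sequence[GeneModel],
    anchor_flank: int = 2000,
    min_gene_length: int = 4000,
    bin: int = 100,
    chrom_sizes: Mapping[str, int] | None = None,
) -> MetageneProfile:
    """Side-by-side strand-aware profiles anchored at the TSS and the TES.

    Genes shorter than ``min_gene_length`` are excluded (and counted) so
    the two anchor windows cannot overlap; requires
    ``min_gene_length >= 2 * anchor_flank``.
    """
    if min_gene_length < 2 * anchor_flank:
        raise ValueError("min_gene_length must be >= 2 * anchor_flank")
    qualifying = [g for g in genes if g.length >= min_gene_length]
    n_excluded = len(genes) - len(qualifying)
    if not qualifying:
        raise ValueError("no gene passes the length filter")
    if n_excluded:
        logger.info("metagene_profile: excluded %d short genes", n_excluded)
    pm_tss = tag_density_matrix(
        track, _tss_anchors(qualifying), anchor_flank, bin, True, chrom_sizes
    )
    pm_tes = tag_density_matrix(
        track, _tes_anchors(qualifying), anchor_flank, bin, True, chrom_sizes
    )
    return MetageneProfile(
        tss_profile=pm_tss.matrix.mean(axis=0),
        tes_profile=pm_tes.matrix.mean(axis=0),
        bin_offsets=pm_tss.bin_offsets(),
        n_genes=len(qualifying),
        n_excluded=n_excluded,
    )


@dataclass
class MethylationCpGProfile:
    methylation: np.ndarray  # per-bin mean meth fraction (NaN where no CpG)
    cpg_density: np.ndarray  # CpGs per bp per anchor
    bin_offsets: np.ndarray
    n_anchors: int


def methylation_cpg_profile(
    cpgs: CpGTable,
    anchors: Sequence[GenomicInterval],
    flank: int = 5000,
    bin: int = 100,
    strand_aware: bool = False,
) -> MethylationCpGProfile:
    """Average methylation and CpG density per bin around anchors.

    Methylation is the unweighted mean of CpG fractions pooled across all
    anchors per bin (NaN where no CpG falls); density is CpGs per bp,
    averaged over anchors.
    """
    if (2 * flank) % bin != 0:
        raise ValueError(f"bin {bin} does not divide window {2 * flank}")
    n_bins = 2 * flank // bin
    meth_sum = np.zeros(n_bins)
    count = np.zeros(n_bins)
    n_anchors = 0
    for anchor in anchors:
        point = anchor.center
        lo = point - flank
        if lo < 0:
            continue
        n_anchors += 1
        pos, meth, _ = cpgs.fetch(anchor.chrom, lo, point + flank)
        bins = (pos - lo) // bin
        if strand_aware and anchor.strand == "-":
            bins = n_bins - 1 - bins
        np.add.at(meth_sum, bins, meth)
        np.add.at(count, bins, 1)
    if n_anchors == 0:
        raise ValueError("no anchor could be profiled")
    with np.errstate(invalid="ignore"):
        meth_mean = np.where(count > 0, meth_sum / count, np.nan)
    density = count / (n_anchors * bin)
    offsets = (np.arange(n_bins) + 0.5) * bin - flank
    return MethylationCpGProfile(meth_mean, density, offsets, n_anchors)
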
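"""Methylation levels at intervals, methyl-CpG density and ChIP enrichment
tracks, and the ranked density-versus-enrichment correlation.

Methyl-CpG density follows the convention: the sum of per-CpG methylation
fractions within a window divided by the window length, in units of
methylated-CpG equivalents per bp. Enrichment is log2 of tag-frequency
ratios (ChIP over input) with a pseudo-frequency so empty windows stay
finite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core import CpGTable, GenomicInterval, TagTrack

logger = logging.getLogger(__name__)


@dataclass
class WindowTrack:
    """Genome-tiling per-window values (density, enrichment or methylation).

    Windows tile each chromosome from position 0 with the given step; the
    last partial window is dropped, so each chromosome contributes
    ``floor((chrom_len - window) / step) + 1`` windows.
    """

    window: int
    step: int
    chrom_sizes: dict[str, int]
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, vals in self.values.items():
            expected = self.n_windows(chrom)
            if len(vals) != expected:
                raise ValueError(
                    f"{chrom}: {len(vals)} values, expected {expected}"
                )

    def n_windows(self, chrom: str) -> int:
        size = self.chrom_sizes[chrom]
        if size < self.window:
            return 0
        return (size - self.window) // self.step + 1

    def window_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_windows(chrom), dtype=np.int64) * self.step

    @property
    def chroms(self) -> list[str]:
        return sorted(self.values)

    def flatten(self) -> np.ndarray:
        """All values in genome order (chromosomes sorted by name)."""
        return np.concatenate(
            [self.values[c] for c in self.chroms]
        ) if self.values else np.empty(0)

    def same_grid(self, other: "WindowTrack") -> bool:
        return (
            self.window == other.window
            and self.step == other.step
            and self.chroms == other.chroms
            and all(self.n_windows(c) == other.n_windows(c) for c in self.chroms)
        )


def interval_methylation(
    site: GenomicInterval, cpgs: CpGTable, min_coverage: int = 1
) -> float | None:
    """Coverage-weighted mean methylation over CpGs inside ``site``.

    Only CpGs with coverage >= ``min_coverage`` contribute; returns ``None``
    (undefined) when no CpG qualifies.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    _, meth, cov = cpgs.fetch(site.chrom, site.start, site.end)
    keep = cov >= min_coverage
    if not np.any(keep):
        return None
    w = cov[keep].astype(np.float64)
    return float(np.sum(meth[keep] * w) / np.sum(w))


@dataclass
class SiteMethylationResult:
    """Per-site methylation levels with the count of undefined sites."""

    values: np.ndarray
    n_undefined: int
    summary: tuple[float, float, float, float, float]  # min, Q1, median, Q3, max


def five_number_summary(values: np.ndarray) -> tuple[float, float, float, float, float]:
    """(min, Q1, median, Q3, max) with linear quantile interpolation."""
    q = np.percentile(values, [0, 25, 50, 75, 100], method="linear")
    return tuple(float(x) for x in q)  # type: ignore[return-value]


def methylation_site_distribution(
    sites: Sequence[GenomicInterval],
    cpgs: CpGTable,
    min_coverage: int = 1,
) -> SiteMethylationResult:
    """Methylation level per site plus a five-number summary.

    Sites without any qualifying CpG are excluded and counted; raises if
    every site is undefined.
    """
    values = []
    n_undef = 0
    for site in sites:
        level = interval_methylation(site, cpgs, min_coverage)
        if level is None:
            n_undef += 1
        else:
            values.append(level)
    if not values:
        raise ValueError("all sites have undefined methylation")
    if n_undef:
        logger.info("methylation_site_distribution: %d undefined sites", n_undef)
    arr = np.asarray(values, dtype=np.float64)
    return SiteMethylationResult(arr, n_undef, five_number_summary(arr))


def mcpg_density_track(
    cpgs: CpGTable,
    chrom_sizes: dict[str, int],
    window: int,
    step: int | None = None,
) -> WindowTrack:
    """Methyl-CpG density per tiling window.

    value(w) = sum of meth_fraction over CpGs in w / window length
    (methylated-CpG equivalents per bp). Windows without CpGs get 0.
    """
    if step is None:
        step = window
    if step > window:
        raise ValueError("step > window leaves gaps and would bias ranking")
    track = WindowTrack(window, step, dict(chrom_sizes))
    for chrom, size in chrom_sizes.items():
        n = track.n_windows(chrom)
        if n == 0:
            track.values[chrom] = np.empty(0, dtype=np.float64)
            continue
        pos, meth, _ = cpgs.fetch(chrom, 0, size)
        starts = track.window_starts(chrom)
        csum = np.concatenate(([0.0], np.cumsum(meth)))
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        track.values[chrom] = (csum[hi] - csum[lo]) / float(window)
    return track


def methylation_level_track(
    cpgs: CpGTable,
    chrom_sizes: dict[str, int],
    window: int,
    step: int | None = None,
) -> WindowTrack:
    """Mean methylation fraction per window (NaN where a window has no CpG).

    This is the genome-wide sliding-window summary used to compare whole
    methylomes; unlike :func:`mcpg_density_track` it averages rather than
    sums, so it is insensitive to CpG density.
    """
    if step is None:
        step = window
    track = WindowTrack(window, step, dict(chrom_sizes))
    for chrom, size in chrom_sizes.items():
        n = track.n_windows(chrom)
        if n == 0:
            track.values[chrom] = np.empty(0, dtype=np.float64)
            continue
        pos, meth, _ = cpgs.fetch(chrom, 0, size)
        starts = track.window_starts(chrom)
        csum = np.concatenate(([0.0], np.cumsum(meth)))
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        counts = (hi - lo).astype(np.float64)
        with np.errstate(invalid="ignore"):
            track.values[chrom] = np.where(
                counts > 0, (csum[hi] - csum[lo]) / counts, np.nan
            )
    return track


def enrichment_track(
    chip: TagTrack,
    input_track: TagTrack,
    chrom_sizes: dict[str, int],
    window: int,
    step: int | None = None,
) -> WindowTrack:
    """log2 ChIP-over-input tag-frequency ratio per window.

    value(w) = log2((chip_w/chip_total + p) / (input_w/input_total + p))
    with pseudo-frequency p = 0.5 / min(chip_total, input_total). Each tag
    is assigned to the window containing its 5' position (for overlapping
    sliding windows, to every window containing it).
    """
    if chip.total_mapped <= 0 or input_track.total_mapped <= 0:
        raise ValueError("zero total mapped reads in chip or input track")
    if step is None:
        step = window
    p = 0.5 / min(chip.total_mapped, input_track.total_mapped)
    track = WindowTrack(window, step, dict(chrom_sizes))
    for chrom in chrom_sizes:
        n = track.n_windows(chrom)
        if n == 0:
            track.values[chrom] = np.empty(0, dtype=np.float64)
            continue
        starts = track.window_starts(chrom)
        ends = starts + window
        chip_pos = chip.positions(chrom)
        in_pos = input_track.positions(chrom)
        c = np.searchsorted(chip_pos, ends) - np.searchsorted(chip_pos, starts)
        i = np.searchsorted(in_pos, ends) - np.searchsorted(in_pos, starts)
        chip_f = c / chip.total_mapped + p
        in_f = i / input_track.total_mapped + p
        track.values[chrom] = np.log2(chip_f / in_f)
    return track


@dataclass
class RankedCurve:
    """Windows ranked by density with smoothed enrichment and Spearman rho."""

    rank_quantiles: np.ndarray  # in (0, 1], one per curve sample
    density: np.ndarray  # density at the sampled ranks
    enrichment: np.ndarray  # smoothed enrichment at the sampled ranks
    rho: float
    n_windows: int


def ranked_density_enrichment(
    density: WindowTrack,
    enrichment: WindowTrack,
    n_points: int = 200,
) -> RankedCurve:
    """Rank windows by methyl-CpG density and trace mean enrichment.

    Windows are sorted ascending by density (ties broken by genomic order,
    deterministically); enrichment is smoothed by a running mean over blocks
    of ceil(N / n_points) windows and sampled at n_points evenly spaced
    ranks. Spearman rho is computed over all windows; if either variable is
    constant the correlation is defined as 0.
    """
    if not density.same_grid(enrichment):
        raise ValueError("density and enrichment tracks use different grids")
    d = density.flatten()
    e = enrichment.flatten()
    n = len(d)
    if n == 0:
        raise ValueError("empty tracks")
    order = np.argsort(d, kind="stable")  # stable sort = genomic tie-break
    d_sorted = d[order]
    e_sorted = e[order]
    block = max(1, math.ceil(n / n_points))
    kernel = np.ones(block) / block
    smoothed = np.convolve(e_sorted, kernel, mode="same")
    idx = np.unique(np.linspace(0, n - 1, min(n_points, n)).round().astype(int))
    if np.ptp(d) == 0 or np.ptp(e) == 0:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(d, e).statistic)
    return RankedCurve(
        rank_quantiles=(idx + 1) / n,
        density=d_sorted[idx],
        enrichment=smoothed[idx],
        rho=rho,
        n_windows=n,
    )


def write_bedgraph(path: str, track: WindowTrack) -> None:
    """Export a WindowTrack as bedGraph (step-sized records, NaN skipped)."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts = track.window_starts(chrom)
            vals = track.values[chrom]
            for s, v in zip(starts, vals):
                if np.isnan(v):
                    continue
                fh.write(f"{chrom}\t{s}\t{s + track.window}\t{v:.6g}\n")
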
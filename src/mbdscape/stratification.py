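"""Expression- and density-based gene stratification into tertiles.

Genes are ranked by a per-gene value (RPKM, gene-body H3K36me3 tags per bp,
or gene-body methyl-CpG density) and split into three equal-size tiers
("high", "medium", "low"); a gene subset of interest is then compared
against the tiers by its five-number summary and nearest-median tier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import CpGTable, GeneModel, TagTrack
from .methylation import five_number_summary

TIERS = ("high", "medium", "low")


def compute_rpkm(
    counts: pd.Series, gene_lengths: pd.Series, total_mapped: int
) -> pd.Series:
    """RPKM = count / (gene length in kb x total mapped reads in millions)."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:3]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    return counts / (lengths / 1e3 * total_mapped / 1e6)


def tertile_bins(
    values: pd.Series,
    eligibility: Callable[[float], bool] | None = None,
) -> pd.Series:
    """Tier labels ("high"/"medium"/"low") for eligible genes.

    Ineligible genes (default: value <= 0, i.e. not expressed) are excluded
    from the returned series. Genes are ranked descending with ties broken
    by stable gene-id order; when the eligible count is not divisible by 3
    the remainder goes to the top tiers (10 genes -> 4/3/3).
    """
    if eligibility is None:
        eligibility = lambda v: v > 0  # noqa: E731
    eligible = values[values.map(eligibility)]
    n = len(eligible)
    if n < 3:
        raise ValueError(f"need >= 3 eligible genes, got {n}")
    # stable gene-id tie-break: sort by id first, then stably by -value
    by_id = eligible.sort_index(kind="stable")
    order = by_id.iloc[np.argsort(-by_id.to_numpy(), kind="stable")]
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.repeat(TIERS, sizes)
    return pd.Series(labels, index=order.index, name="tier")


def genebody_density(
    source: TagTrack | CpGTable, genes: Sequence[GeneModel]
) -> pd.Series:
    """Per-gene signal per bp over the transcript span.

    For a tag track: tag 5' positions within [tx_start, tx_end) divided by
    gene length. For a methylome: the sum of CpG methylation fractions
    divided by gene length (methyl-CpG density).
    """
    out = {}
    for g in genes:
        if isinstance(source, TagTrack):
            total = source.count_in(g.chrom, g.tx_start, g.tx_end)
        else:
            _, meth, _ = source.fetch(g.chrom, g.tx_start, g.tx_end)
            total = float(meth.sum())
        out[g.gene_id] = total / g.length
    return pd.Series(out, name="density")


@dataclass
class TierComparison:
    """Five-number summaries of a gene subset next to each tier."""

    subset_summary: tuple[float, float, float, float, float]
    tier_summaries: dict[str, tuple[float, float, float, float, float]]
    nearest_tier: str  # tier whose median is closest to the subset median
    subset_n: int


def compare_subset_to_tiers(
    subset: Sequence[str],
    values: pd.Series,
    tiers: pd.Series | None = None,
) -> TierComparison:
    """Compare a gene subset's value distribution against the tertiles.

    ``tiers`` defaults to :func:`tertile_bins` of ``values``. Subset genes
    missing from ``values`` are ignored; an empty (effective) subset is an
    error.
    """
    if tiers is None:
        tiers = tertile_bins(values)
    subset_vals = values.reindex([g for g in subset if g in values.index]).dropna()
    if subset_vals.empty:
        raise ValueError("empty gene subset")
    subset_summary = five_number_summary(subset_vals.to_numpy())
    tier_summaries = {}
    for tier in TIERS:
        members = tiers.index[tiers == tier]
        tier_summaries[tier] = five_number_summary(
            values.reindex(members).to_numpy()
        )
    subset_median = subset_summary[2]
    nearest = min(TIERS, key=lambda t: abs(tier_summaries[t][2] - subset_median))
    return TierComparison(subset_summary, tier_summaries, nearest, len(subset_vals))
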
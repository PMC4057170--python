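"""Tumor/normal cohort methylation comparison at binding-site sets.

A cohort is a samples x sites matrix of array-style methylation fractions
(beta values, in [0,1], NaN for missing) with a tumor/normal label per
sample. The comparison computes, per site set, the per-sample mean
methylation and a two-sided Mann-Whitney U test between groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval

logger = logging.getLogger(__name__)

GROUP_TUMOR = "tumor"
GROUP_NORMAL = "normal"

#: Smallest p-value ever reported; p is floored here rather than at zero.
P_FLOOR = float(np.finfo(np.float64).tiny)


@dataclass
class CohortMatrix:
    """Samples x sites methylation beta values with group labels."""

    sample_ids: list[str]
    groups: list[str]  # per sample, "tumor" or "normal"
    sites: list[GenomicInterval]
    values: np.ndarray  # shape (n_samples, n_sites), NaN = missing

    def __post_init__(self) -> None:
        n_samples, n_sites = self.values.shape
        if len(self.sample_ids) != n_samples or len(self.groups) != n_samples:
            raise ValueError("sample_ids/groups length mismatch with values")
        if len(self.sites) != n_sites:
            raise ValueError("sites length mismatch with values")
        bad = self.groups and set(self.groups) - {GROUP_TUMOR, GROUP_NORMAL}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("methylation values outside [0,1]")

    def sample_mask(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.groups], dtype=bool)

    def site_keys(self) -> list[tuple[str, int, int]]:
        return [(s.chrom, s.start, s.end) for s in self.sites]


def write_cohort(path: str, matrix: CohortMatrix) -> None:
    """TSV layout: header row of sample ids, second row of group labels,
    then one row per site (``chrom:start-end`` followed by values)."""
    with open(path, "w") as fh:
        fh.write("site\t" + "\t".join(matrix.sample_ids) + "\n")
        fh.write("group\t" + "\t".join(matrix.groups) + "\n")
        for j, s in enumerate(matrix.sites):
            vals = "\t".join(
                "NA" if not np.isfinite(v) else f"{v:.6g}"
                for v in matrix.values[:, j]
            )
            fh.write(f"{s.chrom}:{s.start}-{s.end}\t{vals}\n")


def read_cohort(path: str) -> CohortMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        group_row = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        groups = group_row[1:]
        sites: list[GenomicInterval] = []
        rows: list[list[float]] = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            chrom, span = fields[0].split(":")
            start, end = span.split("-")
            sites.append(GenomicInterval(chrom, int(start), int(end)))
            rows.append(
                [float("nan") if v == "NA" else float(v) for v in fields[1:]]
            )
    values = np.array(rows, dtype=np.float64).T if rows else np.empty((len(sample_ids), 0))
    return CohortMatrix(sample_ids, groups, sites, values)


def sample_site_means(
    matrix: CohortMatrix, site_subset: Iterable[GenomicInterval]
) -> pd.Series:
    """Per-sample mean methylation over the subset of sites.

    Sites are matched by (chrom, start, end); the mean ignores missing
    values; samples missing every subset site are dropped with a log note.
    Raises when no subset site is present in the matrix.
    """
    wanted = {(s.chrom, s.start, s.end) for s in site_subset}
    cols = [j for j, key in enumerate(matrix.site_keys()) if key in wanted]
    if not cols:
        raise ValueError("site subset does not intersect the cohort matrix")
    sub = matrix.values[:, cols]
    finite = np.isfinite(sub)
    counts = finite.sum(axis=1)
    sums = np.where(finite, sub, 0.0).sum(axis=1)
    means = np.divide(sums, counts, out=np.full(len(sub), np.nan),
                      where=counts > 0)
    keep = np.isfinite(means)
    if not np.all(keep):
        logger.info("sample_site_means: dropped %d all-missing samples",
                    int((~keep).sum()))
    return pd.Series(means[keep], index=np.array(matrix.sample_ids)[keep])


@dataclass
class MannWhitneyResult:
    u: float  # U statistic of the first group
    p: float  # two-sided, floored at P_FLOOR, never 0
    method: str  # "exact" or "asymptotic"
    z: float  # normal-approximation z with tie correction (0 for exact path)


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The p-value is exact (full enumeration of rank arrangements) when
    n_a + n_b <= 16 and there are no ties, otherwise a normal approximation
    with tie and continuity corrections is used. p is floored at the
    smallest positive double so it is never reported as 0.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # every ordering is equally extreme: no evidence of a shift
        return MannWhitneyResult(u=a.size * b.size / 2, p=1.0, method="degenerate",
                                 z=0.0)
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = (a.size + b.size) <= 16 and not has_ties
    res = stats.mannwhitneyu(
        a, b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    # z from the tie-corrected normal approximation, reported alongside p
    # because p itself may sit at a display floor.
    n1, n2 = a.size, b.size
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    u = float(res.statistic)
    z = (u - mu) / sigma if sigma > 0 else 0.0
    return MannWhitneyResult(
        u=u,
        p=max(float(res.pvalue), P_FLOOR),
        method="exact" if exact else "asymptotic",
        z=float(z),
    )


@dataclass
class SetComparison:
    """Tumor-vs-normal comparison of per-sample means for one site set."""

    set_name: str
    tumor_means: pd.Series
    normal_means: pd.Series
    tumor_median: float
    normal_median: float
    test: MannWhitneyResult | None
    note: str = ""


def cohort_comparison(
    matrix: CohortMatrix,
    site_sets: Mapping[str, Sequence[GenomicInterval]],
    random_matrix: CohortMatrix | None = None,
    random_name: str = "random",
) -> dict[str, SetComparison]:
    """Per-sample means per group plus the Mann-Whitney test for each
    named site set; an optional random-site matrix is analysed the same
    way under ``random_name``. Groups of size < 2 yield summaries with an
    underpowered note instead of a test."""
    results: dict[str, SetComparison] = {}

    def one(name: str, mat: CohortMatrix, sites: Sequence[GenomicInterval]):
        means = sample_site_means(mat, sites)
        groups = pd.Series(mat.groups, index=mat.sample_ids).reindex(means.index)
        tumor = means[groups == GROUP_TUMOR]
        normal = means[groups == GROUP_NORMAL]
        if tumor.empty or normal.empty:
            raise ValueError(f"set {name!r}: a group has no samples")
        note = ""
        test: MannWhitneyResult | None = None
        if len(tumor) < 2 or len(normal) < 2:
            note = "underpowered: fewer than 2 samples in a group"
        else:
            test = mann_whitney_u(tumor.to_numpy(), normal.to_numpy())
        results[name] = SetComparison(
            set_name=name,
            tumor_means=tumor,
            normal_means=normal,
            tumor_median=float(tumor.median()),
            normal_median=float(normal.median()),
            test=test,
            note=note,
        )

    for name, sites in site_sets.items():
        one(name, matrix, sites)
    if random_matrix is not None:
        one(random_name, random_matrix, random_matrix.sites)
    return results
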
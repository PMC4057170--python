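"""End-to-end orchestration: simulate (or ingest) -> annotate -> methylation
-> cluster -> stratify -> cohort, with every figure-level number written to
a stable file name and a checksummed manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import annotation as ann
from . import cohort as coh
from . import methylation as meth
from . import profiles as prof
from . import stratification as strat
from .core import (
    GenomeAnnotation,
    read_bed,
    read_gene_table,
    read_methcounts,
    read_tags,
    write_bed,
)
from .synthetic import (
    SyntheticConfig,
    SyntheticDataset,
    TRACK_NAMES,
    simulate,
)

logger = logging.getLogger(__name__)

DISPLAY_ONLY_MARKS = ("H3K27me3", "H3K9me3")


@dataclass
class PipelineConfig:
    """Either a simulate block or a complete set of real-input paths.

    ``inputs`` keys (real mode): peaks, genes, cgis, methcounts, and
    tags (a mapping of track name to BED6 path including "MBD2" and
    "input"); optional: expression (TSV gene_id<TAB>rpkm), cohort and
    cohort_random (cohort-matrix TSV).
    """

    outdir: str
    seed: int = 42
    simulate: SyntheticConfig | None = None
    inputs: dict | None = None
    # per-stage parameters
    min_coverage: int = 1
    density_window: int = 1000
    heatmap_bin: int = 20
    profile_bin: int = 100
    profile_flank: int = 5000
    kmeans_k: int = 5
    merge_threshold: float = 0.8
    metagene_flank: int = 2000
    min_gene_length: int = 4000

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(
                "config must provide exactly one of a simulate block or "
                "real-input paths"
            )
        if self.inputs is not None:
            required = {"peaks", "genes", "cgis", "methcounts", "tags"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"missing input paths: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "simulate"})
        if sim is not None:
            cfg.simulate = SyntheticConfig.from_dict(sim)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_real(config: PipelineConfig) -> SyntheticDataset:
    """Build a dataset-shaped bundle from real input files."""
    paths = config.inputs or {}
    peaks = read_bed(paths["peaks"])
    genes = read_gene_table(paths["genes"])
    cgis = read_bed(paths["cgis"])
    methylome = read_methcounts(paths["methcounts"])
    chrom_sizes: dict[str, int] = {}
    for g in genes:
        chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.tx_end)
    for iv in list(peaks) + list(cgis):
        chrom_sizes[iv.chrom] = max(chrom_sizes.get(iv.chrom, 0), iv.end)
    for chrom in methylome.chroms:
        pos, _, _ = methylome.fetch(chrom, 0, 2**62)
        if len(pos):
            chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), int(pos[-1]) + 1)
    genome = GenomeAnnotation(chrom_sizes, genes, cgis)
    tracks = {
        name: read_tags(path, name) for name, path in paths["tags"].items()
    }
    expression = None
    if "expression" in paths:
        expr_df = pd.read_csv(paths["expression"], sep="\t", index_col=0)
        expression = expr_df.iloc[:, 0]
    cohort = coh.read_cohort(paths["cohort"]) if "cohort" in paths else None
    cohort_random = (
        coh.read_cohort(paths["cohort_random"]) if "cohort_random" in paths else None
    )
    from .synthetic import SyntheticTruth

    truth = SyntheticTruth(peaks, ["unknown"] * len(peaks), [], {})
    return SyntheticDataset(
        config=SyntheticConfig(seed=config.seed),
        genome=genome,
        methylome=methylome,
        tracks=tracks,
        truth=truth,
        expression=expression if expression is not None else pd.Series(dtype=float),
        cohort=cohort,  # type: ignore[arg-type]
        cohort_random=cohort_random,  # type: ignore[arg-type]
    )


def cluster4_promoter_genes(
    assignment: prof.ClusterAssignment, genome: GenomeAnnotation, max_dist: int = 2000
) -> list[str]:
    """Genes whose TSS lies near an anchor of the mirror-merged cluster.

    Used in real-input mode, where the planted cluster-4 gene list is not
    available: the merged cluster (the one assembled from two mirrored
    halves) marks one-sided active-promoter sites, and its anchors are
    mapped back to the nearest TSS within ``max_dist`` bp.
    """
    if not assignment.merge_history:
        return []
    merged_label_old = assignment.merge_history[-1][0]
    # after renumbering, find the cluster containing reversed rows
    candidates = set(assignment.labels[assignment.reversed_rows].tolist())
    target = candidates.pop() if len(candidates) == 1 else merged_label_old
    members = assignment.members(int(target))
    out = []
    for g in genome.genes:
        tss = g.tss
        for mi in members:
            a = assignment.anchors[mi]
            if a.chrom == g.chrom and abs(a.center - tss) <= max_dist:
                out.append(g.gene_id)
                break
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    The manifest maps each output file to its SHA-256 checksum and records
    the full configuration; a rerun with the same config and seed
    reproduces identical checksums.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stage_counters": {}, "files": {}}

    if config.simulate is not None:
        sim_cfg = config.simulate
        data = simulate(sim_cfg)
    else:
        data = _load_real(config)
    genome, methylome, tracks = data.genome, data.methylome, data.tracks
    peaks = data.truth.peaks

    def save(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["files"][name] = _sha256(path)

    # --- inputs snapshot (simulated mode) ---------------------------------
    if config.simulate is not None:
        save("peaks.bed", lambda p: write_bed(str(p), peaks))

    # --- annotation -------------------------------------------------------
    index = ann.AnnotationIndex(genome)
    obs = ann.annotate_sites(peaks, index)
    rand_sites = ann.sample_random_lengthmatched(peaks, genome, config.seed)
    rand_counts = ann.annotate_sites(rand_sites, index)
    folds = ann.fold_over_random(obs, rand_counts)

    def write_annotation(path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\tpercent\tfold_over_random\n")
            for cat in ann.ALL_CATEGORIES:
                fh.write(
                    f"{cat}\t{obs[cat]}\t{100 * obs.fraction(cat):.4g}\t"
                    f"{folds[cat]:.6g}\n"
                )

    save("annotation_counts.tsv", write_annotation)

    # --- methylation ------------------------------------------------------
    dist = meth.methylation_site_distribution(peaks, methylome, config.min_coverage)
    manifest["stage_counters"]["sites_undefined_methylation"] = dist.n_undefined

    def write_site_meth(path: Path) -> None:
        with open(path, "w") as fh:
            mn, q1, med, q3, mx = dist.summary
            fh.write(f"# five-number summary: {mn:.6g} {q1:.6g} {med:.6g} "
                     f"{q3:.6g} {mx:.6g}\n")
            fh.write("site\tlevel\n")
            defined = [
                (s, meth.interval_methylation(s, methylome, config.min_coverage))
                for s in peaks
            ]
            for s, lev in defined:
                if lev is not None:
                    fh.write(f"{s.chrom}:{s.start}-{s.end}\t{lev:.6g}\n")

    save("site_methylation.tsv", write_site_meth)

    density = meth.mcpg_density_track(
        methylome, genome.chrom_sizes, config.density_window
    )
    enrich = meth.enrichment_track(
        tracks["MBD2"], tracks["input"], genome.chrom_sizes, config.density_window
    )
    curve = meth.ranked_density_enrichment(density, enrich)
    save("mcpg_density.bedgraph", lambda p: meth.write_bedgraph(str(p), density))
    save("mbd2_enrichment.bedgraph", lambda p: meth.write_bedgraph(str(p), enrich))

    def write_curve(path: Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# spearman_rho\t{curve.rho:.6g}\n")
            fh.write(f"# n_windows\t{curve.n_windows}\n")
            fh.write("rank_quantile\tdensity\tenrichment\n")
            for q, d, e in zip(curve.rank_quantiles, curve.density, curve.enrichment):
                fh.write(f"{q:.6g}\t{d:.6g}\t{e:.6g}\n")

    save("ranked_density_enrichment.tsv", write_curve)

    # --- profiles & clustering -------------------------------------------
    matrices = {
        name: prof.tag_density_matrix(
            tracks[name], peaks, config.profile_flank, config.heatmap_bin,
            strand_aware=False, chrom_sizes=genome.chrom_sizes,
        )
        for name in tracks
    }
    assignment = prof.kmeans_cluster(
        matrices, config.kmeans_k, config.seed,
        display_only=[m for m in DISPLAY_ONLY_MARKS if m in matrices],
    )
    merged = prof.merge_mirrored(assignment, matrices, config.merge_threshold)
    manifest["stage_counters"]["clusters_after_merge"] = merged.k
    manifest["stage_counters"]["n_merges"] = len(merged.merge_history)

    def write_clusters(path: Path) -> None:
        with open(path, "w") as fh:
            for a, lab in zip(merged.anchors, merged.labels):
                fh.write(f"{a.chrom}\t{a.start}\t{a.end}\tcluster{lab}\t0\t.\n")

    save("cluster_assignment.bed", write_clusters)

    def write_cluster_profiles(path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("mark\tcluster\tbin_offset\tmean\n")
            offsets = next(iter(matrices.values())).bin_offsets()
            for mark in sorted(merged.cluster_means):
                means = merged.cluster_means[mark]
                for c in range(1, merged.k + 1):
                    for off, v in zip(offsets, means[c - 1]):
                        fh.write(f"{mark}\t{c}\t{off:g}\t{v:.6g}\n")

    save("cluster_profiles.tsv", write_cluster_profiles)

    # per-cluster methylation / CpG density profile
    mprof = prof.methylation_cpg_profile(
        methylome, peaks, config.profile_flank, config.profile_bin
    )

    def write_meth_profile(path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_offset\tmethylation\tcpg_density\n")
            for off, m, d in zip(mprof.bin_offsets, mprof.methylation,
                                 mprof.cpg_density):
                fh.write(f"{off:g}\t{m:.6g}\t{d:.6g}\n")

    save("site_methylation_profile.tsv", write_meth_profile)

    # --- cluster-4 TSS / metagene profiles -------------------------------
    genes_by_id = {g.gene_id: g for g in genome.genes}
    if data.truth.cluster4_genes:
        c4_ids = data.truth.cluster4_genes
    else:
        c4_ids = cluster4_promoter_genes(merged, genome)
    c4_genes = [genes_by_id[g] for g in c4_ids if g in genes_by_id]
    if c4_genes:
        tssp = prof.tss_profile(
            tracks["MBD2"], c4_genes, config.profile_flank, config.profile_bin,
            chrom_sizes=genome.chrom_sizes,
        )
        manifest["stage_counters"]["tss_profile_max_offset_bp"] = tssp.max_offset_bp

        def write_tss(path: Path) -> None:
            with open(path, "w") as fh:
                fh.write(f"# max_offset_bp\t{tssp.max_offset_bp:g}\n")
                fh.write("bin_offset\tmean\n")
                for off, v in zip(tssp.bin_offsets, tssp.profile):
                    fh.write(f"{off:g}\t{v:.6g}\n")

        save("cluster4_tss_profile.tsv", write_tss)

        mg = prof.metagene_profile(
            tracks["H3K36me3"], c4_genes, config.metagene_flank,
            config.min_gene_length, config.profile_bin, genome.chrom_sizes,
        )
        manifest["stage_counters"]["metagene_excluded_short_genes"] = mg.n_excluded

        def write_metagene(path: Path) -> None:
            with open(path, "w") as fh:
                fh.write("bin_offset\ttss_mean\ttes_mean\n")
                for off, a, b in zip(mg.bin_offsets, mg.tss_profile, mg.tes_profile):
                    fh.write(f"{off:g}\t{a:.6g}\t{b:.6g}\n")

        save("cluster4_metagene_h3k36me3.tsv", write_metagene)

    # --- stratification ---------------------------------------------------
    if len(data.expression):
        tiers = strat.tertile_bins(data.expression)

        def write_tiers(path: Path) -> None:
            with open(path, "w") as fh:
                fh.write("gene_id\trpkm\ttier\n")
                for gid in data.expression.index:
                    fh.write(
                        f"{gid}\t{data.expression[gid]:.6g}\t"
                        f"{tiers.get(gid, 'excluded')}\n"
                    )

        save("expression_tiers.tsv", write_tiers)

        if c4_genes:
            comparisons = {"rpkm": strat.compare_subset_to_tiers(
                c4_ids, data.expression, tiers)}
            k36 = strat.genebody_density(tracks["H3K36me3"], genome.genes)
            comparisons["h3k36me3_density"] = strat.compare_subset_to_tiers(
                c4_ids, k36, strat.tertile_bins(k36))
            mcpg = strat.genebody_density(methylome, genome.genes)
            comparisons["mcpg_density"] = strat.compare_subset_to_tiers(
                c4_ids, mcpg, strat.tertile_bins(mcpg))

            def write_cmp(path: Path) -> None:
                with open(path, "w") as fh:
                    fh.write("metric\tgroup\tmin\tq1\tmedian\tq3\tmax"
                             "\tnearest_tier\n")
                    for metric, c in comparisons.items():
                        rows = [("cluster4", c.subset_summary)] + [
                            (t, c.tier_summaries[t]) for t in strat.TIERS
                        ]
                        for gname, s in rows:
                            vals = "\t".join(f"{x:.6g}" for x in s)
                            fh.write(f"{metric}\t{gname}\t{vals}\t"
                                     f"{c.nearest_tier}\n")

            save("tier_comparison.tsv", write_cmp)

    # --- cohort -----------------------------------------------------------
    if data.cohort is not None:
        site_sets: dict = {"all_sites": data.cohort.sites}
        if data.truth.cluster4_genes:
            c4_sites = data.truth.peaks_of_class("cluster4")
            if c4_sites:
                site_sets["cluster4"] = c4_sites
        results = coh.cohort_comparison(
            data.cohort, site_sets, random_matrix=data.cohort_random
        )

        def write_cohort_cmp(path: Path) -> None:
            with open(path, "w") as fh:
                fh.write("set\tn_tumor\tn_normal\ttumor_median\tnormal_median"
                         "\tU\tp\tz\tnote\n")
                for name in sorted(results):
                    r = results[name]
                    if r.test is not None:
                        u, p, z = f"{r.test.u:g}", f"{r.test.p:.6g}", f"{r.test.z:.6g}"
                    else:
                        u = p = z = "NA"
                    fh.write(
                        f"{name}\t{len(r.tumor_means)}\t{len(r.normal_means)}\t"
                        f"{r.tumor_median:.6g}\t{r.normal_median:.6g}\t"
                        f"{u}\t{p}\t{z}\t{r.note}\n"
                    )

        save("cohort_comparison.tsv", write_cohort_cmp)

    # --- manifest ---------------------------------------------------------
    cfg_dict = {
        k: v for k, v in vars(config).items() if k not in ("simulate", "inputs")
    }
    if config.simulate is not None:
        cfg_dict["simulate"] = config.simulate.to_dict()
    if config.inputs is not None:
        cfg_dict["inputs"] = config.inputs
    manifest["config"] = cfg_dict
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
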
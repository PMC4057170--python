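# mbdscape

Downstream analysis of genome-wide binding of MBD2, a methyl-CpG binding
domain protein of the NuRD co-repressor complex. Given binding sites
(ChIP-seq peaks), a base-resolution methylome (per-CpG methylation calls),
gene and CpG-island (CGI) annotations, aligned ChIP tags for a panel of
chromatin marks, per-gene expression, and a tumor/normal methylation
cohort, the package answers the questions an epigenomics analyst asks of
such data:

- **Where does the protein bind?** Hierarchical annotation of sites into
  promoter / exon / intron / intergenic, each split CGI vs non-CGI, with
  enrichment expressed as fold over a matched random null.
- **Is binding driven by methylation?** Coverage-weighted methylation
  levels at sites, methyl-CpG density tracks, and the genome-wide rank
  correlation between density and ChIP enrichment over input.
- **What chromatin contexts does it occupy?** Peak-centred tag-density
  matrices across marks, k-means clustering with merging of mirrored
  clusters (which arise because peak-centred windows ignore transcription
  direction), and TSS/metagene average profiles.
- **How active are the bound genes?** Expression and gene-body-density
  tertiles ("high"/"medium"/"low") with subset-vs-tier comparisons.
- **Is the binding signature cancer-relevant?** Per-patient mean
  methylation at site sets, tumor vs normal, tested with a two-sided
  Mann–Whitney U.

A first-class synthetic-data generator (`mbdscape.synthetic`) emulates all
of these inputs with planted ground truth — hypermethylated CGI peaks, a
"cluster 4" subset of lowly expressed CGI promoters with active marks at
the TSS and MBD2 ~1 kb downstream, and a cohort with elevated tumor
methylation at bound sites only — so every stage can be validated by
parameter recovery.

## Core statistics

- Interval methylation: the coverage-weighted mean
  `m(S) = Σᵢ cᵢ·βᵢ / Σᵢ cᵢ` over CpGs i in site S with methylation
  fraction βᵢ ∈ [0,1] and read coverage cᵢ.
- Methyl-CpG density per window w of length L: `d(w) = Σ_{i∈w} βᵢ / L`
  (methylated-CpG equivalents per bp).
- ChIP enrichment per window: `log2((n_c/N_c + p) / (n_i/N_i + p))` with
  tag counts n, library sizes N and pseudo-frequency
  `p = 0.5 / min(N_c, N_i)`.
- Fold over random per category c:
  `(obs_c/obs_total) / (rand_c/rand_total)` against a length-matched (or
  additionally category-matched) random region set.
- Mann–Whitney U, two-sided, exact by enumeration for small untied
  samples and normal approximation with tie and continuity corrections
  otherwise; p is floored at the smallest positive double, never 0.

All coordinates are 0-based half-open (BED convention) throughout.

## Worked example

```python
import numpy as np
from mbdscape import SyntheticConfig, simulate
from mbdscape.annotation import (annotate_sites, sample_random_lengthmatched,
                                 fold_over_random, AnnotationCategory)
from mbdscape.methylation import (methylation_site_distribution,
                                  mcpg_density_track, enrichment_track,
                                  ranked_density_enrichment)
from mbdscape.profiles import (tag_density_matrix, kmeans_cluster,
                               merge_mirrored, tss_profile)
from mbdscape.cohort import cohort_comparison

data = simulate(SyntheticConfig(seed=42))

dist = methylation_site_distribution(data.truth.peaks, data.methylome)
print(f"sites with methylation in [0.8, 1.0]: "
      f"{100*np.mean((dist.values >= 0.8) & (dist.values <= 1.0)):.1f}%")

obs = annotate_sites(data.truth.peaks, data.genome)
rand = annotate_sites(
    sample_random_lengthmatched(data.truth.peaks, data.genome, seed=42),
    data.genome)
folds = fold_over_random(obs, rand)
cat = AnnotationCategory("promoter", True)
print(f"CGI-promoter sites: {obs[cat]}/{obs.total} "
      f"({folds[cat]:.1f}-fold over random)")

density = mcpg_density_track(data.methylome, data.genome.chrom_sizes, window=1000)
enrich = enrichment_track(data.tracks["MBD2"], data.tracks["input"],
                          data.genome.chrom_sizes, window=1000)
print(f"density/enrichment Spearman rho: "
      f"{ranked_density_enrichment(density, enrich).rho:.3f}")

mats = {name: tag_density_matrix(t, data.truth.peaks, flank=5000, bin=20,
                                 chrom_sizes=data.genome.chrom_sizes)
        for name, t in data.tracks.items()}
merged = merge_mirrored(
    kmeans_cluster(mats, k=5, seed=0, display_only=("H3K27me3", "H3K9me3")),
    mats)
print(f"clusters after mirror merging: {merged.k} "
      f"({len(merged.merge_history)} merges)")

by_id = {g.gene_id: g for g in data.genome.genes}
prof = tss_profile(data.tracks["MBD2"],
                   [by_id[g] for g in data.truth.cluster4_genes],
                   flank=5000, bin=100, chrom_sizes=data.genome.chrom_sizes)
print(f"cluster-4 MBD2 maximum: {prof.max_offset_bp:.0f} bp downstream of the TSS")

res = cohort_comparison(data.cohort,
                        {"cluster4": data.truth.peaks_of_class("cluster4")},
                        random_matrix=data.cohort_random)
print(f"cluster-4 tumor vs normal: p = {res['cluster4'].test.p:.2e}; "
      f"random sites: p = {res['random'].test.p:.2f}")
```

Output:

```
sites with methylation in [0.8, 1.0]: 90.0%
CGI-promoter sites: 125/150 (25.0-fold over random)
density/enrichment Spearman rho: 0.326
clusters after mirror merging: 4 (1 merges)
cluster-4 MBD2 maximum: 950 bp downstream of the TSS
cluster-4 tumor vs normal: p = 1.17e-16; random sites: p = 0.57
```

Reading the numbers: binding concentrates at highly methylated CGI
promoters (90% of sites at 80–100% methylation, 25-fold CGI-promoter
enrichment over random); genome-wide enrichment rises with methyl-CpG
density (positive rank correlation); the five k-means groups collapse to
four once the two mirrored one-sided clusters are merged; that merged
cluster places MBD2 just under 1 kb downstream of the TSS; and in the
cohort, tumor samples are hypermethylated at those sites while a random
region set matched for genomic distribution shows no shift.

The same stages run from the shell (`mbdscape simulate`, `annotate`,
`methylation-at-sites`, `density-track`, `rank-correlation`, `profile`,
`cluster`, `tss-profile`, `metagene`, `stratify`, `cohort`), and
`mbdscape run --config cfg.yaml` executes the whole pipeline into an
output directory with a checksummed `manifest.json`; reruns with the same
config and seed reproduce identical checksums.

## Layout

- `mbdscape.core` — domain types (intervals, gene models, CpG tables, tag
  tracks), BED/BED12/methcounts I/O, interval-tree overlap queries
- `mbdscape.synthetic` — the generator and its planted ground truth
- `mbdscape.annotation` — hierarchical classification, random nulls, folds
- `mbdscape.methylation` — interval methylation, density/enrichment
  window tracks, ranked correlation
- `mbdscape.profiles` — tag-density matrices, clustering, mirror merging,
  TSS/metagene/methylation profiles
- `mbdscape.stratification` — RPKM, tertiles, gene-body densities
- `mbdscape.cohort` — beta-value matrices, Mann–Whitney U, comparisons
- `mbdscape.pipeline` — end-to-end orchestration with manifest
- `docs/methods.md` — model, parameter and design documentation
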
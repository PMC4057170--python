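# Methods

## Scope and data model

The package analyses genome-wide binding of a methyl-CpG reader (MBD2)
around five questions: genomic distribution of binding sites, their
relationship to DNA methylation, their chromatin-mark context, the
transcriptional state of the bound genes, and the behaviour of the bound
loci in a tumor/normal methylation cohort. It operates on five in-memory
containers: located intervals (`GenomicInterval`), gene models with exon
structure (`GeneModel`), an indexed per-CpG methylome (`CpGTable`),
aligned-read 5' positions per track (`TagTrack`), and a samples × sites
beta-value matrix with group labels (`CohortMatrix`).

All coordinates are 0-based half-open, in every module and every file
dialect; overlap means sharing at least one base. Chromosome names match
by exact string equality. These conventions are deliberate: they are
BED-native, they remove every off-by-one ambiguity, and they make the
brute-force oracles in the test suite trivially comparable to the indexed
implementations.

## Annotation

Each site receives one of four features in a fixed hierarchy — promoter,
exon, intron, intergenic — and, independently, a CGI flag:

- promoter: overlap with any TSS ± 1000 bp window (half-open
  `[tss-1000, tss+1000)`), strand entering only through the TSS
  definition (transcript start on `+`, `tx_end − 1` on `−`). Windows are
  not clipped at the transcript boundaries of short genes; for a 1 kb
  window and genes ≥ 2 kb this cannot create gaps, and unclipped windows
  keep the rule stateless.
- exon: overlap with any annotated exon of any gene;
- intron: within a transcript span but matched by neither rule above;
- intergenic: otherwise.

A site overlapping the promoter windows of two genes still counts once —
the unit of counting is the category, so the eight categories always
partition the site set. The CGI flag is evaluated against all CpG islands
regardless of the feature outcome.

Two random nulls are provided. The *length-matched* null draws, per
observed site, a length (with replacement) from the empirical site-length
distribution and places it uniformly, chromosomes weighted by length;
start positions are drawn so the interval always fits, which is
equivalent to redrawing clipped intervals. The *distribution-matched*
null additionally rejection-samples until the per-category counts equal
the observed ones (budget of 10⁶ attempts per category, after which the
unreachable category is named in the error). Fold over random is the
ratio of category shares; a category present in the observed but absent
in the random set reports +inf, and 0/0 reports NaN rather than raising.
Random placement ignores assembly gaps and mappability — synthetic
genomes have neither, and for real genomes an optional blacklist would be
the appropriate extension (not implemented; see limitations).

## Methylation

Site-level methylation is the coverage-weighted mean of per-CpG
fractions, with a configurable coverage floor (default `min_coverage=1`:
deep whole-genome bisulfite data needs no floor, and keeping every call
preserves the split/recombine identity tested in the suite). A site with
no qualifying CpG is *undefined* — a value, not an error — and excluded
with a count from distribution summaries.

Methyl-CpG density over a window is the sum of methylation fractions
divided by window length, in methylated-CpG equivalents per bp; the unit
choice (per bp rather than per window) is documented here because the
verbal definition of "normalized by length" leaves it open. Windows tile
each chromosome from zero; the last partial window is dropped rather than
rescaled so the constant-length normalization stays exact. Enrichment per
window is `log2((n_chip/N_chip + p)/(n_input/N_input + p))` with
`p = 0.5/min(N_chip, N_input)` so empty windows stay finite; tags are
assigned to windows by their 5' position. The ranked
density-vs-enrichment curve sorts windows ascending by density (ties
broken by genomic order via a stable sort), smooths enrichment with a
running mean over `ceil(N/n_points)` windows and reports Spearman's rho
over all windows; a constant vector is defined to have rho = 0 (the
correlation is otherwise undefined and the flat curve carries the same
message).

## Profiles and clustering

Tag-density matrices count tag 5' ends per bin in anchor-centred windows
(anchor = interval midpoint), scaled to reads per 10 million mapped — an
arbitrary but fixed unit; a normalization-invariance test guarantees the
constant is immaterial. Anchors whose window would cross a chromosome
edge are dropped and counted. Heatmap-resolution matrices default to
20-bp bins; averaged profiles (TSS, metagene, methylation/CpG) use 100-bp
bins. Strand-aware matrices reverse the rows of minus-strand anchors so
bin 0 is always the most upstream bin in the anchor's frame.

Clustering runs Lloyd's k-means (k-means++ seeding, 20 restarts, fixed
seed) on the concatenation of per-mark matrices. Three per-mark
transformations precede concatenation, and each is a deliberate choice:

1. a 5-bin running mean (100 bp at 20-bp bins) suppresses shot noise
   without moving kernel-scale structure;
2. scaling to unit 95th percentile equalizes sequencing depth across
   marks;
3. winsorizing at 2 after scaling bounds the influence of any one mark.
   Without the clip, a mark with signal at only a minority of anchors has
   its 95th percentile at background level, the scaling then inflates its
   signal bins by an order of magnitude, and k-means spends all its
   clusters on substructure of that one mark.

Marks can be designated display-only (repressive marks and methylation
analogues by default): they are excluded from the feature vector but
still receive per-cluster mean profiles, and a test asserts they never
change the assignment.

Peak-centred matrices ignore transcription direction, so any
direction-coupled signal (active marks on the TSS side of the binding
site) produces *mirrored* cluster pairs. `merge_mirrored` compares every
cluster pair by the Pearson correlation between one cluster's mean
feature profile and the bin-reversed mean of the other, computed over the
concatenated participating marks in the clustering feature space — so
marks with structure dominate and flat noise tracks cannot dilute the
signal. A pair merges only if the mirror correlation exceeds the
threshold (default 0.8) *and* exceeds the un-reversed correlation by a
margin (default 0.1): for genuinely mirrored asymmetric profiles the
direct correlation is low, while two merely similar symmetric clusters
have mirror ≈ direct and are left apart. Merged rows are flagged
"reversed orientation" and re-oriented when means are recomputed, and the
search repeats best-first to closure. k defaults to 5 before merging with
the threshold as a config key; the synthetic default data then typically
collapses to 4 clusters by one merge of the two one-sided orientations.

## Stratification

RPKM = count / (gene length in kb × library size in millions), computed
from uniquely mapped totals. Gene tiers rank eligible genes (default:
value > 0, i.e. "expressed") descending and split them into three
equal-size bins, remainders going to the top tiers (10 genes → 4/3/3) and
ties broken by stable gene-id order — both rules exist purely for
determinism. Gene-body densities divide tag counts (or summed CpG
methylation fractions) over `[tx_start, tx_end)` by gene length. Subset
comparisons report five-number summaries side by side and the tier whose
median is nearest the subset's.

## Cohort

Per-sample means at a site set ignore missing beta values (standard for
array-style matrices; no imputation); samples missing every subset site
are dropped with a log count. The tumor/normal test is a two-sided
Mann–Whitney U with midrank ties: exact by enumeration when
n₁+n₂ ≤ 16 with no ties, otherwise normal approximation with tie and
continuity corrections (both paths delegated to `scipy.stats`, validated
in the suite against an independent full-enumeration oracle). The
p-value is floored at the smallest positive double and the tie-corrected
z statistic is reported alongside it, because p-values at display floors
(such as the conventional 2.2e-16) carry no magnitude information of
their own. Groups with fewer than two samples produce summaries plus an
"underpowered" note instead of a test.

## Synthetic data: what it emulates, and what it does not

The generator plants, at desk scale, the statistical structures the
analysis is meant to recover. Defaults (the shipped study conditions):
2 chromosomes × 5 Mb, 300 non-overlapping genes (2–20 kb, 2–8 exons,
alternating strands, ≥3 kb intergenic gaps so CGIs cannot stray into a
neighbour's promoter window), promoter CGIs at 80% of genes and exonic
CGIs at 25% (300–1500 bp), 60% of CGIs hypermethylated. CpGs are placed
by a Poisson process at 1 per ~10 bp inside CGIs and 1 per ~100 bp
outside; methylation fractions are Beta(20,2) in hypermethylated CGIs,
Beta(1,20) in other CGIs, Beta(5,5) in the background; coverage is
Poisson(30).

150 binding sites are planted in four classes: 40 "cluster 4" sites at
TSS + Normal(1000, 150) bp into the gene body (strand-aware) of genes
whose promoter CGI is asymmetric — 100 bp upstream to 1400 bp downstream
of the TSS, always hypermethylated — so the displaced site still sits on
methylated, CpG-dense sequence; 85 sites centred on hypermethylated
promoter CGIs; 10 on hypermethylated exonic CGIs; 15 on CGI-free
background. Overall 90% of sites sit on hypermethylated CGIs.

Tags: every track carries homogeneous Poisson background at 0.01 tags/bp.
MBD2 adds a 400-bp triangular kernel per site with area
`rate × fold × width/2` (fold 15; exon and background sites bind at 0.5×
and 0.2× of that amplitude, mimicking the weaker signal density of
non-promoter classes) plus a genome-wide reader component of
Poisson(coupling × β) tags per CpG (coupling 1.0), which is what makes
enrichment track methylation density *away* from called peaks. Active
marks (Pol2, H3K4me3, H2A.Zac, H3K27ac, P300) add TSS-centred kernels at
cluster-4 genes only, with a 1.5-kb support reflecting the broad domains
these marks occupy at promoters. H3K36me3 adds uniform gene-body tags
scaled by expression tier (0.5×/1.5×/3×). H3K27me3 and H3K9me3 are pure
background. Expression is log-normal with cluster-4 genes redrawn
uniformly between the global 20th and 60th percentiles (low-to-medium).
The cohort (100 tumor / 30 normal) adds Normal(0, 0.02) noise per
sample-site to the site's methylome level, plus a +0.05 shift in tumor
samples, clipped to [0,1]; the companion random-site matrix applies the
shift to no site. The triangular kernel (rather than Gaussian) was
chosen because its finite support makes expected-count oracles exact; one
global seed fans out to an independent stream per generator and per
track, so regenerating one output never perturbs another.

Not emulated: read-level bisulfite chemistry and conversion errors,
nucleotide sequence, fragment-size and mappability structure, copy-number
and purity effects in the cohort, correlated noise between marks, and
biological replicate variation. Passing recovery tests therefore
demonstrates that the analysis code extracts planted structure correctly
at realistic magnitudes — not that it is robust to every artefact of real
libraries.

## Numerical and degenerate-input conventions

Quantiles use linear interpolation between order statistics everywhere
(the numpy default), fixed so cross-implementation tests are exact.
Undefined site methylation is a counted exclusion; an all-undefined site
set is an error. Constant vectors give rho = 0; identical pooled MWU
groups give p = 1; rand=0 folds give ±inf/NaN flags. Ties are always
broken by a stable, documented order (genomic position for window
ranking, gene id for tier ranking). The pipeline writes a manifest with a
SHA-256 checksum per output file; determinism under a fixed config and
seed is asserted end-to-end in the suite.

## Problem sizes

The shipped defaults (10 Mb genome, ~126k CpGs, ~100–165k tags per
track, 150 sites, 130 cohort samples) generate in about two seconds and
run the full pipeline in under a minute on one CPU; they were chosen as
the smallest scale at which every planted structure is recoverable with
comfortable statistical margins, and all tests and the acceptance script
run at this scale.

## Known limitations

- Real-input mode identifies cluster-4-like genes by mapping anchors of
  the mirror-merged cluster to TSSs within 2 kb; with few tracks or no
  mirrored pair it returns an empty set and the dependent stages are
  skipped.
- The distribution-matched null can be slow or unreachable when a
  category's genomic share is tiny; the attempt budget and per-category
  error make this explicit rather than silent.
- No mappability/blacklist handling in random placement.
- One transcript model per gene id; no isoforms.
- bedGraph is the only track export (no bigWig).
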
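"""Synthetic-data generator: planted structure, determinism and calibration."""

import numpy as np
import pytest

from mbdscape.annotation import PROMOTER_HALF_WINDOW
from mbdscape.core import GenomicInterval
from mbdscape.methylation import interval_methylation
from mbdscape.synthetic import (
    CLASS_BACKGROUND,
    CLASS_CGI_EXON,
    CLASS_CLUSTER4,
    CLASS_HYPER_PROMOTER,
    SyntheticConfig,
    generate_chip_tags,
    generate_cohort,
    generate_expression,
    generate_genome,
    generate_methylome,
    plant_sites,
    simulate,
)


def _cfg(**kw):
    base = dict(seed=1, n_genes=100, n_peaks=40, n_cluster4=10,
                cohort_n_tumor=10, cohort_n_normal=5)
    base.update(kw)
    return SyntheticConfig(**base)


class TestGenome:
    def test_seeded_determinism(self):
        a = generate_genome(_cfg())
        b = generate_genome(_cfg())
        assert a.genes == b.genes
        assert a.cgis == b.cgis
        assert a.cgi_hyper == b.cgi_hyper

    def test_no_promoter_cgi_when_fraction_zero(self):
        genome = generate_genome(_cfg(cgi_promoter_fraction=0.0, n_cluster4=0))
        windows = []
        for g in genome.genes:
            windows.append(
                (g.chrom, max(0, g.tss - PROMOTER_HALF_WINDOW),
                 g.tss + PROMOTER_HALF_WINDOW)
            )
        for cgi in genome.cgis:
            for chrom, lo, hi in windows:
                assert not (cgi.chrom == chrom and cgi.start < hi and lo < cgi.end)

    def test_promoter_cgi_count_binomial(self):
        genome = generate_genome(
            SyntheticConfig(seed=3, n_genes=200, cgi_promoter_fraction=0.5,
                            n_cluster4=0)
        )
        n_prom = sum(1 for c in genome.cgis if c.name.startswith("CGI:promoter"))
        assert 90 <= n_prom <= 110  # 100 +/- 10

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="infeasible packing"):
            generate_genome(
                SyntheticConfig(seed=1, n_chroms=1, chrom_length=200_000,
                                n_genes=100, n_cluster4=0)
            )

    def test_genes_non_overlapping_within_bounds(self):
        genome = generate_genome(_cfg())
        by_chrom = {}
        for g in genome.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
            assert 0 <= g.tx_start < g.tx_end <= genome.chrom_sizes[g.chrom]
            assert 2 <= len(g.exons) <= 8
            assert 2000 <= g.length <= 20000
        for glist in by_chrom.values():
            glist.sort(key=lambda g: g.tx_start)
            for a, b in zip(glist, glist[1:]):
                assert a.tx_end <= b.tx_start


@pytest.fixture(scope="module")
def genome_and_cpgs():
    cfg = _cfg()
    genome = generate_genome(cfg)
    return cfg, genome, generate_methylome(genome, cfg)


class TestMethylome:

    def test_unmethylated_cgi_mean_matches_beta(self, genome_and_cpgs):
        cfg, genome, cpgs = genome_and_cpgs
        vals = []
        for cgi, hyper in zip(genome.cgis, genome.cgi_hyper):
            if hyper:
                continue
            _, meth, _ = cpgs.fetch(cgi.chrom, cgi.start, cgi.end)
            vals.extend(meth.tolist())
        a, b = cfg.meth_cgi_unmeth_dist
        assert np.mean(vals) == pytest.approx(a / (a + b), abs=0.01)  # ~0.048

    def test_hyper_cgi_mean_matches_beta(self, genome_and_cpgs):
        cfg, genome, cpgs = genome_and_cpgs
        vals = []
        for cgi, hyper in zip(genome.cgis, genome.cgi_hyper):
            if hyper:
                _, meth, _ = cpgs.fetch(cgi.chrom, cgi.start, cgi.end)
                vals.extend(meth.tolist())
        a, b = cfg.meth_cgi_hyper_dist
        assert np.mean(vals) == pytest.approx(a / (a + b), abs=0.01)

    def test_global_mean_between_component_means(self, genome_and_cpgs):
        cfg, genome, cpgs = genome_and_cpgs
        all_meth = np.concatenate(
            [cpgs.fetch(c, 0, genome.chrom_sizes[c])[1] for c in cpgs.chroms]
        )
        lo = cfg.meth_cgi_unmeth_dist[0] / sum(cfg.meth_cgi_unmeth_dist)
        hi = cfg.meth_cgi_hyper_dist[0] / sum(cfg.meth_cgi_hyper_dist)
        assert lo < all_meth.mean() < hi

    def test_cgi_density_elevated(self, genome_and_cpgs):
        cfg, genome, cpgs = genome_and_cpgs
        cgi_bp = sum(c.length for c in genome.cgis)
        cgi_n = sum(
            len(cpgs.fetch(c.chrom, c.start, c.end)[0]) for c in genome.cgis
        )
        genome_bp = sum(genome.chrom_sizes.values())
        assert cgi_n / cgi_bp > 3 * (len(cpgs) / genome_bp)


class TestSites:
    def test_class_balance_matches_config(self):
        cfg = _cfg()
        truth = plant_sites(generate_genome(cfg), cfg)
        counts = {
            cls: truth.peak_classes.count(cls)
            for cls in (CLASS_CLUSTER4, CLASS_HYPER_PROMOTER,
                        CLASS_CGI_EXON, CLASS_BACKGROUND)
        }
        n_hyper = round(cfg.frac_peaks_hypermeth * cfg.n_peaks)
        assert counts[CLASS_CLUSTER4] == cfg.n_cluster4
        assert counts[CLASS_BACKGROUND] == cfg.n_peaks - n_hyper
        assert sum(counts.values()) == cfg.n_peaks
        assert len(truth.peaks) == cfg.n_peaks

    def test_hypermeth_fraction_raises_peak_methylation(self):
        # monotonicity over three seeds: more peaks on hypermethylated CGIs
        # means higher mean interval methylation of the peak set
        for seed in (1, 2, 3):
            means = []
            for frac in (0.3, 0.9):
                cfg = _cfg(seed=seed, frac_peaks_hypermeth=frac)
                genome = generate_genome(cfg)
                cpgs = generate_methylome(genome, cfg)
                truth = plant_sites(genome, cfg)
                levels = [
                    interval_methylation(p, cpgs)
                    for p in truth.peaks
                ]
                means.append(np.mean([x for x in levels if x is not None]))
            assert means[1] > means[0]


class TestChipTags:
    def test_kernel_area_expected_tags(self):
        # one planted promoter peak, fold 20, background 0.01/bp:
        # expected extra tags under the 400-bp kernel = 0.01*20*200 = 40
        cfg = _cfg(n_peaks=1, n_cluster4=0, frac_peaks_hypermeth=1.0,
                   frac_hyper_exon=0.0, peak_fold=20.0, mbd2_meth_coupling=0.0)
        genome = generate_genome(cfg)
        cpgs = generate_methylome(genome, cfg)
        tracks, truth = generate_chip_tags(genome, cpgs, cfg)
        (peak,) = truth.peaks
        center = peak.center
        got = tracks["MBD2"].count_in(peak.chrom, center - 200, center + 200)
        background = cfg.tag_background_rate * 400
        extra = got - background
        assert extra == pytest.approx(40, abs=4 * np.sqrt(40 + background))

    def test_null_fold_indistinguishable_from_input(self):
        cfg = _cfg(peak_fold=1.0, mbd2_meth_coupling=0.0)
        genome = generate_genome(cfg)
        cpgs = generate_methylome(genome, cfg)
        tracks, _ = generate_chip_tags(genome, cpgs, cfg)
        n1, n2 = tracks["MBD2"].n_tags, tracks["input"].n_tags
        # two-sample Poisson rate test at alpha=0.01
        z = (n1 - n2) / np.sqrt(n1 + n2)
        assert abs(z) < 2.58

    def test_seeded_determinism(self):
        cfg = _cfg()
        genome = generate_genome(cfg)
        cpgs = generate_methylome(genome, cfg)
        t1, _ = generate_chip_tags(genome, cpgs, cfg)
        t2, _ = generate_chip_tags(genome, cpgs, cfg)
        for name in t1:
            for chrom in t1[name].chroms:
                assert np.array_equal(
                    t1[name].positions(chrom), t2[name].positions(chrom)
                )


class TestExpression:
    def test_cluster4_genes_within_band(self):
        cfg = _cfg()
        genome = generate_genome(cfg)
        rpkm = generate_expression(genome, cfg)
        lo, hi = rpkm.attrs["cluster4_band"]
        truth = plant_sites(genome, cfg)
        for gid in truth.cluster4_genes:
            assert lo <= rpkm[gid] <= hi

    def test_cluster4_median_below_high_tertile(self):
        from mbdscape.stratification import tertile_bins

        cfg = _cfg()
        genome = generate_genome(cfg)
        rpkm = generate_expression(genome, cfg)
        truth = plant_sites(genome, cfg)
        tiers = tertile_bins(rpkm)
        high_median = rpkm[tiers.index[tiers == "high"]].median()
        assert rpkm[truth.cluster4_genes].median() < high_median


class TestCohort:
    def test_planted_gap_near_delta(self, genome_and_cpgs):
        cfg, genome, cpgs = genome_and_cpgs
        truth = plant_sites(genome, cfg)
        mat = generate_cohort(truth.peaks, cpgs, cfg)
        tumor = mat.values[mat.sample_mask("tumor")]
        normal = mat.values[mat.sample_mask("normal")]
        # peaks sit near methylation 0.9, so the +delta shift is partially
        # clipped at 1.0; the observed gap is positive and bounded by delta
        gap = np.nanmean(tumor) - np.nanmean(normal)
        assert 0.0 < gap <= cfg.cohort_effect_delta + 0.01

    def test_unclipped_gap_matches_delta(self, genome_and_cpgs):
        cfg, genome, cpgs = genome_and_cpgs
        # mid-methylated random sites leave room for the full +delta shift
        sites = [
            GenomicInterval("chr1", s, s + 500)
            for s in range(100_000, 400_000, 6_000)
        ]
        mat = generate_cohort(sites, cpgs, cfg)
        gap = (np.nanmean(mat.values[mat.sample_mask("tumor")])
               - np.nanmean(mat.values[mat.sample_mask("normal")]))
        assert gap == pytest.approx(cfg.cohort_effect_delta, abs=0.01)

    def test_values_clipped_to_unit_interval(self, genome_and_cpgs):
        cfg, genome, cpgs = genome_and_cpgs
        cfg2 = _cfg(cohort_effect_delta=0.5, cohort_noise_sd=0.3)
        truth = plant_sites(genome, cfg)
        mat = generate_cohort(truth.peaks, cpgs, cfg2)
        assert np.nanmax(mat.values) <= 1.0
        assert np.nanmin(mat.values) >= 0.0

    def test_no_effect_when_delta_zero(self, genome_and_cpgs):
        cfg, genome, cpgs = genome_and_cpgs
        truth = plant_sites(genome, cfg)
        mat = generate_cohort(truth.peaks, cpgs, _cfg(cohort_effect_delta=0.0))
        gap = (np.nanmean(mat.values[mat.sample_mask("tumor")])
               - np.nanmean(mat.values[mat.sample_mask("normal")]))
        assert abs(gap) < 0.01


class TestSimulate:
    def test_full_determinism(self, small_config, small_dataset):
        other = simulate(small_config)
        assert other.truth.peaks == small_dataset.truth.peaks
        assert other.expression.equals(small_dataset.expression)
        assert np.array_equal(other.cohort.values, small_dataset.cohort.values)
        for name in other.tracks:
            for chrom in other.tracks[name].chroms:
                assert np.array_equal(
                    other.tracks[name].positions(chrom),
                    small_dataset.tracks[name].positions(chrom),
                )

    def test_random_sites_match_peak_distribution(self, small_dataset):
        from mbdscape.annotation import annotate_sites

        obs = annotate_sites(small_dataset.truth.peaks, small_dataset.genome)
        rand = annotate_sites(small_dataset.random_sites, small_dataset.genome)
        assert obs.counts == rand.counts
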
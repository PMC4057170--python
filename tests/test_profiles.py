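"""Tag-density matrices, k-means + mirror merging, TSS/metagene profiles."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mbdscape.core import CpGRecord, CpGTable, GeneModel, GenomicInterval, TagTrack
from mbdscape.profiles import (
    ProfileMatrix,
    average_profile,
    kmeans_cluster,
    merge_mirrored,
    metagene_profile,
    methylation_cpg_profile,
    tag_density_matrix,
    tss_profile,
)


def anchors_at(centers, chrom="chr1", strand="."):
    return [GenomicInterval(chrom, c - 50, c + 50, strand) for c in centers]


class TestTagDensityMatrix:
    def test_no_tags_zero_matrix(self):
        pm = tag_density_matrix(TagTrack("t", []), anchors_at([10_000]), 1000, 100)
        assert pm.matrix.shape == (1, 20)
        assert not pm.matrix.any()

    def test_tag_at_center_lands_in_first_downstream_bin(self):
        track = TagTrack("t", [("chr1", 10_000, "+")])
        pm = tag_density_matrix(track, anchors_at([10_000]), 5000, 20)
        assert pm.matrix.shape == (1, 500)
        assert np.flatnonzero(pm.matrix[0]).tolist() == [250]

    def test_bin_must_divide_window(self):
        with pytest.raises(ValueError):
            tag_density_matrix(TagTrack("t", []), anchors_at([10_000]), 1000, 300)

    def test_edge_anchors_dropped(self):
        pm = tag_density_matrix(
            TagTrack("t", []), anchors_at([400, 10_000]), 1000, 100,
            chrom_sizes={"chr1": 10_500},
        )
        assert pm.n_dropped == 2  # one near each edge
        assert pm.matrix.shape[0] == 0

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(5)
        tags = [("chr1", int(p), "+") for p in rng.integers(0, 50_000, 2000)]
        track = TagTrack("t", tags)
        centers = [5_000, 12_345, 30_001]
        flank, bin_ = 2000, 100
        pm = tag_density_matrix(track, anchors_at(centers), flank, bin_)
        scale = 1e7 / track.total_mapped
        for row, center in zip(pm.matrix, centers):
            for b in range(2 * flank // bin_):
                lo = center - flank + b * bin_
                expected = sum(1 for _, p, _ in tags if lo <= p < lo + bin_)
                assert row[b] == pytest.approx(expected * scale)

    def test_matrix_total_equals_window_tags_times_norm(self):
        rng = np.random.default_rng(6)
        tags = [("chr1", int(p), "+") for p in rng.integers(0, 100_000, 5000)]
        track = TagTrack("t", tags)
        centers = [20_000, 21_000, 70_000]  # first two windows overlap
        pm = tag_density_matrix(track, anchors_at(centers), 5000, 100)
        in_windows = sum(
            track.count_in("chr1", c - 5000, c + 5000) for c in centers
        )
        assert pm.matrix.sum() == pytest.approx(in_windows * 1e7 / track.total_mapped)

    def test_normalization_invariance_under_duplication(self):
        tags = [("chr1", int(p), "+") for p in range(9_000, 11_000, 13)]
        t1 = TagTrack("t", tags)
        t2 = TagTrack("t", tags * 2)
        a = tag_density_matrix(t1, anchors_at([10_000]), 1000, 100)
        b = tag_density_matrix(t2, anchors_at([10_000]), 1000, 100)
        assert np.allclose(a.matrix, b.matrix)

    def test_strand_aware_row_reversal(self):
        track = TagTrack("t", [("chr1", 10_300, "+")])
        plus = tag_density_matrix(
            track, anchors_at([10_000], strand="+"), 1000, 100, strand_aware=True
        )
        minus = tag_density_matrix(
            track, anchors_at([10_000], strand="-"), 1000, 100, strand_aware=True
        )
        assert np.flatnonzero(plus.matrix[0]).tolist() == [13]
        assert np.flatnonzero(minus.matrix[0]).tolist() == [6]  # mirrored


def make_matrix(rows, name="m", flank=1000, bin_=100):
    n = len(rows)
    anchors = anchors_at(list(range(5000, 5000 + 10_000 * n, 10_000)))
    return ProfileMatrix(name, anchors, flank, bin_, np.asarray(rows, float))


def bump(center, width, nbins=20, height=10.0):
    x = np.arange(nbins)
    return height * np.exp(-0.5 * ((x - center) / width) ** 2)


class TestKmeans:
    def test_recovers_planted_archetypes(self):
        rng = np.random.default_rng(0)
        a = bump(10, 2)
        b = np.full(20, 4.0)
        rows = [a + rng.normal(0, 0.4, 20) for _ in range(30)] + [
            b + rng.normal(0, 0.4, 20) for _ in range(30)
        ]
        truth = [0] * 30 + [1] * 30
        asg = kmeans_cluster({"m": make_matrix(rows)}, k=2, seed=1)
        assert adjusted_rand_score(truth, asg.labels) >= 0.95

    def test_k1_mean_is_column_mean(self):
        rows = np.random.default_rng(1).random((10, 20))
        asg = kmeans_cluster({"m": make_matrix(rows)}, k=1, seed=0,
                             smooth_bins=1, clip=None)
        assert np.all(asg.labels == 1)
        assert np.allclose(asg.cluster_means["m"][0], rows.mean(axis=0))

    def test_same_seed_identical(self):
        rows = np.random.default_rng(2).random((40, 20))
        m = {"m": make_matrix(rows)}
        a = kmeans_cluster(m, k=3, seed=9)
        b = kmeans_cluster(m, k=3, seed=9)
        assert np.array_equal(a.labels, b.labels)

    def test_k_exceeding_anchors_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster({"m": make_matrix(np.ones((3, 20)))}, k=5, seed=0)

    def test_display_only_marks_do_not_change_assignment(self, default_dataset):
        data = default_dataset
        mats = {
            n: tag_density_matrix(t, data.truth.peaks, 5000, 20,
                                  chrom_sizes=data.genome.chrom_sizes)
            for n, t in data.tracks.items()
        }
        display = ("H3K27me3", "H3K9me3")
        with_display = kmeans_cluster(mats, 5, seed=0, display_only=display)
        without = kmeans_cluster(
            {n: m for n, m in mats.items() if n not in display}, 5, seed=0
        )
        assert np.array_equal(with_display.labels, without.labels)

    def test_cluster4_recovery_on_default_data(self, default_dataset):
        data = default_dataset
        mats = {
            n: tag_density_matrix(t, data.truth.peaks, 5000, 20,
                                  chrom_sizes=data.genome.chrom_sizes)
            for n, t in data.tracks.items()
        }
        asg = kmeans_cluster(mats, 5, seed=0,
                             display_only=("H3K27me3", "H3K9me3"))
        merged = merge_mirrored(asg, mats, 0.8)
        truth = np.array(data.truth.peak_classes) == "cluster4"
        labels = merged.labels
        best = max(set(labels.tolist()),
                   key=lambda c: (labels == c)[truth].sum())
        assert adjusted_rand_score(truth, labels == best) >= 0.8


class TestMergeMirrored:
    def _clustered(self, groups, k, seed=3):
        rng = np.random.default_rng(seed)
        rows, truth = [], []
        for gi, base in enumerate(groups):
            for _ in range(20):
                rows.append(base + rng.normal(0, 0.3, len(base)))
                truth.append(gi)
        m = {"m": make_matrix(rows)}
        return kmeans_cluster(m, k=k, seed=0, smooth_bins=1, clip=None), m, truth

    def test_exact_mirror_pair_merged(self):
        left = bump(5, 1.5)
        asg, m, truth = self._clustered([left, left[::-1]], k=2)
        merged = merge_mirrored(asg, m, threshold=0.8)
        assert merged.k == 1
        assert len(merged.merge_history) == 1
        assert merged.reversed_rows.sum() == 20

    def test_symmetric_profiles_not_merged(self):
        # two distinct symmetric archetypes: mirror image equals the
        # profile itself, so mirrors carry no extra evidence
        center_tall = bump(9.5, 2, height=10)
        center_wide = bump(9.5, 5, height=3)
        asg, m, _ = self._clustered([center_tall, center_wide], k=2)
        merged = merge_mirrored(asg, m, threshold=0.8)
        assert merged.k == 2
        assert merged.merge_history == []

    def test_mirror_pair_among_distinct_clusters(self):
        groups = [bump(5, 1.5), bump(5, 1.5)[::-1], bump(9.5, 3, height=20),
                  np.full(20, 1.0)]
        asg, m, truth = self._clustered(groups, k=4)
        merged = merge_mirrored(asg, m, threshold=0.8)
        assert merged.k == 3
        assert len(merged.merge_history) == 1
        # the merged cluster holds exactly the mirror-pair members
        labels = merged.labels
        pair = np.array(truth) < 2
        merged_cluster = labels[merged.reversed_rows][0]
        assert np.array_equal(labels == merged_cluster, pair)


class TestAverageProfile:
    def test_single_member(self):
        rows = np.arange(20.0).reshape(1, 20)
        res = average_profile(make_matrix(rows))
        assert np.allclose(res.mean, rows[0])
        assert np.allclose(res.p50, rows[0])
        assert np.allclose(res.p90, rows[0])

    def test_mean_of_zero_and_two_rows(self):
        rows = np.vstack([np.zeros(20), np.full(20, 2.0)])
        res = average_profile(make_matrix(rows))
        assert np.allclose(res.mean, 1.0)

    def test_percentiles_match_numpy_oracle(self):
        rows = np.random.default_rng(7).random((25, 20))
        res = average_profile(make_matrix(rows), members=range(25))
        assert np.allclose(res.p50, np.percentile(rows, 50, axis=0))
        assert np.allclose(res.p90, np.percentile(rows, 90, axis=0))

    def test_empty_member_set_rejected(self):
        with pytest.raises(ValueError):
            average_profile(make_matrix(np.ones((4, 20))), members=[])


def uniform_track(rng, length, rate, chrom="chr1"):
    n = rng.poisson(rate * length)
    return TagTrack.from_arrays(
        "t", {chrom: rng.integers(0, length, n).astype(np.int64)}
    )


class TestTssProfile:
    def test_cluster4_mbd2_peaks_downstream(self, default_dataset):
        data = default_dataset
        by_id = {g.gene_id: g for g in data.genome.genes}
        c4 = [by_id[g] for g in data.truth.cluster4_genes]
        res = tss_profile(data.tracks["MBD2"], c4, 5000, 100,
                          chrom_sizes=data.genome.chrom_sizes)
        assert res.max_offset_bp == pytest.approx(1000, abs=200)

    def test_minus_strand_tag_counted_upstream(self):
        gene = GeneModel("g", "chr1", "-", 20_000, 30_000,
                         (GenomicInterval("chr1", 20_000, 30_000, "-"),))
        # 500 bp 5' of the TSS (29_999) on a minus gene = genomic 30_499
        track = TagTrack("t", [("chr1", 30_499, "+")])
        res = tss_profile(track, [gene], 5000, 100)
        assert res.bin_offsets[np.argmax(res.profile)] < 0

    def test_uniform_background_flat(self):
        rng = np.random.default_rng(12)
        track = uniform_track(rng, 3_000_000, rate=0.05)
        genes = [
            GeneModel(f"g{i}", "chr1", "+", s, s + 5_000,
                      (GenomicInterval("chr1", s, s + 5_000, "+"),))
            for i, s in enumerate(range(10_000, 2_900_000, 14_000))
        ]
        res = tss_profile(track, genes, 5000, 100)
        assert res.profile.max() / res.profile.min() < 1.5


class TestMetagene:
    def _genes(self, length, n=30, spacing=30_000):
        return [
            GeneModel(f"g{i}", "chr1", "+", s, s + length,
                      (GenomicInterval("chr1", s, s + length, "+"),))
            for i, s in enumerate(range(10_000, 10_000 + spacing * n, spacing))
        ]

    def test_no_qualifying_genes_is_error(self):
        with pytest.raises(ValueError):
            metagene_profile(TagTrack("t", []), self._genes(3_000),
                             anchor_flank=2000, min_gene_length=4000)

    def test_short_flank_constraint(self):
        with pytest.raises(ValueError):
            metagene_profile(TagTrack("t", []), self._genes(6_000),
                             anchor_flank=3000, min_gene_length=4000)

    def test_excluded_count(self):
        genes = self._genes(6_000) + self._genes(3_000, n=5, spacing=31_000)
        rng = np.random.default_rng(3)
        track = uniform_track(rng, 2_000_000, 0.01)
        res = metagene_profile(track, genes, 2000, 4000)
        assert res.n_excluded == 5
        assert res.n_genes == 30

    def test_uniform_gene_body_steps_down_after_tes(self):
        genes = self._genes(6_000)
        rng = np.random.default_rng(4)
        parts = [rng.integers(g.tx_start, g.tx_end, 600) for g in genes]
        track = TagTrack.from_arrays(
            "t", {"chr1": np.concatenate(parts).astype(np.int64)}
        )
        res = metagene_profile(track, genes, 2000, 4000)
        inside = res.tes_profile[:20].mean()   # bins before the TES
        outside = res.tes_profile[20:].mean()  # bins after the TES
        assert outside < 0.2 * inside


class TestMethylationCpGProfile:
    def test_uniform_methylome_flat(self):
        cpgs = CpGTable([CpGRecord("chr1", p, 0.8, 10)
                         for p in range(100, 30_000, 50)])
        res = methylation_cpg_profile(cpgs, anchors_at([15_000]), 5000, 100)
        vals = res.methylation[np.isfinite(res.methylation)]
        assert np.allclose(vals, 0.8)

    def test_density_zero_outside_cpg_region(self):
        cpgs = CpGTable([CpGRecord("chr1", p, 0.5, 10)
                         for p in range(14_900, 15_100, 10)])
        res = methylation_cpg_profile(cpgs, anchors_at([15_000]), 5000, 100)
        center = res.cpg_density[np.abs(res.bin_offsets) < 100]
        flanks = res.cpg_density[np.abs(res.bin_offsets) > 1000]
        assert center.sum() > 0
        assert not flanks.any()
        assert np.isnan(res.methylation[np.abs(res.bin_offsets) > 1000]).all()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(40_000, 800, replace=False))
        meth = rng.random(800)
        cpgs = CpGTable([CpGRecord("chr1", int(p), float(m), 10)
                         for p, m in zip(pos, meth)])
        centers = [10_000, 20_000, 30_000]
        res = methylation_cpg_profile(cpgs, anchors_at(centers), 2000, 100)
        for b in range(40):
            collected = []
            for c in centers:
                lo = c - 2000 + b * 100
                mask = (pos >= lo) & (pos < lo + 100)
                collected.extend(meth[mask].tolist())
            if collected:
                assert res.methylation[b] == pytest.approx(np.mean(collected))
                assert res.cpg_density[b] == pytest.approx(
                    len(collected) / (3 * 100))
            else:
                assert np.isnan(res.methylation[b])
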
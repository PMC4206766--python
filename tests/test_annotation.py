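"""GTF parsing, strand-aware TSSs, proximal assignment, TSS profiles."""

from __future__ import annotations

import numpy as np
import pytest

from chipnet import (
    GeneModel,
    GenomicInterval,
    ParseError,
    PeakSet,
    assign_proximal,
    read_gene_models,
    tss_distance_profile,
)
from chipnet.simulate import write_gtf

from conftest import random_genes, random_peakset


def brute_assign(peaks, genes, window, mode="interval"):
    """Exhaustive all-pairs oracle for proximal assignment."""
    pairs = set()
    for g in genes:
        lo, hi = g.tss - window, g.tss + window  # closed window
        for p in peaks:
            if p.chrom != g.chrom:
                continue
            if mode == "interval":
                hit = p.start <= hi and p.end - 1 >= lo
            else:
                hit = lo <= p.midpoint <= hi
            if hit:
                sign = 1 if g.strand == "+" else -1
                pairs.add((g.gene_id, p.id, (p.midpoint - g.tss) * sign))
    return pairs


class TestReadGeneModels:
    def gtf_line(self, chrom, start, end, strand, gene_id):
        return (f"{chrom}\tsrc\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f'gene_id "{gene_id}";\n')

    def test_coordinates_converted_and_tss_strand_aware(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            self.gtf_line("chr1", 1001, 2000, "+", "gplus")
            + self.gtf_line("chr1", 1001, 2000, "-", "gminus")
        )
        models = {g.gene_id: g for g in read_gene_models(gtf)}
        assert models["gplus"].span_start == 1000
        assert models["gplus"].span_end == 2000
        assert models["gplus"].tss == 1000
        assert models["gminus"].tss == 1999

    def test_identical_duplicates_collapse(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(self.gtf_line("chr1", 10, 100, "+", "g1") * 2)
        assert len(read_gene_models(gtf)) == 1

    def test_conflicting_duplicates_rejected(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            self.gtf_line("chr1", 10, 100, "+", "g1")
            + self.gtf_line("chr1", 10, 200, "+", "g1")
        )
        with pytest.raises(ParseError, match="conflicting"):
            read_gene_models(gtf)

    def test_round_trip_with_writer(self, tmp_path):
        rng = np.random.default_rng(2)
        genes = sorted(random_genes(rng, 20),
                       key=lambda g: (g.chrom, g.span_start, g.gene_id))
        gtf = tmp_path / "sim.gtf"
        write_gtf(genes, gtf)
        assert read_gene_models(gtf) == genes


class TestAssignProximal:
    def gene(self, tss=50_000, strand="+", chrom="chr1", gene_id="g1"):
        if strand == "+":
            return GeneModel(gene_id, chrom, strand, tss, tss + 2_000)
        return GeneModel(gene_id, chrom, strand, tss - 1_999, tss + 1)

    def peakset(self, *coords):
        return PeakSet("f", "b", [GenomicInterval("chr1", s, e) for s, e in coords])

    def test_inside_window_with_signed_distance(self):
        result = assign_proximal(self.peakset((45_000, 46_000)), [self.gene()],
                                 window=10_000)
        assert result.pairs == [("g1", "f_1", -4_500)]

    def test_closed_window_boundary(self):
        # window ends at 60,000: a peak starting at 60,001 just misses
        out = assign_proximal(self.peakset((60_001, 61_000)), [self.gene()],
                              window=10_000)
        assert out.pairs == []
        edge = assign_proximal(self.peakset((60_000, 61_000)), [self.gene()],
                               window=10_000)
        assert [(g, p) for g, p, _ in edge.pairs] == [("g1", "f_1")]

    def test_minus_strand_distance_sign_flips(self):
        gene = self.gene(strand="-")
        result = assign_proximal(self.peakset((45_000, 46_000)), [gene],
                                 window=10_000)
        # peak lies 3' of a minus-strand TSS: positive (downstream... upstream
        # means negative); midpoint 45,500 is left of tss 50,000, so +4,500
        assert result.pairs == [("g1", "f_1", 4_500)]

    def test_empty_gene_collection_rejected(self):
        with pytest.raises(ValueError, match="empty gene"):
            assign_proximal(self.peakset((0, 10)), [], window=100)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("mode", ["interval", "midpoint"])
    def test_matches_exhaustive_all_pairs_oracle(self, seed, mode):
        rng = np.random.default_rng(seed)
        genes = random_genes(rng, 30, max_pos=100_000)
        peaks = random_peakset(rng, 100, "f", max_pos=100_000, max_width=900)
        got = assign_proximal(peaks, genes, window=10_000, mode=mode)
        assert set(got.pairs) == brute_assign(peaks, genes, 10_000, mode)

    def test_window_monotonicity(self):
        rng = np.random.default_rng(42)
        genes = random_genes(rng, 25, max_pos=80_000)
        peaks = random_peakset(rng, 80, "f", max_pos=80_000)
        small = set(assign_proximal(peaks, genes, window=4_000).pairs)
        large = set(assign_proximal(peaks, genes, window=12_000).pairs)
        assert {(g, p) for g, p, _ in small} <= {(g, p) for g, p, _ in large}

    def test_distance_respects_window_bound(self):
        rng = np.random.default_rng(9)
        genes = random_genes(rng, 25, max_pos=80_000)
        peaks = random_peakset(rng, 120, "f", max_pos=80_000, max_width=600)
        window = 10_000
        by_id = peaks.by_id
        for _, peak_id, dist in assign_proximal(peaks, genes, window=window).pairs:
            # interval mode admits peaks whose edge clips the window, so the
            # midpoint may exceed it by at most half the peak width
            assert abs(dist) <= window + by_id[peak_id].width / 2
        for _, _, dist in assign_proximal(peaks, genes, window=window,
                                          mode="midpoint").pairs:
            assert abs(dist) <= window


class TestTssDistanceProfile:
    def test_peaks_at_tss_pile_in_zero_bin(self):
        genes = [GeneModel(f"g{i}", "chr1", "+", 20_000 * (i + 1),
                           20_000 * (i + 1) + 1_000) for i in range(5)]
        peaks = PeakSet("f", "b", [
            GenomicInterval("chr1", g.tss - 50, g.tss + 50) for g in genes])
        counts, edges = tss_distance_profile(peaks, genes, span=10_000, bin=1_000)
        zero_bin = int(np.searchsorted(edges, 0, side="right")) - 1
        assert counts[zero_bin] == 5 and counts.sum() == 5

    def test_known_offset_lands_in_expected_bin(self):
        gene = GeneModel("g1", "chr1", "+", 50_000, 52_000)
        peaks = PeakSet("f", "b", [GenomicInterval("chr1", 57_100, 57_300)])
        counts, edges = tss_distance_profile(peaks, [gene], span=10_000, bin=1_000)
        # midpoint 57,200 -> distance +7,200 -> bin [7,000, 8,000)
        idx = list(edges).index(7_000)
        assert counts[idx] == 1 and counts.sum() == 1

    def test_gene_free_chromosome_peaks_excluded_and_matches_scan(self):
        rng = np.random.default_rng(4)
        genes = random_genes(rng, 15, chroms=("chr1",), max_pos=60_000)
        peaks = random_peakset(rng, 200, "f", chroms=("chr1", "chrU"),
                               max_pos=60_000)
        span, bin_ = 10_000, 1_000
        counts, _ = tss_distance_profile(peaks, genes, span=span, bin=bin_)
        expected = 0
        for p in peaks:
            if p.chrom != "chr1":
                continue
            dists = sorted(
                ((abs(p.midpoint - g.tss), g.gene_id, g) for g in genes
                 if g.chrom == p.chrom))
            g = dists[0][2]
            sign = 1 if g.strand == "+" else -1
            if abs((p.midpoint - g.tss) * sign) <= span:
                expected += 1
        assert counts.sum() == expected

    def test_gaussian_planted_offsets_give_modal_zero_bin(self):
        rng = np.random.default_rng(123)
        genes = [GeneModel(f"g{i}", "chr1", "+", 40_000 * (i + 1),
                           40_000 * (i + 1) + 500) for i in range(20)]
        ivs = []
        for _ in range(600):
            g = genes[int(rng.integers(0, len(genes)))]
            mid = g.tss + int(rng.normal(0, 2_000))
            ivs.append(GenomicInterval("chr1", mid - 100, mid + 100))
        counts, edges = tss_distance_profile(
            PeakSet("f", "b", ivs), genes, span=10_000, bin=1_000)
        zero_bin = int(np.searchsorted(edges, 0, side="right")) - 1
        assert counts.argmax() in (zero_bin, zero_bin - 1)
        assert counts[zero_bin] + counts[zero_bin - 1] > counts.sum() * 0.3
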
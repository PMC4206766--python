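"""PWM construction, JASPAR I/O, scanning, centrality, and enrichment."""

from __future__ import annotations

import numpy as np
import pytest

from chipnet import (
    GenomicInterval,
    ParseError,
    PeakSet,
    best_hit,
    motif_centrality,
    motif_set_enrichment,
    peak_hit_stats,
    read_jaspar,
    scan_sequence,
    write_jaspar,
)
from chipnet.motifs import PFM
from chipnet.simulate import default_motif

RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(RC)[::-1]


def brute_scan(pfm: PFM, seq: str, rel_threshold: float):
    """Per-window rescoring oracle using plain Python loops."""
    lom = pfm.log_odds
    L = pfm.length
    span = pfm.max_score - pfm.min_score
    hits = []
    for offset in range(len(seq) - L + 1):
        window = seq[offset : offset + L].upper()
        if any(c not in "ACGT" for c in window):
            continue
        for strand, w in (("+", window), ("-", revcomp(window))):
            raw = sum(lom["ACGT".index(c), j] for j, c in enumerate(w))
            rel = (raw - pfm.min_score) / span
            if rel >= rel_threshold:
                hits.append((offset, strand, round(raw, 9)))
    return sorted(hits)


@pytest.fixture
def pfm():
    return default_motif()


class TestPfmAndJaspar:
    def test_log_odds_matches_biopython_pssm(self, pfm):
        from Bio import motifs as bio_motifs

        m = bio_motifs.Motif(
            counts={b: list(pfm.counts["ACGT".index(b)]) for b in "ACGT"})
        m.pseudocounts = {b: pfm.pseudocount * bg
                          for b, bg in zip("ACGT", pfm.background)}
        m.background = dict(zip("ACGT", pfm.background))
        expected = np.array([[m.pssm[b][j] for j in range(pfm.length)]
                             for b in "ACGT"])
        np.testing.assert_allclose(pfm.log_odds, expected, rtol=1e-12)

    def test_consensus_scores_relative_one(self, pfm):
        hits = scan_sequence(pfm, pfm.consensus, rel_threshold=1.0)
        assert hits and hits[0].rel_score == 1.0 and hits[0].offset == 0

    def test_jaspar_round_trip(self, tmp_path, pfm):
        p1 = tmp_path / "m.jaspar"
        write_jaspar(pfm, p1)
        loaded = read_jaspar(p1)
        assert loaded.motif_id == pfm.motif_id
        np.testing.assert_array_equal(loaded.counts, pfm.counts)

    def test_three_row_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.jaspar"
        bad.write_text(">M1 m\nA [1 2 3 4]\nC [1 2 3 4]\nG [1 2 3 4]\n")
        with pytest.raises(ParseError):
            read_jaspar(bad)

    def test_short_matrix_rejected(self):
        with pytest.raises(ValueError, match="length"):
            PFM(motif_id="x", counts=np.ones((4, 3)))

    def test_negative_counts_rejected(self):
        counts = np.ones((4, 6))
        counts[0, 0] = -1
        with pytest.raises(ValueError, match="nonnegative"):
            PFM(motif_id="x", counts=counts)


class TestScanSequence:
    def test_embedded_consensus_found_at_offset(self, pfm):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        seq = ("".join(bases[i] for i in rng.integers(0, 4, 10))
               + pfm.consensus
               + "".join(bases[i] for i in rng.integers(0, 4, 30)))
        top = best_hit(scan_sequence(pfm, seq, 0.8))
        assert top.offset == 10 and top.rel_score == 1.0 and top.strand == "+"

    def test_reverse_complement_mirrors_scan(self, pfm):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        # hits within float rounding of the threshold may differ between the
        # two summation orders; compare only hits clearly above it
        margin = 1e-9
        fwd = [h for h in scan_sequence(pfm, seq, 0.5)
               if h.rel_score >= 0.5 + margin]
        rev = [h for h in scan_sequence(pfm, revcomp(seq), 0.5)
               if h.rel_score >= 0.5 + margin]
        L, n = pfm.length, len(seq)
        mirrored = sorted(
            (n - L - h.offset, "+" if h.strand == "-" else "-",
             round(h.raw_score, 9))
            for h in rev)
        assert sorted((h.offset, h.strand, round(h.raw_score, 9))
                      for h in fwd) == mirrored

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_per_window_rescoring_oracle(self, pfm, seed):
        rng = np.random.default_rng(seed)
        seq = list("ACGT"[i] for i in rng.integers(0, 4, 300))
        for pos in rng.integers(0, 300, 5):  # sprinkle Ns
            seq[pos] = "N"
        seq = "".join(seq)
        got = sorted((h.offset, h.strand, round(h.raw_score, 9))
                     for h in scan_sequence(pfm, seq, 0.6))
        assert got == brute_scan(pfm, seq, 0.6)

    def test_threshold_monotonicity(self, pfm):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        loose = {(h.offset, h.strand) for h in scan_sequence(pfm, seq, 0.55)}
        tight = {(h.offset, h.strand) for h in scan_sequence(pfm, seq, 0.70)}
        assert tight <= loose

    def test_sequence_shorter_than_motif(self, pfm):
        assert scan_sequence(pfm, "ACGT", 0.5) == []


class TestPeakHitStats:
    def test_planted_everywhere_gives_fraction_one(self, pfm):
        from chipnet.simulate import plant_motifs, simulate_genome_annotation

        genome, genes = simulate_genome_annotation(1, 100_000, 5, seed=5)
        peaks = PeakSet("f", "b", [
            GenomicInterval("chr1", 1_000 * i + 200, 1_000 * i + 700)
            for i in range(50)])
        genome, truth = plant_motifs(genome, peaks, pfm, rate=1.0,
                                     center_sd=50, seed=5)
        stats = peak_hit_stats(peaks, genome, pfm, rel_threshold=0.8)
        assert stats.fraction == 1.0
        # planted positions are recovered exactly (consensus scores highest)
        for peak in peaks:
            planted = truth["per_peak"][peak.id]
            assert stats.best_hits[peak.id].offset == planted["offset"]

    def test_out_of_bounds_peak_names_id(self, pfm):
        genome = {"chr1": "ACGT" * 100}
        peaks = PeakSet("f", "b", [GenomicInterval("chr1", 390, 600, id="pk9")])
        with pytest.raises(ValueError, match="pk9"):
            peak_hit_stats(peaks, genome, pfm)

    def test_planted_rate_recovered_with_background_control(self, pfm):
        from chipnet.simulate import plant_motifs, simulate_genome_annotation

        genome0, _ = simulate_genome_annotation(1, 450_000, 2, seed=8)
        peaks = PeakSet("f", "b", [
            GenomicInterval("chr1", 1_000 * i + 100, 1_000 * i + 700)
            for i in range(400)])
        control = peak_hit_stats(peaks, genome0, pfm, 0.8).fraction
        genome1, _ = plant_motifs(genome0, peaks, pfm, rate=0.5,
                                  center_sd=50, seed=8)
        observed = peak_hit_stats(peaks, genome1, pfm, 0.8).fraction
        # planted half plus chance hits in the unplanted half
        expected = 0.5 + 0.5 * control
        assert abs(observed - expected) <= 3 * np.sqrt(0.25 / 400) + 0.02


class TestMotifCentrality:
    def make_peaks(self, n, width=1_000):
        return PeakSet("f", "b", [
            GenomicInterval("chr1", 2_000 * i, 2_000 * i + width)
            for i in range(n)])

    def hits_at(self, peaks, starts, motif_length=10):
        from chipnet.motifs import MotifHit

        return {
            iv.id: MotifHit(offset=int(s), strand="+", raw_score=1.0,
                            rel_score=1.0, peak_id=iv.id)
            for iv, s in zip(peaks, starts)
        }

    def test_midpoint_hits_have_zero_mean_offset(self):
        peaks = self.make_peaks(20)
        L = 10
        hits = self.hits_at(peaks, [500 - L // 2] * 20, L)
        res = motif_centrality(hits, peaks, motif_length=L)
        assert res.mean_abs_offset == 0.0

    def test_uniform_hits_match_closed_form(self):
        rng = np.random.default_rng(12)
        n, width, L = 2_000, 1_000, 10
        peaks = self.make_peaks(n, width)
        starts = rng.integers(0, width - L + 1, n)
        res = motif_centrality(self.hits_at(peaks, starts, L), peaks,
                               motif_length=L, seed=1)
        # |offset| of a uniform point in [-w/2, w/2] has mean w/4
        expect = width / 4
        se = (width / np.sqrt(48)) / np.sqrt(n)
        assert abs(res.mean_abs_offset - expect) <= 3 * se + L

    def test_central_hits_beat_uniform_null(self):
        rng = np.random.default_rng(13)
        n, width, L = 400, 1_000, 10
        peaks = self.make_peaks(n, width)
        starts = np.clip(
            (width // 2 + rng.normal(0, 50, n)).astype(int) - L // 2,
            0, width - L)
        res = motif_centrality(self.hits_at(peaks, starts, L), peaks,
                               motif_length=L, seed=2)
        assert res.mean_abs_offset < res.null_mean_abs_offsets.min()


class TestMotifSetEnrichment:
    def test_equal_rates_give_zero_statistic(self):
        res = motif_set_enrichment((50, 50), (50, 50))
        assert res.chi2 == 0.0 and res.fold_enrichment == 1.0

    def test_known_table_statistic(self):
        res = motif_set_enrichment((10, 90), (30, 70))
        assert res.chi2 == pytest.approx(12.5)
        assert res.fold_enrichment == pytest.approx((10 / 100) / (30 / 100))

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(99)
        detected = 0
        for _ in range(100):
            a = int(rng.binomial(500, 0.5))
            b = int(rng.binomial(500, 0.25))
            res = motif_set_enrichment((a, 500 - a), (b, 500 - b))
            if res.p_value < 0.01:
                detected += 1
        assert detected >= 95
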
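"""k-mer decomposition, exact mapping, segment merging, knee detection."""

import numpy as np
import pytest

from pannumt._encode import revcomp
from pannumt.kmer import (KmerHit, decompose, length_histogram, map_kmers,
                          merge_positions, turning_point)
from pannumt.panmito import MitoRecord

from conftest import random_dna
from oracles import mask_merge, naive_kmer_scan


def recs(*seqs):
    return [MitoRecord(id=f"r{i}", sequence=s, kind="control")
            for i, s in enumerate(seqs)]


class TestDecompose:
    def test_clean_record_window_count(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 120)
        table = decompose(recs(seq), k=20)
        assert table.total_segments == 101

    def test_windows_overlapping_ambiguity_codes_dropped(self):
        # of the 7 windows of ACGTNACGTA only positions 0, 5, 6 avoid the N
        table = decompose(recs("ACGTNACGTA"), k=4)
        assert table.total_segments == 3
        assert all("N" not in km for km in table.counts)
        table_iupac = decompose(recs("ACGTRACGTA"), k=4)
        assert table_iupac.total_segments == 3

    def test_homopolymer_counts(self):
        table = decompose(recs("A" * 30), k=20)
        assert (table.unique_count, table.total_segments) == (1, 11)

    def test_counts_accumulate_across_records(self):
        table = decompose(recs("ACGTACGTACGTACGTACGTA",
                               "ACGTACGTACGTACGTACGTA"), k=20)
        assert table.counts["ACGTACGTACGTACGTACGT"] == 2
        assert table.counts["CGTACGTACGTACGTACGTA"] == 2


class TestMapKmers:
    def test_single_planted_kmer_one_hit(self):
        rng = np.random.default_rng(1)
        km = random_dna(rng, 20)
        genome = {"c": random_dna(rng, 500) + km + random_dna(rng, 500)}
        table = decompose(recs(km), k=20)
        hits = map_kmers(table, genome)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].strand) == (500, "+")

    def test_reverse_complement_hit_on_minus(self):
        rng = np.random.default_rng(2)
        km = random_dna(rng, 20)
        table = decompose(recs(km), k=20)
        hits = map_kmers(table, {"c": revcomp(km)})
        assert [(h.start, h.strand) for h in hits] == [(0, "-")]

    def test_matches_naive_sliding_window_scan(self):
        rng = np.random.default_rng(3)
        pool_seq = random_dna(rng, 400)
        genome_seq = (random_dna(rng, 3000) + pool_seq[50: 120]
                      + random_dna(rng, 3000) + revcomp(pool_seq[200: 260])
                      + random_dna(rng, 3000))
        table = decompose(recs(pool_seq), k=20)
        got = {(h.kmer, h.start) for h in map_kmers(table, {"c": genome_seq})}
        assert got == naive_kmer_scan(set(table.counts), genome_seq, 20)

    def test_mismatch_tolerance_is_monotone(self):
        rng = np.random.default_rng(4)
        pool_seq = random_dna(rng, 60)
        genome = {"c": random_dna(rng, 800) + pool_seq + random_dna(rng, 800)}
        table = decompose(recs(pool_seq), k=20)
        h0 = {(h.kmer, h.start) for h in map_kmers(table, genome, 0)}
        h1 = {(h.kmer, h.start) for h in map_kmers(table, genome, 1)}
        h2 = {(h.kmer, h.start) for h in map_kmers(table, genome, 2)}
        assert h0 <= h1 <= h2

    def test_mismatch_mode_matches_naive_scan(self):
        rng = np.random.default_rng(5)
        pool_seq = random_dna(rng, 40)
        genome_seq = random_dna(rng, 600) + pool_seq[:20] + random_dna(rng, 600)
        table = decompose(recs(pool_seq), k=20)
        got = {(h.kmer, h.start)
               for h in map_kmers(table, {"c": genome_seq}, max_mismatch=2)}
        assert got == naive_kmer_scan(set(table.counts), genome_seq, 20, 2)

    def test_mismatch_bound_enforced(self):
        table = decompose(recs("A" * 25), k=20)
        with pytest.raises(ValueError):
            map_kmers(table, {"c": "A" * 30}, max_mismatch=4)


class TestMergePositions:
    def hit(self, start, kmer="A" * 20, chrom="c"):
        return KmerHit(chrom, start, "+", kmer, 1)

    def test_overlapping_footprints_fuse(self):
        segs = merge_positions([self.hit(0), self.hit(5, "C" * 20)], k=20)
        assert len(segs) == 1
        assert (segs[0].interval.start, segs[0].interval.end) == (0, 25)
        assert segs[0].supporting_kmers == 2

    def test_distant_kmers_stay_separate(self):
        segs = merge_positions([self.hit(0), self.hit(100)], k=20)
        assert [(s.interval.start, s.interval.end) for s in segs] == [
            (0, 20), (100, 120)]

    def test_footprints_match_mask_oracle(self):
        rng = np.random.default_rng(6)
        from pannumt.intervals import GenomicInterval
        starts = sorted(int(s) for s in rng.integers(0, 3000, size=150))
        hits = [self.hit(s, kmer=f"{i:020d}") for i, s in enumerate(starts)]
        segs = merge_positions(hits, k=20)
        expected = mask_merge(
            [GenomicInterval("c", s, s + 20) for s in starts])
        assert [(s.interval.chrom, s.interval.start, s.interval.end)
                for s in segs] == sorted(expected)

    def test_depth_reflects_stacking(self):
        segs = merge_positions(
            [self.hit(0), self.hit(1, "C" * 20), self.hit(2, "G" * 20)], k=20)
        assert segs[0].depth_max == 3


class TestHistogramAndKnee:
    def test_histogram_counts_lengths(self):
        segs = merge_positions(
            [KmerHit("c", 0, "+", "A" * 20, 1),
             KmerHit("c", 100, "+", "C" * 20, 1),
             KmerHit("c", 200, "+", "G" * 20, 1),
             KmerHit("c", 205, "+", "T" * 20, 1)], k=20)
        hist = length_histogram(segs)
        assert {L: c for L, (c, _) in hist.items()} == {20: 2, 25: 1}
        assert sum(c for c, _ in hist.values()) == len(segs)

    def test_empty_histogram(self):
        assert length_histogram([]) == {}

    def test_constructed_knee_at_28(self):
        hist = {L: 100_000 for L in range(20, 28)}
        hist.update({L: 100 for L in range(28, 45)})
        assert turning_point(hist, k=20) == 28

    def test_flat_histogram_warns_and_defaults(self, caplog):
        hist = {L: 500 for L in range(20, 60)}
        with caplog.at_level("WARNING"):
            assert turning_point(hist, k=20) == 28
        assert "default" in caplog.text

    def test_knee_equals_exhaustive_log_drop_search(self):
        rng = np.random.default_rng(8)
        lengths = sorted(rng.choice(np.arange(20, 61), size=25, replace=False))
        hist = {int(L): int(c) for L, c in
                zip(lengths, rng.integers(1, 100_000, size=25))}
        got = turning_point(hist, k=20)
        # independent exhaustive scan over first differences of log-counts
        import math
        best, best_drop = 28, 0.0
        ls = sorted(hist)
        for prev, L in zip(ls, ls[1:]):
            if 21 <= L <= 60:
                drop = math.log(hist[prev]) - math.log(hist[L])
                if drop > best_drop:
                    best, best_drop = L, drop
        assert got == best
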
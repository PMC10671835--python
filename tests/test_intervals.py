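"""Interval algebra: merge, summary stats, overlap fractions, BED round-trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pannumt.intervals import (GenomicInterval, IntervalSet, blacklist_union,
                               merge, overlap_stats, read_bed, summary_stats,
                               write_bed)

from oracles import mask_intersection_length, mask_merge


def iset(triples, genome=""):
    return IntervalSet(
        (GenomicInterval(c, a, b) for c, a, b in triples), genome=genome)


def triples(s):
    return [(iv.chrom, iv.start, iv.end) for iv in s]


interval_lists = st.lists(
    st.tuples(st.sampled_from(["chr1", "chr2"]),
              st.integers(0, 300), st.integers(1, 60)),
    min_size=1, max_size=40,
).map(lambda raw: [(c, a, a + w) for c, a, w in raw])


class TestMerge:
    def test_overlapping_pair(self):
        assert triples(merge(iset([("c", 0, 10), ("c", 5, 15)]))) == [("c", 0, 15)]

    def test_book_ended_pair_joined(self):
        assert triples(merge(iset([("c", 0, 10), ("c", 10, 20)]))) == [("c", 0, 20)]

    def test_min_gap_bridges_small_gaps(self):
        got = merge(iset([("c", 0, 10), ("c", 14, 20)]), min_gap=5)
        assert triples(got) == [("c", 0, 20)]
        got = merge(iset([("c", 0, 10), ("c", 15, 20)]), min_gap=5)
        assert triples(got) == [("c", 0, 10), ("c", 15, 20)]

    def test_thousand_random_intervals_match_mask_oracle(self):
        rng = np.random.default_rng(77)
        ivs = [GenomicInterval(f"chr{rng.integers(1, 4)}",
                               int(a), int(a + rng.integers(1, 200)))
               for a in rng.integers(0, 50_000, size=1000)]
        got = triples(merge(IntervalSet(ivs)))
        assert got == sorted(mask_merge(ivs))

    @settings(deadline=None, derandomize=True)
    @given(interval_lists, st.randoms())
    def test_idempotent_and_order_independent(self, raw, rnd):
        once = merge(iset(raw))
        assert merge(once) == once
        shuffled = list(raw)
        rnd.shuffle(shuffled)
        assert merge(iset(shuffled)) == once


class TestSummaryStats:
    def test_two_intervals(self):
        s = summary_stats(iset([("c", 0, 10), ("c", 20, 50)]))
        assert (s.count, s.total_length, s.min, s.max, s.mean) == (2, 40, 10, 30, 20.0)

    def test_single_interval_degenerate(self):
        s = summary_stats(iset([("c", 5, 12)]))
        assert s.min == s.max == s.median == s.mean == 7

    def test_lower_median_for_even_count(self):
        s = summary_stats(iset([("c", 0, 10), ("c", 20, 40)]))
        assert s.median == 10

    def test_empty_set_warns_all_zero(self, caplog):
        with caplog.at_level("WARNING"):
            s = summary_stats(IntervalSet([]))
        assert s.count == 0 and s.total_length == 0
        assert "empty" in caplog.text


class TestOverlapStats:
    def test_identical_sets_fraction_one(self):
        a = iset([("c", 0, 100), ("c", 200, 250)])
        st_ = overlap_stats(a, a)
        assert (st_.frac_a_in_b, st_.frac_b_in_a, st_.frac_shared_of_union) == (1, 1, 1)

    def test_disjoint_sets_share_nothing(self):
        st_ = overlap_stats(iset([("c", 0, 10)]), iset([("c", 50, 60)]))
        assert st_.shared_length == 0

    def test_blacklist_containment_fraction(self):
        # one compilation of 415,928 bases of which 278,266 are shared:
        # the containment fraction is ~0.669 (reported rounded as "70%")
        a = iset([("c", 0, 278_266), ("c", 300_000, 700_000)])
        b = iset([("c", 0, 278_266), ("c", 1_000_000, 1_137_662)])
        st_ = overlap_stats(a, b)
        assert st_.shared_length == 278_266
        assert st_.frac_b_in_a == pytest.approx(278_266 / 415_928)
        assert st_.frac_b_in_a == pytest.approx(0.669, abs=5e-4)

    def test_genome_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="genome label"):
            overlap_stats(iset([("c", 0, 1)], "hg19"), iset([("c", 0, 1)], "t2t"))

    @settings(deadline=None, derandomize=True)
    @given(interval_lists, interval_lists)
    def test_inclusion_exclusion_identity(self, raw_a, raw_b):
        a, b = merge(iset(raw_a)), merge(iset(raw_b))
        st_ = overlap_stats(a, b)
        union = merge(IntervalSet(list(a) + list(b)))
        assert (a.total_length() + b.total_length()
                == union.total_length() + st_.shared_length)

    @settings(deadline=None, derandomize=True)
    @given(interval_lists, interval_lists)
    def test_shared_length_symmetric_and_matches_mask(self, raw_a, raw_b):
        a, b = merge(iset(raw_a)), merge(iset(raw_b))
        assert (overlap_stats(a, b).shared_length
                == overlap_stats(b, a).shared_length
                == mask_intersection_length(list(a), list(b)))


class TestBlacklistUnion:
    def test_numts_alone_unchanged(self):
        numts = merge(iset([("c", 0, 10), ("c", 50, 60)]))
        empty = IntervalSet([])
        assert triples(blacklist_union(numts, empty, empty)) == triples(numts)

    def test_idempotent_on_identical_inputs(self):
        a = merge(iset([("c", 0, 10), ("c", 50, 60)]))
        assert triples(blacklist_union(a, a, a)) == triples(a)

    def test_provenance_labels_recorded(self):
        numts = iset([("c", 0, 10)])
        ext = iset([("c", 5, 20)])
        pile = iset([("c", 100, 120)])
        out = list(blacklist_union(numts, ext, pile))
        assert out[0].name == "numts,blacklist"
        assert out[1].name == "pileup"

    def test_union_length_matches_mask_oracle(self):
        rng = np.random.default_rng(9)
        sets = []
        for _ in range(3):
            ivs = [GenomicInterval("c", int(a), int(a + rng.integers(1, 80)))
                   for a in rng.integers(0, 5000, size=100)]
            sets.append(merge(IntervalSet(ivs)))
        out = blacklist_union(*sets)
        expected = sum(b - a for _, a, b in mask_merge(
            [iv for s in sets for iv in s]))
        assert out.total_length() == expected


class TestBedIO:
    def test_round_trip_preserves_set(self, tmp_path):
        s = iset([("chr1", 100, 200), ("chr2", 0, 50)])
        p = tmp_path / "a.bed"
        write_bed(s, p)
        assert read_bed(p) == s

    def test_strand_column_preserved(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\tname1\t3.5\t-\n")
        s = read_bed(p)
        (iv,) = s
        assert (iv.name, iv.score, iv.strand) == ("name1", 3.5, "-")
        out = tmp_path / "b.bed"
        write_bed(s, out)
        assert read_bed(out) == s

    def test_reversed_coordinates_error_with_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\nchr1\t100\t50\n")
        with pytest.raises(ValueError, match="2"):
            read_bed(p)

    def test_track_lines_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\nchr1\t0\t10\n")
        with caplog.at_level("WARNING"):
            s = read_bed(p)
        assert len(s) == 1 and "skipping" in caplog.text
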
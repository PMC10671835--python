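"""Seeding, X-drop extension, e-value filtering, and NUMT discovery."""

import numpy as np
import pytest

from pannumt._encode import encode, revcomp
from pannumt.align import (AlignmentHit, FilterThresholds, Seed,
                           extend_alignment, filter_hits, find_numts,
                           seed_hits)
from pannumt.panmito import MitoRecord, PanMitogenome

from conftest import random_dna
from oracles import naive_seed_scan, swg_local


def single_record_pool(seq, kind="full", rec_id="q"):
    return PanMitogenome(
        records=[MitoRecord(id=rec_id, sequence=seq, kind=kind)], pad=0)


class TestSeedHits:
    def test_identical_sequences_seed_at_origin(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 50)
        seeds = seed_hits(seq, seq, word_size=11)
        plus = [s for s in seeds if s.strand == "+"]
        assert any(s.qstart == 0 and s.sstart == 0 and s.length == 50
                   for s in plus)

    def test_reverse_complement_seeds_minus_only(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 60)
        seeds = seed_hits(seq, revcomp(seq), word_size=11)
        assert seeds and all(s.strand == "-" for s in seeds)

    def test_matches_naive_maximal_run_scan(self):
        rng = np.random.default_rng(42)
        q, s = random_dna(rng, 1000), random_dna(rng, 1000)
        # plant shared words so the comparison is not vacuous
        s = s[:100] + q[300:340] + s[140:600] + q[700:725] + s[625:]
        got = {(sd.qstart, sd.sstart, sd.length)
               for sd in seed_hits(q, s, word_size=11) if sd.strand == "+"}
        expected = naive_seed_scan(q, s, 11)
        assert got == expected


class TestExtendAlignment:
    def test_identical_octamer_scores_all_matches(self):
        hit = extend_alignment(Seed(0, 0, 8, "+"), "ACGTACGT", "ACGTACGT")
        assert (hit.score, hit.identity, hit.gaps) == (16, 100.0, 0)
        assert (hit.query_start, hit.query_end) == (1, 8)

    def test_one_mismatch_in_ten(self):
        q = "ACGTACGTAC"
        s = "ACGTAGGTAC"  # interior mismatch at column 6
        hit = extend_alignment(Seed(0, 0, 5, "+"), q, s)
        assert hit.score == 9 * 2 - 3
        assert hit.identity == pytest.approx(90.0)
        assert hit.aligned_cols == 10 and hit.mismatches == 1

    def test_minus_strand_reported_on_forward_coordinates(self):
        rng = np.random.default_rng(8)
        q = random_dna(rng, 40)
        s = revcomp(q)
        (seed,) = [sd for sd in seed_hits(q, s, 11)
                   if sd.strand == "-" and sd.length == 40]
        hit = extend_alignment(seed, q, s)
        assert (hit.query_start, hit.query_end) == (1, 40)
        assert (hit.subject_start, hit.subject_end) == (0, 40)
        assert hit.identity == 100.0

    @pytest.mark.parametrize("trial", range(5))
    def test_score_equals_full_dp_when_seed_in_optimum(self, trial):
        rng = np.random.default_rng(100 + trial)
        core = random_dna(rng, 60)
        mut = "".join(
            b if rng.random() > 0.1 else "ACGT"[rng.integers(0, 4)]
            for b in core)
        q = random_dna(rng, 10) + core + random_dna(rng, 10)
        s = random_dna(rng, 10) + mut + random_dna(rng, 10)
        best, path = swg_local(encode(q), encode(s))
        seeds = [sd for sd in seed_hits(q, s, 11) if sd.strand == "+"]
        pathset = set(path)
        has_inside_seed = any(
            all((sd.qstart + k + 1, sd.sstart + k + 1) in pathset
                for k in range(sd.length))
            for sd in seeds)
        if not has_inside_seed:
            pytest.skip("optimal alignment contains no exact 11-mer")
        assert max(extend_alignment(sd, q, s).score for sd in seeds) == best


class TestFilterHits:
    def make_hit(self, evalue=1e-6, matches=90, cols=100, sub_len=100):
        return AlignmentHit(
            query_id="q", query_start=1, query_end=cols,
            subject_chrom="c", subject_start=0, subject_end=sub_len,
            strand="+", score=2 * matches - 3 * (cols - matches),
            aligned_cols=cols, matches=matches, mismatches=cols - matches,
            gaps=0, gap_opens=0, evalue=evalue)

    def test_identity_exactly_63_removed(self):
        kept, removed = filter_hits(
            [self.make_hit(matches=63, cols=100)], FilterThresholds())
        assert kept == [] and removed["identity"] == 1

    def test_28bp_high_identity_hit_retained(self):
        hit = self.make_hit(evalue=1e-6, matches=27, cols=28, sub_len=28)
        assert hit.identity > 90
        kept, _ = filter_hits([hit], FilterThresholds())
        assert kept == [hit]

    def test_evalue_1e3_removed(self):
        kept, removed = filter_hits(
            [self.make_hit(evalue=1e-3)], FilterThresholds())
        assert kept == [] and removed["evalue"] == 1

    def test_length_27_removed(self):
        kept, removed = filter_hits(
            [self.make_hit(sub_len=27)], FilterThresholds())
        assert kept == [] and removed["length"] == 1


class TestFindNumts:
    def test_planted_exact_copy_recovered_with_full_identity(self):
        rng = np.random.default_rng(21)
        q = random_dna(rng, 3000)
        back = random_dna(rng, 6000)
        genome = {"chr1": back[:2500] + q[1000: 2000] + back[2500:]}
        numts, hits = find_numts(single_record_pool(q), genome)
        assert len(numts) == 1
        (iv,) = numts
        assert abs(iv.start - 2500) <= 5 and abs(iv.end - 3500) <= 5
        assert max(h.identity for h in hits) > 99.0

    def test_half_identity_copy_rejected(self):
        rng = np.random.default_rng(22)
        q = random_dna(rng, 2000)
        copy = "".join(
            b if rng.random() > 0.5 else "ACGT"[rng.integers(0, 4)]
            for b in q[500: 1000])
        genome = {"chr1": random_dna(rng, 3000) + copy + random_dna(rng, 3000)}
        numts, _ = find_numts(single_record_pool(q), genome)
        assert len(numts) == 0

    def test_strand_symmetry_mirror_intervals(self):
        rng = np.random.default_rng(23)
        q = random_dna(rng, 1500)
        back = random_dna(rng, 4000)
        g = back[:1500] + q[200: 900] + back[1500:]
        fwd, _ = find_numts(single_record_pool(q), {"c": g})
        rev, _ = find_numts(single_record_pool(q), {"c": revcomp(g)})
        n = len(g)
        mirrored = sorted((n - iv.end, n - iv.start) for iv in rev)
        assert sorted((iv.start, iv.end) for iv in fwd) == mirrored

    def test_planted_copy_boundaries_exact_with_inert_flanks(self):
        # flank bases chosen to mismatch the continuing query, so the
        # optimal local alignment cannot drift past the planted boundary
        rng = np.random.default_rng(24)
        q = random_dna(rng, 1000)
        insert = q[200: 500]
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        left = "".join(flip[b] for b in q[170: 200])
        right = "".join(flip[b] for b in q[500: 530])
        back = random_dna(rng, 2000)
        genome = {"c": back[:800] + left + insert + right + back[800:]}
        start = 800 + 30
        numts, _ = find_numts(single_record_pool(q), genome)
        (iv,) = numts
        assert abs(iv.start - start) <= 2
        assert abs(iv.end - (start + 300)) <= 2

    def test_pad_only_hits_wrap_to_origin_coordinates(self):
        rng = np.random.default_rng(25)
        seq = random_dna(rng, 2000)
        rec = MitoRecord(id="m", sequence=seq + seq[:100], kind="full",
                         original_length=2000, pad=100)
        pool = PanMitogenome(records=[rec], pad=100)
        # plant a copy of the molecule's first 60 bases, flanked by bases
        # that mismatch the continuing query so extension stops exactly
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        left_stop = "".join(flip[b] for b in seq[1997: 2000])
        right_stop = "".join(flip[b] for b in seq[60: 63])
        genome = {"c": random_dna(rng, 1500) + left_stop + seq[:60]
                  + right_stop + random_dna(rng, 1500)}
        _, hits = find_numts(pool, genome, thresholds=FilterThresholds(
            max_evalue=1e-3, min_identity=63, min_length=28))
        assert hits
        # both the origin copy and its pad duplicate report wrapped coords
        assert all(h.query_start == 1 and h.query_end == 60 for h in hits)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            find_numts(PanMitogenome(records=[], pad=0), {"c": "ACGT" * 100})
        with pytest.raises(ValueError):
            find_numts(single_record_pool("ACGT" * 100), {})
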
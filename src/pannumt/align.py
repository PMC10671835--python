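"""Seed-and-extend discovery of mtDNA-like nuclear regions (NUMTs).

The search follows the classic word-seeded local-alignment strategy: exact
word matches (default word size 11) between a pool query and the nuclear
subject are located through a sorted k-mer index of the subject, collapsed
into maximal exact runs, and extended in both directions with affine-gap
X-drop dynamic programming.  Hit significance uses Karlin–Altschul
e-values (``K m n exp(-lambda S)``) and hits are filtered on e-value,
percent identity (gap columns included in the denominator, as BLAST's
``pident`` does) and subject-interval length before merging into a NUMT
compilation.

Effective search lengths ``m`` and ``n`` are the raw query and subject
lengths; no BLAST-style length adjustment is applied, and that choice is
recorded in run manifests so results are self-describing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from ._encode import encode, kmer_keys, revcomp_codes
from .intervals import GenomicInterval, IntervalSet, merge
from .karlin import ScoringScheme
from .panmito import PanMitogenome

log = logging.getLogger(__name__)

DEFAULT_WORD_SIZE = 11
DEFAULT_XDROP = 20


@dataclass(frozen=True)
class FilterThresholds:
    """Hit acceptance thresholds.

    ``min_identity`` is strict (identity must exceed it); ``min_length`` is
    inclusive on the subject-interval length (a 28 bp hit passes the default).
    """

    max_evalue: float = 1e-4
    min_identity: float = 63.0
    min_length: int = 28

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must be in [0, 100]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class Seed:
    """A maximal exact match: query[qstart:qstart+length] == subject word.

    Coordinates are 0-based on the seeding frame: for '-' seeds the query
    coordinate refers to the reverse-complemented query.
    """

    qstart: int
    sstart: int
    length: int
    strand: str


@dataclass(frozen=True)
class AlignmentHit:
    """A scored, e-valued local alignment between a pool query and a contig.

    Query coordinates are 1-based inclusive on the (possibly padded) query
    in its forward orientation; subject coordinates are 0-based half-open
    on the nuclear sequence's forward strand.
    """

    query_id: str
    query_start: int
    query_end: int
    subject_chrom: str
    subject_start: int
    subject_end: int
    strand: str
    score: int
    aligned_cols: int
    matches: int
    mismatches: int
    gaps: int
    gap_opens: int
    evalue: float
    query_kind: str = "full"

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.aligned_cols

    @property
    def subject_length(self) -> int:
        return self.subject_end - self.subject_start


class GenomeIndex:
    """Sorted word-key index of one nuclear sequence (forward strand)."""

    def __init__(self, name: str, sequence: str, word_size: int = DEFAULT_WORD_SIZE):
        if word_size < 4:
            raise ValueError("word_size must be >= 4")
        self.name = name
        self.word_size = word_size
        self.codes = encode(sequence)
        self.length = len(self.codes)
        keys, valid = kmer_keys(self.codes, word_size)
        pos = np.nonzero(valid)[0]
        keys = keys[pos]
        order = np.argsort(keys, kind="stable")
        self.sorted_keys = keys[order]
        self.sorted_pos = pos[order].astype(np.int64)

    def lookup(self, query_keys: np.ndarray, query_valid: np.ndarray):
        """All (query_pos, subject_pos) exact word matches, as two arrays."""
        qpos_all = np.nonzero(query_valid)[0]
        qkeys = query_keys[qpos_all]
        left = np.searchsorted(self.sorted_keys, qkeys, side="left")
        right = np.searchsorted(self.sorted_keys, qkeys, side="right")
        counts = right - left
        hit = counts > 0
        if not hit.any():
            return (np.empty(0, dtype=np.int64),) * 2
        qpos = np.repeat(qpos_all[hit], counts[hit])
        spos = np.concatenate(
            [self.sorted_pos[l:r] for l, r in zip(left[hit], right[hit])]
        )
        return qpos, spos


def _collapse_runs(qpos: np.ndarray, spos: np.ndarray, word_size: int,
                   strand: str) -> list[Seed]:
    """Collapse word matches on a shared diagonal into maximal exact runs."""
    if len(qpos) == 0:
        return []
    diag = spos - qpos
    order = np.lexsort((qpos, diag))
    qpos, spos, diag = qpos[order], spos[order], diag[order]
    breaks = np.nonzero((np.diff(diag) != 0) | (np.diff(qpos) != 1))[0] + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [len(qpos)]))
    return [
        Seed(int(qpos[a]), int(spos[a]),
             int(qpos[b - 1] - qpos[a]) + word_size, strand)
        for a, b in zip(starts, ends)
    ]


def seed_hits(query: str, subject: str,
              word_size: int = DEFAULT_WORD_SIZE) -> list[Seed]:
    """Maximal exact matches of length >= word_size, on both strands.

    '-' strand seeds report the query coordinate on the reverse-complemented
    query and the subject coordinate on the forward subject.
    """
    index = GenomeIndex("subject", subject, word_size)
    seeds: list[Seed] = []
    qcodes = encode(query)
    for strand, codes in (("+", qcodes), ("-", revcomp_codes(qcodes))):
        keys, valid = kmer_keys(codes, word_size)
        qp, sp = index.lookup(keys, valid)
        seeds.extend(_collapse_runs(qp, sp, word_size, strand))
    return seeds


def _max_gap_reach(scheme: ScoringScheme, x_drop: int) -> int:
    """Longest affordable gap excursion under the X-drop bound."""
    return max(1, (x_drop - scheme.gap_open) // scheme.gap_extend + 1)


def extend_seed(seed: Seed, qcodes: np.ndarray, scodes: np.ndarray,
                scheme: ScoringScheme, x_drop: int = DEFAULT_XDROP):
    """Extend a seed in both directions; return (score, qb, qe, sb, se).

    Coordinates are 0-based half-open in the frame of the passed arrays.
    The result is the maximal-scoring local alignment containing the seed's
    exact-match run, up to X-drop termination.
    """
    r, p = scheme.reward, scheme.penalty
    go, ge = scheme.gap_open, scheme.gap_extend
    reach = _max_gap_reach(scheme, x_drop)
    qs, ss, L = seed.qstart, seed.sstart, seed.length

    qrem = len(qcodes) - (qs + L)
    srem = min(len(scodes) - (ss + L), qrem + reach)
    right = _kernels.xdrop_extend(
        qcodes[qs + L:], scodes[ss + L: ss + L + srem], r, p, go, ge, x_drop)
    srem = min(ss, qs + reach)
    left = _kernels.xdrop_extend(
        np.ascontiguousarray(qcodes[:qs][::-1]),
        np.ascontiguousarray(scodes[ss - srem: ss][::-1]),
        r, p, go, ge, x_drop)
    score = L * r + right[0] + left[0]
    qb, qe = qs - left[1], qs + L + right[1]
    sb, se = ss - left[2], ss + L + right[2]
    return score, qb, qe, sb, se


def _hit_stats(qcodes, scodes, qb, qe, sb, se, scheme, x_drop):
    """Banded global re-alignment of the extended rectangle, for hit stats."""
    off = (se - sb) - (qe - qb)
    margin = _max_gap_reach(scheme, x_drop) + 4
    band_lo = min(0, off) - margin
    band_hi = max(0, off) + margin
    return _kernels.banded_global_stats(
        np.ascontiguousarray(qcodes[qb:qe]), np.ascontiguousarray(scodes[sb:se]),
        scheme.reward, scheme.penalty, scheme.gap_open, scheme.gap_extend,
        band_lo, band_hi)


def extend_alignment(seed: Seed, query: str, subject: str,
                     scheme: ScoringScheme | None = None,
                     x_drop: int = DEFAULT_XDROP,
                     query_id: str = "query",
                     subject_chrom: str = "subject") -> AlignmentHit:
    """Full hit construction for one seed of :func:`seed_hits`.

    Pass the same forward-orientation strings given to :func:`seed_hits`;
    '-' seeds are aligned in the reverse-complement frame internally and
    reported on forward coordinates for both sequences.
    """
    scheme = scheme or ScoringScheme()
    qcodes, scodes = encode(query), encode(subject)
    m = len(qcodes)
    if seed.strand == "-":
        qcodes = revcomp_codes(qcodes)
    score, qb, qe, sb, se = extend_seed(seed, qcodes, scodes, scheme, x_drop)
    gscore, matches, mism, gaps, gopens, cols = _hit_stats(
        qcodes, scodes, qb, qe, sb, se, scheme, x_drop)
    ev = scheme.evalue(score, m, len(scodes))
    if seed.strand == "-":
        qb, qe = m - qe, m - qb
    return AlignmentHit(
        query_id=query_id, query_start=qb + 1, query_end=qe,
        subject_chrom=subject_chrom, subject_start=sb, subject_end=se,
        strand=seed.strand, score=int(score), aligned_cols=int(cols),
        matches=int(matches), mismatches=int(mism), gaps=int(gaps),
        gap_opens=int(gopens), evalue=ev)


def filter_hits(hits: list[AlignmentHit], thresholds: FilterThresholds):
    """Apply the e-value / identity / length filters.

    Returns ``(kept, removed_counts)`` where the counts record how many hits
    each criterion rejected (a hit can be counted under several).
    """
    removed = {"evalue": 0, "identity": 0, "length": 0}
    kept = []
    for h in hits:
        ok = True
        if h.evalue > thresholds.max_evalue:
            removed["evalue"] += 1
            ok = False
        if h.identity <= thresholds.min_identity:
            removed["identity"] += 1
            ok = False
        if h.subject_length < thresholds.min_length:
            removed["length"] += 1
            ok = False
        if ok:
            kept.append(h)
    return kept, removed


def _search_record(rec, index: GenomeIndex, scheme: ScoringScheme,
                   n_total: int, x_drop: int,
                   max_evalue: float) -> list[AlignmentHit]:
    """All extensions of one pool record against one indexed contig.

    Extensions scoring below the e-value reporting threshold are dropped
    without computing alignment statistics (they could never pass the
    filters), exactly as an aligner run with an e-value cutoff would.
    """
    qcodes = encode(rec.sequence)
    m = len(qcodes)
    min_report_score = scheme.score_cutoff(max_evalue, m, n_total)
    hits: list[AlignmentHit] = []
    reach = _max_gap_reach(scheme, x_drop)
    for strand in ("+", "-"):
        codes = qcodes if strand == "+" else revcomp_codes(qcodes)
        keys, valid = kmer_keys(codes, index.word_size)
        qp, sp = index.lookup(keys, valid)
        seeds = _collapse_runs(qp, sp, index.word_size, strand)
        seeds.sort(key=lambda s: (s.sstart, s.qstart))
        cov: dict[int, int] = {}
        seen: set[tuple[int, int, int, int]] = set()
        for seed in seeds:
            d = seed.sstart - seed.qstart
            if cov.get(d, -1) >= seed.sstart + seed.length:
                continue
            score, qb, qe, sb, se = extend_seed(seed, codes, index.codes,
                                                scheme, x_drop)
            d1, d2 = sb - qb, se - qe
            for dd in range(min(d1, d2) - reach, max(d1, d2) + reach + 1):
                if cov.get(dd, -1) < se:
                    cov[dd] = se
            if score < min_report_score:
                continue
            key = (qb, qe, sb, se)
            if key in seen:
                continue
            seen.add(key)
            gscore, matches, mism, gaps, gopens, cols = _hit_stats(
                codes, index.codes, qb, qe, sb, se, scheme, x_drop)
            if strand == "+":
                q1, q2 = qb + 1, qe
            else:  # map back from the reverse-complemented query frame
                q1, q2 = m - qe + 1, m - qb
            hits.append(AlignmentHit(
                query_id=rec.id, query_start=q1, query_end=q2,
                subject_chrom=index.name, subject_start=sb, subject_end=se,
                strand=strand, score=int(score), aligned_cols=int(cols),
                matches=int(matches), mismatches=int(mism), gaps=int(gaps),
                gap_opens=int(gopens),
                evalue=scheme.evalue(int(score), m, n_total),
                query_kind=rec.kind))
    return hits


def _wrap_pad_hits(hits: list[AlignmentHit], pool: PanMitogenome):
    """Remap query coordinates of hits lying entirely within the pad.

    A hit confined to the circular extension is the same alignment as one
    starting at position 1 of the unpadded molecule; reporting it on wrapped
    coordinates keeps downstream breakpoint profiles origin-consistent.
    """
    orig = {rec.id: rec.original_length for rec in pool}
    out = []
    for h in hits:
        L = orig.get(h.query_id)
        if L is not None and h.query_start > L:
            h = replace(h, query_start=h.query_start - L,
                        query_end=h.query_end - L)
        out.append(h)
    return out


def find_numts(
    pool: PanMitogenome,
    genome: dict[str, str],
    scheme: ScoringScheme | None = None,
    thresholds: FilterThresholds | None = None,
    word_size: int = DEFAULT_WORD_SIZE,
    x_drop: int = DEFAULT_XDROP,
) -> tuple[IntervalSet, list[AlignmentHit]]:
    """Search every pool record against a nuclear genome.

    *genome* maps contig name to sequence.  Returns the merged NUMT interval
    set and the filtered per-hit table (retained for breakpoint profiling).
    """
    if pool.total == 0:
        raise ValueError("empty pan-mitogenome pool")
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty nuclear genome")
    scheme = scheme or ScoringScheme()
    thresholds = thresholds or FilterThresholds()
    n_total = sum(len(s) for s in genome.values())

    all_hits: list[AlignmentHit] = []
    for name in genome:
        index = GenomeIndex(name, genome[name], word_size)
        for rec in pool:
            all_hits.extend(_search_record(
                rec, index, scheme, n_total, x_drop, thresholds.max_evalue))
    all_hits = _wrap_pad_hits(all_hits, pool)
    kept, removed = filter_hits(all_hits, thresholds)
    log.info("find_numts: %d raw hits, %d after filters (removed %s)",
             len(all_hits), len(kept), removed)
    numts = merge(IntervalSet(
        (GenomicInterval(h.subject_chrom, h.subject_start, h.subject_end)
         for h in kept)))
    return numts, kept


OUTFMT6_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "score")


def write_hit_table(hits: list[AlignmentHit], path) -> None:
    """Tab-separated hit table with BLAST outfmt-6 column semantics.

    ``sstart``/``send`` are 1-based inclusive with sstart > send on '-'
    hits, as BLAST prints them; the final column is the raw score.
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(OUTFMT6_COLUMNS) + "\n")
        for h in hits:
            if h.strand == "+":
                s1, s2 = h.subject_start + 1, h.subject_end
            else:
                s1, s2 = h.subject_end, h.subject_start + 1
            fh.write("\t".join(map(str, (
                h.query_id, h.subject_chrom, f"{h.identity:.2f}",
                h.aligned_cols, h.mismatches, h.gap_opens,
                h.query_start, h.query_end, s1, s2,
                f"{h.evalue:.2e}", h.score))) + "\n")
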
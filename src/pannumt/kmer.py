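"""k-mer decomposition of the pool and short-segment homology scanning.

Full-length NUMT discovery by thresholded local alignment cannot report
segments shorter than its e-value cutoff allows (~28 bp under the default
scheme), yet shorter mtDNA-like stretches still capture reads and amplicon
primers.  This module decomposes the pan-mitogenome into k-mers (default
20), maps them exactly onto a nuclear genome on both strands, merges the
per-base footprints into maximal segments, and locates the knee of the
segment-length distribution — the point where segment counts collapse,
which motivates the minimum credible NUMT length.

The k-mer table maps directly against the genome; no pseudo-FASTQ reads or
fake quality strings are manufactured to coax a read aligner into doing
k-mer matching — the mathematical content is identical.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._encode import encode, kmer_keys, revcomp
from .intervals import GenomicInterval
from .panmito import PanMitogenome

log = logging.getLogger(__name__)

DEFAULT_K = 20
#: Length filter motivated by the knee of the segment-length distribution.
DEFAULT_MIN_NUMT_LEN = 28


@dataclass
class KmerTable:
    """Multiset of k-mers extracted from a sequence pool."""

    k: int
    counts: Counter

    @property
    def total_segments(self) -> int:
        return sum(self.counts.values())

    @property
    def unique_count(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class KmerHit:
    """One distinct (k-mer, genome position) placement."""

    chrom: str
    start: int
    strand: str
    kmer: str
    pool_count: int


@dataclass(frozen=True)
class MappedSegment:
    """A maximal nuclear segment covered by mapped k-mers."""

    interval: GenomicInterval
    supporting_kmers: int
    depth_max: int


def decompose(pool: PanMitogenome | list, k: int = DEFAULT_K) -> KmerTable:
    """Slide a k-window base by base over every pool record and count k-mers.

    Windows containing N or any other IUPAC ambiguity code are discarded;
    only clean {A,C,G,T} words enter the table.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts: Counter = Counter()
    records = pool.records if isinstance(pool, PanMitogenome) else pool
    for rec in records:
        seq = rec.sequence if hasattr(rec, "sequence") else str(rec)
        codes = encode(seq)
        _, valid = kmer_keys(codes, k)
        for pos in np.nonzero(valid)[0]:
            counts[seq[pos: pos + k]] += 1
    return KmerTable(k=k, counts=counts)


def _exact_hits(table: KmerTable, chrom: str, seq: str) -> list[KmerHit]:
    codes = encode(seq)
    keys, valid = kmer_keys(codes, table.k)
    sorted_kmers = sorted(table.counts)
    tkeys = np.array(
        [kmer_keys(encode(km), table.k)[0][0] for km in sorted_kmers],
        dtype=np.int64) if sorted_kmers else np.empty(0, dtype=np.int64)
    order = np.argsort(tkeys)
    tkeys = tkeys[order]
    kmers_by_key = [sorted_kmers[i] for i in order]

    hits: list[KmerHit] = []
    pos_all = np.nonzero(valid)[0]
    for strand in ("+", "-"):
        if strand == "+":
            win_keys = keys[pos_all]
        else:
            # key of the reverse complement of each genome window
            rc = 3 - codes
            k = table.k
            win_keys = np.zeros(len(pos_all), dtype=np.int64)
            for t in range(k):
                win_keys = (win_keys << 2) | rc[pos_all + k - 1 - t].astype(np.int64)
        idx = np.searchsorted(tkeys, win_keys)
        ok = (idx < len(tkeys))
        ok[ok] &= tkeys[idx[ok]] == win_keys[ok]
        for p, i in zip(pos_all[ok], idx[ok]):
            km = kmers_by_key[i]
            hits.append(KmerHit(chrom, int(p), strand, km, table.counts[km]))
    return hits


def _mismatch_hits(table: KmerTable, chrom: str, seq: str,
                   max_mismatch: int) -> list[KmerHit]:
    """Hamming-tolerant mapping via pigeonhole chunking of table k-mers."""
    k = table.k
    nchunks = max_mismatch + 1
    bounds = [round(i * k / nchunks) for i in range(nchunks + 1)]
    chunk_index: dict[tuple[int, str], list[str]] = {}
    for km in table.counts:
        for ci in range(nchunks):
            chunk = km[bounds[ci]: bounds[ci + 1]]
            chunk_index.setdefault((ci, chunk), []).append(km)
    hits: dict[tuple[str, int, str], str] = {}
    for strand in ("+", "-"):
        genome = seq if strand == "+" else revcomp(seq)
        L = len(genome)
        for p in range(L - k + 1):
            window = genome[p: p + k]
            if any(b not in "ACGT" for b in window):
                continue
            fwd_pos = p if strand == "+" else L - k - p
            cands: set[str] = set()
            for ci in range(nchunks):
                cands.update(
                    chunk_index.get((ci, window[bounds[ci]: bounds[ci + 1]]), ()))
            for km in cands:
                mism = sum(a != b for a, b in zip(km, window))
                if mism <= max_mismatch:
                    hits.setdefault((km, fwd_pos, strand), km)
    return [KmerHit(chrom, pos, strand, km, table.counts[km])
            for (km, pos, strand), _ in sorted(hits.items())]


def map_kmers(table: KmerTable, genome: dict[str, str],
              max_mismatch: int = 0) -> list[KmerHit]:
    """Place every table k-mer on the genome, both strands.

    Each distinct (k-mer, position) pair is reported once — a k-mer
    matching the same spot on both strands (a reverse-complement
    palindrome) collapses to a single placement, mirroring duplicate
    removal in read-based pipelines.  ``max_mismatch`` up to 3 enables
    Hamming-tolerant matching; the default is exact.
    """
    if not genome:
        raise ValueError("empty genome")
    if max_mismatch > 3:
        raise ValueError("max_mismatch must be <= 3")
    hits: list[KmerHit] = []
    for chrom, seq in genome.items():
        if max_mismatch == 0:
            raw = _exact_hits(table, chrom, seq)
        else:
            raw = _mismatch_hits(table, chrom, seq, max_mismatch)
        # collapse duplicate placements of the same k-mer
        seen: set[tuple[str, int]] = set()
        for h in sorted(raw, key=lambda h: (h.start, h.strand)):
            if (h.kmer, h.start) in seen:
                continue
            seen.add((h.kmer, h.start))
            hits.append(h)
    return hits


def merge_positions(hits: list[KmerHit], k: int = DEFAULT_K) -> list[MappedSegment]:
    """Merge overlapping k-mer footprints into maximal mapped segments."""
    by_chrom: dict[str, list[KmerHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    segments: list[MappedSegment] = []
    for chrom in sorted(by_chrom):
        hs = sorted(by_chrom[chrom], key=lambda h: h.start)
        group: list[KmerHit] = []
        end = -1
        for h in hs + [None]:
            if h is not None and (not group or h.start <= end):
                group.append(h)
                end = max(end, h.start + k)
                continue
            if group:
                start = group[0].start
                depth = np.zeros(end - start, dtype=np.int64)
                for g in group:
                    depth[g.start - start: g.start - start + k] += 1
                segments.append(MappedSegment(
                    interval=GenomicInterval(chrom, start, end),
                    supporting_kmers=len({g.kmer for g in group}),
                    depth_max=int(depth.max())))
            if h is not None:
                group = [h]
                end = h.start + k
    return segments


def length_histogram(segments: list[MappedSegment]) -> dict[int, tuple[int, int]]:
    """Map segment length -> (segment count, supporting k-mer count)."""
    hist: dict[int, list[int]] = {}
    for seg in segments:
        L = len(seg.interval)
        entry = hist.setdefault(L, [0, 0])
        entry[0] += 1
        entry[1] += seg.supporting_kmers
    return {L: (c, s) for L, (c, s) in sorted(hist.items())}


def turning_point(histogram: dict[int, tuple[int, int] | int],
                  k: int = DEFAULT_K,
                  search_range: tuple[int, int] | None = None,
                  default: int = DEFAULT_MIN_NUMT_LEN) -> int:
    """Locate the knee of the (log) k-mer count vs segment length curve.

    Operationalizes the visual "turning point" of the length distribution
    as the length L within ``search_range`` (default ``[k+1, 3k]``) with
    the maximal drop of log-counts relative to the previous occupied
    length; ties break toward smaller L.  A flat or unoccupied range
    yields *default* with a warning.
    """
    if not histogram:
        log.warning("turning_point: empty histogram, returning default %d", default)
        return default
    lo, hi = search_range if search_range else (k + 1, 3 * k)
    lengths = sorted(histogram)

    def count_of(L: int) -> float:
        v = histogram[L]
        return float(v[1] if isinstance(v, (tuple, list)) else v)

    best_L, best_drop = None, 0.0
    for prev, L in zip(lengths, lengths[1:]):
        if not lo <= L <= hi:
            continue
        c_prev, c = count_of(prev), count_of(L)
        if c_prev <= 0 or c <= 0:
            continue
        drop = math.log(c_prev) - math.log(c)
        if drop > best_drop:
            best_drop, best_L = drop, L
    if best_L is None:
        log.warning(
            "turning_point: no decreasing step in [%d, %d]; returning default %d",
            lo, hi, default)
        return default
    return best_L


def write_segments_bed(segments: list[MappedSegment], path) -> None:
    """Segments as BED4+2: name = supporting k-mers, extra depth column."""
    with open(path, "w") as fh:
        for seg in segments:
            iv = seg.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                     f"kmers={seg.supporting_kmers}\t{seg.depth_max}\n")


def write_histogram(histogram: dict[int, tuple[int, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("length\tn_segments\tn_kmers\n")
        for L, (c, s) in histogram.items():
            fh.write(f"{L}\t{c}\t{s}\n")
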
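"""BED-backed genomic interval algebra.

Internal coordinates are 0-based half-open throughout (the BED convention);
mitochondrial positions are converted to 1-based inclusive only at the
reporting edge (see :mod:`pannumt.breakpoints`).  Merging joins book-ended
intervals by default, matching ``bedtools merge``.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """A collection of intervals grouped per chromosome, sorted by start.

    ``genome`` is a free-text assembly label; operations combining two sets
    refuse mismatched labels to prevent cross-assembly comparisons.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), genome: str = ""):
        self.genome = genome
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in self._by_chrom.values():
            ivs.sort(key=lambda iv: (iv.start, iv.end))

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def per_chrom(self, chrom: str) -> list[GenomicInterval]:
        return list(self._by_chrom.get(chrom, []))

    def total_length(self) -> int:
        return sum(len(iv) for iv in self)


def merge(intervals: IntervalSet, min_gap: int = 0) -> IntervalSet:
    """Merge overlapping intervals into a minimal disjoint set.

    Intervals separated by a gap < *min_gap* are also joined; with the
    default ``min_gap = 0`` book-ended intervals (end == next start) merge,
    as ``bedtools merge`` does.  Names of merged inputs are concatenated
    (de-duplicated, order-preserving) so provenance survives union-building.
    """
    out: list[GenomicInterval] = []
    for chrom in intervals.chroms:
        ivs = intervals.per_chrom(chrom)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        names: list[str] = [ivs[0].name] if ivs[0].name else []
        for iv in ivs[1:]:
            gap = iv.start - cur_end
            if gap <= 0 or gap < min_gap:
                cur_end = max(cur_end, iv.end)
                if iv.name and iv.name not in names:
                    names.append(iv.name)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end,
                                           ",".join(names) or None))
                cur_start, cur_end = iv.start, iv.end
                names = [iv.name] if iv.name else []
        out.append(GenomicInterval(chrom, cur_start, cur_end,
                                   ",".join(names) or None))
    return IntervalSet(out, genome=intervals.genome)


@dataclass(frozen=True)
class SummaryStats:
    count: int
    total_length: int
    min: int
    median: int
    mean: float
    max: int


def summary_stats(intervals: IntervalSet) -> SummaryStats:
    """Count / total / min / median / mean / max of interval lengths.

    The median of an even count is the lower median, so that every reported
    statistic is an attained interval length.  An empty set yields all
    zeros with a warning.
    """
    lengths = sorted(len(iv) for iv in intervals)
    if not lengths:
        log.warning("summary_stats on an empty interval set")
        return SummaryStats(0, 0, 0, 0, 0.0, 0)
    return SummaryStats(
        count=len(lengths),
        total_length=sum(lengths),
        min=lengths[0],
        median=statistics.median_low(lengths),
        mean=sum(lengths) / len(lengths),
        max=lengths[-1],
    )


def _check_same_genome(a: IntervalSet, b: IntervalSet) -> None:
    if a.genome != b.genome:
        raise ValueError(
            f"genome label mismatch: {a.genome!r} vs {b.genome!r}"
        )


def intersect_length(a: IntervalSet, b: IntervalSet) -> int:
    """Total bases shared by two merged interval sets (sweep per chromosome)."""
    shared = 0
    for chrom in a.chroms:
        xs, ys = a.per_chrom(chrom), b.per_chrom(chrom)
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if hi > lo:
                shared += hi - lo
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return shared


@dataclass(frozen=True)
class OverlapStats:
    shared_length: int
    frac_a_in_b: float
    frac_b_in_a: float
    frac_shared_of_union: float


def overlap_stats(a: IntervalSet, b: IntervalSet) -> OverlapStats:
    """Base-level overlap between two merged compilations.

    Returns the shared length plus three fractions (shared/|A|, shared/|B|,
    shared/|A ∪ B|).  Both conditional fractions are reported because
    published comparisons of NUMT compilations use sometimes one, sometimes
    the other denominator.
    """
    _check_same_genome(a, b)
    a, b = merge(a), merge(b)
    shared = intersect_length(a, b)
    la, lb = a.total_length(), b.total_length()
    union = la + lb - shared
    return OverlapStats(
        shared_length=shared,
        frac_a_in_b=shared / la if la else 0.0,
        frac_b_in_a=shared / lb if lb else 0.0,
        frac_shared_of_union=shared / union if union else 0.0,
    )


def blacklist_union(
    numts: IntervalSet,
    external_blacklist: IntervalSet,
    observed_pileups: IntervalSet,
) -> IntervalSet:
    """Union of NUMTs, an external mito-blacklist, and observed read pileups.

    This is the combined exclusion set ("NUMTs-Blacklist") recommended for
    chromatin-accessibility assays; each output interval's name lists which
    source compilations contributed to it.
    """
    _check_same_genome(numts, external_blacklist)
    _check_same_genome(numts, observed_pileups)
    labelled: list[GenomicInterval] = []
    for src, ivs in (("numts", numts),
                     ("blacklist", external_blacklist),
                     ("pileup", observed_pileups)):
        labelled.extend(replace(iv, name=src) for iv in ivs)
    return merge(IntervalSet(labelled, genome=numts.genome))


def read_bed(path) -> IntervalSet:
    """Read a 3–6 column BED file (0-based half-open) into an IntervalSet.

    ``track`` and ``browser`` lines are skipped with a warning; malformed
    coordinates raise with the offending line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                log.warning("%s:%d: skipping header line", path, lineno)
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] != "." else None
            intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path) -> None:
    """Write an IntervalSet as BED, emitting only the populated columns."""
    ncols = 3
    for iv in intervals:
        if iv.strand is not None:
            ncols = 6
            break
        if iv.score is not None:
            ncols = max(ncols, 5)
        elif iv.name is not None:
            ncols = max(ncols, 4)
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if ncols >= 4:
                fields.append(iv.name if iv.name is not None else ".")
            if ncols >= 5:
                fields.append(f"{iv.score:g}" if iv.score is not None else ".")
            if ncols >= 6:
                fields.append(iv.strand if iv.strand is not None else ".")
            fh.write("\t".join(fields) + "\n")
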
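"""Project NUMT hits back onto circular mtDNA coordinates.

Every filtered hit carries the query interval it came from; projecting
those intervals onto the 16,569 bp circular mitogenome yields a per-position
coverage profile plus per-position counts of hit endpoints.  Insertion
breakpoints show up two ways: as dips in coverage and as peaks of endpoint
density.  Both are computed; low-coverage runs can then be annotated
against an mtDNA feature map (control region, tRNA, rRNA, coding genes).

All positions in this module are 1-based inclusive, the convention in
which mitochondrial features are published (control region
16,024–16,569 ∪ 1–576); conversion from the interval modules' 0-based
half-open frame happens only here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

MT_LENGTH = 16_569

CATEGORIES = ("control", "tRNA", "rRNA", "CDS")


@dataclass
class MtCoverageProfile:
    """Per-position hit coverage and endpoint counts on the circular mtDNA."""

    mt_length: int = MT_LENGTH
    coverage: np.ndarray = field(default=None)  # index 0 is position 1
    endpoints: np.ndarray = field(default=None)
    n_hits: int = 0

    def __post_init__(self) -> None:
        if self.coverage is None:
            self.coverage = np.zeros(self.mt_length, dtype=np.int64)
        if self.endpoints is None:
            self.endpoints = np.zeros(self.mt_length, dtype=np.int64)


@dataclass(frozen=True)
class MtFeature:
    name: str
    start: int  # 1-based inclusive; start > end means the feature wraps
    end: int
    category: str

    def positions(self, mt_length: int) -> np.ndarray:
        """0-based position indices covered, handling origin wrap."""
        if self.start <= self.end:
            return np.arange(self.start - 1, self.end)
        return np.concatenate(
            [np.arange(self.start - 1, mt_length), np.arange(0, self.end)])


@dataclass
class MtAnnotation:
    features: list[MtFeature]
    mt_length: int = MT_LENGTH

    def __post_init__(self) -> None:
        for f in self.features:
            if not (1 <= f.start <= self.mt_length and 1 <= f.end <= self.mt_length):
                raise ValueError(f"feature {f.name} outside 1..{self.mt_length}")
            if f.category not in CATEGORIES:
                raise ValueError(f"feature {f.name}: unknown category {f.category}")


def project_to_mt(hits, mt_length: int = MT_LENGTH, pad: int = 100,
                  record_lengths: dict[str, int] | None = None
                  ) -> MtCoverageProfile:
    """Accumulate wrapped query-interval coverage and endpoint counts.

    Hits are expected to carry 1-based inclusive query intervals on the
    padded molecule (length ``mt_length + pad``); positions beyond
    ``mt_length`` wrap to ``p - mt_length``.  Only hits whose queries are
    anchored on mitogenome coordinates (full-length or reference records)
    belong here — control-fragment hits have fragment-local coordinates.

    Real molecules differ from the canonical circle length by a few indel
    bases; passing ``record_lengths`` (id -> unpadded length) widens the
    corrupt-hit bound to each record's own padded length while still
    projecting onto the canonical ``mt_length`` circle.
    """
    prof = MtCoverageProfile(mt_length=mt_length)
    for h in hits:
        q1, q2 = h.query_start, h.query_end
        own = (record_lengths or {}).get(h.query_id, mt_length)
        if not (1 <= q1 <= q2 <= max(own, mt_length) + pad):
            raise ValueError(
                f"hit {h.query_id} query interval {q1}..{q2} exceeds padded "
                f"molecule length {max(own, mt_length) + pad}")
        idx = np.arange(q1 - 1, q2) % mt_length
        np.add.at(prof.coverage, idx, 1)  # a hit spanning the pad revisits bases
        prof.endpoints[(q1 - 1) % mt_length] += 1
        prof.endpoints[(q2 - 1) % mt_length] += 1
        prof.n_hits += 1
    return prof


def _circular_runs(mask: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Maximal circular runs of True, as 1-based inclusive (start, end).

    A run wrapping the origin is reported once with start > end.
    """
    n = len(mask)
    if mask.all():
        return [(1, n)]
    if not mask.any():
        return []
    # rotate so position 0 is outside any run, then scan linearly
    off = int(np.nonzero(~mask)[0][0])
    rot = np.roll(mask, -off)
    runs = []
    d = np.diff(rot.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if rot[-1]:
        ends.append(n)
    for a, b in zip(starts, ends):
        if b - a >= min_run:
            s = (a + off) % n
            e = (b - 1 + off) % n
            runs.append((s + 1, e + 1))
    runs.sort()
    return runs


def low_coverage_regions(profile: MtCoverageProfile, quantile: float = 0.05,
                         min_run: int = 20) -> list[tuple[int, int]]:
    """Maximal circular runs of low coverage, candidate breakpoint zones.

    Positions whose coverage is <= the given quantile of the coverage
    distribution form the low mask; runs shorter than *min_run* are
    discarded.  Runs may wrap the origin (start > end).  A uniform profile
    has no distinguishable low positions and yields an empty list; an
    all-zero profile yields the full circle with a warning.
    """
    cov = profile.coverage
    if cov.max() == cov.min():
        if cov.max() == 0:
            log.warning("low_coverage_regions: all-zero profile")
            return [(1, profile.mt_length)]
        return []
    thresh = np.quantile(cov, quantile, method="lower")
    return _circular_runs(cov <= thresh, min_run)


def annotate_regions(regions: list[tuple[int, int]], annotation: MtAnnotation):
    """Per-region fractions of bases in each feature category.

    Each base is assigned at most one category (priority: control > tRNA >
    rRNA > CDS when features overlap); remaining bases count as
    ``unannotated``, so the fractions of one region sum to exactly 1.
    """
    n = annotation.mt_length
    cat_of = np.full(n, -1, dtype=np.int8)
    for ci in reversed(range(len(CATEGORIES))):  # low priority painted first
        for f in annotation.features:
            if f.category == CATEGORIES[ci]:
                cat_of[f.positions(n)] = ci
    out = []
    for start, end in regions:
        if start <= end:
            idx = np.arange(start - 1, end)
        else:
            idx = np.concatenate([np.arange(start - 1, n), np.arange(0, end)])
        cats = cat_of[idx]
        fracs = {c: float((cats == i).sum()) / len(idx)
                 for i, c in enumerate(CATEGORIES)}
        fracs["unannotated"] = float((cats == -1).sum()) / len(idx)
        out.append(((start, end), fracs))
    return out


def write_profile(profile: MtCoverageProfile, path) -> None:
    """Tab-separated per-position profile: position, coverage, endpoints."""
    with open(path, "w") as fh:
        fh.write("position\tcoverage\tendpoints\n")
        for i in range(profile.mt_length):
            fh.write(f"{i + 1}\t{profile.coverage[i]}\t{profile.endpoints[i]}\n")
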
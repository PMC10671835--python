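"""Synthetic mitochondrial populations and nuclear genomes with planted NUMTs.

The generator emulates the structure the discovery method consumes:

* a full-length mtDNA population derived from one random root mitogenome by
  independent per-lineage substitutions and small indels (a star phylogeny —
  the real pool is an observational database, not a modelled genealogy, and
  the method only needs its redundancy/diversity structure), with a
  configurable fraction of exact duplicate entries;
* control-region fragments (400–1598 bp) cut from population members at the
  control-region coordinates, wrapping the circular origin as needed;
* an i.i.d. nuclear background with NUMT copies planted at known positions:
  each copy is cut from the circular root, mutated to a target divergence
  (10:1 substitution:indel mix, geometric indel lengths capped at 10 bp)
  and inserted, with the post-insertion coordinates recorded in a truth set.

Everything is deterministic under the configured seed; independent RNG
streams are derived per generator so that, e.g., planting NUMTs never
perturbs the population draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, IntervalSet
from .panmito import MitoRecord

MT_LENGTH = 16_569
#: Control region (D-loop) bounds, 1-based inclusive, wrapping the origin.
CONTROL_REGION = ((16_024, 16_569), (1, 576))

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class NumtSpec:
    """One planted insertion: source window on the circular root + target."""

    source_start: int        # 0-based on the circular root
    source_length: int
    divergence: float
    insertion_point: int     # 0-based on the pre-insertion background


@dataclass
class SimConfig:
    """Generator settings; the defaults define the standard benchmark scene."""

    seed: int = 7
    mt_length: int = MT_LENGTH
    n_full: int = 24
    dup_fraction: float = 0.25
    sub_rate: float = 0.01
    indel_rate: float = 0.0005
    n_control: int = 40
    control_len_range: tuple[int, int] = (400, 1598)
    background_len: int = 2_000_000
    background_gc: float = 0.41
    n_numts: int = 50
    numt_len_range: tuple[int, int] = (35, 14_855)
    max_divergence: float = 0.20
    numt_specs: list[NumtSpec] | None = None
    k: int = 20

    def __post_init__(self) -> None:
        for r in (self.dup_fraction, self.sub_rate, self.indel_rate,
                  self.max_divergence):
            if not 0 <= r < 1:
                raise ValueError("rates must lie in [0, 1)")
        lo, hi = self.control_len_range
        if not 0 < lo <= hi < self.mt_length:
            raise ValueError("control_len_range must lie within (0, mt_length)")


@dataclass
class TruthSet:
    """Simulated nuclear genome plus the exact planted-NUMT intervals."""

    genome: dict[str, str]
    truth: IntervalSet
    specs: list[NumtSpec] = field(default_factory=list)
    divergences: dict[tuple[str, int, int], float] = field(default_factory=dict)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode()


def root_mitogenome(config: SimConfig) -> str:
    """The shared root mtDNA all lineages and planted copies derive from."""
    return _random_seq(_rng(config, 0), config.mt_length, gc=0.44)


def mutate(seq: str, sub_rate: float, indel_rate: float,
           rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions and small indels to a sequence.

    Substitutions pick a different base uniformly.  Indels occur at
    ``indel_rate`` per site, insertion or deletion with equal probability,
    lengths geometric(0.5) capped at 10 bp.
    """
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(codes)
    lut = {b: i for i, b in enumerate(b"ACGT")}
    arr = np.array([lut[b] for b in codes], dtype=np.int8)
    subs = np.nonzero(rng.random(n) < sub_rate)[0]
    if len(subs):
        arr[subs] = (arr[subs] + rng.integers(1, 4, size=len(subs))) % 4
    out: list[str] = []
    indel_sites = set(np.nonzero(rng.random(n) < indel_rate)[0].tolist())
    i = 0
    while i < n:
        if i in indel_sites:
            length = min(int(rng.geometric(0.5)), 10)
            if rng.random() < 0.5:  # deletion
                i += length
                continue
            ins = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
            out.append(chr(_BASES[arr[i]]) + ins)
            i += 1
        else:
            out.append(chr(_BASES[arr[i]]))
            i += 1
    return "".join(out)


def simulate_population(config: SimConfig) -> list[MitoRecord]:
    """Full-length records: mutated lineages plus exact duplicate entries.

    Exactly ``round(dup_fraction * n_full)`` records are byte-copies of
    earlier distinct lineages, so exact deduplication must retain
    ``n_full - that`` records.  Lineages whose indels push them below the
    full-length acceptance bound are redrawn (bounded retries).
    """
    rng = _rng(config, 1)
    root = root_mitogenome(config)
    n_dup = int(round(config.dup_fraction * config.n_full))
    n_distinct = config.n_full - n_dup
    distinct: list[str] = []
    min_len = 16_530 if config.mt_length >= 16_530 else int(config.mt_length * 0.997)
    mutating = config.sub_rate > 0 or config.indel_rate > 0
    for _ in range(n_distinct):
        chosen = None
        for _attempt in range(50):
            seq = mutate(root, config.sub_rate, config.indel_rate, rng)
            if len(seq) < min_len:
                continue
            if mutating and seq in distinct:
                continue  # redraw; collisions are astronomically rare anyway
            chosen = seq
            break
        if chosen is None:
            raise RuntimeError("could not satisfy the length constraint; "
                               "indel_rate too high for the minimum length")
        distinct.append(chosen)
    seqs = list(distinct)
    for i in range(n_dup):
        seqs.append(distinct[int(rng.integers(0, n_distinct))])
    return [MitoRecord(id=f"sim_full_{i:05d}", sequence=s, kind="full")
            for i, s in enumerate(seqs)]


def control_region_positions(mt_length: int = MT_LENGTH) -> np.ndarray:
    """0-based circular positions of the control region."""
    (a1, a2), (b1, b2) = CONTROL_REGION
    return np.concatenate([np.arange(a1 - 1, a2), np.arange(b1 - 1, b2)])


def simulate_control_fragments(population: list[MitoRecord],
                               config: SimConfig) -> list[MitoRecord]:
    """Cut control-region fragments from random population members.

    Fragment starts are uniform over the control-region coordinates,
    lengths uniform in ``control_len_range``; fragments crossing the origin
    wrap circularly on the donor molecule.
    """
    if not population:
        raise ValueError("population is empty")
    rng = _rng(config, 2)
    lo, hi = config.control_len_range
    ctrl = control_region_positions(config.mt_length)
    frags = []
    for i in range(config.n_control):
        donor = population[int(rng.integers(0, len(population)))]
        L = len(donor.sequence)
        start = int(ctrl[rng.integers(0, len(ctrl))]) % L
        flen = int(rng.integers(lo, hi + 1))
        doubled = donor.sequence + donor.sequence
        frags.append(MitoRecord(id=f"sim_ctrl_{i:05d}",
                                sequence=doubled[start: start + flen],
                                kind="control"))
    return frags


def _default_specs(config: SimConfig, rng: np.random.Generator) -> list[NumtSpec]:
    lo, hi = config.numt_len_range
    lengths = np.exp(rng.uniform(math.log(lo), math.log(hi),
                                 size=config.n_numts)).astype(int)
    lengths = np.clip(lengths, lo, hi)
    divs = rng.uniform(0.0, config.max_divergence, size=config.n_numts)
    # non-overlapping insertion points with room between them
    points = np.sort(rng.choice(
        np.arange(1000, config.background_len - 1000),
        size=config.n_numts, replace=False))
    while np.any(np.diff(points) < 50):
        points = np.sort(rng.choice(
            np.arange(1000, config.background_len - 1000),
            size=config.n_numts, replace=False))
    starts = rng.integers(0, config.mt_length, size=config.n_numts)
    return [NumtSpec(int(s), int(L), float(d), int(p))
            for s, L, d, p in zip(starts, lengths, divs, points)]


def plant_numts(config: SimConfig, chrom: str = "chrS") -> TruthSet:
    """Generate the nuclear background and insert divergent mtDNA copies.

    Returns the genome plus a truth interval set whose name field records
    each copy's source window and divergence.  Insertion points are
    required to be distinct and non-overlapping.
    """
    rng = _rng(config, 3)
    root = root_mitogenome(config)
    doubled = root + root
    background = _random_seq(rng, config.background_len, config.background_gc)
    specs = config.numt_specs or _default_specs(config, rng)
    pts = [sp.insertion_point for sp in specs]
    if len(set(pts)) != len(pts):
        raise ValueError("overlapping insertion points")
    order = np.argsort(pts)
    pieces: list[str] = []
    truth: list[GenomicInterval] = []
    divergences: dict[tuple[str, int, int], float] = {}
    cursor = 0
    placed = 0
    for oi in order:
        sp = specs[oi]
        if sp.source_length > config.mt_length:
            raise ValueError("source_length exceeds the mitogenome")
        src = doubled[sp.source_start: sp.source_start + sp.source_length]
        sub = sp.divergence * 10.0 / 11.0
        indel = sp.divergence / 11.0
        copy = mutate(src, sub, indel, rng)
        pieces.append(background[cursor: sp.insertion_point])
        start = sum(len(p) for p in pieces)
        pieces.append(copy)
        end = start + len(copy)
        name = (f"numt{oi:03d}|src={sp.source_start}+{sp.source_length}"
                f"|div={sp.divergence:.3f}")
        truth.append(GenomicInterval(chrom, start, end, name))
        divergences[(chrom, start, end)] = sp.divergence
        cursor = sp.insertion_point
        placed += 1
    pieces.append(background[cursor:])
    genome = {chrom: "".join(pieces)}
    return TruthSet(genome=genome,
                    truth=IntervalSet(truth, genome="sim"),
                    specs=specs, divergences=divergences)


@dataclass
class RecoveryReport:
    """Recovery metrics of a called compilation against the planted truth."""

    recall: float
    precision: float
    mean_boundary_error: float
    recovered: list[tuple[GenomicInterval, GenomicInterval]]
    missed: list[GenomicInterval]
    false_calls: list[GenomicInterval]

    def recall_at(self, truthset: TruthSet, max_divergence: float) -> float:
        """Recall restricted to truth NUMTs with divergence <= the bound."""
        div = truthset.divergences
        key = lambda iv: (iv.chrom, iv.start, iv.end)
        rec = sum(1 for t, _ in self.recovered
                  if div[key(t)] <= max_divergence)
        tot = rec + sum(1 for t in self.missed if div[key(t)] <= max_divergence)
        return rec / tot if tot else 1.0

    def boundary_error_at(self, truthset: TruthSet,
                          max_divergence: float) -> float:
        """Mean |boundary offset| over recovered pairs below the bound."""
        div = truthset.divergences
        errs = [abs(t.start - c.start) + abs(t.end - c.end)
                for t, c in self.recovered
                if div[(t.chrom, t.start, t.end)] <= max_divergence]
        return sum(errs) / (2 * len(errs)) if errs else 0.0


def evaluate_recovery(called: IntervalSet, truthset: TruthSet,
                      slack: int = 5) -> RecoveryReport:
    """Score a called interval set against the planted truth.

    A truth interval is recovered when some called interval overlaps it
    reciprocally by >= 50%; a called interval overlapping no truth at all
    counts as a false call.  Boundary error is the mean absolute start/end
    offset over recovered pairs; *slack* is the tolerance within which a
    recovered boundary is considered exact in the per-pair bookkeeping.
    """
    truth = list(truthset.truth)
    calls = list(called)
    recovered, missed = [], []
    used_calls: set[int] = set()
    for t in truth:
        best, best_ov = None, 0
        for ci, c in enumerate(calls):
            if c.chrom != t.chrom:
                continue
            ov = min(c.end, t.end) - max(c.start, t.start)
            if ov <= 0:
                continue
            if ov >= 0.5 * len(t) and ov >= 0.5 * len(c) and ov > best_ov:
                best, best_ov = ci, ov
        if best is None:
            missed.append(t)
        else:
            recovered.append((t, calls[best]))
            used_calls.add(best)
    false_calls = []
    for ci, c in enumerate(calls):
        touches = any(
            c.chrom == t.chrom and min(c.end, t.end) - max(c.start, t.start) > 0
            for t in truth)
        if not touches:
            false_calls.append(c)
    n_truth = len(truth)
    recall = len(recovered) / n_truth if n_truth else 1.0
    precision = (len(calls) - len(false_calls)) / len(calls) if calls else 1.0
    errs = [abs(t.start - c.start) + abs(t.end - c.end) for t, c in recovered]
    mbe = sum(errs) / (2 * len(errs)) if errs else 0.0
    return RecoveryReport(recall=recall, precision=precision,
                          mean_boundary_error=mbe, recovered=recovered,
                          missed=missed, false_calls=false_calls)
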
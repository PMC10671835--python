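"""Build the pan-mitogenome query pool from mitochondrial FASTA inputs.

The pool combines three kinds of query sequences: full-length mitochondrial
genomes (exact duplicates removed, short assemblies filtered out),
control-region fragments (kept redundant — identical fragments map to the
same nuclear regions and are merged downstream anyway), and one reference
mitogenome.  Because mtDNA is circular, full-length records are extended by
copying their first ``pad`` bases onto the end, so alignments spanning the
arbitrary linearization origin are not lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO

from ._encode import IUPAC_CODES

log = logging.getLogger(__name__)

#: Minimum accepted full-length mitogenome (the shortest plausible complete
#: human mtDNA; shorter entries are partial assemblies).
DEFAULT_MIN_FULL_LEN = 16_530
#: Circular extension length in bases.
DEFAULT_PAD = 100

KINDS = ("full", "control", "reference")


@dataclass(frozen=True)
class MitoRecord:
    """One query sequence with circular-padding bookkeeping."""

    id: str
    sequence: str
    kind: str
    original_length: int = 0
    pad: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown record kind {self.kind!r}")
        if self.original_length == 0:
            object.__setattr__(self, "original_length", len(self.sequence))
        if self.original_length < 1:
            raise ValueError(f"{self.id}: empty sequence")
        if len(self.sequence) != self.original_length + self.pad:
            raise ValueError(f"{self.id}: length/pad bookkeeping inconsistent")
        if self.pad > 0:
            if self.kind == "control":
                raise ValueError(f"{self.id}: control fragments are never padded")
            if self.sequence[-self.pad:] != self.sequence[: self.pad]:
                raise ValueError(f"{self.id}: pad bases do not wrap the origin")


@dataclass
class PanMitogenome:
    """The assembled query pool plus per-kind bookkeeping."""

    records: list[MitoRecord]
    pad: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {k: sum(r.kind == k for r in self.records) for k in KINDS}

    @property
    def total(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def read_fasta(path, kind: str = "full") -> list[MitoRecord]:
    """Read a FASTA file into unpadded records of the given kind.

    The record id is the first whitespace-delimited header token.  Sequences
    are uppercased; any character outside the IUPAC nucleotide alphabet
    raises an error naming the record and position.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        for pos, base in enumerate(seq, start=1):
            if base not in IUPAC_CODES:
                raise ValueError(
                    f"{path}: record {entry.id!r} has non-IUPAC character "
                    f"{base!r} at position {pos}"
                )
        records.append(MitoRecord(id=entry.id, sequence=seq, kind=kind))
    if not records:
        log.warning("%s: no FASTA records found", path)
    return records


def dedup_exact(records: list[MitoRecord]) -> tuple[list[MitoRecord], list[str]]:
    """Drop byte-identical sequences, keeping the first of each group.

    Returns ``(survivors, removed_ids)``.  Input order is preserved.
    Identity means exact full-sequence equality after uppercasing; collapsing
    of merely similar sequences is deliberately not attempted — their hits
    merge downstream regardless.
    """
    seen: set[str] = set()
    survivors: list[MitoRecord] = []
    removed: list[str] = []
    for rec in records:
        if rec.pad:
            raise ValueError(f"{rec.id}: dedup must run before circular extension")
        if rec.sequence in seen:
            removed.append(rec.id)
        else:
            seen.add(rec.sequence)
            survivors.append(rec)
    if removed:
        log.info("dedup_exact removed %d duplicate records", len(removed))
    return survivors, removed


def filter_full_length(
    records: list[MitoRecord], min_len: int = DEFAULT_MIN_FULL_LEN
) -> list[MitoRecord]:
    """Keep records with original_length >= min_len (partial assemblies out)."""
    kept = [r for r in records if r.original_length >= min_len]
    if len(kept) < len(records):
        log.info(
            "filter_full_length discarded %d records shorter than %d bp",
            len(records) - len(kept), min_len,
        )
    return kept


def circular_extend(record: MitoRecord, pad: int = DEFAULT_PAD) -> MitoRecord:
    """Append the first *pad* bases to the end, emulating circularity."""
    if pad == 0:
        return record
    if record.pad:
        raise ValueError(f"{record.id}: already padded")
    if record.original_length <= pad:
        raise ValueError(
            f"{record.id}: length {record.original_length} <= pad {pad}"
        )
    return replace(record, sequence=record.sequence + record.sequence[:pad], pad=pad)


def assemble_panmito(
    full: list[MitoRecord],
    control: list[MitoRecord],
    reference: MitoRecord,
    pad: int = DEFAULT_PAD,
) -> PanMitogenome:
    """Combine padded full genomes, raw control fragments, and the reference.

    ``full`` must already be deduplicated and length-filtered.  Control
    fragments are linear sub-sequences and are never padded.  Record ids
    must be unique across the whole pool.
    """
    padded_full = [circular_extend(r, pad) if not r.pad else r for r in full]
    ref = circular_extend(reference, pad) if not reference.pad else reference
    ref = replace(ref, kind="reference") if ref.kind != "reference" else ref
    records = padded_full + list(control) + [ref]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record ids in pool: {dupes[:5]}")
    pool = PanMitogenome(records=records, pad=pad)
    log.info(
        "pan-mitogenome pool: %d full + %d control + %d reference = %d",
        pool.counts["full"], pool.counts["control"],
        pool.counts["reference"], pool.total,
    )
    return pool


def write_manifest(pool: PanMitogenome, path) -> None:
    """Tab-separated pool manifest: id, kind, original_length, pad."""
    with open(path, "w") as fh:
        fh.write("id\tkind\toriginal_length\tpad\n")
        for rec in pool:
            fh.write(f"{rec.id}\t{rec.kind}\t{rec.original_length}\t{rec.pad}\n")


def write_fasta(records, path) -> None:
    """Write records as single-line-per-sequence FASTA (deterministic)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
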
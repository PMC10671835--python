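"""End-to-end discovery pipeline with config, logging, and provenance.

``discover`` chains pool building, alignment search, interval merging,
summary statistics, k-mer scanning, breakpoint profiling and exclusion-set
construction, writing every product plus a JSON manifest that echoes the
full configuration, the package version, and SHA-256 checksums of all
inputs.  Identical config + inputs therefore produce byte-identical
outputs, and every result file is self-describing via the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from . import __version__
from .align import FilterThresholds, find_numts, write_hit_table
from .breakpoints import project_to_mt, write_profile
from .intervals import (IntervalSet, blacklist_union, merge, read_bed,
                        summary_stats, write_bed)
from .karlin import ScoringScheme
from .kmer import (decompose, length_histogram, map_kmers, merge_positions,
                   turning_point, write_histogram, write_segments_bed)
from .panmito import (assemble_panmito, dedup_exact, filter_full_length,
                      read_fasta, write_manifest)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Flat pipeline configuration; every threshold is echoed to the manifest."""

    full_fasta: str = ""
    control_fasta: str = ""
    reference_fasta: str = ""
    genome_fasta: str = ""
    external_blacklist_bed: str = ""
    pileup_bed: str = ""
    out_dir: str = "run"
    genome_label: str = "genome"

    pad: int = 100
    min_full_len: int = 16_530
    reward: int = 2
    penalty: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    max_evalue: float = 1e-4
    min_identity: float = 63.0
    min_length: int = 28
    word_size: int = 11
    x_drop: int = 20
    k: int = 20
    max_mismatch: int = 0
    mt_length: int = 16_569
    coverage_quantile: float = 0.05
    min_low_run: int = 20

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_genome_fasta(path) -> dict[str, str]:
    """Read a nuclear FASTA into an ordered contig -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def discover(config: RunConfig) -> Path:
    """Run the full discovery chain; returns the run directory.

    Any stage failure raises :class:`StageError` naming the stage, with
    partial outputs retained in the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    counts: dict[str, dict] = {}
    try:
        stage = "build-panmito"
        full = read_fasta(config.full_fasta, kind="full")
        control = (read_fasta(config.control_fasta, kind="control")
                   if config.control_fasta else [])
        ref = read_fasta(config.reference_fasta, kind="reference")[0]
        full_dedup, removed = dedup_exact(full)
        full_kept = filter_full_length(full_dedup, config.min_full_len)
        pool = assemble_panmito(full_kept, control, ref, pad=config.pad)
        write_manifest(pool, out / "pool_manifest.tsv")
        counts[stage] = {"full_in": len(full), "duplicates": len(removed),
                         "short": len(full_dedup) - len(full_kept),
                         "pool_total": pool.total}
        log.info("%s: %s", stage, counts[stage])

        stage = "find-numts"
        genome = read_genome_fasta(config.genome_fasta)
        scheme = ScoringScheme(reward=config.reward, penalty=config.penalty,
                               gap_open=config.gap_open,
                               gap_extend=config.gap_extend)
        thresholds = FilterThresholds(max_evalue=config.max_evalue,
                                      min_identity=config.min_identity,
                                      min_length=config.min_length)
        numts, hits = find_numts(pool, genome, scheme, thresholds,
                                 word_size=config.word_size,
                                 x_drop=config.x_drop)
        numts = IntervalSet(list(numts), genome=config.genome_label)
        write_hit_table(hits, out / "hits.tsv")
        write_bed(numts, out / "numts.bed")
        counts[stage] = {"hits": len(hits), "numts": len(numts),
                         "total_length": numts.total_length()}
        log.info("%s: %s", stage, counts[stage])

        stage = "summary-stats"
        stats = summary_stats(numts)
        with open(out / "numts_summary.tsv", "w") as fh:
            fh.write("NUMTs\tTotal_Length\tMin\tMedian\tMean\tMax\n")
            fh.write(f"{stats.count}\t{stats.total_length}\t{stats.min}\t"
                     f"{stats.median}\t{stats.mean:.1f}\t{stats.max}\n")

        stage = "kmer-scan"
        table = decompose(pool, k=config.k)
        khits = map_kmers(table, genome, max_mismatch=config.max_mismatch)
        segments = merge_positions(khits, k=config.k)
        hist = length_histogram(segments)
        knee = turning_point(hist, k=config.k)
        write_segments_bed(segments, out / "segments.bed")
        write_histogram(hist, out / "kmer_hist.tsv")
        counts[stage] = {"unique_kmers": table.unique_count,
                         "total_windows": table.total_segments,
                         "hits": len(khits), "segments": len(segments),
                         "turning_point": knee}
        log.info("%s: %s", stage, counts[stage])

        stage = "breakpoints"
        mt_hits = [h for h in hits if h.query_kind in ("full", "reference")]
        rec_lens = {r.id: r.original_length for r in pool}
        profile = project_to_mt(mt_hits, mt_length=config.mt_length,
                                pad=config.pad, record_lengths=rec_lens)
        write_profile(profile, out / "mt_coverage.tsv")
        counts[stage] = {"projected_hits": profile.n_hits}

        stage = "blacklist-union"
        empty = IntervalSet([], genome=config.genome_label)
        ext = (read_bed(config.external_blacklist_bed)
               if config.external_blacklist_bed else empty)
        ext.genome = config.genome_label
        pile = read_bed(config.pileup_bed) if config.pileup_bed else empty
        pile.genome = config.genome_label
        combined = blacklist_union(numts, ext, pile)
        write_bed(combined, out / "blacklist.bed")
        counts[stage] = {"regions": len(combined),
                         "total_length": combined.total_length()}

        stage = "manifest"
        inputs = {p: _sha256(p) for p in (
            config.full_fasta, config.control_fasta, config.reference_fasta,
            config.genome_fasta, config.external_blacklist_bed,
            config.pileup_bed) if p}
        manifest = {
            "pannumt_version": __version__,
            "config": config.to_dict(),
            "scheme": {"lambda": scheme.lambda_, "K": scheme.K,
                       "source": scheme.source,
                       "length_adjustment": "none (raw m, n)"},
            "input_sha256": inputs,
            "stage_counts": counts,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc
    return out
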
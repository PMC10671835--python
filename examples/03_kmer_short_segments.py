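"""Scan a genome for short mtDNA-like segments with 20-mers.

Full-length NUMT discovery cannot report segments shorter than the e-value
cutoff allows, so short homologies are found by exact 20-mer matching:
decompose the pool into 20-mers, place them on both strands, merge the
footprints, and inspect the segment-length distribution and its knee.
"""

from pannumt.kmer import (decompose, length_histogram, map_kmers,
                          merge_positions, turning_point)
from pannumt.panmito import MitoRecord, PanMitogenome
from pannumt.simulate import SimConfig, plant_numts, root_mitogenome

cfg = SimConfig(seed=11, background_len=200_000, n_numts=6,
                numt_len_range=(40, 800))
truthset = plant_numts(cfg)
pool = PanMitogenome(records=[MitoRecord(
    id="ref", sequence=root_mitogenome(cfg), kind="reference")], pad=0)

table = decompose(pool, k=20)
print(f"{table.unique_count} unique 20-mers from {table.total_segments} windows")

hits = map_kmers(table, truthset.genome)
segments = merge_positions(hits, k=20)
hist = length_histogram(segments)
print(f"{len(hits)} placements merged into {len(segments)} segments "
      f"(min length {min(len(s.interval) for s in segments)} bp)")
print("length histogram (length: segments, supporting 20-mers):")
for length, (n_seg, n_kmer) in list(hist.items())[:8]:
    print(f"  {length}: {n_seg}, {n_kmer}")
print(f"turning point of the distribution: {turning_point(hist, k=20)} bp")
# segments at exactly 20 bp are isolated single-20-mer placements; longer
# segments indicate overlapping homology, i.e. candidate short NUMTs.
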
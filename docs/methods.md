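# Methods

## The discovery model

A NUMT is detected as a statistically significant local alignment between
some member of a mitochondrial query pool and the nuclear genome. The
pipeline has five stages: pool assembly, seeded alignment search,
interval algebra, 20-mer short-segment scanning, and circular breakpoint
profiling. Each stage is usable on its own from Python; `discover` chains
them with a provenance manifest.

### Pool assembly

Full-length mitogenomes are deduplicated by exact byte equality of the
uppercased sequence. Near-duplicate collapsing is deliberately not
attempted: it would require an arbitrary similarity cutoff, and redundant
queries are harmless because identical queries map to the same nuclear
regions, which merge downstream. Records shorter than 16,530 bp are
treated as partial assemblies and dropped. Accepted molecules are
circularly extended by `pad` (default 100) bases — the first `pad` bases
appended to the end — so alignments spanning the arbitrary linearization
origin are recovered; a hit lying entirely inside the pad is re-reported
on wrapped origin coordinates. Control-region fragments are linear
sub-sequences (400–1,598 bp) and are never padded or deduplicated. Record
ids must be globally unique; a collision is an error rather than a silent
rename.

### Alignment search

Seeding finds every maximal exact match of length ≥ `word_size`
(default 11) via a sorted k-mer index of the subject, on both strands.
Each seed not already covered by a previous extension (tracked per
diagonal) is extended in both directions with affine-gap X-drop dynamic
programming: cells scoring more than `x_drop` (default 20) below the best
score seen so far are abandoned, which keeps the live band a few tens of
columns wide and the cost linear in alignment length. Alignment
statistics (matches, mismatches, gap columns) come from a banded global
re-alignment of the extended rectangle with a deterministic traceback
(ties prefer diagonal steps, then subject gaps, then query gaps). Percent
identity counts gap columns in the denominator.

Significance uses the Karlin–Altschul expectation
`E = K·m·n·exp(−λS)` with `m`, `n` the raw query and subject lengths — no
BLAST-style effective-length adjustment, a choice recorded in every run
manifest. For the default scheme (+2/−3, gap open 5, extend 2) the gapped
pair (λ = 0.625, K = 0.41) is shipped as constants mirroring the
published blastn gapped table, because gapped Karlin–Altschul parameters
are empirical and not derivable in closed form. Any other scheme falls
back to computed ungapped values with a warning: λ is the unique positive
root of the exponential-sum equation, found by bracketed root-finding to
residual < 1e−9, and K comes from the standard lattice series truncated
at relative change < 1e−6 (the implementation reproduces the published
ungapped constants, e.g. 0.408 for +2/−3). Exactness of K only shifts
e-values by a constant factor; the filters sit far from the boundary.

Hits are kept when e-value ≤ 1e−4, identity strictly greater than 63, and
the subject interval is at least 28 bp (inclusive — a 28 bp hit passes).
Extensions scoring below the e-value reporting threshold are dropped
before statistics are computed, exactly as an aligner run with an e-value
cutoff would. Surviving subject intervals merge into the NUMT
compilation.

### Interval algebra

Coordinates are 0-based half-open (BED) internally; mitochondrial
positions are converted to 1-based inclusive only in the breakpoint
module. Merging joins overlapping and book-ended intervals (the
`bedtools merge` default); `min_gap` additionally joins intervals
separated by strictly fewer bases than the gap. Summary statistics use
the lower median for even counts so every reported value is an attained
length. Compilation comparisons emit both conditional overlap fractions
(shared/|A| and shared/|B|) as well as shared/|A∪B|, because published
comparisons alternate between denominators. The exclusion-set union
labels each output interval with the sources (numts / blacklist / pileup)
that contributed to it.

### 20-mer scan and the minimum NUMT length

The pool is decomposed into overlapping k-mers (default k = 20); windows
containing N or any IUPAC ambiguity code are discarded. The table maps
directly against the genome by exact matching on both strands — the
pseudo-read detour (fabricated FASTQ with constant quality fed to a read
aligner) is bypassed since its mathematical content is identical.
Duplicate placements of the same k-mer at the same position collapse.
Hamming-tolerant matching up to 3 mismatches is available via pigeonhole
chunking for closer emulation of seed-tolerant read aligners, but exact
matching is the default because it makes the naive-scan oracle total and
the tool deterministic. Merged per-base footprints give mapped segments
(minimum possible length k); the "turning point" of the segment-length
distribution is operationalized as the length in `[k+1, 3k]` with the
maximal drop in log k-mer counts between consecutive occupied lengths,
ties toward smaller lengths, defaulting to 28 with a warning when the
range is flat or unoccupied. On real genomes this knee sits at 25–30 bp,
which motivates the 28 bp minimum NUMT length; on small simulated scenes
the knee location is a data outcome and is simply reported.

### Breakpoint profiling

Query intervals of filtered hits from mitogenome-anchored records (full
and reference kinds only — control-fragment coordinates are
fragment-local) are projected onto the canonical circle: positions past
`mt_length` wrap by subtraction, coverage increments once per hit per
position, and both wrapped endpoints increment an endpoint counter.
Simulated or real molecules can differ from the canonical length by a few
indel bases, so the corrupt-hit bound accepts each record's own padded
length when record lengths are supplied. "Breakpoint" has no standard
statistic, so both operationalizations are reported: endpoint density and
maximal circular runs of coverage at or below the `quantile` (default
0.05) threshold lasting at least `min_run` (default 20) positions. A
uniform profile yields no low runs (nothing is distinguishable); an
all-zero profile yields the full circle with a warning. Low runs are
annotated per base against control/tRNA/rRNA/CDS features with a fixed
priority (control first) so category fractions plus the unannotated
remainder sum to one.

## The simulator and what it does (not) show

The generator is the package's test bed. It emulates the structure the
method consumes, not human population genetics:

* **Population**: a star phylogeny — each full-length record derives from
  one random root (44% GC) by i.i.d. substitutions (default 0.01/site)
  and indels (5e−4/site, geometric(0.5) lengths capped at 10 bp), with a
  configurable fraction (default 0.25) of exact duplicate entries.
  Records violating the 16,530 bp bound are redrawn.
* **Control fragments**: cut from random members at the control-region
  coordinates (16,024–16,569 ∪ 1–576), uniform lengths 400–1,598 bp,
  wrapping the origin.
* **Planted NUMTs**: the standard scene plants 50 copies with log-uniform
  lengths 35–14,855 bp and uniform divergence 0–20% (10:1
  substitution:indel mix) into a 2 Mb i.i.d. background at 41% GC, with
  exact post-insertion truth coordinates.

Sizes (24-member population, 2 Mb background) were chosen so the full
benchmark runs in well under a minute while keeping ≥ 50 recovery events
per scene. Everything is deterministic per seed through derived,
independent RNG streams, so planting never perturbs the population draw.

What passing these tests shows: the search recovers insertions whose
divergence is within the identity filter's reach, with base-accurate
boundaries at low divergence, and rejects copies beyond it. What it does
not show: behaviour on real repeat structure (segmental duplications,
satellite, low-complexity tracts — the i.i.d. background has none),
real mtDNA haplotype topology, or chromosome-scale performance.

Recovery scoring counts a truth interval as found when a called interval
overlaps it by ≥ 50% reciprocally; boundary error is the mean absolute
start/end offset over recovered pairs. Note that with random flanks the
*optimal* local alignment occasionally extends a few bases past a planted
boundary (a chance flank match raises the score); this is correct
alignment behaviour, so exact-boundary tests construct flanks that cannot
extend, and scene-level tests assert mean error bounds instead.

## Numerical and design notes

* All DP is integer arithmetic; no floating-point scores, so results are
  platform-exact and ties are resolved deterministically.
* λ root-finding brackets `[1e−12, hi]` with `hi` doubled until the sum
  exceeds 1; Brent's method at machine tolerance; an expected pair score
  ≥ 0 is rejected (no valid λ exists).
* The X-drop bound caps gap excursions at
  `(x_drop − gap_open)/gap_extend + 1` bases, which sizes the traceback
  band; the band is widened by that reach plus a safety margin.
* `word_size` 11 and `x_drop` 20 are the defaults; both are configurable.
  Larger `x_drop` trades speed for resilience to long interior
  low-identity stretches (which otherwise split a hit in two; the merge
  step usually rejoins them).
* Degenerate inputs: empty pool or genome is an error in `find_numts`;
  empty interval sets produce all-zero summaries with a warning; an empty
  k-mer histogram returns the default 28 bp cutoff with a warning.
* Known limitations: no dust/seg-style masking of low-complexity query
  regions (real control-region homopolymers could seed excessive hits on
  real genomes), no BLAST length adjustment (e-values are conservative
  for short queries), and single-threaded search sized for megabase-scale
  simulated scenes rather than full reference genomes.
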
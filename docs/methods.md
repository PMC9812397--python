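# Methods

## Model

A sequencing library is modelled as a pool of read tuples (the
co-indexed records of all FASTQ files for one cluster/molecule). A
*source structure* assigns spans of those reads to named segments; a
*variable* groups one or more segments (a combinatorial group encodes
a single joint value) and sits in a forest hierarchy: `independent`,
`parental`, or `local` to a parent variable. The package's central
object is the **value tree**: for every variable, the multiset of its
observed sequence tuples under each chain of ancestor values. The
tree is exactly what translation needs — which values exist, how
often, and in which scopes — and it is small enough to merge on a
single node while segment extraction and correction stream in
independent chunks.

Reads are taken exactly as stored; reverse-complement layouts must be
declared as separate structures. Coordinates are 0-based half-open.
When several structures are declared, matchers apply in configuration
order and the first full match claims the read; ambiguity is
therefore resolved deterministically and user-controllably.

## Segment location

Fixed spans are validated for pairwise overlap at compile time.
Anchored segments are located between an upstream and a downstream
motif. Each motif match requires its `inner_exact_len` bases adjacent
to the segment to match exactly and tolerates up to
`outer_max_mismatch` substitutions in the remaining flank (defaults 3
and 2, matching common practice for 20-bp flanks); `N` in a read
mismatches every motif base. The search scans upstream positions left
to right and, per admissible upstream hit, segment lengths from
`min_len` upward, taking the first admissible downstream hit — the
first admissible flank pair wins, which makes matching deterministic
on repetitive reads. Substitution errors in flanks are absorbed by
the fuzzy policy; indels in the segment itself are tolerated through
the `min_len`/`max_len` window.

## Quality policy

Per-segment quality is summarised as the arithmetic mean and minimum
of integer Phred scores. A record fails when any governed segment has
mean below `min_avg_q` or minimum below `min_base_q`; the thresholds
read "below X fails", so equality passes. The whole record drops on
failure — a partially decodable record cannot be translated, so
segment-level salvage would only create phantom reads. Defaults are
permissive (0/0); the well-barcoding configuration uses 20/10.

## Error correction

Correction operates per segment on tallies merged across all chunks,
making the resulting table independent of the chunking.

**Knee detection.** Sequences are ranked by descending count (count
ties broken lexicographically, which only fixes rank labels, not the
accepted set). Duplicate counts are collapsed to their last rank and
the rank–count curve is taken to log₁₀–log₁₀ space. The knee is the
interior vertex lying above the chord joining the curve's endpoints
that has the largest log-count drop to the next level; ties go to the
smaller rank. This is a deliberate, robust surrogate for "the
maximum-curvature point": raw discrete turn angles wobble with count
jitter along a sloped abundance plateau and can even peak at the
*bottom* of the abundance cliff when the error tail is steep, whereas
the largest multiplicative gap pins the cliff top and the
above-the-chord restriction prevents a single dominant sequence from
posing as the knee. Degenerate inputs: with all counts equal or
fewer than three sequences everything is accepted; with exactly two
count levels the knee is the edge of the upper plateau. The accepted
set is every sequence ranked at or above the knee.

**Imputation-to-majority.** Accepted sequences map to themselves;
each below-knee sequence maps to its nearest accepted sequence by
Levenshtein distance if that distance is ≤ `levenshtein_max` (default
1), else drops. Nearest-neighbour ties break by higher count, then
lexicographic order — deterministic, and biased toward the likelier
origin.

**Allowlist mapping.** Exact members map to themselves; other
sequences map to the unique nearest allowlist entry within the
threshold. If two entries are equidistant at the minimum the sequence
drops: correcting to an arbitrary barcode would fabricate identity.

**Plugin contract.** An external command receives an input TSV path
(sequence, count; descending count) and an output path, and must
write a total 2-column TSV (raw, corrected-or-`-`). Non-zero exit or
a non-total table aborts the run. This is the hook for third-party
cluster-based correctors.

Levenshtein distance is unit-cost over {A,C,G,T,N} with `N`
mismatching everything, including another `N` — an uncalled base
never certifies identity. Distances are computed with edlib, with
`N` masked to distinct out-of-alphabet letters on the two sides to
realise the N rule; a banded cutoff at the threshold keeps the
nearest-neighbour search linear in the accepted-pool size.

Correction tables are total over observed sequences and idempotent:
every corrected sequence is an accepted-set member mapping to itself.

## Value encoding and optimization

Valued variables (those in the hierarchy or carrying a correction
method; payload variables pass through untouched) contribute one
sequence tuple per record, keyed under the chain of ancestor values.
Chunk trees merge by sequence, so encoding is chunking-invariant.

Optimization renumbers each root variable 0..n−1 by descending total
count and each local scope independently 0..k−1 by descending
in-scope count, recursing through multilayer hierarchies. Frequency
ties break by lexicographic order of the underlying sequence tuples —
an arbitrary but run- and chunking-stable choice, flagged at info
level in logs. Within each scope the map is injective, so the
renumbered tree is isomorphic to the input; the species count per
variable equals its maximum scope cardinality, which no
topology-preserving renumbering can beat (the per-scope maps must be
injective). Because values are ranked by frequency, truncation at a
destination pool's capacity keeps the most frequent values.

The `no_optimize` control mode numbers every variable globally by
descending total count, ignoring scopes — the degraded behaviour a
scope-blind translation would exhibit, kept for comparison runs.

## Destination assembly

A destination variable owns ordered units: an IUPAC template
(capacity = product of per-position base-set sizes; lowercase
rejected) or an allowlist (capacity = number of rows, file order).
An optimized value is encoded in mixed radix over unit capacities,
most-significant unit first, IUPAC digits enumerating each position's
base set alphabetically. The map is injective over the pool capacity;
values at or beyond capacity drop the record with reason `capacity`.
Bequeath-and-pad copies the source sequence and extends it with the
pad base (default A) to the declared length. Conversion tables map
the concatenated source sequence directly; missing keys drop with
`table_miss`. Pass-through segments copy sequence and per-base
quality verbatim.

Qualities: every base of a reassigned, bequeathed or table-converted
segment receives round-half-up of the mean of the contributing source
segments' average Q, clamped to [2, 40]; pad bases and constant
fillers receive exactly Q40. The rounding direction and the floor of
2 (printable `#`) are package choices; the combinatorial many-to-one
mean is likewise a choice, since one average per source segment must
become one value per destination segment.

**Spatial tiling.** The conversion-table builder scales bead
coordinates by a user factor, tiles destination arrays across the
enlarged field on a fixed-pitch grid, and assigns each bead to the
Euclidean-nearest spot of its containing tile. Equidistant spots
resolve to the lowest spot index; beads outside the grid are reported
unassigned and excluded from the table. Reported statistics: beads
per spot and the fraction of beads holding a spot of their own.

## Workflow and chunking

`interpret` streams read tuples in order-preserving chunks (default
100 000), extracts and quality-filters records, tallies per chunk,
merges tallies, builds correction tables once, applies them to every
record, and encodes per-chunk value trees merged into one. `translate`
optimizes the merged tree and emits destination FASTQ plus a manifest
of telescoping per-stage counts and drop reasons (`no_match`,
`quality`, `correction_drop`, `capacity`, `table_miss`). Both stages
are deterministic given config and input; chunks are independent
between the two merge barriers, so any scheduler can fan them out.
The only randomness in the package lives in the simulators, seeded
from a single integer.

## Simulators

Each generator emits a read family with per-read truth and the
matching configuration: droplet scRNA-seq (16-bp cell + 12-bp UMI +
20-bp gene-tag payload; molecules per cell and gene drawn from a
truncated geometric distribution, default p = 0.4 capped at the
configured maximum, producing the uneven scope sizes that make
optimization non-trivial), four pooled well-barcoding layouts over
the full 384-well geometry (16 rows × 24 columns) discriminated by
exact 8-bp library tags, four-tier combinatorial indexing on two
index reads, spatially barcoded beads with uniform coordinates, and
anchored long reads with 20-bp flanks. Barcode pools are drawn with
pairwise Levenshtein distance ≥ 3 so single errors are correctable;
errors are i.i.d. per-base substitutions plus an optional single
indel. The simulators do not model instrument-specific error
profiles, quality-score decay along cycles, chimeras, or read-length
heterogeneity, so green tests certify the decoding/translation logic
under the declared error model, not performance on any particular
instrument's data.

## Problem sizes

The default test and acceptance runs use desk-scale libraries chosen
to exercise every code path with comfortable margins: the round-trip
evaluation uses 200 cells × 100 gene tags (≈50 000 reads, matrices
compared over 20 000 entries), chunk-invariance uses a ≈5 000-read
library at chunk sizes 1/7/1000, and the correction oracle uses pools
of ≤200 sequences where exhaustive dynamic programming is feasible.

## Known limitations

- Above-knee sequences are never re-clustered against each other;
  correction assumes the accepted set is the true set.
- No probabilistic UMI collapsing (directional-network style); value
  identity is exact post-correction, and translation preserves it
  rather than denoising it.
- A destination read is assembled only from declared segments; gaps
  between placements are not filled.
- The anchored matcher takes the first admissible flank pair; a
  degenerate motif occurring early in a long read can shadow a later,
  better placement.
- Translation across structures requires every reassign-destination's
  source variable to be present in the matched structure; records
  from structures lacking one are dropped as `no_match`.
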
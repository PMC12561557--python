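# Methods

## Problem and model

`scafmap` works on *alignment blocks*: contiguous aligned segments between
a de novo contig and a reference chromosome, each with coordinates on both
sequences, an orientation and a percent identity.  Blocks are the natural
unit for chromosome-scale questions — where a contig sits, where the
assembly breaks, what is missing, what is inverted — without touching
base-level alignment.  Internally every interval is 0-based half-open;
tabular outputs (block TSV, reports, AGP) print 1-based inclusive
coordinates, the convention of per-chromosome report tables; BED output is
0-based half-open as the format requires.

## Contiguity statistics

N_x uses the inclusive convention: the length of the first contig, in
descending order, at which the cumulative sum reaches ≥ x% of the total;
L_x is its 1-based rank.  Conventions for N_x vary at the boundary; the
threshold comparison is done as `100·cumsum ≥ x·total` in 64-bit integers,
so ties at exactly x% are deterministic and no floating-point slack is
involved.  Scaffold gap counts are maximal runs of N/n.

## Per-chromosome evaluation

* **Grouping**: blocks partition by chromosome and sort by
  (ref_start, ref_end); all tie-breaks throughout the package are
  lexicographic on (name, start), so outputs are deterministic.
* **End annotation** follows a fixed precedence per block end:
  chromosome terminus (touches 0 or the chromosome length) → contig
  terminus (the corresponding query coordinate touches the contig end,
  swapped for reverse-orientation blocks) → overlaps-neighbour (negative
  reference gap) → abuts-gap (neighbour gap ≥ `min_uncovered_stretch`) →
  alignment break.  The repeat flag marks blocks whose reference interval
  is overlapped by a block of a different contig (interval-tree query).
* **Colinear runs** are chained greedily left-to-right: a block extends the
  current run iff same query, same orientation, non-negative reference
  progression within `colinear_gap_tolerance`, and query coordinates
  advancing in the direction the orientation implies.  Greedy (not optimal)
  chaining is deliberate: blocks from a one-to-one assembly-to-reference
  mapping are near-disjoint, and greedy is linear-time and deterministic.
* **Inversions**: a reverse-orientation run whose query also has forward
  runs both before and after it in reference order on the same chromosome
  is a *flanked* (confident) inversion; reverse runs without that context
  are still reported, flagged low-confidence.
* **Uncovered stretches** are the complement of the union of block
  intervals within [0, chrom_len), kept at length ≥ `min_uncovered_stretch`
  (default 5000).  The threshold is inclusive; the boundary case is
  ambiguous in prose descriptions of "stretches larger than 5 kb", and
  inclusive was chosen and is documented here.
* **Fragmentation hotspots**: non-overlapping windows of `hotspot_window`
  bases; a window with ≥ `hotspot_min_interruptions` block boundaries
  (starts + ends) is flagged, and adjacent flagged windows merge.  The
  defaults (1 Mb, 10) suit real mammalian chromosomes with a few hundred
  blocks; at the simulator's Mb-scale toy genomes the background density is
  far higher, and scenario configs use a 100 kb window with threshold 20.
* **Report row**: coverage is the measure of the interval union over the
  chromosome length; identity is the reference-length-weighted mean of
  block identities (the aggregation used by upstream evaluation tools is
  unpublished, so this is a package convention); per-chromosome L50/L90
  count the fewest contigs whose summed aligned length reaches 50%/90% of
  the *chromosome length* (not of the aligned length) — chromosomes where
  90% is unreachable keep l90 = n_contigs and set a shortfall flag.

## Reference-guided scaffolding

One scaffold per reference chromosome.  Assignment: each contig goes to
the chromosome holding the argmax of its summed aligned reference length
(ties by chromosome name); it is unplaced when that fraction is below
`min_assign_fraction` (default 0.6, one interpretable confidence knob) or
its aligned length is below `min_contig`.  Orientation is the
aligned-length-weighted majority over its blocks (ties forward); the
anchor is the reference extent of its majority-orientation blocks; order
is by anchor midpoint.  The gap after a contig is the next anchor start
minus its anchor end: positive values are used verbatim — even below
`min_gap_size`, since an exactly inferred small gap is more informative
than a floor — while abutting or overlapping anchors get a fixed
`min_gap_size` spacer (default 100 bases, a documented stand-in: contigs
are never trimmed or merged, which preserves sequence-conservation
guarantees).  Scaffold sequences concatenate oriented contigs
(reverse-complemented as placed) with N-runs of the inferred sizes; AGP
v2.1, placement TSV and unplaced lists are written alongside.  The module
contains no randomness; identical inputs reproduce identical bytes.

## The simulator

The generator emulates what a long-read assembly of a repeat-poor genome
looks like when mapped back to its reference: chromosomes tiled end-to-end
by long colinear fragments, with controlled deviations.  Defaults define
the baseline study conditions: three chromosomes of 2/1/0.5 Mb, 30
fragments per chromosome, and a 50 kb tandem-repeat array (171-base
alphoid-like unit) at 450 kb of chr1 that is shattered into 50
micro-fragments — the toy-scale analogue of a centromeric region observed
at ~22% of the length of a ~200 Mb chromosome.  Scenario knobs default
off: dropped intervals (excised and recorded), per-cut break losses
(uniform in a `break_loss` range, so inter-fragment distances are positive
and gap inference can be scored exactly), inversions, and identity noise.

Cut positions are rejection-sampled until the configured count is reached,
each at least 2000 bases from every other cut and from segment edges.
Inversions come in two styles: `contig` reverse-complements whole
fragments (one reverse block per inverted contig), and `internal`
reverse-complements an interior slice (20–40% of the fragment, ≥10%
margins, fragments ≥3 kb only), producing the forward/reverse/forward
block triplet that a real within-contig inversion shows in a dotplot and
that the flanked-inversion detector targets.  Identity noise draws
per-block substitution counts from Binomial(ref_len, rate) and lowers the
recorded identity; the residues themselves are untouched — the noise
models the identity statistic, not the sequence, which keeps
sequence-level round-trip tests exact and is the model's main
simplification.  Randomness uses three documented numpy streams derived
from the config seed ((seed,0) reference, (seed,1) fragmentation, (seed,2)
noise); identical configs are bit-reproducible.

What the simulator does **not** model: read-level error or chimeras,
heterozygosity, segmental duplications, translocations, or misassembled
(chimeric) contigs.  Passing tests therefore demonstrate correctness of
the block-level algorithms under clean one-to-one geometry, not robustness
to misassembly — real QUAST/minimap2 block sets can be fed in through the
PAF or block-TSV readers for that.

## Formats

FASTA via Biopython.  PAF (minimap2 dialect) is read with identity =
100·matches/alignment-length (no CIGAR parsing — blocks, not bases, are
the unit here).  The canonical block TSV is this package's own dialect
(1-based inclusive; descending coordinates mean reverse orientation, as
QUAST-style tables encode minus-strand blocks); it is a documented
stand-in for the unpublished schema of upstream evaluation tools.  AGP
v2.1 writes W component lines and N gap lines (gap_type `scaffold`,
linkage `yes`); the reader recovers order, orientation and gap sizes
exactly.

## Numerical and formatting choices

Percentages print with one decimal (Python float formatting: nearest,
ties-to-even on the binary value).  Empty chromosomes report coverage 0
with a shortfall flag rather than being omitted.  Zero-alignment-length
PAF rows are skipped with a warning.  The run manifest records a wall-clock
timestamp; determinism guarantees therefore cover all data outputs
byte-for-byte, and the manifest up to that field.

## Test-scale choices

The suite and the acceptance script run on Mb-scale genomes (0.1–3.5 Mb,
tens to hundreds of fragments), chosen so the full pipeline including
oracle recomputation completes in seconds while every code path — drops,
inversions, shattering, noise, scaffolding round-trips — is exercised at
sizes where brute-force oracles (boolean coverage masks, pairwise overlap
scans, cumulative-sum walks) remain exact and cheap.
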
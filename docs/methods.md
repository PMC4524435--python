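# Methods

This document records the algorithmic choices and parameter conventions
behind each module.

## Coordinates and sequence model

All internal coordinates are 1-based inclusive on the plus strand.
`CircularSequence` wraps positions through the origin when circular;
`GenomicInterval.wraps_origin` marks intervals with `start > end` that
run through the origin.  Writers convert to each format's native
convention (BED 0-based half-open; GFF3 and bedGraph as specified).

## LIMP detection

The pattern `(AACCA)_m [AATGAAA | TTTCATT] (TGGTT)_n` with
`2 ≤ m, n ≤ 13` is matched by a single regular-expression pass over the
linearized sequence plus a one-pattern-length overhang, so wraparound
copies are found exactly once.  Because the pattern class is its own
reverse complement (the reverse complement of an `(m, +, n)` copy is an
`(n, −, m)` copy), scanning the plus strand is complete.  Occurrences
sharing a loop anchor are deduplicated keeping the maximal copy — a
wrapped copy can also surface as a truncated prefix occurrence of the
linearized string.  Derived metrics: `total = 5m + 7 + 5n`,
`stem = 5·min(m, n)` (only pairable units count), `anchor = start + 5m + 7`.

**Palindromic extension.**  From both ends of the repeat the palindrome
is extended symmetrically while the outer base pair remains a perfect
reverse complement.  Degenerate flanking units (pentanucleotides one
substitution away from the AACCA/TGGTT consensus) commonly add a few
base pairs; one repeat in the published set gains 21 bp per side.

**Remnants.**  An 11–20 nt window containing the full 7-nt loop plus
partial arms, with at most one substitution (budget shared between loop
and arms), outside detected LIMP footprints, and not itself a full
stem-loop (perfect loop with ≥ 2 perfect units on both sides is
excluded).  The detector maximizes the window length, spending the
mismatch budget where it extends the match furthest; overlapping windows
merge into one hit.

**Generic palindromes.**  Maximal inverted repeats with arm ≥ 16 bp
("stem longer than 15 bp") and loop ≤ 20 nt ("loop shorter than 21 nt").
A hit is reported at its deepest closure: if the two innermost loop
bases could pair, the structure is reported with the smaller loop.  The
perfect-arm scanner uses a vectorized 4-bp seed filter followed by
outward extension; a quadratic scanner handles mismatch-tolerant arms.
Both are validated against an independent brute-force oracle in the test
suite.

**HyLIMPs.**  Palindrome hits whose arms contain the hybrid
decanucleotide AACCAGAGCC (left) or its reverse complement (right); the
core GAGCC/GGCTC adjacency at the loop is flagged.  Because arms are
reported symmetrically, the detected unit count is the minimum of the
two branch counts.

**Repeat families.**  Iterative best-hit annotation with edlib
(infix alignment, both strands): the best location above the identity
threshold (default 80%) is reported and masked, until no hit remains.

## Thermodynamics

- RNA hairpin ΔG: ViennaRNA minimum free energy at 37 °C, Turner 2004
  parameters; DNA input is transcribed in place.  The fold window for a
  LIMP is its extended palindromic region widened by adjacent degenerate
  repeat units (in frame with the repeat, up to three per side): a
  degenerate unit next to surplus units of the opposite branch pairs
  with them (G·U wobbles included) and contributes to the measured
  stability.
- DNA strand hairpins: ViennaRNA with Mathews 2004 DNA parameters
  (the RNA parameter set is restored afterwards).
- Linear duplex: SantaLucia unified nearest-neighbor stack sum plus
  initiation terms at 37 °C, computed from the enthalpy/entropy tables
  and cross-checked in the tests against independently transcribed
  published ΔG37 stack values.
- Cruciform penalty: `(ΔG_hairpin,strand1 + ΔG_hairpin,strand2) −
  ΔG_duplex` over the extended palindromic region.  Positive values mean
  the cruciform is less stable than B-form duplex, which is why
  extrusion requires negative supercoiling.

## Rearrangement evidence

For N LIMPs there are `2N²` junction classes: each left flank, direct or
reverse-complemented, against each right flank.  Flanks extend up to
400 bp or to the neighboring LIMP footprint.  A uniquely mapping,
unclipped read pair supports a class when one mate lies wholly in the
left flank and the other wholly in the right flank with the orientations
the junction molecule implies — direct: (left +, right −); reverse
complement: (both −) — and the implied insert on the junction molecule
(left span + repeat length + right span) is at most 600 bp.  The cap is
required because each inter-LIMP interval is simultaneously one repeat's
right flank and the next repeat's left flank, so unconstrained matching
would let ordinary concordant pairs mimic off-diagonal support.  Each
pair counts toward at most one class (smallest implied insert; ties are
dropped as ambiguous).  The matrix offers a log10 view with −1 for empty
cells.

**Unit variants.**  A read shows a changed unit number when its net
indel over the A-run (or T-run) is a nonzero multiple of 5 nt.
Soft-clipped reads are re-anchored when the clipped bases are exact unit
repeats adjacent to the run.  Each read counts on at most one side.

**Deletions.**  Deletion operations ≥ 20 nt are left-normalized (slid
left while the flanking base equals the last deleted base), clustered,
and reported with the direct-repeat length measured on the genome;
events need ≥ 3 supporting reads and a repeat of ≥ 8 nt.

## Expression

Coverage tracks come from bedGraph files or from alignment pileup
(aligned M/=/X bases add depth; deletions do not).  A LIMP is
*interrupted* when the minimum depth over its footprint is ≤ 5 reads
(published rule), *low* up to 25 (implementation choice: published low
minima were 13–19 and normal minima 47+), else *normal*.  The
stem-length report checks the observed dichotomy: stems < 20 bp are
never interrupted, stems > 25 bp always are; 20–25 bp is unconstrained.

## Synthetic data

`generate_genome` plants requested features into i.i.d. background at a
target G+C, with a 12-nt margin between features, and returns ground
truth.  Guards pin the bases just outside every planted repeat so unit
counts and palindromic extensions are exactly as specified, and the
bases flanking planted direct repeats so deletion placement and repeat
length are exact.  `published_genome()` reconstructs the published
chromosome: 69,997 bp, 36% G+C, the 19 published LIMP structures at
their published anchors (with their degenerate flanking units and the
21-bp extension of repeat #10), five HyLIMPs, six remnant fragments, the
12-copy GAGGGCTAC array, the repeat-family consensus copies, the
divergent promoter motifs and the three deletion-prone direct repeats
(173/9, 110/12, 57/11 nt).

`simulate_genomic_read_pairs` samples fragments from a molecule
population: the reference circle plus configured variant circles —
recombinant (arc-deleted, joining one LIMP's upstream arc to another's
downstream arc), deletion and unit-variant molecules.  All variants are
full circles, so per-bp fragment sampling makes expected off-diagonal
junction support equal the molecule fraction times the diagonal mean.
True alignments are emitted with reference-order CIGARs: reference gaps
≤ 1 kb become D runs, larger discontinuities soft-clip the shorter read
side, inserted bases give I.  Reads are FR-oriented with Gaussian insert
sizes and independent substitution errors.

`simulate_rnaseq_coverage` models two divergent transcription units
tiling the circle from a pair of promoters, with near-zero depth between
the promoters, a short ramp downstream of each, collapse to ~1 read over
every LIMP whose stem is ≥ 26 bp (the published > 25 bp processing-site
dichotomy) and Poisson noise per position.

## Reporting

`limp_summary` assembles one row per LIMP (structure, lengths, extended
region, RNA ΔG, unit-variant counts, coverage class) depending on which
inputs are supplied; `aggregate_summary` reproduces the totals-row
statistics (sums of lengths and unit-change counts, means, interrupted
count).
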
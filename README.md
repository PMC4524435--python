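# limptools

Analysis toolkit for a family of short palindromic repeats (LIMPs,
*L. incisa* Mitochondrial Palindromes) on circular organellar genomes:

    5'-(AACCA)m [AATGAAA | TTTCATT] (TGGTT)n-3'      2 <= m, n <= 13

The package covers the complete analysis around these repeats:

- **Detection** (`limptools.detect`) — LIMPs (maximal occurrences,
  wraparound-aware), palindromic extension into degenerate flanking
  units, LIMP remnants (11–20 nt fragments that cannot fold), generic
  inverted-repeat scanning, HyLIMPs (AACCAGAGCC hybrid palindromes),
  motif scanning, tandem arrays and repeat-family annotation.
- **Thermodynamics** (`limptools.thermo`) — RNA hairpin minimum free
  energy (ViennaRNA, Turner 2004), DNA strand hairpins (Mathews 2004 DNA
  parameters), linear-duplex free energy (SantaLucia unified
  nearest-neighbor) and the cruciform extrusion penalty
  `(dG_hairpin1 + dG_hairpin2) − dG_duplex`.
- **Rearrangement evidence** (`limptools.rearrange`) — the 2·N² junction
  classes joining any LIMP's left flank (direct or reverse complement)
  to any LIMP's right flank, read-pair support counting with orientation
  and implied-insert constraints, unit-number variant counting from
  CIGAR strings, deletion detection between direct repeats, inter-LIMP
  coverage statistics.
- **Expression** (`limptools.expression`) — coverage tracks (bedGraph
  I/O, pileup from alignments), classification of each LIMP as
  interrupted (minimum depth ≤ 5), low or normal, and the stem-length /
  interruption relationship report.
- **Synthetic data** (`limptools.simulate`) — a first-class generator:
  genomes with planted features and ground truth, paired-end genomic
  reads from mixed molecule populations (reference, recombinant,
  deletion and unit-variant circles) with true alignments, RNA-Seq
  coverage with divergent promoters and processing-site cleavage, and
  FASTQ/SAM writers.  `published_genome()` reconstructs the published
  69,997-bp chromosome with all 19 documented LIMPs at their published
  coordinates.
- **Reporting** (`limptools.report`) — per-LIMP summary tables
  (TSV/Markdown/DataFrame) with aggregate totals.

## Command line

```
limptools detect genome.fasta --gff3 features.gff3 --remnants
limptools thermo genome.fasta
limptools joints genome.fasta alignments.sam --log --deletions
limptools coverage genome.fasta depth.bedgraph
limptools simulate --out-prefix sim --seed 1 --reads
limptools report genome.fasta --alignments aln.sam --bedgraph cov.bedgraph -o summary.tsv
```

## Library example

```python
import limptools as lt

genome, truth = lt.published_genome()
limps = [lt.extend_palindrome(genome, r) for r in lt.detect_limps(genome)]
rows = lt.limp_summary(genome, limps)
print(lt.aggregate_summary(rows))
```

## Conventions

All coordinates are 1-based inclusive on the plus strand; circular
sequences wrap through the origin.  BED output is converted to 0-based
half-open.  A LIMP's `start` is the first base of its first A-unit and
its `anchor` the first base of its first T-unit (`start + 5m + 7`).
Stem length counts only pairable units, `5·min(m, n)`.

## Testing

```
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out acceptance.json
```

See `docs/methods.md` for the algorithmic details and parameter
conventions.
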
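"""Sequence containers and circular-coordinate arithmetic.

The pipeline works on a single circular organellar chromosome.  All
coordinates are 1-based inclusive throughout the package; writers convert
to each file format's native convention (BED 0-based half-open, GFF3
1-based inclusive).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger("limptools")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")

#: fraction of N residues above which a sequence is rejected
MAX_N_FRACTION = 0.05


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a (possibly circular) sequence.

    ``wraps_origin`` permits ``start > end`` on a circular sequence, in
    which case the interval runs from ``start`` through the origin to
    ``end``.
    """

    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError("coordinates are 1-based; start/end must be >= 1")
        if not self.wraps_origin and self.start > self.end:
            raise ValueError(
                f"start {self.start} > end {self.end} without wraps_origin"
            )

    def length(self, seq_length: int) -> int:
        if self.wraps_origin and self.start > self.end:
            return seq_length - self.start + 1 + self.end
        return self.end - self.start + 1


@dataclass
class CircularSequence:
    """A DNA sequence with a circularity flag.

    Subsequence extraction across the origin succeeds iff ``is_circular``.
    """

    identifier: str
    residues: str
    is_circular: bool = True

    def __post_init__(self):
        self.residues = self.residues.upper()
        bad = set(self.residues) - VALID_BASES
        if bad:
            raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
        if len(self.residues) == 0:
            raise ValueError("empty sequence")
        n_frac = self.residues.count("N") / len(self.residues)
        if n_frac > MAX_N_FRACTION:
            raise ValueError(
                f"sequence is {n_frac:.1%} N (limit {MAX_N_FRACTION:.0%})"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    # -- coordinate helpers -------------------------------------------------

    def wrap(self, pos: int) -> int:
        """Map an arbitrary integer position onto 1..length (circular)."""
        return (pos - 1) % self.length + 1

    def base(self, pos: int) -> str:
        """Residue at a 1-based position, wrapping if circular."""
        if not self.is_circular and not (1 <= pos <= self.length):
            raise IndexError(f"position {pos} outside linear sequence")
        return self.residues[(pos - 1) % self.length]

    def fetch(self, start: int, length: int) -> str:
        """``length`` residues beginning at 1-based ``start`` (plus strand),
        wrapping the origin when circular."""
        if length < 0:
            raise ValueError("negative length")
        s = (start - 1) % self.length
        if s + length <= self.length:
            return self.residues[s : s + length]
        if not self.is_circular:
            raise IndexError("interval runs past the end of a linear sequence")
        out = self.residues[s:]
        rem = length - len(out)
        reps, tail = divmod(rem, self.length)
        return out + self.residues * reps + self.residues[:tail]

    def rotated(self, offset: int) -> "CircularSequence":
        """The same circular molecule with the origin moved by ``offset``
        (new position 1 = old position offset+1)."""
        if not self.is_circular:
            raise ValueError("cannot rotate a linear sequence")
        off = offset % self.length
        return CircularSequence(
            self.identifier, self.residues[off:] + self.residues[:off], True
        )


def subsequence(seq: CircularSequence, interval: GenomicInterval) -> str:
    """Extract residues for ``interval``; reverse-complemented when the
    strand is '-', wrapping the origin when ``wraps_origin``."""
    if interval.wraps_origin and not seq.is_circular:
        raise ValueError("origin-wrapping interval on a linear sequence")
    if not interval.wraps_origin and interval.end > seq.length:
        raise ValueError(f"interval end {interval.end} > length {seq.length}")
    n = interval.length(seq.length)
    s = seq.fetch(interval.start, n)
    return reverse_complement(s) if interval.strand == "-" else s


def gc_content(seq: CircularSequence) -> float:
    """(G + C) / (length - N).  N residues are excluded from the
    denominator; an all-N sequence is an error."""
    denom = seq.length - seq.residues.count("N")
    if denom == 0:
        raise ValueError("all-N sequence has no defined GC content")
    return (seq.residues.count("G") + seq.residues.count("C")) / denom


def read_sequence(
    path: str | Path,
    format: str = "fasta",
    circular: bool | None = None,
) -> CircularSequence:
    """Read the first record of a FASTA or GenBank file.

    Circularity is taken from the GenBank topology field when present,
    else from the ``circular`` argument; the pipeline default is circular.
    A multi-record file triggers a warning and returns the first record.
    """
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {format!r}")
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise ValueError(f"no records in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path} contains {len(records)} records; using the first",
            stacklevel=2,
        )
        logger.warning("%s contains %d records; using the first", path, len(records))
    rec = records[0]
    is_circ = circular
    if format == "genbank":
        topo = rec.annotations.get("topology")
        if topo is not None:
            is_circ = topo == "circular"
    if is_circ is None:
        is_circ = True  # pipeline default for organellar chromosomes
    return CircularSequence(rec.id, str(rec.seq).upper(), is_circ)


def write_fasta(seq: CircularSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq.identifier}\n")
        for i in range(0, seq.length, width):
            fh.write(seq.residues[i : i + width] + "\n")


# -- feature writers --------------------------------------------------------

def write_gff3(
    features: Iterable[tuple[str, GenomicInterval, dict]],
    path: str | Path,
    seqid: str,
) -> None:
    """Write (feature_type, interval, attributes) triples as GFF3
    (1-based inclusive, matching the package's internal convention)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ftype, iv, attrs in features:
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                f"{seqid}\tlimptools\t{ftype}\t{iv.start}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attr_s}\n"
            )


def write_bed(
    features: Iterable[tuple[str, GenomicInterval]],
    path: str | Path,
    seqid: str,
) -> None:
    """Write (name, interval) pairs as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for name, iv in features:
            fh.write(f"{seqid}\t{iv.start - 1}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
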
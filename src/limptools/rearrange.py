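"""Read-pair evidence for LIMP-mediated genome rearrangements.

A recombination between two LIMPs produces a molecule joining the left
flank of one repeat to the right flank of another.  For N repeats there
are 2*N^2 distinguishable junction classes: each left flank, taken in
direct or reverse-complement orientation, against each right flank.  The
N "diagonal" classes (same repeat, direct orientation) are the reference
configuration.  Support is counted from read pairs with one mate wholly
inside each flank.

Strand bookkeeping on the recombinant molecule fixes the expected mate
orientations: a direct junction yields (left mate +, right mate -) pairs,
a reverse-complement junction yields both mates on -.  Because each
inter-LIMP interval is simultaneously one repeat's right flank and the
next repeat's left flank, a cap on the implied junction-molecule insert
size is required so that ordinary concordant pairs cannot masquerade as
off-diagonal support.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import CircularSequence, GenomicInterval
from .detect import LimpRecord

# ---------------------------------------------------------------------------
# alignment records
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: mapping-quality threshold for "uniquely mapping"
MAPQ_UNIQUE = 20


@dataclass
class AlignmentRecord:
    """Minimal alignment abstraction (a thin view over SAM fields)."""

    query_id: str
    read_number: int  # 1 or 2
    ref_start: int  # 1-based leftmost reference position
    strand: str  # '+' or '-'
    cigar: str
    mapq: int = 60
    sequence: str | None = None

    def __post_init__(self):
        ops = _CIGAR_RE.findall(self.cigar)
        if not ops or "".join(f"{n}{o}" for n, o in ops) != self.cigar:
            raise ValueError(f"bad CIGAR {self.cigar!r}")
        self._ops = [(int(n), o) for n, o in ops]

    @property
    def ops(self) -> list[tuple[int, str]]:
        return self._ops

    @property
    def reference_span(self) -> int:
        return sum(n for n, o in self._ops if o in "MDN=X")

    @property
    def ref_end(self) -> int:
        """1-based inclusive end; may exceed the genome length for
        origin-wrapping alignments (wrap with modular arithmetic)."""
        return self.ref_start + self.reference_span - 1

    @property
    def is_unique(self) -> bool:
        return self.mapq >= MAPQ_UNIQUE

    @classmethod
    def from_pysam(cls, seg) -> "AlignmentRecord":
        return cls(
            query_id=seg.query_name,
            read_number=2 if seg.is_read2 else 1,
            ref_start=seg.reference_start + 1,
            strand="-" if seg.is_reverse else "+",
            cigar=seg.cigarstring,
            mapq=seg.mapping_quality,
            sequence=seg.query_sequence,
        )


def read_alignments_sam(path: str | Path) -> list[AlignmentRecord]:
    """Load mapped records from a SAM file via pysam."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.cigarstring is None:
                continue
            out.append(AlignmentRecord.from_pysam(seg))
    return out


def read_alignments_tsv(path: str | Path) -> list[AlignmentRecord]:
    """Internal plain-TSV alignment dialect:
    query_id  read_number  ref_start  strand  cigar  mapq"""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            qid, rno, start, strand, cigar, mapq = line.rstrip("\n").split("\t")
            out.append(
                AlignmentRecord(qid, int(rno), int(start), strand, cigar, int(mapq))
            )
    return out


def write_alignments_tsv(records: list[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#query_id\tread_number\tref_start\tstrand\tcigar\tmapq\n")
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.read_number}\t{r.ref_start}\t{r.strand}\t"
                f"{r.cigar}\t{r.mapq}\n"
            )


# ---------------------------------------------------------------------------
# flanks and junction classes
# ---------------------------------------------------------------------------

FLANK_MAX_DEFAULT = 400


@dataclass(frozen=True)
class Flank:
    limp_id: int
    side: str  # 'left' or 'right'
    orientation: str  # 'direct' or 'revcomp'
    interval: GenomicInterval


def extract_flanks(
    genome: CircularSequence,
    limps: list[LimpRecord],
    max_len: int = FLANK_MAX_DEFAULT,
) -> list[Flank]:
    """One left and one right flank per LIMP, truncated at ``max_len`` or
    at the nearest neighboring LIMP footprint, whichever is shorter."""
    if not limps:
        raise ValueError("no LIMPs")
    L = genome.length
    order = sorted(limps, key=lambda r: r.start)
    flanks = []
    n = len(order)
    for idx, limp in enumerate(order):
        prev = order[(idx - 1) % n]
        nxt = order[(idx + 1) % n]
        prev_end = (prev.start + prev.total_length - 2) % L + 1
        if n == 1:
            gap_left = gap_right = L - limp.total_length
        else:
            gap_left = (limp.start - prev_end - 2) % L + 1 if n > 1 else 0
            gap_right = (nxt.start - (limp.start + limp.total_length) - 1) % L + 1
        left_len = min(max_len, gap_left)
        right_len = min(max_len, gap_right)
        ls = genome.wrap(limp.start - left_len)
        le = genome.wrap(limp.start - 1)
        rs = genome.wrap(limp.start + limp.total_length)
        re_ = genome.wrap(limp.start + limp.total_length + right_len - 1)
        lid = limp.limp_id if limp.limp_id is not None else idx + 1
        if left_len > 0:
            flanks.append(
                Flank(lid, "left", "direct",
                      GenomicInterval(ls, le, "+", wraps_origin=(le < ls)))
            )
        if right_len > 0:
            flanks.append(
                Flank(lid, "right", "direct",
                      GenomicInterval(rs, re_, "+", wraps_origin=(re_ < rs)))
            )
    return flanks


@dataclass(frozen=True)
class JunctionClass:
    left_id: int
    left_orientation: str  # 'direct' or 'revcomp'
    right_id: int

    @property
    def is_diagonal(self) -> bool:
        return self.left_id == self.right_id and self.left_orientation == "direct"

    def label(self) -> str:
        prefix = "L" if self.left_orientation == "direct" else "Lrev"
        return f"{prefix}{self.left_id}xR{self.right_id}"


def enumerate_junctions(limps: list) -> list[JunctionClass]:
    """Every pairing of a left flank (direct or reverse-complemented) with
    a right flank: 2*N^2 classes for N LIMPs."""
    if not limps:
        raise ValueError("no LIMPs")
    ids = []
    for idx, limp in enumerate(limps):
        lid = getattr(limp, "limp_id", None)
        ids.append(lid if lid is not None else idx + 1)
    out = []
    for orient in ("direct", "revcomp"):
        for i in ids:
            for j in ids:
                out.append(JunctionClass(i, orient, j))
    return out


class JointMatrix:
    """Read-pair support counts per junction class, with the published
    log10 view (-1 sentinel for empty cells)."""

    def __init__(self, junctions: list[JunctionClass]):
        self.junctions = list(junctions)
        self.counts: dict[JunctionClass, int] = {j: 0 for j in junctions}

    def add(self, junction: JunctionClass) -> None:
        self.counts[junction] += 1

    @property
    def log_view(self) -> dict[JunctionClass, float]:
        return {
            j: (np.log10(c) if c > 0 else -1.0) for j, c in self.counts.items()
        }

    def total(self) -> int:
        return sum(self.counts.values())

    def off_diagonal_nonzero(self) -> list[JunctionClass]:
        return [j for j, c in self.counts.items() if c > 0 and not j.is_diagonal]

    def to_dataframe(self, log: bool = False) -> pd.DataFrame:
        ids = sorted({j.left_id for j in self.junctions})
        rows = [f"L{i}" for i in ids] + [f"Lrev{i}" for i in ids]
        cols = [f"R{j}" for j in ids]
        df = pd.DataFrame(0.0 if log else 0, index=rows, columns=cols)
        source = self.log_view if log else self.counts
        for j, v in source.items():
            row = ("L" if j.left_orientation == "direct" else "Lrev") + str(j.left_id)
            df.loc[row, f"R{j.right_id}"] = v
        return df


def _contains(flank: GenomicInterval, start: int, end: int, L: int) -> bool:
    """Whole containment of [start, end] (end may exceed L for wraps)."""
    flen = flank.length(L)
    off = (start - flank.start) % L
    return off + (end - start) < flen


def count_joint_support(
    alignments: list[AlignmentRecord],
    junctions: list[JunctionClass],
    flanks: list[Flank],
    genome_length: int,
    limps: list[LimpRecord] | None = None,
    max_implied_insert: int = 600,
    mapq_min: int = MAPQ_UNIQUE,
) -> JointMatrix:
    """Count uniquely mapping read pairs supporting each junction class.

    A pair supports a class iff one mate maps wholly inside the class's
    left flank and the other wholly inside its right flank, with the mate
    orientations the junction molecule implies, and the implied insert on
    that molecule is at most ``max_implied_insert``.  Each pair supports
    at most one class (smallest implied insert; ambiguous ties dropped).
    """
    L = genome_length
    for rec in alignments:
        if rec.ref_start < 1 or rec.ref_start > L:
            raise ValueError(f"alignment at {rec.ref_start} outside genome")
    limp_len = {}
    if limps:
        for idx, lp in enumerate(limps):
            lid = lp.limp_id if lp.limp_id is not None else idx + 1
            limp_len[lid] = lp.total_length
    lefts = [f for f in flanks if f.side == "left"]
    rights = [f for f in flanks if f.side == "right"]
    matrix = JointMatrix(junctions)
    jset = set(junctions)

    pairs: dict[str, dict[int, AlignmentRecord]] = defaultdict(dict)
    for rec in alignments:
        if rec.mapq >= mapq_min:
            pairs[rec.query_id][rec.read_number] = rec

    for qid, mates in pairs.items():
        if len(mates) != 2:
            continue
        r1, r2 = mates[1], mates[2]
        if any("S" in r.cigar or "H" in r.cigar for r in (r1, r2)):
            continue  # clipped reads cross a junction; not wholly inside
        candidates = []
        for a, b in ((r1, r2), (r2, r1)):
            # a plays the left-flank mate, b the right-flank mate
            for lf in lefts:
                if not _contains(lf.interval, a.ref_start, a.ref_end, L):
                    continue
                for rf in rights:
                    if not _contains(rf.interval, b.ref_start, b.ref_end, L):
                        continue
                    if a.strand == "+" and b.strand == "-":
                        orient = "direct"
                        left_span = (lf.interval.end - a.ref_start) % L + 1
                    elif a.strand == "-" and b.strand == "-":
                        orient = "revcomp"
                        left_span = (a.ref_end - lf.interval.start) % L + 1
                    else:
                        continue
                    jc = JunctionClass(lf.limp_id, orient, rf.limp_id)
                    if jc not in jset:
                        continue
                    right_span = (b.ref_end - rf.interval.start) % L + 1
                    implied = left_span + right_span + limp_len.get(jc.left_id, 0)
                    if implied <= max_implied_insert:
                        candidates.append((implied, jc))
        if not candidates:
            continue
        candidates.sort(key=lambda t: t[0])
        if len(candidates) > 1 and candidates[0][0] == candidates[1][0] \
                and candidates[0][1] != candidates[1][1]:
            continue  # ambiguous assignment
        matrix.add(candidates[0][1])
    return matrix


# ---------------------------------------------------------------------------
# unit-number variants
# ---------------------------------------------------------------------------


def count_unit_variants(
    alignments: list[AlignmentRecord],
    limp: LimpRecord,
    genome: CircularSequence | None = None,
) -> tuple[int, int]:
    """Reads whose indel over the A-unit (resp. T-unit) run is a nonzero
    multiple of the 5-nt unit length; each read counts on at most one
    side (the side with the larger net indel; ties go to the A side).

    Soft-clipped reads are re-anchored when the clipped bases are exact
    repeats of the adjacent unit (requires read sequences).
    """
    L = genome.length if genome is not None else None
    a_start = limp.start
    a_end = limp.start + 5 * limp.m - 1
    t_start = limp.start + 5 * limp.m + 7
    t_end = t_start + 5 * limp.n - 1

    def in_run(pos: int, lo: int, hi: int) -> bool:
        if L is None:
            return lo <= pos <= hi
        return (pos - lo) % L <= (hi - lo) % L

    a_count = t_count = 0
    for rec in alignments:
        a_indel = t_indel = 0
        ref = rec.ref_start
        for op_i, (n, op) in enumerate(rec.ops):
            if op in "M=X":
                ref += n
            elif op == "D":
                if in_run(ref, a_start, a_end):
                    a_indel -= n
                elif in_run(ref, t_start, t_end):
                    t_indel -= n
                ref += n
            elif op == "I":
                if in_run(ref - 1, a_start, a_end):
                    a_indel += n
                elif in_run(ref - 1, t_start, t_end):
                    t_indel += n
            elif op == "S" and rec.sequence is not None:
                # clip at a read end adjacent to a unit run: exact unit
                # repeats in the clipped bases indicate extra units
                clip = rec.sequence[:n] if op_i == 0 else rec.sequence[-n:]
                anchor = rec.ref_start - 1 if op_i == 0 else rec.ref_end + 1
                unit = None
                if in_run(anchor, a_start, a_end):
                    unit = "AACCA"
                elif in_run(anchor, t_start, t_end):
                    unit = "TGGTT"
                if unit and n >= 5 and n % 5 == 0 and clip in (unit * 13):
                    if unit == "AACCA":
                        a_indel += n
                    else:
                        t_indel += n
        a_var = a_indel != 0 and a_indel % 5 == 0
        t_var = t_indel != 0 and t_indel % 5 == 0
        if a_var and t_var:
            if abs(a_indel) >= abs(t_indel):
                a_count += 1
            else:
                t_count += 1
        elif a_var:
            a_count += 1
        elif t_var:
            t_count += 1
    return a_count, t_count


# ---------------------------------------------------------------------------
# deletions between direct repeats
# ---------------------------------------------------------------------------


def detect_deletions(
    alignments: list[AlignmentRecord],
    genome: CircularSequence,
    min_repeat: int = 8,
    min_del_len: int = 20,
    min_support: int = 3,
) -> list[tuple[int, int, int]]:
    """Cluster reads carrying the same large deletion and report
    (position, deletion_length, direct_repeat_length).

    Deletions are left-normalized before clustering (a deletion between
    direct repeats is alignable at any offset within the repeat).  The
    direct-repeat length is measured on the genome as the maximal k with
    genome[p .. p+k-1] == genome[p+len .. p+len+k-1] from the leftmost
    placement p.  Events supported by fewer than ``min_support`` reads
    are suppressed; ``min_repeat`` sets the shortest repeat reported.
    """
    L = genome.length
    support: dict[tuple[int, int], int] = defaultdict(int)
    for rec in alignments:
        ref = rec.ref_start
        for n, op in rec.ops:
            if op in "M=X":
                ref += n
            elif op == "D":
                if n >= min_del_len:
                    pos = ref  # first deleted base, 1-based
                    while genome.base(genome.wrap(pos - 1)) == genome.base(
                        genome.wrap(pos + n - 1)
                    ):
                        pos -= 1
                    support[(genome.wrap(pos), n)] += 1
                ref += n
    events = []
    for (pos, dlen), cnt in sorted(support.items()):
        if cnt < min_support:
            continue
        k = 0
        while k < dlen and genome.base(genome.wrap(pos + k)) == genome.base(
            genome.wrap(pos + dlen + k)
        ):
            k += 1
        if k < min_repeat:
            continue
        events.append((pos, dlen, k))
    return events


# ---------------------------------------------------------------------------
# inter-LIMP coverage
# ---------------------------------------------------------------------------


def interlimp_coverage(track, limps: list[LimpRecord]) -> list[tuple[int, float, float]]:
    """Mean and standard deviation of per-position depth in each circular
    inter-LIMP region.  Region i lies between LIMPs i and i+1; the last
    region runs from the last LIMP back to the first."""
    depth = np.asarray(track.depth if hasattr(track, "depth") else track)
    L = len(depth)
    order = sorted(limps, key=lambda r: r.start)
    out = []
    n = len(order)
    for idx, limp in enumerate(order):
        nxt = order[(idx + 1) % n]
        start = (limp.start + limp.total_length - 1) % L + 1  # after this LIMP
        end = (nxt.start - 2) % L + 1  # before the next LIMP
        span = (end - start) % L + 1
        if n == 1:
            span = L - limp.total_length
        if span <= 0:
            raise ValueError(f"zero-length inter-LIMP region after LIMP {idx + 1}")
        idxs = (np.arange(span) + start - 1) % L
        vals = depth[idxs]
        lid = limp.limp_id if limp.limp_id is not None else idx + 1
        out.append((lid, float(vals.mean()), float(vals.std())))
    return out
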
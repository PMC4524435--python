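"""RNA-Seq coverage tracks and coverage-interruption classification.

A LIMP that folds into a long stem-loop on the primary transcript can be
a processing site: RNA-Seq depth collapses over the repeat.  Following
the published convention, a repeat whose minimum depth is 5 reads or
fewer is classified *interrupted*; the low/normal boundary (default 25)
is an implementation choice, since published "low" minima were 13-19
reads and "normal" ones 47+.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .detect import LimpRecord

INTERRUPTION_MAX_DEFAULT = 5
LOW_MAX_DEFAULT = 25

#: stem-length boundaries of the published interruption rule (bp)
STEM_SHORT = 20  # stems < 20 bp: no interruption
STEM_LONG = 25   # stems > 25 bp: complete interruption


class CoverageTrack:
    """Per-position read depth over the circular genome."""

    def __init__(self, depth):
        self.depth = np.asarray(depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    @property
    def length(self) -> int:
        return len(self.depth)

    def __len__(self) -> int:
        return len(self.depth)

    def interval_min(self, start: int, span: int) -> int:
        idxs = (np.arange(span) + start - 1) % self.length
        return int(self.depth[idxs].min())

    def to_bedgraph(self, path: str | Path, seqid: str) -> None:
        """Write as bedGraph (0-based half-open), merging equal runs."""
        d = self.depth
        with open(path, "w") as fh:
            run_start = 0
            for i in range(1, len(d) + 1):
                if i == len(d) or d[i] != d[run_start]:
                    fh.write(f"{seqid}\t{run_start}\t{i}\t{int(d[run_start])}\n")
                    run_start = i

    @classmethod
    def from_bedgraph(cls, path: str | Path, genome_length: int) -> "CoverageTrack":
        depth = np.zeros(genome_length, dtype=np.int64)
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                _, start, end, value = line.split()[:4]
                depth[int(start) : int(end)] = int(float(value))
        return cls(depth)


def coverage_from_alignments(alignments, genome_length: int) -> CoverageTrack:
    """Per-position count of reads covering each base.  Aligned-base runs
    (M/=/X) add depth; deletion runs do not.  Origin-wrapping alignments
    on a circular genome add depth on both sides of the origin."""
    depth = np.zeros(genome_length, dtype=np.int64)
    for rec in alignments:
        ref = rec.ref_start
        for n, op in rec.ops:
            if op in "M=X":
                idxs = (np.arange(n) + ref - 1) % genome_length
                depth[idxs] += 1
                ref += n
            elif op in "DN":
                ref += n
        if rec.ref_start < 1:
            raise ValueError("alignment before position 1")
    return CoverageTrack(depth)


@dataclass(frozen=True)
class ExpressionClass:
    limp_id: int
    min_coverage: int
    expression: str  # 'interrupted', 'low' or 'normal'


def classify_limp_expression(
    track: CoverageTrack,
    limp: LimpRecord,
    interruption_max: int = INTERRUPTION_MAX_DEFAULT,
    low_max: int = LOW_MAX_DEFAULT,
) -> ExpressionClass:
    """Classify by the minimum depth over the LIMP footprint:
    interrupted (<= interruption_max), low (<= low_max), else normal."""
    if track.length == 0:
        raise ValueError("empty track")
    mn = track.interval_min(limp.start, limp.total_length)
    if mn <= interruption_max:
        cls = "interrupted"
    elif mn <= low_max:
        cls = "low"
    else:
        cls = "normal"
    return ExpressionClass(
        limp_id=limp.limp_id if limp.limp_id is not None else 0,
        min_coverage=mn,
        expression=cls,
    )


@dataclass
class StemRuleReport:
    """Verdict on the stem-length / interruption relationship: short
    stems (< 20 bp) should never be interrupted, long stems (> 25 bp)
    always; the 20-25 bp band is unconstrained (partial effects)."""

    short_total: int
    short_interrupted: int
    mid_total: int
    mid_interrupted: int
    long_total: int
    long_interrupted: int
    violations: list

    @property
    def holds(self) -> bool:
        return not self.violations


def stem_coverage_relationship(records) -> StemRuleReport:
    """``records`` is an iterable of (stem_length, ExpressionClass or
    class string) pairs."""
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least two records")
    short = mid = long_ = 0
    short_i = mid_i = long_i = 0
    violations = []
    for stem, cls in records:
        label = cls.expression if isinstance(cls, ExpressionClass) else cls
        interrupted = label == "interrupted"
        if stem < STEM_SHORT:
            short += 1
            short_i += interrupted
            if interrupted:
                violations.append((stem, label))
        elif stem <= STEM_LONG:
            mid += 1
            mid_i += interrupted
        else:
            long_ += 1
            long_i += interrupted
            if not interrupted:
                violations.append((stem, label))
    return StemRuleReport(short, short_i, mid, mid_i, long_, long_i, violations)


def mean_coverage(track: CoverageTrack, exclude=None) -> float:
    """Mean depth over non-excluded positions; ``exclude`` is a list of
    1-based inclusive intervals (GenomicInterval or (start, end))."""
    keep = np.ones(track.length, dtype=bool)
    for iv in exclude or ():
        start = getattr(iv, "start", None) or iv[0]
        end = getattr(iv, "end", None) or iv[1]
        wraps = getattr(iv, "wraps_origin", False) or end < start
        if wraps:
            keep[start - 1 :] = False
            keep[:end] = False
        else:
            keep[start - 1 : end] = False
    if not keep.any():
        raise ValueError("all positions excluded")
    return float(track.depth[keep].mean())
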
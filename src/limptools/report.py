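"""Per-LIMP summary tables and aggregate statistics.

The summary mirrors the per-repeat feature table of the analysis: one
row per LIMP with its structure (m, loop orientation, n), derived
lengths, the extended palindromic region, hairpin free energy, read
counts with changed unit numbers and the RNA-Seq coverage class.
Columns whose inputs are not supplied stay None and are rendered as
'.' in the text formats.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

from .genome import CircularSequence
from .detect import LimpRecord, extend_palindrome
from .thermo import limp_rna_dg
from .rearrange import AlignmentRecord, count_unit_variants
from .expression import CoverageTrack, classify_limp_expression


@dataclass
class LimpSummaryRow:
    limp_id: int
    start: int
    anchor: int
    m: int
    loop: str
    n: int
    total_length: int
    stem_length: int
    region_length: int
    dg_rna: float | None = None
    a_changes: int | None = None
    t_changes: int | None = None
    coverage_class: str | None = None
    min_coverage: int | None = None


COLUMNS = [f.name for f in fields(LimpSummaryRow)]


def limp_summary(
    genome: CircularSequence,
    limps: list[LimpRecord],
    alignments: list[AlignmentRecord] | None = None,
    track: CoverageTrack | None = None,
    with_thermo: bool = True,
) -> list[LimpSummaryRow]:
    """One summary row per LIMP.  Unit-variant counts need ``alignments``;
    coverage classification needs ``track``; ``with_thermo=False`` skips
    the hairpin free energies."""
    if not limps:
        raise ValueError("no LIMPs to summarize")
    rows = []
    for idx, limp in enumerate(limps):
        if limp.extended_region is None:
            limp = extend_palindrome(genome, limp)
        row = LimpSummaryRow(
            limp_id=limp.limp_id if limp.limp_id is not None else idx + 1,
            start=limp.start,
            anchor=limp.anchor,
            m=limp.m,
            loop=limp.loop_orientation,
            n=limp.n,
            total_length=limp.total_length,
            stem_length=limp.stem_length,
            region_length=limp.extended_length,
        )
        if with_thermo:
            row.dg_rna = limp_rna_dg(genome, limp)
        if alignments is not None:
            row.a_changes, row.t_changes = count_unit_variants(
                alignments, limp, genome
            )
        if track is not None:
            cls = classify_limp_expression(track, limp)
            row.coverage_class = cls.expression
            row.min_coverage = cls.min_coverage
        rows.append(row)
    return rows


def aggregate_summary(rows: list[LimpSummaryRow]) -> dict:
    """Totals-row statistics over a summary table."""
    if not rows:
        raise ValueError("empty summary")
    n = len(rows)
    agg = {
        "n_limps": n,
        "sum_total_length": sum(r.total_length for r in rows),
        "sum_stem_length": sum(r.stem_length for r in rows),
        "sum_region_length": sum(r.region_length for r in rows),
        "mean_total_length": round(sum(r.total_length for r in rows) / n, 1),
        "mean_stem_length": round(sum(r.stem_length for r in rows) / n, 1),
    }
    if all(r.dg_rna is not None for r in rows):
        agg["mean_dg_rna"] = round(sum(r.dg_rna for r in rows) / n, 1)
    if all(r.a_changes is not None for r in rows):
        agg["sum_a_changes"] = sum(r.a_changes for r in rows)
        agg["sum_t_changes"] = sum(r.t_changes for r in rows)
        agg["sum_changes"] = agg["sum_a_changes"] + agg["sum_t_changes"]
    if all(r.coverage_class is not None for r in rows):
        agg["n_interrupted"] = sum(
            1 for r in rows if r.coverage_class == "interrupted"
        )
    return agg


def summary_dataframe(rows: list[LimpSummaryRow]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in COLUMNS} for r in rows])


def _cell(v) -> str:
    return "." if v is None else str(v)


def write_summary_tsv(rows: list[LimpSummaryRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(_cell(getattr(r, c)) for c in COLUMNS) + "\n")


def format_summary_markdown(rows: list[LimpSummaryRow]) -> str:
    lines = [
        "| " + " | ".join(COLUMNS) + " |",
        "|" + "---|" * len(COLUMNS),
    ]
    for r in rows:
        lines.append(
            "| " + " | ".join(_cell(getattr(r, c)) for c in COLUMNS) + " |"
        )
    agg = aggregate_summary(rows)
    lines.append("")
    lines.append(
        "Totals: "
        + ", ".join(f"{k}={v}" for k, v in agg.items())
    )
    return "\n".join(lines) + "\n"
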
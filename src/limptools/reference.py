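"""Published reference data for the *L. incisa* mitochondrial palindrome
(LIMP) analysis.

These constants transcribe the published per-repeat feature table and a
handful of printed sequence features (promoter motifs, the nonanucleotide
tandem array, interspersed repeat-family consensus sequences).  They serve
as inputs: the synthetic genome reconstruction plants exactly these
structures, and the summary/aggregation code is validated against the
printed totals.
"""

from __future__ import annotations

from dataclasses import dataclass

#: length of the circular mitochondrial chromosome (bp)
GENOME_LENGTH = 69_997

#: overall G+C fraction of the chromosome
GENOME_GC = 0.36

A_UNIT = "AACCA"
T_UNIT = "TGGTT"
LOOP_PLUS = "AATGAAA"
LOOP_MINUS = "TTTCATT"
UNIT_LEN = 5
LOOP_LEN = 7

#: hybrid decanucleotide of the related HyLIMP palindrome family
HYLIMP_UNIT = "AACCAGAGCC"


@dataclass(frozen=True)
class LimpReference:
    """One published LIMP: structure, derived metrics and measurements.

    ``anchor`` is the 1-based position of the first nucleotide of the
    first T-unit.  ``region_length`` is the palindromic region including
    nucleotides extending the stem.  ``a_changes``/``t_changes`` count
    genomic reads showing a changed number of A-/T-units.  ``min_coverage``
    is the RNA-Seq read count at the position of lowest coverage;
    ``coverage_class`` is 'interrupted', 'low' or 'normal'.
    """

    limp_id: int
    anchor: int
    m: int
    loop: str
    n: int
    total_length: int
    stem_length: int
    region_length: int
    a_changes: int
    t_changes: int
    dg_rna: float
    coverage_class: str
    min_coverage: int


LIMP_TABLE: tuple[LimpReference, ...] = (
    LimpReference(1, 33, 5, "+", 4, 52, 20, 52, 0, 6, -30.6, "low", 19),
    LimpReference(2, 2152, 8, "+", 6, 77, 30, 77, 18, 5, -49.7, "interrupted", 2),
    LimpReference(3, 7742, 7, "+", 8, 82, 35, 82, 0, 11, -63.0, "interrupted", 1),
    LimpReference(4, 10697, 8, "-", 7, 82, 35, 82, 0, 6, -61.2, "interrupted", 0),
    LimpReference(5, 14093, 8, "-", 9, 92, 40, 96, 9, 7, -77.6, "interrupted", 1),
    LimpReference(6, 15481, 7, "+", 10, 92, 35, 92, 1, 2, -66.6, "interrupted", 1),
    LimpReference(7, 16799, 10, "-", 9, 102, 45, 102, 4, 12, -80.0, "interrupted", 1),
    LimpReference(8, 17732, 8, "+", 9, 92, 40, 96, 20, 5, -76.8, "interrupted", 0),
    LimpReference(9, 18115, 7, "-", 8, 82, 35, 86, 12, 0, -68.2, "interrupted", 0),
    LimpReference(10, 23885, 3, "-", 2, 32, 10, 74, 1, 0, -55.2, "normal", 145),
    LimpReference(11, 29424, 3, "-", 9, 67, 15, 67, 1, 6, -27.4, "normal", 47),
    LimpReference(12, 32075, 11, "+", 13, 127, 55, 127, 27, 12, -101.7, "interrupted", 1),
    LimpReference(13, 43731, 3, "+", 3, 37, 15, 37, 4, 0, -21.7, "normal", 83),
    LimpReference(14, 50059, 12, "-", 8, 107, 40, 107, 1, 7, -70.4, "interrupted", 5),
    LimpReference(15, 55976, 4, "+", 13, 92, 20, 96, 8, 10, -48.0, "low", 13),
    LimpReference(16, 59523, 5, "-", 5, 57, 25, 57, 0, 0, -41.3, "low", 18),
    LimpReference(17, 60233, 8, "-", 7, 82, 35, 82, 0, 1, -61.2, "interrupted", 1),
    LimpReference(18, 66788, 7, "-", 9, 87, 35, 87, 4, 9, -63.1, "interrupted", 1),
    LimpReference(19, 67694, 9, "+", 8, 92, 40, 92, 14, 6, -68.2, "interrupted", 1),
)

#: published totals row (sum of total lengths, sum of stem lengths)
PUBLISHED_SUM_TOTAL = 1533
PUBLISHED_SUM_STEM = 605
PUBLISHED_SUM_REGION = 1591
PUBLISHED_MEAN_TOTAL = 80.7
PUBLISHED_SUM_A_CHANGES = 124
PUBLISHED_SUM_T_CHANGES = 105
PUBLISHED_MEAN_DG = -59.6

#: mean free-energy cost of the cruciform relative to linear duplex DNA
PUBLISHED_CRUCIFORM_PENALTY = 23.3

#: the three short deletions observed between direct repeats
#: (deletion length nt, direct repeat length nt)
PUBLISHED_DELETIONS = ((173, 9), (110, 12), (57, 11))

#: divergent putative promoter motifs (motif, 1-based position, strand)
PROMOTER_MOTIFS = (("TATATAGAA", 69_264, "-"), ("TTTATAGGA", 69_295, "+"))

#: tandem array downstream of rps12: 12 head-to-tail copies
TANDEM_UNIT = "GAGGGCTAC"
TANDEM_COPIES = 12

#: interspersed repeat-family consensus sequences
REPEAT_FAMILIES: tuple[tuple[str, str], ...] = (
    ("Repeat_2", "GCCTGTACAAATCTCTGCCCAACCGTAATGAAATGGTTGGCAAAAGAAAAAGAAATGGTGAGAGTAATCAAATGGTTGGCTC"),
    ("Repeat_3", "CCAGTTAAAATGAATGGCAAAAAACAAATGGTTGG"),
    ("Repeat_4", "CTCCACACCATTTCATTAATCTCTGATTTGTTCA"),
    ("Repeat_5", "TTTGGTTTGGTTTGGTTACAAATCAGAGAAAAGCAGGGGCTC"),
    ("Repeat_6", "TTACGGTTGGGCAGAGAAAAAAGGCAACCGTGAAAAAAAAAGCTGCGGT"),
    ("Repeat_7", "AATCTCTGATTTGTTCAGGAACAACTGGTTGGG"),
)

#: degenerate pentanucleotide units printed next to particular LIMPs:
#: AGCCA / CGGTG flanking #2; GTCCA GACCA left of #5, 8, 9 and 15.
DEGENERATE_LEFT_FLANKS = {
    2: "AGCCA",
    5: "GTCCAGACCA",
    8: "GTCCAGACCA",
    9: "GTCCAGACCA",
    15: "GTCCAGACCA",
}
DEGENERATE_RIGHT_FLANKS = {2: "CGGTG"}
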
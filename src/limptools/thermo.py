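"""Nearest-neighbor free-energy evaluation of palindrome secondary
structure.

Two questions are asked of every LIMP.  First, how stable is the
stem-loop the repeat forms when transcribed as RNA?  This is the minimum
free energy of the hairpin fold at 37 degC under the Turner 2004 RNA
parameter set (computed with ViennaRNA; for these repeats the MFE
structure is the single stem-loop implied by the palindrome).  Second,
how much less stable is the DNA cruciform -- both strands folded onto
themselves over the palindromic region -- than the linear B-form duplex?
The penalty is

    cruciform_penalty = (dG_hairpin_strand1 + dG_hairpin_strand2) - dG_duplex

and is positive when the cruciform is less stable, which is why cruciform
extrusion requires negative supercoiling.  DNA hairpins use ViennaRNA's
Mathews 2004 DNA parameters; the linear duplex is the SantaLucia unified
nearest-neighbor stack sum plus initiation.  Unpaired surplus repeat
units of an asymmetric palindrome behave as dangling tails, not loop.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as mt

from .genome import CircularSequence, reverse_complement, subsequence
from .detect import LimpRecord, extend_palindrome
from .reference import A_UNIT, T_UNIT, UNIT_LEN

_lock = threading.Lock()

# folding temperature (degC); both parameter sets are evaluated at 37
TEMPERATURE_C = 37.0
_T_KELVIN = 310.15

MIN_FOLDABLE = 9  # 3-bp stem + 3-nt loop


def _rna():
    import RNA

    return RNA


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThermoResult:
    """Hairpin and duplex free energies (kcal/mol) for one palindrome."""

    dg_hairpin: float  # strand-1 hairpin (DNA parameters)
    dg_hairpin_revcomp: float  # strand-2 hairpin
    dg_duplex: float  # linear double-stranded form of the region
    cruciform_penalty: float


def rna_hairpin_dg(sequence: str) -> float:
    """Minimum free energy (kcal/mol) of the RNA hairpin fold at 37 degC.

    DNA input is transcribed in place (T -> U).  A sequence that cannot
    form at least a 3-bp stem with a 3-nt loop is an error; a sequence
    with no stable fold returns 0.0 (ViennaRNA's open chain).
    """
    rna = sequence.upper().replace("T", "U")
    if len(rna) < MIN_FOLDABLE:
        raise ValueError(f"sequence of {len(rna)} nt is too short to fold")
    RNA = _rna()
    with _lock:
        RNA.params_load_RNA_Turner2004()
        _, mfe = RNA.fold_compound(rna).mfe()
    return round(float(mfe), 2)


def dna_hairpin_dg(sequence: str) -> float:
    """MFE (kcal/mol) of a single DNA strand folded on itself
    (Mathews 2004 DNA nearest-neighbor parameters)."""
    dna = sequence.upper().replace("U", "T")
    if len(dna) < MIN_FOLDABLE:
        raise ValueError(f"sequence of {len(dna)} nt is too short to fold")
    RNA = _rna()
    with _lock:
        RNA.params_load_DNA_Mathews2004()
        try:
            _, mfe = RNA.fold_compound(dna).mfe()
        finally:
            RNA.params_load_RNA_Turner2004()
    return round(float(mfe), 2)


_COMP = str.maketrans("ACGT", "TGCA")


def _stack_key(dinuc: str) -> str:
    table = mt.DNA_NN3
    key = dinuc + "/" + dinuc.translate(_COMP)
    if key in table:
        return key
    rev = dinuc.translate(_COMP)[::-1]
    return rev + "/" + rev.translate(_COMP)


def _dg37(key: str) -> float:
    dh, ds = mt.DNA_NN3[key]
    return dh - _T_KELVIN * ds / 1000.0


def dna_duplex_dg(sequence: str) -> float:
    """Free energy (kcal/mol) of the linear B-DNA duplex of ``sequence``
    with its perfect complement: unified SantaLucia nearest-neighbor
    stack sum plus duplex initiation, 37 degC, 1 M NaCl."""
    dna = sequence.upper().replace("U", "T")
    if len(dna) < 2:
        raise ValueError("duplex requires at least 2 bp")
    if set(dna) - set("ACGT"):
        raise ValueError("non-DNA characters in duplex sequence")
    total = sum(_dg37(_stack_key(dna[i : i + 2])) for i in range(len(dna) - 1))
    for base in (dna[0], dna[-1]):
        total += _dg37("init_A/T" if base in "AT" else "init_G/C")
    return round(total, 2)


def cruciform_penalty(seq: CircularSequence, limp: LimpRecord) -> ThermoResult:
    """Free-energy cost of extruding the cruciform at a LIMP.

    Both strand hairpins are folded over the extended palindromic region
    with DNA parameters and compared with the linear duplex of the same
    region.  For a perfect palindrome the two strand hairpins are
    (near-)equal by symmetry.
    """
    if limp.extended_region is None:
        limp = extend_palindrome(seq, limp)
    region = subsequence(seq, limp.extended_region)
    h1 = dna_hairpin_dg(region)
    h2 = dna_hairpin_dg(reverse_complement(region))
    duplex = dna_duplex_dg(region)
    return ThermoResult(
        dg_hairpin=h1,
        dg_hairpin_revcomp=h2,
        dg_duplex=duplex,
        cruciform_penalty=round(h1 + h2 - duplex, 2),
    )


# ---------------------------------------------------------------------------
# LIMP-specific fold window
# ---------------------------------------------------------------------------


def _degenerate_unit(fragment: str, unit: str) -> bool:
    return (
        len(fragment) == UNIT_LEN
        and sum(a != b for a, b in zip(fragment, unit)) <= 1
    )


def limp_fold_window(seq: CircularSequence, limp: LimpRecord) -> str:
    """Sequence window folded for a LIMP's hairpin energy: the extended
    palindromic region, widened by immediately adjacent degenerate repeat
    units (pentanucleotides within one substitution of the AACCA / TGGTT
    consensus).  Degenerate units next to a repeat pair with surplus
    units of the opposite branch (G-T/G-U wobbles included), so they
    contribute to the folded structure even though the perfect-match
    palindrome extension stops before them."""
    if limp.extended_region is None:
        limp = extend_palindrome(seq, limp)
    L = seq.length
    ext = (limp.extended_length - limp.total_length) // 2
    # degenerate units are searched in frame with the repeat, outward from
    # the perfect-unit boundary
    n_left = 0
    while n_left < 3:
        p = seq.wrap(limp.start - UNIT_LEN * (n_left + 1))
        if not _degenerate_unit(seq.fetch(p, UNIT_LEN), A_UNIT):
            break
        n_left += 1
    limp_end = limp.start + limp.total_length - 1
    n_right = 0
    while n_right < 3:
        p = seq.wrap(limp_end + 1 + UNIT_LEN * n_right)
        if not _degenerate_unit(seq.fetch(p, UNIT_LEN), T_UNIT):
            break
        n_right += 1
    pad_left = max(ext, UNIT_LEN * n_left)
    pad_right = max(ext, UNIT_LEN * n_right)
    start = seq.wrap(limp.start - pad_left)
    return seq.fetch(start, limp.total_length + pad_left + pad_right)


def limp_rna_dg(seq: CircularSequence, limp: LimpRecord) -> float:
    """RNA hairpin free energy of a LIMP in its genomic context window."""
    return rna_hairpin_dg(limp_fold_window(seq, limp))
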
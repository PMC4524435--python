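"""Independent brute-force reference implementations used as oracles."""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_palindromes(s: str, min_arm: int, max_loop: int) -> set:
    """All maximal inverted repeats of a linear string, reported at their
    deepest closure, as (1-based start, loop_length, arm_length) triples.

    Quadratic scan, independent of the production implementation: for
    every center and loop size whose innermost bases pair (and whose loop
    cannot close further), walk outward while bases stay complementary.
    """
    n = len(s)
    hits = set()
    for g in range(0, max_loop + 1):
        for i in range(1, n - g):  # i = 0-based index of the first loop base
            if _COMP.get(s[i - 1]) != s[i + g]:
                continue
            if g >= 2 and _COMP.get(s[i]) == s[i + g - 1]:
                continue  # loop closes further: not the deepest closure
            ext = 0
            while (
                i - 1 - ext >= 0
                and i + g + ext < n
                and _COMP.get(s[i - 1 - ext]) == s[i + g + ext]
            ):
                ext += 1
            if ext >= min_arm:
                hits.add((i - ext + 1, g, ext))
    return hits


def brute_force_motif(s: str, motif: str, max_mismatch: int, circular: bool) -> set:
    """(1-based position, strand) occurrences of motif on both strands."""
    rc = "".join(_COMP[c] for c in reversed(motif))
    text = s + (s[: len(motif) - 1] if circular else "")
    out = set()
    for strand, q in (("+", motif), ("-", rc)):
        for i in range(min(len(s), len(text) - len(q) + 1)):
            mm = sum(a != b for a, b in zip(text[i : i + len(q)], q))
            if mm <= max_mismatch:
                out.add((i + 1, strand))
    return out


# SantaLucia (1998) unified nearest-neighbor free energies at 37 degC,
# kcal/mol, 1 M NaCl -- transcribed independently of Biopython's
# enthalpy/entropy table.
_UNIFIED_DG37 = {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84,
}
_INIT_GC = 0.98
_INIT_AT = 1.03


def unified_duplex_dg37(s: str) -> float:
    """Published unified-parameter duplex free energy of s:complement."""
    total = sum(_UNIFIED_DG37[s[i : i + 2]] for i in range(len(s) - 1))
    total += _INIT_AT if s[0] in "AT" else _INIT_GC
    total += _INIT_AT if s[-1] in "AT" else _INIT_GC
    return total
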
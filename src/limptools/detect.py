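"""Detection of LIMPs, LIMP remnants, HyLIMPs, generic palindromes,
motifs, tandem arrays and repeat-family copies on a circular genome.

The LIMP (mitochondrial palindrome) pattern is
``(AACCA)_m [AATGAAA | TTTCATT] (TGGTT)_n`` with ``2 <= m, n <= 13``.
Because the pattern class is its own reverse complement (the reverse
complement of an (m, +, n) copy is an (n, -, m) copy), scanning the plus
strand suffices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np

from .genome import CircularSequence, GenomicInterval, reverse_complement
from .reference import (
    A_UNIT,
    HYLIMP_UNIT,
    LOOP_LEN,
    LOOP_MINUS,
    LOOP_PLUS,
    T_UNIT,
    UNIT_LEN,
)

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LimpRecord:
    """One detected LIMP.

    ``start`` is the 1-based position of the first A-unit; ``anchor`` the
    position of the first nucleotide of the first T-unit
    (= start + 5m + 7, wrapped).  ``stem_length`` counts only pairable
    units, 5*min(m, n).
    """

    m: int
    loop_orientation: str
    n: int
    start: int
    anchor: int
    total_length: int
    stem_length: int
    extended_region: GenomicInterval | None = None
    extended_length: int | None = None
    limp_id: int | None = None

    @property
    def end(self) -> int:
        # may exceed the sequence length for wraparound copies; callers
        # wrap through CircularSequence.wrap
        return self.start + self.total_length - 1

    def footprint(self, seq_length: int) -> GenomicInterval:
        end = (self.start + self.total_length - 2) % seq_length + 1
        wraps = end < self.start
        return GenomicInterval(self.start, end, "+", wraps_origin=wraps)


@dataclass(frozen=True)
class PalindromeHit:
    arm_length: int
    loop_length: int
    start: int
    mismatches: int = 0

    @property
    def total_length(self) -> int:
        return 2 * self.arm_length + self.loop_length

    @property
    def end(self) -> int:
        return self.start + self.total_length - 1


@dataclass(frozen=True)
class RemnantHit:
    start: int
    matched_fragment: str
    mismatches: int


@dataclass(frozen=True)
class HyLimpRecord:
    left_units: int
    right_units: int
    core_present: bool
    loop_length: int
    start: int
    arm_length: int


@dataclass(frozen=True)
class RepeatAnnotation:
    family_name: str
    interval: GenomicInterval
    percent_identity: float


# ---------------------------------------------------------------------------
# LIMP detection
# ---------------------------------------------------------------------------

MIN_UNITS_DEFAULT = 2
MAX_UNITS_DEFAULT = 13


def limp_metrics(m: int, loop_orientation: str, n: int) -> tuple[int, int]:
    """Total length (5m + 7 + 5n) and stem length (5*min(m, n)) of a LIMP.

    The stem only pairs as many units as the shorter branch provides.
    """
    if m < 2 or n < 2:
        raise ValueError("unit counts below 2 do not form a LIMP")
    if loop_orientation not in ("+", "-"):
        raise ValueError(f"loop orientation must be + or -, got {loop_orientation!r}")
    total = UNIT_LEN * m + LOOP_LEN + UNIT_LEN * n
    stem = UNIT_LEN * min(m, n)
    return total, stem


def limp_sequence(m: int, loop_orientation: str, n: int) -> str:
    """Canonical plus-strand DNA of an (m, loop, n) LIMP."""
    loop = LOOP_PLUS if loop_orientation == "+" else LOOP_MINUS
    return A_UNIT * m + loop + T_UNIT * n


def parse_limp(fragment: str) -> tuple[int, str, int] | None:
    """Parse a DNA fragment that should be exactly one LIMP; returns
    (m, loop_orientation, n) or None if the fragment is not a full LIMP."""
    pat = re.fullmatch(
        r"((?:AACCA)+)(AATGAAA|TTTCATT)((?:TGGTT)+)", fragment.upper()
    )
    if not pat:
        return None
    m = len(pat.group(1)) // UNIT_LEN
    n = len(pat.group(3)) // UNIT_LEN
    if m < 2 or n < 2:
        return None
    return m, "+" if pat.group(2) == LOOP_PLUS else "-", n


def detect_limps(
    seq: CircularSequence,
    min_units: int = MIN_UNITS_DEFAULT,
    max_units: int = MAX_UNITS_DEFAULT,
) -> list[LimpRecord]:
    """All maximal, non-overlapping LIMP occurrences on the plus strand,
    sorted by start position; wraparound copies are reported once."""
    L = seq.length
    overhang = min(L, 2 * UNIT_LEN * max_units + LOOP_LEN + UNIT_LEN)
    s = seq.residues + (seq.residues[:overhang] if seq.is_circular else "")
    pat = re.compile(
        rf"((?:AACCA){{{min_units},{max_units}}})"
        rf"(AATGAAA|TTTCATT)"
        rf"((?:TGGTT){{{min_units},{max_units}}})"
    )
    records: list[LimpRecord] = []
    seen_starts: set[int] = set()
    for match in pat.finditer(s):
        idx = match.start()
        if idx >= L:
            continue  # wraparound duplicate of a copy already seen
        start = idx + 1
        if start in seen_starts:
            continue
        seen_starts.add(start)
        m = len(match.group(1)) // UNIT_LEN
        n = len(match.group(3)) // UNIT_LEN
        loop = "+" if match.group(2) == LOOP_PLUS else "-"
        total, stem = limp_metrics(m, loop, n)
        anchor = (start + UNIT_LEN * m + LOOP_LEN - 1) % L + 1
        records.append(
            LimpRecord(
                m=m,
                loop_orientation=loop,
                n=n,
                start=start,
                anchor=anchor,
                total_length=total,
                stem_length=stem,
            )
        )
    # A wrapped copy can also surface as a truncated prefix occurrence at
    # the start of the linearized string; occurrences sharing a loop (same
    # anchor) are the same repeat, so keep only the maximal one.
    by_anchor: dict[int, LimpRecord] = {}
    for rec in records:
        best = by_anchor.get(rec.anchor)
        if best is None or rec.total_length > best.total_length:
            by_anchor[rec.anchor] = rec
    records = sorted(by_anchor.values(), key=lambda r: r.start)
    for i, rec in enumerate(records, start=1):
        rec.limp_id = i
    return records


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def extend_palindrome(
    seq: CircularSequence, limp: LimpRecord, max_extension: int = 250
) -> LimpRecord:
    """Extend the palindrome symmetrically outward from the LIMP ends while
    the outer bases remain perfect reverse complements.

    Degenerate flanking units can extend the stem beyond the perfect
    repeat units; extension stops at the first non-complementary pair.
    """
    L = seq.length
    left = limp.start - 1  # position just before the first A-unit
    right = limp.start + limp.total_length  # just after the last T-unit
    ext = 0
    cap = min(max_extension, (L - limp.total_length) // 2)
    while ext < cap:
        a = seq.base(((left - ext - 1) % L) + 1) if seq.is_circular else None
        if not seq.is_circular:
            if left - ext < 1 or right + ext > L:
                break
            a = seq.base(left - ext)
            b = seq.base(right + ext)
        else:
            a = seq.base(seq.wrap(left - ext))
            b = seq.base(seq.wrap(right + ext))
        if _COMP.get(a) != b:
            break
        ext += 1
    ext_len = limp.total_length + 2 * ext
    s = seq.wrap(limp.start - ext) if seq.is_circular else limp.start - ext
    e = seq.wrap(limp.start + limp.total_length - 1 + ext) if seq.is_circular \
        else limp.start + limp.total_length - 1 + ext
    region = GenomicInterval(s, e, "+", wraps_origin=(e < s))
    return replace(limp, extended_region=region, extended_length=ext_len)


# ---------------------------------------------------------------------------
# LIMP remnants
# ---------------------------------------------------------------------------

REMNANT_MIN = 11
REMNANT_MAX = 20


def _canonical_left(d: int) -> str:
    """Base found d positions left of the loop in a canonical LIMP."""
    return A_UNIT[-(((d - 1) % UNIT_LEN) + 1)]


def _canonical_right(d: int) -> str:
    """Base found d positions right of the loop in a canonical LIMP."""
    return T_UNIT[(d - 1) % UNIT_LEN]


def _masked(positions: set[int], start: int, length: int, L: int) -> bool:
    return any(((start - 1 + k) % L) + 1 in positions for k in range(length))


def detect_remnants(
    seq: CircularSequence,
    limps: list[LimpRecord],
    max_mismatch: int = 1,
) -> list[RemnantHit]:
    """Sites carrying an 11-20 nt fragment of the canonical LIMP string
    (full 7-nt loop included) with <= max_mismatch substitutions, outside
    detected LIMP footprints, that cannot form the full stem-loop.
    Overlapping hits are merged into one."""
    L = seq.length
    mask: set[int] = set()
    for rec in limps:
        for k in range(rec.total_length):
            mask.add(((rec.start - 1 + k) % L) + 1)

    side_max = REMNANT_MAX - LOOP_LEN  # max arm contribution to the window

    def side_ext(pos_of, canon, budget):
        """Best extension lengths by mismatch spend: {spent: length}."""
        out = {}
        run = 0
        while run < side_max and seq_char(pos_of(run + 1)) == canon(run + 1):
            run += 1
        out[0] = run
        if budget >= 1 and run < side_max:
            run2 = run + 1  # spend the mismatch on this base
            while run2 < side_max and seq_char(pos_of(run2 + 1)) == canon(run2 + 1):
                run2 += 1
            out[1] = run2
        return out

    def seq_char(p):
        if seq.is_circular:
            return seq.base(seq.wrap(p))
        if 1 <= p <= L:
            return seq.base(p)
        return "?"  # off the end of a linear sequence: never matches

    raw: list[tuple[int, int, int]] = []  # (win_start, win_len, mismatches)
    for p in range(1, L + 1):
        for loop in (LOOP_PLUS, LOOP_MINUS):
            frag = seq.fetch(p, LOOP_LEN) if seq.is_circular else None
            if frag is None:
                if p + LOOP_LEN - 1 > L:
                    continue
                frag = seq.fetch(p, LOOP_LEN)
            loop_mm = sum(a != b for a, b in zip(frag, loop))
            if loop_mm > max_mismatch:
                continue
            budget = max_mismatch - loop_mm
            lefts = side_ext(lambda d: p - d, _canonical_left, budget)
            rights = side_ext(lambda d: p + LOOP_LEN - 1 + d, _canonical_right, budget)
            best = None
            for bl, el in lefts.items():
                for br, er in rights.items():
                    if bl + br > budget:
                        continue
                    win = LOOP_LEN + min(el, side_max) + min(er, side_max)
                    cand = (min(win, REMNANT_MAX), loop_mm + bl + br, el, er)
                    if best is None or cand[0] > best[0] or (
                        cand[0] == best[0] and cand[1] < best[1]
                    ):
                        best = cand
            if best is None or best[0] < REMNANT_MIN:
                continue
            win, mm, el, er = best
            # trim symmetric overflow beyond the 20-nt cap from the longer arm
            while LOOP_LEN + el + er > REMNANT_MAX:
                if el >= er:
                    el -= 1
                else:
                    er -= 1
            win_start = p - el
            win_len = LOOP_LEN + el + er
            # exclude full LIMPs: perfect loop with >=2 perfect units each side
            if loop_mm == 0:
                m_units = perfect_units(seq, p, left=True)
                n_units = perfect_units(seq, p + LOOP_LEN, left=False)
                if m_units >= 2 and n_units >= 2:
                    continue
            if _masked(mask, win_start, win_len, L):
                continue
            raw.append((seq.wrap(win_start) if seq.is_circular else win_start,
                        win_len, mm))

    # merge overlapping windows into single remnant hits
    raw.sort()
    hits: list[RemnantHit] = []
    cur = None
    for start, win_len, mm in raw:
        if cur is not None and start <= cur[1] + 1 and start >= cur[0]:
            cur = (cur[0], max(cur[1], start + win_len - 1), min(cur[2], mm))
        else:
            if cur is not None:
                hits.append(_remnant_from(seq, cur))
            cur = (start, start + win_len - 1, mm)
    if cur is not None:
        hits.append(_remnant_from(seq, cur))
    return hits


def _remnant_from(seq: CircularSequence, cur: tuple[int, int, int]) -> RemnantHit:
    start, end, mm = cur
    frag = seq.fetch(start, min(end - start + 1, REMNANT_MAX))
    return RemnantHit(start=start, matched_fragment=frag, mismatches=mm)


def perfect_units(seq: CircularSequence, loop_edge: int, left: bool) -> int:
    """Number of perfect repeat units immediately left of ``loop_edge``
    (position of the loop's first base) or starting at ``loop_edge``
    (position just after the loop) on the right."""
    count = 0
    L = seq.length
    while count < MAX_UNITS_DEFAULT:
        if left:
            p = loop_edge - UNIT_LEN * (count + 1)
            unit = A_UNIT
        else:
            p = loop_edge + UNIT_LEN * count
            unit = T_UNIT
        if not seq.is_circular and (p < 1 or p + UNIT_LEN - 1 > L):
            break
        if seq.fetch(seq.wrap(p) if seq.is_circular else p, UNIT_LEN) != unit:
            break
        count += 1
    return count


# ---------------------------------------------------------------------------
# generic palindrome scan
# ---------------------------------------------------------------------------

MIN_ARM_DEFAULT = 16  # "stem longer than 15 bp" is strict
MAX_LOOP_DEFAULT = 20  # "loop shorter than 21 nt"


def scan_palindromes(
    seq: CircularSequence,
    min_arm: int = MIN_ARM_DEFAULT,
    max_loop: int = MAX_LOOP_DEFAULT,
    max_mismatch: int = 0,
    exclude: list[GenomicInterval] | None = None,
) -> list[PalindromeHit]:
    """All maximal inverted repeats with arm >= min_arm and loop <= max_loop.

    A hit is reported at its deepest closure: if the innermost loop bases
    could pair, the structure is reported with the smaller loop instead.
    ``exclude`` drops hits overlapping the given intervals (used to report
    non-LIMP palindromes).
    """
    L = seq.length
    if max_mismatch == 0:
        hits = _scan_palindromes_fast(seq, min_arm, max_loop)
    else:
        hits = _scan_palindromes_slow(seq, min_arm, max_loop, max_mismatch)
    if exclude:
        excluded = set()
        for iv in exclude:
            span = iv.length(L)
            for k in range(span):
                excluded.add(((iv.start - 1 + k) % L) + 1)
        hits = [
            h
            for h in hits
            if not _masked(excluded, h.start, h.total_length, L)
        ]
    hits.sort(key=lambda h: (h.start, h.loop_length))
    return hits


_ENC = np.frombuffer(b"\x00" * 256, dtype=np.uint8).copy()
for _i, _b in enumerate(b"ACGTN"):
    _ENC[_b] = _i + 1
_COMP_CODE = np.array([0, 4, 3, 2, 1, 0], dtype=np.uint8)  # N pairs nothing


def _encode(s: str) -> np.ndarray:
    return _ENC[np.frombuffer(s.encode(), dtype=np.uint8)]


def _scan_palindromes_fast(seq, min_arm, max_loop) -> list[PalindromeHit]:
    L = seq.length
    overhang = min(L, 2 * 300 + max_loop)  # arms capped at 300 bp
    s = seq.residues + (seq.residues[:overhang] if seq.is_circular else "")
    a = _encode(s)
    c = _COMP_CODE[a]
    n = len(a)
    seed = 4
    hits = []
    seen = set()
    for g in range(0, max_loop + 1):
        # pair k at innermost center i (0-based left-arm end = i-1):
        # a[i-1-k] must complement a[i+g+k]
        ok = None
        for k in range(min(seed, min_arm)):
            d = g + 1 + 2 * k
            m = a[: n - d] == c[d:]  # m[j] True iff (j, j+d) pair
            # align to center index i: j = i-1-k  ->  i = j+1+k
            arr = np.zeros(n, dtype=bool)
            arr[k + 1 : k + 1 + len(m)] = m
            ok = arr if ok is None else (ok & arr)
        for i in np.nonzero(ok)[0]:
            i = int(i)
            # maximality on the inside: the loop must not close further
            if g >= 2 and a[i] and a[i] == _COMP_CODE[a[i + g - 1]]:
                continue
            ext = seed
            while (
                i - 1 - ext >= 0
                and i + g + ext < n
                and a[i - 1 - ext]
                and a[i - 1 - ext] == c[i + g + ext]
            ):
                ext += 1
            if ext < min_arm:
                continue
            start0 = i - ext  # 0-based start in padded string
            if start0 >= L:
                continue
            start = start0 % L + 1
            key = (start, g, ext)
            if key in seen:
                continue
            seen.add(key)
            hits.append(PalindromeHit(arm_length=ext, loop_length=g, start=start))
    return hits


def _scan_palindromes_slow(seq, min_arm, max_loop, max_mismatch):
    """Mismatch-tolerant scan; per-center outward walk, arms must end on a
    matching pair.  Intended for small inputs."""
    L = seq.length
    overhang = min(L, 700) if seq.is_circular else 0
    s = seq.residues + seq.residues[:overhang]
    n = len(s)
    hits = []
    seen = set()
    for g in range(0, max_loop + 1):
        for i in range(1, n - g):
            if i - 1 < 0 or i + g >= n:
                continue
            if _COMP.get(s[i - 1]) != s[i + g]:
                continue
            if g >= 2 and _COMP.get(s[i]) == s[i + g - 1]:
                continue
            ext, mm, best = 0, 0, 0
            while i - 1 - ext >= 0 and i + g + ext < n:
                if _COMP.get(s[i - 1 - ext]) == s[i + g + ext]:
                    ext += 1
                    best = ext
                elif mm < max_mismatch:
                    mm += 1
                    ext += 1
                else:
                    break
            if best < min_arm:
                continue
            start0 = i - best
            if start0 >= L:
                continue
            key = (start0 % L + 1, g, best)
            if key not in seen:
                seen.add(key)
                hits.append(
                    PalindromeHit(
                        arm_length=best, loop_length=g, start=start0 % L + 1,
                        mismatches=mm,
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# HyLIMPs
# ---------------------------------------------------------------------------

HYLIMP_UNIT_RC = reverse_complement(HYLIMP_UNIT)  # GGCTCTGGTT
HYLIMP_CORE_LEFT = "GAGCC"
HYLIMP_CORE_RIGHT = "GGCTC"


def detect_hylimps(
    seq: CircularSequence,
    min_arm: int = MIN_ARM_DEFAULT,
    max_loop: int = MAX_LOOP_DEFAULT,
) -> list[HyLimpRecord]:
    """Palindrome hits whose arms contain the hybrid decanucleotide
    AACCAGAGCC (left arm) or its reverse complement (right arm)."""
    out = []
    for hit in scan_palindromes(seq, min_arm=min_arm, max_loop=max_loop):
        left = seq.fetch(hit.start, hit.arm_length)
        right = seq.fetch(
            seq.wrap(hit.start + hit.arm_length + hit.loop_length)
            if seq.is_circular
            else hit.start + hit.arm_length + hit.loop_length,
            hit.arm_length,
        )
        lu = left.count(HYLIMP_UNIT)
        ru = right.count(HYLIMP_UNIT_RC)
        if lu < 1 and ru < 1:
            continue
        core = left.endswith(HYLIMP_CORE_LEFT) and right.startswith(
            HYLIMP_CORE_RIGHT
        )
        out.append(
            HyLimpRecord(
                left_units=lu,
                right_units=ru,
                core_present=core,
                loop_length=hit.loop_length,
                start=hit.start,
                arm_length=hit.arm_length,
            )
        )
    return out


# ---------------------------------------------------------------------------
# motifs, tandem arrays, repeat families
# ---------------------------------------------------------------------------


def scan_motif(
    seq: CircularSequence, motif: str, max_mismatch: int = 0
) -> list[tuple[int, str]]:
    """All occurrences of ``motif`` on both strands; positions are the
    plus-strand leftmost base of the occurrence."""
    motif = motif.upper()
    if len(motif) < 4:
        raise ValueError("motif length must be >= 4")
    L = seq.length
    overhang = min(L, len(motif) - 1) if seq.is_circular else 0
    s = seq.residues + seq.residues[:overhang]
    a = _encode(s)
    hits = []
    for strand, query in (("+", motif), ("-", reverse_complement(motif))):
        q = _encode(query)
        k = len(q)
        if len(a) < k:
            continue
        mm = np.zeros(len(a) - k + 1, dtype=np.int32)
        for j in range(k):
            mm += a[j : len(a) - k + 1 + j] != q[j]
        for idx in np.nonzero(mm <= max_mismatch)[0]:
            if idx < L:
                hits.append((int(idx) + 1, strand))
    hits.sort()
    return hits


def find_tandem_arrays(
    seq: CircularSequence, unit: str, min_copies: int = 3
) -> list[tuple[int, int]]:
    """Maximal runs of >= min_copies exact head-to-tail copies of ``unit``.

    Returns (position of first copy, copy number) pairs; runs never
    overlap and cover exactly copy_number * len(unit) nucleotides.
    """
    unit = unit.upper()
    if len(unit) < 3:
        raise ValueError("unit length must be >= 3")
    L = seq.length
    overhang = min(L, len(unit) * 64) if seq.is_circular else 0
    s = seq.residues + seq.residues[:overhang]
    pat = re.compile(f"(?:{re.escape(unit)}){{{min_copies},}}")
    out = []
    seen = set()
    for match in pat.finditer(s):
        idx = match.start()
        copies = len(match.group(0)) // len(unit)
        # extend leftward across the origin if the preceding unit matches
        if seq.is_circular:
            while True:
                prev = (idx - len(unit)) % L
                if seq.fetch(prev + 1, len(unit)) == unit and idx - len(unit) >= -L:
                    idx -= len(unit)
                    copies += 1
                    if copies * len(unit) > L:
                        break
                else:
                    break
        if idx >= L:
            continue
        start = idx % L + 1
        if start in seen:
            continue
        seen.add(start)
        out.append((start, copies))
    out.sort()
    return out


def annotate_repeat_families(
    seq: CircularSequence,
    consensus_set: list[tuple[str, str]],
    min_identity: float = 0.8,
) -> list[RepeatAnnotation]:
    """Greedy best-first local matching of each family consensus (both
    strands) against the genome; non-overlapping hits with identity >=
    ``min_identity`` are reported."""
    import edlib

    L = seq.length
    out = []
    for name, consensus in consensus_set:
        if not consensus:
            raise ValueError(f"empty consensus for {name}")
        consensus = consensus.upper()
        k = int((1.0 - min_identity) * len(consensus))
        for strand in ("+", "-"):
            query = consensus if strand == "+" else reverse_complement(consensus)
            overhang = min(L, len(query)) if seq.is_circular else 0
            target = list(seq.residues + seq.residues[:overhang])
            for _ in range(200):  # safety cap on hits per family/strand
                res = edlib.align(query, "".join(target), mode="HW",
                                  task="locations", k=k)
                if res["editDistance"] < 0 or not res["locations"]:
                    break
                beg, end = res["locations"][0]
                ident = 1.0 - res["editDistance"] / len(query)
                if beg < L:
                    s1 = beg % L + 1
                    e1 = end % L + 1
                    out.append(
                        RepeatAnnotation(
                            family_name=name,
                            interval=GenomicInterval(
                                s1, e1, strand, wraps_origin=(e1 < s1)
                            ),
                            percent_identity=ident,
                        )
                    )
                for p in range(beg, end + 1):
                    target[p] = "N"
    out.sort(key=lambda r: (r.interval.start, r.family_name))
    return out
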
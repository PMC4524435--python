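import numpy as np
import pytest
from hypothesis import given, strategies as st

from limptools.genome import CircularSequence, reverse_complement
from limptools.detect import (
    detect_hylimps,
    detect_limps,
    detect_remnants,
    extend_palindrome,
    find_tandem_arrays,
    annotate_repeat_families,
    limp_metrics,
    limp_sequence,
    parse_limp,
    scan_motif,
    scan_palindromes,
)

from oracles import brute_force_motif, brute_force_palindromes

units = st.integers(2, 13)
loops = st.sampled_from(["+", "-"])


def g_pad(core: str, left: int = 30, right: int = 30) -> CircularSequence:
    """Embed a construct in a G-only background (G matches no canonical
    LIMP position adjacent to a loop and pairs with nothing present)."""
    return CircularSequence("t", "G" * left + core + "G" * right)


# ---------------------------------------------------------------------------
# metrics / parsing
# ---------------------------------------------------------------------------


def test_limp_metrics_known_values():
    assert limp_metrics(2, "+", 2) == (27, 10)
    assert limp_metrics(5, "+", 4) == (52, 20)
    assert limp_metrics(3, "-", 2) == (32, 10)
    assert limp_metrics(11, "+", 13) == (127, 55)
    with pytest.raises(ValueError):
        limp_metrics(1, "+", 5)
    with pytest.raises(ValueError):
        limp_metrics(3, "x", 3)


@given(units, loops, units)
def test_parse_limp_roundtrip(m, loop, n):
    assert parse_limp(limp_sequence(m, loop, n)) == (m, loop, n)


def test_parse_limp_rejects():
    assert parse_limp("AACCAAATGAAATGGTT") is None  # m = 1
    assert parse_limp("AACCAAACCAAATGAAA") is None  # no T branch
    assert parse_limp("G" + limp_sequence(2, "+", 2)) is None  # not exact


@given(units, loops, units)
def test_revcomp_symmetry_of_pattern(m, loop, n):
    rc = reverse_complement(limp_sequence(m, loop, n))
    flipped = "+" if loop == "-" else "-"
    assert parse_limp(rc) == (n, flipped, m)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


@given(units, loops, units)
def test_detect_single_planted_limp(m, loop, n):
    seq = g_pad(limp_sequence(m, loop, n))
    recs = detect_limps(seq)
    assert len(recs) == 1
    r = recs[0]
    assert (r.m, r.loop_orientation, r.n, r.start) == (m, loop, n, 31)
    assert r.anchor == 31 + 5 * m + 7
    assert r.limp_id == 1


@given(units, loops, units, st.integers(0, 200))
def test_detection_rotation_invariance(m, loop, n, off):
    seq = g_pad(limp_sequence(m, loop, n), 40, 40)
    base = detect_limps(seq)
    rot = detect_limps(seq.rotated(off))
    assert [(r.m, r.loop_orientation, r.n) for r in rot] == [
        (r.m, r.loop_orientation, r.n) for r in base
    ]
    assert len(rot) == 1
    assert rot[0].start == seq.rotated(off).wrap(base[0].start - off)


def test_detect_wraparound_limp():
    core = limp_sequence(4, "+", 3)
    seq = g_pad(core, 30, 30)
    # rotate so the LIMP spans the origin
    rot = seq.rotated(30 + len(core) // 2)
    recs = detect_limps(rot)
    assert len(recs) == 1
    assert recs[0].start > rot.length - len(core)


def test_detect_multiple_sorted_ids():
    s = g_pad(limp_sequence(2, "+", 2), 20, 0).residues + g_pad(
        limp_sequence(3, "-", 5), 20, 20
    ).residues
    recs = detect_limps(CircularSequence("t", s))
    assert [r.limp_id for r in recs] == [1, 2]
    assert recs[0].start < recs[1].start


def test_unit_count_bounds():
    # 14 units on one side: the detector reports at most 13
    core = "AACCA" * 14 + "AATGAAA" + "TGGTT" * 3
    recs = detect_limps(g_pad(core))
    assert len(recs) == 1
    assert recs[0].m == 13


# ---------------------------------------------------------------------------
# palindromic extension
# ---------------------------------------------------------------------------


def test_extend_palindrome_exact():
    ext = "ACGTA"
    core = limp_sequence(2, "+", 2)
    seq = g_pad(ext + core + reverse_complement(ext))
    rec = detect_limps(seq)[0]
    rec = extend_palindrome(seq, rec)
    assert rec.extended_length == rec.total_length + 10
    assert rec.extended_region.start == rec.start - 5
    assert rec.extended_region.end == rec.start + rec.total_length - 1 + 5


def test_extend_palindrome_zero():
    seq = g_pad(limp_sequence(2, "-", 2))
    rec = extend_palindrome(seq, detect_limps(seq)[0])
    assert rec.extended_length == rec.total_length


def test_extend_palindrome_across_origin():
    ext = "ACGTA"
    core = limp_sequence(2, "+", 2)
    seq = g_pad(ext + core + reverse_complement(ext)).rotated(30 + 2)
    rec = extend_palindrome(seq, detect_limps(seq)[0])
    assert rec.extended_length == len(core) + 10
    assert rec.extended_region.wraps_origin


# ---------------------------------------------------------------------------
# remnants
# ---------------------------------------------------------------------------


def test_remnant_detected():
    frag = "AACCAAATGAAAT"  # one A-unit, loop, 1 nt of T-unit: 13 nt
    seq = g_pad(frag)
    hits = detect_remnants(seq, [])
    assert len(hits) == 1
    # the merged window covers the planted fragment; the detector may
    # spend its mismatch budget extending into background
    assert hits[0].start <= 31
    assert hits[0].start + len(hits[0].matched_fragment) - 1 >= 31 + len(frag) - 1
    assert hits[0].mismatches <= 1


def test_remnant_window_too_short():
    seq = g_pad("CAAATGAAA")  # 2 + loop + 0 = 9 nt < 11
    assert detect_remnants(seq, [], max_mismatch=0) == []


def test_remnant_with_one_mismatch():
    frag = "AACCAAATGCAAT"  # loop carries one substitution
    hits = detect_remnants(g_pad(frag), [])
    assert len(hits) == 1
    assert hits[0].mismatches == 1


def test_remnant_excludes_full_limp():
    seq = g_pad(limp_sequence(2, "+", 2))
    # not passed as a detected LIMP: the full-stem-loop exclusion rule
    # must still reject it
    assert detect_remnants(seq, []) == []


def test_remnant_masked_by_limp_footprint():
    seq = g_pad(limp_sequence(2, "+", 2))
    limps = detect_limps(seq)
    assert detect_remnants(seq, limps) == []


def test_remnant_minus_loop():
    hits = detect_remnants(g_pad("CCATTTCATTTGG"), [])
    assert len(hits) == 1


# ---------------------------------------------------------------------------
# generic palindromes vs brute force
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(5))
def test_palindrome_scanner_matches_oracle_random(seed):
    rng = np.random.default_rng(seed)
    s = "".join(rng.choice(list("ACGT"), size=3000))
    seq = CircularSequence("t", s, is_circular=False)
    got = {(h.start, h.loop_length, h.arm_length)
           for h in scan_palindromes(seq, min_arm=5, max_loop=8)}
    assert got == brute_force_palindromes(s, 5, 8)


def test_palindrome_scanner_matches_oracle_structured():
    rng = np.random.default_rng(99)
    parts = []
    for _ in range(6):
        parts.append("".join(rng.choice(list("ACGT"), size=150)))
        arm = "".join(rng.choice(list("ACGT"), size=int(rng.integers(16, 40))))
        loop = "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 20))))
        parts.append(arm + loop + reverse_complement(arm))
    s = "".join(parts)[:5000]
    seq = CircularSequence("t", s, is_circular=False)
    got = {(h.start, h.loop_length, h.arm_length)
           for h in scan_palindromes(seq)}
    expected = brute_force_palindromes(s, 16, 20)
    assert got == expected
    assert expected  # the construction must actually contain hits


def test_palindrome_exclude_intervals():
    seq = g_pad(limp_sequence(5, "+", 5), 50, 50)
    limps = [extend_palindrome(seq, r) for r in detect_limps(seq)]
    hits = scan_palindromes(seq, min_arm=10)
    assert hits
    assert scan_palindromes(
        seq, min_arm=10, exclude=[r.extended_region for r in limps]
    ) == []


def test_palindrome_mismatch_arm():
    arm = "ACGTACGTACGTACGTACGT"  # 20 nt
    bad = arm[:10] + "T" + arm[11:]  # one internal substitution
    s = "G" * 30 + bad + "AAA" + reverse_complement(arm) + "G" * 30
    seq = CircularSequence("t", s, is_circular=False)
    perfect = scan_palindromes(seq, min_arm=16, max_mismatch=0)
    tolerant = scan_palindromes(seq, min_arm=16, max_mismatch=1)
    assert not any(h.arm_length >= 16 for h in perfect)
    assert any(h.arm_length >= 16 and h.mismatches == 1 for h in tolerant)


# ---------------------------------------------------------------------------
# HyLIMPs, motifs, tandem arrays, repeat families
# ---------------------------------------------------------------------------


def test_hylimp_detection():
    unit = "AACCAGAGCC"
    left = unit * 2 + "GAGCC"
    element = left + "TTT" + reverse_complement(left)
    seq = g_pad(element, 40, 40)
    recs = detect_hylimps(seq)
    assert len(recs) == 1
    r = recs[0]
    assert (r.left_units, r.right_units, r.core_present) == (2, 2, True)
    assert r.start == 41
    assert r.loop_length == 3


def test_hylimp_not_reported_for_plain_palindrome():
    arm = "ACGTACGTACGTACGTACGT"
    seq = g_pad(arm + "TTT" + reverse_complement(arm), 40, 40)
    assert detect_hylimps(seq, min_arm=16) == []


@given(
    st.text(alphabet="ACGT", min_size=30, max_size=120),
    st.integers(0, 1),
)
def test_motif_scan_matches_oracle(s, mm):
    seq = CircularSequence("t", s)
    motif = "TATATAGAA"
    got = set(scan_motif(seq, motif, max_mismatch=mm))
    assert got == brute_force_motif(s, motif, mm, circular=True)


def test_motif_rejects_short():
    with pytest.raises(ValueError):
        scan_motif(CircularSequence("t", "ACGTACGT"), "ACG")


def test_tandem_array_basic():
    seq = g_pad("GAGGGCTAC" * 4, 25, 25)
    assert find_tandem_arrays(seq, "GAGGGCTAC") == [(26, 4)]


def test_tandem_array_across_origin():
    seq = g_pad("GAGGGCTAC" * 4, 25, 25).rotated(26 + 18)
    hits = find_tandem_arrays(seq, "GAGGGCTAC")
    assert len(hits) == 1
    assert hits[0][1] == 4


def test_tandem_array_below_min_copies():
    seq = g_pad("GAGGGCTAC" * 2, 25, 25)
    assert find_tandem_arrays(seq, "GAGGGCTAC") == []


def test_repeat_family_annotation():
    rng = np.random.default_rng(7)
    bg = "".join(rng.choice(list("ACGT"), size=2000))
    cons = "GCCTGTACAAATCTCTGCCCAACCGTAATGGCATGACCAGGA"
    mutated = cons[:10] + "A" + cons[11:20] + "C" + cons[21:]  # ~95% identity
    diverged = "".join(rng.choice(list("ACGT"), size=len(cons)))
    s = bg[:500] + cons + bg[500:1000] + mutated + bg[1000:1500] + diverged
    seq = CircularSequence("t", s)
    hits = annotate_repeat_families(seq, [("fam", cons)], min_identity=0.85)
    starts = {h.interval.start for h in hits}
    assert 501 in starts
    assert 500 + len(cons) + 501 in starts
    assert all(h.percent_identity >= 0.85 for h in hits)


def test_repeat_family_reverse_strand():
    rng = np.random.default_rng(8)
    bg = "".join(rng.choice(list("ACGT"), size=800))
    cons = "GCCTGTACAAATCTCTGCCCAACCGTAATGGCATGACCAGGA"
    s = bg[:400] + reverse_complement(cons) + bg[400:]
    hits = annotate_repeat_families(
        CircularSequence("t", s), [("fam", cons)], min_identity=0.9
    )
    assert any(h.interval.strand == "-" and h.interval.start == 401 for h in hits)
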
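import numpy as np
import pytest

from limptools.genome import CircularSequence
from limptools.detect import detect_limps, limp_sequence
from limptools.rearrange import (
    AlignmentRecord,
    JunctionClass,
    count_joint_support,
    count_unit_variants,
    detect_deletions,
    enumerate_junctions,
    extract_flanks,
    interlimp_coverage,
    read_alignments_tsv,
    write_alignments_tsv,
)


def two_limp_genome():
    """2000-bp circle with LIMP 1 at 501 (27 nt) and LIMP 2 at 1501."""
    rng = np.random.default_rng(11)
    arr = rng.choice(list("ACGT"), size=2000)
    for start0, core in ((500, limp_sequence(2, "+", 2)),
                         (1500, limp_sequence(2, "-", 2))):
        for k, ch in enumerate(core):
            arr[start0 + k] = ch
    genome = CircularSequence("t", "".join(arr))
    limps = detect_limps(genome)
    assert [(r.start, r.limp_id) for r in limps] == [(501, 1), (1501, 2)]
    return genome, limps


# ---------------------------------------------------------------------------
# records and IO
# ---------------------------------------------------------------------------


def test_cigar_parsing():
    rec = AlignmentRecord("q", 1, 100, "+", "10M2D5M3I7M")
    assert rec.ops == [(10, "M"), (2, "D"), (5, "M"), (3, "I"), (7, "M")]
    assert rec.reference_span == 24
    assert rec.ref_end == 123
    with pytest.raises(ValueError):
        AlignmentRecord("q", 1, 100, "+", "10Q")
    with pytest.raises(ValueError):
        AlignmentRecord("q", 1, 100, "+", "")


def test_mapq_uniqueness():
    assert AlignmentRecord("q", 1, 1, "+", "5M", mapq=20).is_unique
    assert not AlignmentRecord("q", 1, 1, "+", "5M", mapq=3).is_unique


def test_tsv_roundtrip(tmp_path):
    recs = [
        AlignmentRecord("a", 1, 10, "+", "50M", 60),
        AlignmentRecord("a", 2, 400, "-", "20M5D30M", 60),
    ]
    path = tmp_path / "aln.tsv"
    write_alignments_tsv(recs, path)
    back = read_alignments_tsv(path)
    assert [(r.query_id, r.read_number, r.ref_start, r.strand, r.cigar, r.mapq)
            for r in back] == [
        ("a", 1, 10, "+", "50M", 60),
        ("a", 2, 400, "-", "20M5D30M", 60),
    ]


# ---------------------------------------------------------------------------
# flanks and junction enumeration
# ---------------------------------------------------------------------------


def test_enumerate_junctions_count():
    _, limps = two_limp_genome()
    juncs = enumerate_junctions(limps)
    assert len(juncs) == 2 * len(limps) ** 2
    assert len(set(juncs)) == len(juncs)
    assert sum(1 for j in juncs if j.is_diagonal) == len(limps)
    with pytest.raises(ValueError):
        enumerate_junctions([])


def test_junction_labels():
    assert JunctionClass(3, "direct", 7).label() == "L3xR7"
    assert JunctionClass(3, "revcomp", 7).label() == "Lrev3xR7"
    assert JunctionClass(4, "direct", 4).is_diagonal
    assert not JunctionClass(4, "revcomp", 4).is_diagonal


def test_extract_flanks_truncation():
    genome, limps = two_limp_genome()
    flanks = extract_flanks(genome, limps, max_len=400)
    by_key = {(f.limp_id, f.side): f for f in flanks}
    lf1 = by_key[(1, "left")]
    # left of LIMP 1: the gap back to LIMP 2's end (1527) crossing the
    # origin is 973 nt, so the 400-nt cap applies
    assert lf1.interval.length(genome.length) == 400
    assert lf1.interval.end == 500
    rf1 = by_key[(1, "right")]
    assert rf1.interval.start == 528
    assert rf1.interval.length(genome.length) == 400


def test_extract_flanks_neighbor_limited():
    # two LIMPs 100 nt apart: the shared interval is 100 nt on each side
    rng = np.random.default_rng(5)
    arr = rng.choice(list("ACGT"), size=1000)
    core = limp_sequence(2, "+", 2)
    for start0 in (200, 327):  # gap of exactly 100
        for k, ch in enumerate(core):
            arr[start0 + k] = ch
    genome = CircularSequence("t", "".join(arr))
    limps = detect_limps(genome)
    assert len(limps) == 2
    flanks = {(f.limp_id, f.side): f for f in extract_flanks(genome, limps)}
    assert flanks[(1, "right")].interval.length(1000) == 100
    assert flanks[(2, "left")].interval.length(1000) == 100


# ---------------------------------------------------------------------------
# joint support counting
# ---------------------------------------------------------------------------


def _pair(qid, p1, s1, p2, s2, rl=50):
    return [
        AlignmentRecord(qid, 1, p1, s1, f"{rl}M", 60),
        AlignmentRecord(qid, 2, p2, s2, f"{rl}M", 60),
    ]


def _count(genome, limps, alignments, **kw):
    return count_joint_support(
        alignments,
        enumerate_junctions(limps),
        extract_flanks(genome, limps),
        genome.length,
        limps,
        **kw,
    )


def test_diagonal_pair_counted():
    genome, limps = two_limp_genome()
    # straddles LIMP 1: left mate + ending at 500, right mate - in right flank
    aln = _pair("p", 451, "+", 540, "-")
    mat = _count(genome, limps, aln)
    assert mat.counts[JunctionClass(1, "direct", 1)] == 1
    assert mat.total() == 1


def test_direct_offdiagonal_pair():
    genome, limps = two_limp_genome()
    # left flank of 1, right flank of 2: plus/minus with small spans
    aln = _pair("p", 451, "+", 1540, "-")
    mat = _count(genome, limps, aln)
    assert mat.counts[JunctionClass(1, "direct", 2)] == 1


def test_revcomp_pair_orientation():
    genome, limps = two_limp_genome()
    # reverse-complement junction: both mates on minus strand; the
    # left-flank mate sits near the flank START (its sequence is read
    # from the junction backwards on the recombinant molecule)
    aln = _pair("p", 110, "-", 1540, "-")
    mat = _count(genome, limps, aln)
    assert mat.counts[JunctionClass(1, "revcomp", 2)] == 1


def test_wrong_orientation_not_counted():
    genome, limps = two_limp_genome()
    aln = _pair("p", 451, "-", 1540, "+")
    assert _count(genome, limps, aln).total() == 0


def test_implied_insert_cap():
    genome, limps = two_limp_genome()
    # spans imply a junction-molecule insert > 600: rejected
    aln = _pair("p", 110, "+", 1840, "-")
    assert _count(genome, limps, aln).total() == 0
    assert _count(genome, limps, aln, max_implied_insert=2000).total() == 1


def test_clipped_pairs_rejected():
    genome, limps = two_limp_genome()
    aln = _pair("p", 451, "+", 540, "-")
    aln[0] = AlignmentRecord("p", 1, 451, "+", "40M10S", 60)
    assert _count(genome, limps, aln).total() == 0


def test_low_mapq_rejected():
    genome, limps = two_limp_genome()
    aln = _pair("p", 451, "+", 540, "-")
    aln[1] = AlignmentRecord("p", 2, 540, "-", "50M", 0)
    assert _count(genome, limps, aln).total() == 0


def test_mate_not_wholly_inside_flank():
    genome, limps = two_limp_genome()
    # left mate overlaps the LIMP itself (ends at 510): not contained
    aln = _pair("p", 461, "+", 540, "-")
    assert _count(genome, limps, aln).total() == 0


def test_matrix_views():
    genome, limps = two_limp_genome()
    mat = _count(genome, limps, _pair("p", 451, "+", 540, "-"))
    df = mat.to_dataframe()
    assert df.loc["L1", "R1"] == 1
    assert df.shape == (4, 2)
    logdf = mat.to_dataframe(log=True)
    assert logdf.loc["L1", "R1"] == 0.0  # log10(1)
    assert logdf.loc["L2", "R2"] == -1.0  # empty-cell sentinel
    assert mat.off_diagonal_nonzero() == []


# ---------------------------------------------------------------------------
# unit variants
# ---------------------------------------------------------------------------


def unit_genome():
    core = limp_sequence(4, "+", 4)  # start 101: A-run 101-120, T 128-147
    genome = CircularSequence("t", "G" * 100 + core + "G" * 100)
    limp = detect_limps(genome)[0]
    return genome, limp


def test_unit_variant_deletion_and_insertion():
    genome, limp = unit_genome()
    alns = [
        AlignmentRecord("d", 1, 95, "+", "11M5D34M", 60),  # -1 A-unit
        AlignmentRecord("i", 1, 120, "+", "15M5I30M", 60),  # +1 T-unit
        AlignmentRecord("n", 1, 95, "+", "50M", 60),  # no indel
        AlignmentRecord("x", 1, 95, "+", "11M3D36M", 60),  # not unit-sized
    ]
    assert count_unit_variants(alns, limp, genome) == (1, 1)


def test_unit_variant_double_unit():
    genome, limp = unit_genome()
    alns = [AlignmentRecord("d", 1, 95, "+", "11M10D29M", 60)]
    assert count_unit_variants(alns, limp, genome) == (1, 0)


def test_unit_variant_softclip_reanchor():
    genome, limp = unit_genome()
    # clipped tail of exact A-units at the run boundary: counted as +units
    seq = genome.fetch(80, 35) + "AACCA"
    rec = AlignmentRecord("s", 1, 80, "+", "35M5S", 60, sequence=seq)
    assert count_unit_variants([rec], limp, genome) == (1, 0)
    # clipped tail of non-unit sequence: not counted
    seq2 = genome.fetch(80, 35) + "TTTTT"
    rec2 = AlignmentRecord("s", 1, 80, "+", "35M5S", 60, sequence=seq2)
    assert count_unit_variants([rec2], limp, genome) == (0, 0)


def test_unit_variant_outside_run_ignored():
    genome, limp = unit_genome()
    alns = [AlignmentRecord("d", 1, 10, "+", "11M5D34M", 60)]
    assert count_unit_variants(alns, limp, genome) == (0, 0)


# ---------------------------------------------------------------------------
# deletions between direct repeats
# ---------------------------------------------------------------------------


def deletion_genome():
    rng = np.random.default_rng(21)
    arr = rng.choice(list("ACGT"), size=1200)
    repeat = list("ACGTACGTAC")  # 10 nt
    arr[300:310] = repeat
    arr[400:410] = repeat  # deletion of 100 removes 310..409 (1-based 311-410)
    arr[310] = "T" if arr[410] != "T" else "G"
    arr[410] = "C" if arr[310] == "T" else "T"
    genome = CircularSequence("t", "".join(arr))
    return genome


def test_deletion_left_normalization_and_repeat_length():
    genome = deletion_genome()
    # three reads carrying the same deletion placed at different offsets
    # within the direct repeat (all sequence-equivalent placements)
    alns = [
        AlignmentRecord("a", 1, 280, "+", "31M100D19M", 60),  # del at 311
        AlignmentRecord("b", 1, 280, "+", "28M100D22M", 60),  # del at 308
        AlignmentRecord("c", 1, 280, "+", "24M100D26M", 60),  # del at 304
    ]
    events = detect_deletions(alns, genome, min_support=3)
    assert len(events) == 1
    pos, dlen, rlen = events[0]
    assert dlen == 100
    assert rlen == 10
    assert genome.fetch(pos, 10) == genome.fetch(pos + 100, 10)


def test_deletion_support_threshold():
    genome = deletion_genome()
    alns = [AlignmentRecord("a", 1, 280, "+", "31M100D19M", 60)] * 2
    assert detect_deletions(alns, genome, min_support=3) == []


def test_deletion_short_repeat_suppressed():
    genome = deletion_genome()
    alns = [AlignmentRecord("a", 1, 280, "+", "31M100D19M", 60)] * 3
    assert detect_deletions(alns, genome, min_repeat=11) == []


# ---------------------------------------------------------------------------
# inter-LIMP coverage
# ---------------------------------------------------------------------------


def test_interlimp_coverage_constant_track():
    genome, limps = two_limp_genome()
    track = np.full(genome.length, 7)
    regions = interlimp_coverage(track, limps)
    assert len(regions) == len(limps)
    for _, mean, sd in regions:
        assert mean == 7.0
        assert sd == 0.0


def test_interlimp_coverage_regions_partition():
    genome, limps = two_limp_genome()
    track = np.arange(genome.length)
    regions = interlimp_coverage(track, limps)
    total = sum(r.total_length for r in limps)
    # the two inter-LIMP regions plus the LIMPs tile the circle
    n1 = (1501 - 1) - (501 + 27 - 1)  # between LIMP1 end and LIMP2 start
    n2 = genome.length - total - n1
    assert n1 + n2 + total == genome.length
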
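"""Synthetic genomes, genomic read pairs and RNA-Seq coverage with the
structures the analysis assumes.

The generator is first-class, tested code: every feature class the
detectors look for (LIMPs, remnants, HyLIMPs, tandem arrays, repeat
families, deletion-prone direct repeats, recombination junctions,
unit-number variants, processing-site coverage drops) can be planted at
known positions, and ground truth is returned alongside the sequence.

``published_genome`` builds a synthetic reconstruction of the published
mitochondrial chromosome: 69,997 bp at 36% G+C with the 19 published
LIMP structures at their published anchors, the degenerate flanking
units, the 21-bp palindromic extension of LIMP #10, the HyLIMP family,
the GAGGGCTAC tandem array, the three deletion-prone direct repeats and
the divergent promoter motifs.  Background sequence is i.i.d. random,
so coordinates and planted structures are faithful while intergenic
sequence is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import CircularSequence, reverse_complement
from .detect import LimpRecord, limp_sequence, limp_metrics
from .rearrange import AlignmentRecord, JunctionClass
from .expression import CoverageTrack
from . import reference as ref

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: margin kept free around planted features (nt)
PLANT_MARGIN = 12


# ---------------------------------------------------------------------------
# genome specification
# ---------------------------------------------------------------------------


@dataclass
class LimpSpec:
    m: int
    loop: str
    n: int
    start: int | None = None  # 1-based position of the first A-unit
    left_context: str = ""  # e.g. degenerate units, planted verbatim
    right_context: str = ""
    extension: int = 0  # perfect palindromic extension per side


@dataclass
class HyLimpSpec:
    left_units: int
    right_units: int
    loop: str = "TTT"
    start: int | None = None


@dataclass
class DeletionSpec:
    """A deletion-prone locus: two direct repeats of ``repeat_length``
    separated so that recombination deletes ``length`` nt."""

    length: int
    repeat_length: int
    start: int | None = None  # position of the first repeat copy


@dataclass
class GenomeSpec:
    length: int = 20_000
    gc: float = 0.36
    limps: list = field(default_factory=list)
    hylimps: list = field(default_factory=list)
    remnants: list = field(default_factory=list)  # fragment strings or (frag, pos)
    tandem_arrays: list = field(default_factory=list)  # (unit, copies[, pos])
    repeat_family_plants: list = field(default_factory=list)  # (name, seq[, pos])
    motifs: list = field(default_factory=list)  # (motif, pos, strand)
    deletions: list = field(default_factory=list)
    shared_flank_groups: list = field(default_factory=list)
    # each group: (donor_limp_idx, donor_side, acceptor_limp_idx,
    #              acceptor_side, length, revcomp: bool)
    seed: int = 0


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    return rng.choice(_BASES, size=n, p=[p_at, p_gc, p_gc, p_at])


class _Placer:
    def __init__(self, length: int, rng: np.random.Generator):
        self.length = length
        self.rng = rng
        self.occupied: list[tuple[int, int]] = []  # 0-based [start, end)

    def _clashes(self, s: int, ln: int) -> bool:
        a0, a1 = s - PLANT_MARGIN, s + ln + PLANT_MARGIN
        for b0, b1 in self.occupied:
            if a0 < b1 and b0 < a1:
                return True
        return False

    def place(self, ln: int, start: int | None) -> int:
        """Reserve ``ln`` bases; returns the 0-based start."""
        if start is not None:
            s = start - 1
            if s < 0 or s + ln > self.length:
                raise ValueError("feature outside genome")
            if self._clashes(s, ln):
                raise ValueError(f"feature at {start} overlaps a planted feature")
            self.occupied.append((s, s + ln))
            return s
        for _ in range(2000):
            s = int(self.rng.integers(0, self.length - ln))
            if not self._clashes(s, ln):
                self.occupied.append((s, s + ln))
                return s
        raise ValueError("could not place feature without overlap")


def generate_genome(spec: GenomeSpec) -> tuple[CircularSequence, dict]:
    """Build a circular genome with every planted feature, plus ground
    truth.  Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    arr = _rand_seq(rng, spec.length, spec.gc)
    placer = _Placer(spec.length, rng)
    truth: dict = {
        "limps": [],
        "hylimps": [],
        "remnants": [],
        "tandem_arrays": [],
        "repeat_families": [],
        "motifs": [],
        "deletions": [],
    }

    def write(s0: int, text: str) -> None:
        for k, ch in enumerate(text):
            arr[(s0 + k) % spec.length] = ch

    # --- LIMPs -----------------------------------------------------------
    ext_store = {}
    for li, lspec in enumerate(spec.limps):
        core = limp_sequence(lspec.m, lspec.loop, lspec.n)
        ext = ""
        if lspec.extension:
            ext = "".join(_rand_seq(rng, lspec.extension, spec.gc))
        block = ext + core + reverse_complement(ext)
        full = lspec.left_context + block + lspec.right_context
        if lspec.start is not None:
            plant_start = lspec.start - 1 - len(lspec.left_context) - len(ext)
        else:
            plant_start = None
        s0 = placer.place(len(full), None if plant_start is None else plant_start + 1)
        write(s0, full)
        core_start0 = s0 + len(lspec.left_context) + len(ext)
        start = core_start0 % spec.length + 1
        total, stem = limp_metrics(lspec.m, lspec.loop, lspec.n)
        truth["limps"].append(
            {
                "limp_id": li + 1,
                "m": lspec.m,
                "loop": lspec.loop,
                "n": lspec.n,
                "start": start,
                "anchor": (start + 5 * lspec.m + 7 - 1) % spec.length + 1,
                "total_length": total,
                "stem_length": stem,
                "extension": lspec.extension,
            }
        )
        ext_store[li] = (s0, len(full), lspec)

    # --- HyLIMPs ---------------------------------------------------------
    for hspec in spec.hylimps:
        left = ref.HYLIMP_UNIT * hspec.left_units + "GAGCC"
        right = "GGCTC" + reverse_complement(ref.HYLIMP_UNIT) * hspec.right_units
        full = left + hspec.loop + right
        s0 = placer.place(len(full), hspec.start)
        write(s0, full)
        truth["hylimps"].append(
            {
                "start": s0 + 1,
                "left_units": hspec.left_units,
                "right_units": hspec.right_units,
                "loop_length": len(hspec.loop),
                "arm_length": min(len(left), len(right)),
            }
        )

    # --- remnants --------------------------------------------------------
    for item in spec.remnants:
        frag, pos = item if isinstance(item, tuple) else (item, None)
        s0 = placer.place(len(frag), pos)
        write(s0, frag)
        truth["remnants"].append({"start": s0 + 1, "fragment": frag})

    # --- tandem arrays ---------------------------------------------------
    for item in spec.tandem_arrays:
        unit, copies = item[0], item[1]
        pos = item[2] if len(item) > 2 else None
        s0 = placer.place(len(unit) * copies, pos)
        write(s0, unit * copies)
        truth["tandem_arrays"].append(
            {"start": s0 + 1, "unit": unit, "copies": copies}
        )

    # --- repeat-family copies -------------------------------------------
    for item in spec.repeat_family_plants:
        name, cons = item[0], item[1]
        pos = item[2] if len(item) > 2 else None
        s0 = placer.place(len(cons), pos)
        write(s0, cons)
        truth["repeat_families"].append({"name": name, "start": s0 + 1})

    # --- motifs ----------------------------------------------------------
    for motif, pos, strand in spec.motifs:
        text = motif if strand == "+" else reverse_complement(motif)
        s0 = placer.place(len(text), pos)
        write(s0, text)
        truth["motifs"].append({"motif": motif, "start": s0 + 1, "strand": strand})

    # --- deletion-prone direct repeats ----------------------------------
    for dspec in spec.deletions:
        span = dspec.length + dspec.repeat_length
        s0 = placer.place(span + 2, dspec.start)
        repeat = "".join(_rand_seq(rng, dspec.repeat_length, spec.gc))
        write(s0, repeat)
        write(s0 + dspec.length, repeat)
        # pin the bases just past each copy so the measured repeat length
        # and the left-normalized placement are exact
        after1 = arr[(s0 + dspec.repeat_length) % spec.length]
        after2 = [b for b in "ACGT" if b != after1]
        write(s0 + dspec.length + dspec.repeat_length, after2[0])
        before2 = arr[(s0 - 1) % spec.length]
        alt = [b for b in "ACGT" if b != before2]
        write(s0 + dspec.length - 1, alt[0])
        truth["deletions"].append(
            {
                "start": s0 + 1,
                "length": dspec.length,
                "repeat_length": dspec.repeat_length,
            }
        )

    # --- shared flanks ---------------------------------------------------
    for donor, dside, acceptor, aside, ln, rc in spec.shared_flank_groups:
        d = truth["limps"][donor]
        a = truth["limps"][acceptor]
        if dside == "left":
            src0 = (d["start"] - 1 - ln) % spec.length
        else:
            src0 = (d["start"] - 1 + d["total_length"]) % spec.length
        text = "".join(arr[(src0 + k) % spec.length] for k in range(ln))
        if rc:
            text = reverse_complement(text)
        if aside == "left":
            dst0 = (a["start"] - 1 - ln) % spec.length
        else:
            dst0 = (a["start"] - 1 + a["total_length"]) % spec.length
        write(dst0, text)

    # --- guards around LIMPs --------------------------------------------
    # keep unit counts and palindromic extensions exactly as specified:
    # no stray perfect unit or complementary base just outside a plant
    for li, (s0, full_len, lspec) in ext_store.items():
        left_edge = s0  # first base of the plant (context or extension)
        right_edge = s0 + full_len  # first base after the plant
        # no accidental A-unit immediately left of the first planted base
        frag = "".join(arr[(left_edge - 5 + k) % spec.length] for k in range(5))
        if frag == ref.A_UNIT:
            write(left_edge - 5, "C")
        frag = "".join(arr[(right_edge + k) % spec.length] for k in range(5))
        if frag == ref.T_UNIT:
            write(right_edge + 4, "C")
        # break palindromic extension beyond the specified one
        lb = arr[(left_edge - 1) % spec.length]
        rb = arr[right_edge % spec.length]
        if _COMP[lb] == rb:
            write(right_edge, "G" if rb != "G" else "C")

    genome = CircularSequence("synthetic", "".join(arr), is_circular=True)
    return genome, truth


def truth_limp_records(truth: dict) -> list[LimpRecord]:
    """LimpRecord objects for the planted LIMPs (ground truth view)."""
    out = []
    for t in truth["limps"]:
        out.append(
            LimpRecord(
                m=t["m"],
                loop_orientation=t["loop"],
                n=t["n"],
                start=t["start"],
                anchor=t["anchor"],
                total_length=t["total_length"],
                stem_length=t["stem_length"],
                limp_id=t["limp_id"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# the published-genome reconstruction
# ---------------------------------------------------------------------------

#: fixed 21-nt flank used for LIMP #10's palindromic extension (synthetic
#: stand-in; the published extension sequence is not reproduced here)
LIMP10_EXTENSION = "TAATGCATAAAGTATCCAATG"

PUBLISHED_SEED = 20_150_805


def published_spec(seed: int = PUBLISHED_SEED) -> GenomeSpec:
    """Genome specification reproducing the published LIMP structures."""
    limps = []
    for row in ref.LIMP_TABLE:
        start = row.anchor - 5 * row.m - 7
        if start < 1:
            start += ref.GENOME_LENGTH
        lspec = LimpSpec(m=row.m, loop=row.loop, n=row.n, start=start)
        lspec.left_context = ref.DEGENERATE_LEFT_FLANKS.get(row.limp_id, "")
        lspec.right_context = ref.DEGENERATE_RIGHT_FLANKS.get(row.limp_id, "")
        if row.limp_id == 10:
            lspec.extension = 21
        elif row.limp_id in (5, 8, 9, 15):
            # printed palindromic region is 4 nt over the repeat length:
            # a 2-bp perfect extension into the degenerate left units,
            # mirrored by a planted TG..break on the right
            lspec.right_context = "TGA"
        limps.append(lspec)
    hylimps = [
        HyLimpSpec(3, 5, "TTT", 34_000),  # the long, interrupting copy
        HyLimpSpec(2, 2, "TTT", 35_000),
        HyLimpSpec(2, 3, "TTTCATT", 36_000),  # loop shared with the LIMPs
        HyLimpSpec(3, 2, "TTT", 37_000),
        HyLimpSpec(2, 2, "TTTT", 38_000),
    ]
    remnants = [
        ("AACCAAATGAAAT", 19_000),
        ("ACCAAATGAAATGGT", 19_500),
        ("CATTTCATTTGGTT", 20_000),
        ("AACCATTTCATTT", 20_500),
        ("CAAATGAAATGGTTG", 21_000),
        ("CCATTTCATTTGG", 21_500),
    ]
    spec = GenomeSpec(
        length=ref.GENOME_LENGTH,
        gc=ref.GENOME_GC,
        limps=limps,
        hylimps=hylimps,
        remnants=remnants,
        tandem_arrays=[(ref.TANDEM_UNIT, ref.TANDEM_COPIES, 40_000)],
        repeat_family_plants=[
            (name, seq, 41_000 + 200 * k)
            for k, (name, seq) in enumerate(ref.REPEAT_FAMILIES)
        ],
        motifs=[(m, p, s) for m, p, s in ref.PROMOTER_MOTIFS],
        deletions=[
            DeletionSpec(173, 9, 45_000),
            DeletionSpec(110, 12, 46_000),
            DeletionSpec(57, 11, 47_000),
        ],
        seed=seed,
    )
    return spec


def published_genome(seed: int = PUBLISHED_SEED) -> tuple[CircularSequence, dict]:
    """Synthetic reconstruction of the 69,997-bp chromosome (see module
    docstring); planted features match the published table."""
    return generate_genome(published_spec(seed))


# ---------------------------------------------------------------------------
# genomic read-pair simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadSimConfig:
    depth: float = 50.0
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    #: junction -> fraction of molecules carrying that recombination
    recombinant_fractions: dict = field(default_factory=dict)
    #: limp_id -> fraction of molecules with a +/-1 unit change there
    unit_indel_rates: dict = field(default_factory=dict)
    #: deletion index (into truth['deletions']) -> molecule fraction
    deletion_fractions: dict = field(default_factory=dict)
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        for v in (
            list(self.recombinant_fractions.values())
            + list(self.unit_indel_rates.values())
            + list(self.deletion_fractions.values())
            + [self.error_rate]
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


class _Molecule:
    """A molecule as reference segments.  Each segment is
    (mol_start0, ref_start0 or None, length); ref None marks inserted
    bases.  All segments are plus-strand."""

    def __init__(self, name, seq: str, segments, circular: bool):
        self.name = name
        self.seq = seq
        self.segments = segments
        self.circular = circular
        self.length = len(seq)


def _reference_molecule(genome: CircularSequence) -> _Molecule:
    return _Molecule("ref", genome.residues, [(0, 0, genome.length)], True)


def _arc_deleted_molecule(genome, name, del_start0, del_len) -> _Molecule:
    """Circle with [del_start0, del_start0+del_len) removed (0-based,
    may wrap)."""
    L = genome.length
    keep = L - del_len
    start_keep = (del_start0 + del_len) % L
    seq = genome.fetch(start_keep + 1, keep)
    segments = []
    pos = start_keep
    off = 0
    while off < keep:
        run = min(L - pos, keep - off)
        segments.append((off, pos, run))
        off += run
        pos = 0
    return _Molecule(name, seq, segments, True)


def _unit_variant_molecule(genome, name, limp: dict, side: str, change: int) -> _Molecule:
    """Circle with ``change`` (+1/-1) repeat units added or removed from
    one branch of a LIMP."""
    L = genome.length
    start0 = limp["start"] - 1
    if side == "A":
        point0 = start0 + 5  # inside the A run, one unit in
        unit = ref.A_UNIT
    else:
        point0 = start0 + 5 * limp["m"] + 7 + 5
        unit = ref.T_UNIT
    if change == -1:
        mol = _arc_deleted_molecule(genome, name, point0, 5)
        return mol
    before = genome.fetch(1, point0)
    after = genome.residues[point0:]
    seq = before + unit + after
    segments = [(0, 0, point0), (point0, None, 5), (point0 + 5, point0, L - point0)]
    return _Molecule(name, seq, segments, True)


def _junction_molecule(genome, name, jc: JunctionClass, limps: list[dict]) -> _Molecule:
    """Direct recombinant circle joining LIMP ``left_id``'s upstream arc
    to LIMP ``right_id``'s downstream arc (the arc in between, from the
    end of the left LIMP through the end of the right LIMP, is lost)."""
    if jc.left_orientation != "direct":
        raise NotImplementedError("only direct junction molecules are simulated")
    by_id = {t["limp_id"]: t for t in limps}
    li, rj = by_id[jc.left_id], by_id[jc.right_id]
    L = genome.length
    del_start0 = (li["start"] - 1 + li["total_length"]) % L
    del_end0 = (rj["start"] - 1 + rj["total_length"]) % L  # exclusive
    del_len = (del_end0 - del_start0) % L
    if del_len == 0:
        return _reference_molecule(genome)
    return _arc_deleted_molecule(genome, name, del_start0, del_len)


def _cigar_for_window(mol: _Molecule, a: int, rl: int, genome_length: int):
    """Alignment of molecule window [a, a+rl) to the reference: returns
    (ref_start_1based, cigar) or None if unalignable.  Reference gaps up
    to 1 kb become D runs; larger discontinuities soft-clip the shorter
    side; inserted bases give I (or S at the read edge)."""
    chunks = []  # (ref_start0 or None, length)
    off = 0
    while off < rl:
        m = (a + off) % mol.length if mol.circular else a + off
        if m >= mol.length:
            return None
        for ms, rs, ln in mol.segments:
            if ms <= m < ms + ln:
                take = min(ln - (m - ms), rl - off)
                rstart = None if rs is None else rs + (m - ms)
                chunks.append((rstart, take))
                off += take
                break
        else:
            return None
    # merge reference-contiguous chunks, insert D for small gaps
    merged = [list(chunks[0])]
    for rstart, ln in chunks[1:]:
        prev = merged[-1]
        if rstart is not None and prev[0] is not None:
            gap = rstart - (prev[0] + prev[1])
            gap %= genome_length
            if gap == 0:
                prev[1] += ln
                continue
            if 0 < gap <= 1000:
                merged.append(["D", gap])
                merged.append([rstart, ln])
                continue
            merged.append(["BREAK", 0])
        merged.append([rstart, ln])
    # split at BREAK: keep the longest aligned block, soft-clip the rest
    blocks, cur = [], []
    for item in merged:
        if item[0] == "BREAK":
            blocks.append(cur)
            cur = []
        else:
            cur.append(item)
    blocks.append(cur)
    best = max(
        blocks,
        key=lambda b: sum(ln for r, ln in b if r not in (None, "D")),
    )
    left_clip = 0
    for b in blocks:
        if b is best:
            break
        left_clip += sum(ln for r, ln in b if r != "D")
    right_clip = rl - left_clip - sum(ln for r, ln in best if r != "D")
    # trim edge insertions into the clips
    while best and best[0][0] is None:
        left_clip += best.pop(0)[1]
    while best and best[-1][0] is None:
        right_clip += best.pop()[1]
    while best and best[0][0] == "D":
        best.pop(0)
    while best and best[-1][0] == "D":
        best.pop()
    if not best:
        return None
    ops = []
    if left_clip:
        ops.append(f"{left_clip}S")
    for rstart, ln in best:
        if rstart == "D":
            ops.append(f"{ln}D")
        elif rstart is None:
            ops.append(f"{ln}I")
        else:
            ops.append(f"{ln}M")
    if right_clip:
        ops.append(f"{right_clip}S")
    # consecutive M runs merge
    cigar = "".join(ops)
    ref_start0 = best[0][0]
    return ref_start0 % genome_length + 1, cigar


def simulate_genomic_read_pairs(
    genome: CircularSequence, truth: dict, config: ReadSimConfig
):
    """Paired-end reads from a molecule population: the reference circle
    plus configured recombinant, deleted and unit-variant circles.

    Returns (pairs, alignments): ``pairs`` is a list of
    (name, read1, read2) tuples and ``alignments`` the true
    AlignmentRecords (read 1 forward, read 2 reverse, FR layout).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    L = genome.length
    if config.insert_mean >= L:
        raise ValueError("insert larger than genome")
    molecules = [(_reference_molecule(genome), 0.0)]  # weight filled below
    w_other = 0.0
    for jc, f in config.recombinant_fractions.items():
        molecules.append((_junction_molecule(genome, jc.label(), jc, truth["limps"]), f))
        w_other += f
    for di, f in config.deletion_fractions.items():
        d = truth["deletions"][di]
        molecules.append(
            (_arc_deleted_molecule(genome, f"del{di}", d["start"] - 1, d["length"]), f)
        )
        w_other += f
    for lid, rate in config.unit_indel_rates.items():
        limp = next(t for t in truth["limps"] if t["limp_id"] == lid)
        for side in ("A", "T"):
            for change in (+1, -1):
                molecules.append(
                    (
                        _unit_variant_molecule(
                            genome, f"uv{lid}{side}{change:+d}", limp, side, change
                        ),
                        rate / 4.0,
                    )
                )
        w_other += rate
    if w_other >= 1.0:
        raise ValueError("variant molecule fractions sum to >= 1")
    molecules[0] = (molecules[0][0], 1.0 - w_other)

    n_frag = max(1, int(round(config.depth * L / (2 * rl))))
    weights = np.array([w for _, w in molecules])
    weights = weights / weights.sum()
    choices = rng.choice(len(molecules), size=n_frag, p=weights)
    inserts = np.clip(
        rng.normal(config.insert_mean, config.insert_sd, size=n_frag).round(),
        2 * rl,
        None,
    ).astype(int)

    pairs, alignments = [], []
    for k in range(n_frag):
        mol = molecules[choices[k]][0]
        ins = int(inserts[k])
        if ins >= mol.length:
            ins = mol.length - 1
        if mol.circular:
            a = int(rng.integers(0, mol.length))
        else:
            a = int(rng.integers(0, mol.length - ins + 1))
        frag = (
            mol.seq[a : a + ins]
            if a + ins <= mol.length
            else mol.seq[a:] + mol.seq[: (a + ins) % mol.length]
        )
        r1 = frag[:rl]
        r2 = reverse_complement(frag[-rl:])
        name = f"frag{k}"
        # sequencing errors
        r1, r2 = _with_errors(rng, r1, config.error_rate), _with_errors(
            rng, r2, config.error_rate
        )
        pairs.append((name, r1, r2))
        aln1 = _cigar_for_window(mol, a, rl, L)
        aln2 = _cigar_for_window(mol, a + ins - rl, rl, L)
        if aln1:
            alignments.append(
                AlignmentRecord(name, 1, aln1[0], "+", aln1[1], 60, r1)
            )
        if aln2:
            alignments.append(
                AlignmentRecord(
                    name, 2, aln2[0], "-", aln2[1], 60, reverse_complement(r2)
                )
            )
    return pairs, alignments


def _with_errors(rng, read: str, rate: float) -> str:
    if rate <= 0:
        return read
    n_err = rng.binomial(len(read), rate)
    if n_err == 0:
        return read
    arr = list(read)
    for pos in rng.choice(len(read), size=n_err, replace=False):
        arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
    return "".join(arr)


# ---------------------------------------------------------------------------
# RNA-Seq coverage simulation
# ---------------------------------------------------------------------------


def simulate_rnaseq_coverage(
    genome: CircularSequence,
    truth: dict,
    promoters: tuple[int, int],
    cleavage_stem_min: int = 26,
    depth: float = 100.0,
    seed: int = 0,
    ramp: int = 100,
) -> CoverageTrack:
    """Coverage from two divergent polycistronic transcription units.

    The minus-strand unit runs leftward from ``promoters[0]``, the
    plus-strand unit rightward from ``promoters[1]``; together they tile
    the circle, meeting opposite the promoter region.  Expected depth
    ramps from 0 over ``ramp`` nt downstream of each promoter, is ~0
    between the promoters, and collapses to ~1 read over the footprint
    of every LIMP whose stem is at least ``cleavage_stem_min`` bp
    (processing-site model; the default reflects the observed dichotomy
    that stems longer than 25 bp are always processing sites while stems
    under 20 bp never are).  Poisson noise is applied per position.
    """
    rng = np.random.default_rng(seed)
    L = genome.length
    p_minus, p_plus = promoters
    expected = np.full(L, depth, dtype=float)
    gap = (p_plus - p_minus - 1) % L
    for k in range(gap):
        expected[(p_minus + k) % L] = 0.05
    for k in range(ramp):
        frac = (k + 1) / ramp
        expected[(p_plus - 1 + k) % L] = min(
            expected[(p_plus - 1 + k) % L], depth * frac
        )
        expected[(p_minus - 1 - k) % L] = min(
            expected[(p_minus - 1 - k) % L], depth * frac
        )
    for t in truth["limps"]:
        if t["stem_length"] >= cleavage_stem_min:
            for k in range(t["total_length"]):
                expected[(t["start"] - 1 + k) % L] = 1.0
    return CoverageTrack(rng.poisson(expected))


# ---------------------------------------------------------------------------
# FASTQ / SAM output
# ---------------------------------------------------------------------------


def write_fastq(pairs, prefix: str) -> None:
    with open(f"{prefix}_1.fastq", "w") as f1, open(f"{prefix}_2.fastq", "w") as f2:
        for name, r1, r2 in pairs:
            f1.write(f"@{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def write_sam(alignments, genome: CircularSequence, path: str) -> None:
    """True alignments as SAM.  Origin-wrapping records are skipped (SAM
    cannot represent them); mate fields are filled pairwise."""
    by_name: dict[str, dict[int, AlignmentRecord]] = {}
    for rec in alignments:
        by_name.setdefault(rec.query_id, {})[rec.read_number] = rec
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{genome.identifier}\tLN:{genome.length}\n")
        for name, mates in by_name.items():
            if any(r.ref_end > genome.length for r in mates.values()):
                continue
            for rno, rec in sorted(mates.items()):
                mate = mates.get(2 if rno == 1 else 1)
                flag = 0x1 | 0x2
                flag |= 0x40 if rno == 1 else 0x80
                if rec.strand == "-":
                    flag |= 0x10
                if mate is not None and mate.strand == "-":
                    flag |= 0x20
                seq = rec.sequence or "*"
                qual = "I" * len(seq) if seq != "*" else "*"
                pnext = mate.ref_start if mate is not None else 0
                fh.write(
                    f"{name}\t{flag}\t{genome.identifier}\t{rec.ref_start}\t"
                    f"{rec.mapq}\t{rec.cigar}\t=\t{pnext}\t0\t{seq}\t{qual}\n"
                )
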
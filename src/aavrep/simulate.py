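"""Truth-labeled simulation of AAV replication-intermediate molecules.

Generates the seven structural classes of double-stranded intermediates seen
in long-read data of AAV-infected cells:

1. monomer                      - one full genome unit
2. duplex                       - two units fold-back joined at one genome end
3. head-to-tail (HT) repeats    - same-strand units joined by TRT (D-ITR-D)
                                  junctions, one shared ITR orientation
4. alternating repeats          - strand-alternating units joined at genome
                                  ends, ITR orientations independent
5. HT and alternating repeats   - both junction types in one molecule
6. ITR repeats                  - tandem arrays of ITR(+D) copies, no body
7. others                       - snap-back genomes and sub-genomic fragments

plus circular substrates with their rolling-circle-amplification (RCA)
products, a decoy "mitochondrial" reference for normalization, and an
error-bearing read model (per-base substitutions, geometric-length indels).

Orientation truth labels record the internal BB'CC' arrangement *as observed
on the molecule's forward strand*, which is what an orientation caller sees:
embedding a flip palindrome on the minus strand makes it read as flop.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .reference import (
    FLIP,
    FLOP,
    AnnotatedGenome,
    _random_dna,
    other_orientation,
    revcomp,
)

__all__ = [
    "MoleculeRecord",
    "SimConfig",
    "make_molecule",
    "make_circular_and_rca",
    "make_decoy_reference",
    "simulate_reads",
    "mutate_sequence",
    "write_reads_fastq",
    "write_molecules_fasta",
    "truth_table",
]

CATEGORY_NAMES = {
    1: "Monomer",
    2: "Duplex",
    3: "Head-to-tail repeats",
    4: "Alternating repeats",
    5: "Head-to-tail and alternating repeats",
    6: "ITR repeats",
    7: "Others",
}

TRT = "TRT"
FOLD_BACK = "fold-back"
NONE = "none"


@dataclass
class MoleculeRecord:
    """One simulated intermediate with construction ground truth."""

    molecule_id: str
    sequence: str
    category_truth: int
    unit_count: int
    unit_strands: tuple[str, ...]
    itr_orientations: tuple[str, ...]
    junction_types: tuple[str, ...]
    topology: str = "linear"
    subkind: str = ""
    cut_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.category_truth == 3:
            assert len(set(self.unit_strands)) == 1
            assert all(j == TRT for j in self.junction_types)
            assert len(set(self.itr_orientations)) == 1
        if self.category_truth == 4:
            for a, b in zip(self.unit_strands, self.unit_strands[1:]):
                assert a != b


@dataclass
class SimConfig:
    """Study conditions for one simulated run.

    ``category_counts`` gives molecules per category 1..7.  Unit counts per
    concatemer are drawn uniformly from the inclusive ranges below; the
    ITR-array copy range is set so that default arrays exceed the 3,000-nt
    hit-sum read-selection threshold.  Error rates are per base.
    """

    category_counts: dict[int, int] = field(
        default_factory=lambda: {k: 50 for k in range(1, 8)})
    concatemer_units: tuple[int, int] = (2, 4)
    alternating_units: tuple[int, int] = (3, 5)
    mixed_units: tuple[int, int] = (3, 5)
    itr_copies: tuple[int, int] = (22, 34)
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    indel_extend: float = 0.3
    mito_decoy_count: int = 0
    mito_len: int = 16500
    decoy_read_len: tuple[int, int] = (1000, 8000)
    rca_rounds: int = 3
    seed: int = 1

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("error rates must lie in [0, 1)")
        if any(v < 0 for v in self.category_counts.values()):
            raise ValueError("category counts must be >= 0")


# ---------------------------------------------------------------------------
# molecule construction


def _rand_orient(rng: np.random.Generator) -> str:
    return FLIP if rng.random() < 0.5 else FLOP


def _unit_seq(genome: AnnotatedGenome, left_obs: str, right_obs: str) -> str:
    """Full genome unit whose observed ITR orientations are (left_obs,
    right_obs) when scanned on the forward strand."""
    d = genome.d_sequence
    left = genome.palindrome(left_obs) + d
    right = revcomp(genome.palindrome(other_orientation(right_obs)) + d)
    return left + genome.body + right


def _trt_seq(genome: AnnotatedGenome, obs: str) -> str:
    """D' + palindrome + D junction block (the double-D TRT, 165 nt by
    default) with observed orientation ``obs``."""
    d = genome.d_sequence
    return revcomp(d) + genome.palindrome(obs) + d


class _Builder:
    """Accumulates sequence blocks while tracking orientation truth."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.orientations: list[str] = []

    def add(self, seq: str, orients: list[str]) -> None:
        self.parts.append(seq)
        self.orientations.extend(orients)

    def add_rc(self, seq: str, orients: list[str]) -> None:
        self.parts.append(revcomp(seq))
        self.orientations.extend(other_orientation(o) for o in reversed(orients))

    def sequence(self) -> str:
        return "".join(self.parts)


def _ht_block(genome: AnnotatedGenome, n_units: int, obs: str) -> tuple[str, list[str]]:
    """Head-to-tail run of ``n_units`` genomes with TRT junctions, all ITRs
    in one observed orientation."""
    d = genome.d_sequence
    parts = [genome.palindrome(obs) + d + genome.body]
    for _ in range(n_units - 1):
        parts.append(_trt_seq(genome, obs) + genome.body)
    parts.append(revcomp(genome.palindrome(other_orientation(obs)) + d))
    return "".join(parts), [obs] * (n_units + 1)


def make_molecule(genome: AnnotatedGenome, category: int, rng=None, *,
                  unit_count: int | None = None, orientation: str | None = None,
                  subkind: str | None = None,
                  molecule_id: str = "mol") -> MoleculeRecord:
    """Construct one truth-labeled molecule of the given category (1..7).

    ``unit_count`` is the number of genome units (category 6: ITR copies);
    concatemer categories require >= 2 (category 5: >= 3, with mixed
    junctions; category 4 strands strictly alternate).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if category not in CATEGORY_NAMES:
        raise ValueError(f"category must be 1..7, got {category}")

    if category == 1:
        a, b = _rand_orient(rng), _rand_orient(rng)
        return MoleculeRecord(molecule_id, _unit_seq(genome, a, b), 1, 1,
                              ("+",), (a, b), ())

    if category == 2:
        n = 2 if unit_count is None else unit_count
        if n != 2:
            raise ValueError("a duplex has exactly 2 units")
        a, b = _rand_orient(rng), _rand_orient(rng)
        u = _unit_seq(genome, a, b)
        bld = _Builder()
        if rng.random() < 0.5:  # fold at the right genome end
            bld.add(u, [a, b])
            bld.add_rc(u, [a, b])
        else:  # fold at the left genome end
            bld.add_rc(u, [a, b])
            bld.add(u, [a, b])
        return MoleculeRecord(molecule_id, bld.sequence(), 2, 2, ("+", "-"),
                              tuple(bld.orientations), (FOLD_BACK,))

    if category == 3:
        n = unit_count if unit_count is not None else int(rng.integers(2, 5))
        if n < 2:
            raise ValueError("head-to-tail concatemers need >= 2 units")
        obs = orientation or _rand_orient(rng)
        seq, orients = _ht_block(genome, n, obs)
        return MoleculeRecord(molecule_id, seq, 3, n, ("+",) * n,
                              tuple(orients), (TRT,) * (n - 1))

    if category == 4:
        n = unit_count if unit_count is not None else int(rng.integers(3, 6))
        if n < 2:
            raise ValueError("alternating concatemers need >= 2 units")
        bld = _Builder()
        strands = []
        for i in range(n):
            a, b = _rand_orient(rng), _rand_orient(rng)
            u = _unit_seq(genome, a, b)
            if i % 2 == 0:
                bld.add(u, [a, b])
                strands.append("+")
            else:
                bld.add_rc(u, [a, b])
                strands.append("-")
        return MoleculeRecord(molecule_id, bld.sequence(), 4, n,
                              tuple(strands), tuple(bld.orientations),
                              (FOLD_BACK,) * (n - 1))

    if category == 5:
        n = unit_count if unit_count is not None else int(rng.integers(3, 6))
        if n < 3:
            raise ValueError("mixed concatemers need >= 3 units")
        # partition units into >=2 same-strand runs, >=1 run of length >=2,
        # so the molecule carries both TRT and fold-back junctions
        while True:
            runs, left = [], n
            while left > 0:
                r = int(rng.integers(1, min(left, 3) + 1))
                runs.append(r)
                left -= r
            if len(runs) >= 2 and any(r >= 2 for r in runs):
                break
        bld = _Builder()
        strands, junctions = [], []
        for ri, run in enumerate(runs):
            obs = _rand_orient(rng)
            if run >= 2:
                seq, orients = _ht_block(genome, run, obs)
            else:
                o2 = _rand_orient(rng)
                seq, orients = _unit_seq(genome, obs, o2), [obs, o2]
            if ri % 2 == 0:
                bld.add(seq, orients)
                strands.extend(["+"] * run)
            else:
                bld.add_rc(seq, orients)
                strands.extend(["-"] * run)
            junctions.extend([TRT] * (run - 1))
            if ri < len(runs) - 1:
                junctions.append(FOLD_BACK)
        return MoleculeRecord(molecule_id, bld.sequence(), 5, n,
                              tuple(strands), tuple(bld.orientations),
                              tuple(junctions))

    if category == 6:
        m = unit_count if unit_count is not None else int(rng.integers(22, 35))
        if m < 2:
            raise ValueError("ITR arrays need >= 2 copies")
        d = genome.d_sequence
        orients = [_rand_orient(rng) for _ in range(m)]
        seq = "".join(genome.palindrome(o) + d for o in orients)
        return MoleculeRecord(molecule_id, seq, 6, m, ("+",) * m,
                              tuple(orients), (NONE,) * (m - 1))

    # category 7: defective shapes
    kind = subkind or ("snapback" if rng.random() < 0.5 else "fragment")
    if kind == "snapback":
        a, b = _rand_orient(rng), _rand_orient(rng)
        u = _unit_seq(genome, a, b)
        cut = int(len(u) * rng.uniform(0.4, 0.6))
        prefix = u[:cut]
        seq = prefix + revcomp(prefix)
        return MoleculeRecord(molecule_id, seq, 7, 2, ("+", "-"),
                              (a, other_orientation(a)), ("fold-internal",),
                              subkind=kind)
    if kind == "fragment":
        body = genome.body
        n = int(rng.integers(3200, min(3900, len(body)) + 1))
        start = int(rng.integers(0, len(body) - n + 1))
        seq = body[start:start + n]
        return MoleculeRecord(molecule_id, seq, 7, 1, ("+",), (), (),
                              subkind=kind)
    raise ValueError(f"unknown category-7 subkind {kind!r}")


# ---------------------------------------------------------------------------
# circular substrates and RCA


def make_circular_and_rca(genome: AnnotatedGenome, units: int, join: str,
                          rca_rounds: int, rng=None, *, enzyme: str | None = None,
                          orientation: str | None = None,
                          molecule_id: str = "rca") -> MoleculeRecord:
    """Build a circular intermediate and return its linear RCA product.

    ``join='HT'`` joins units head-to-tail through TRT junctions (one shared
    ITR orientation); ``join='alternating'`` joins strand-alternating units
    at genome ends and requires an even unit count so the circle closes
    consistently.  The RCA product is ``rca_rounds`` tandem traversals of
    the circle from a random rotation.  If ``enzyme`` is given, the product
    is trimmed to the span between its outermost cut-site occurrences
    (partial-digest emulation), so the read starts and ends at the cut site;
    remaining internal sites are reported in ``cut_positions``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if units < 1:
        raise ValueError("need >= 1 unit")
    if rca_rounds < 1:
        raise ValueError("need >= 1 RCA round")

    d = genome.d_sequence
    body = genome.body
    cut_local: list[int] = []  # cut offsets within one circle traversal
    ilen = genome.spec.itr_len
    if enzyme is not None:
        genome_cuts = genome.cut_offsets(enzyme)

    if join == "HT":
        obs = orientation or _rand_orient(rng)
        block = body + _trt_seq(genome, obs)  # one circular repeat unit
        circle_parts = [block] * units
        orients = [obs] * units
        strands = ("+",) * units
        junctions = (TRT,) * units  # circular: every junction is a TRT
        # genome coordinate of body start within the block is itr_len
        if enzyme is not None:
            per_block = [c - ilen for c in genome_cuts]
        circle = "".join(circle_parts)
        block_len = len(block)
    elif join == "alternating":
        if units % 2 != 0:
            raise ValueError("alternating circles need an even unit count")
        parts, orients, strands = [], [], []
        for i in range(units):
            a, b = _rand_orient(rng), _rand_orient(rng)
            u = _unit_seq(genome, a, b)
            if i % 2 == 0:
                parts.append(u)
                orients.extend([a, b])
                strands.append("+")
            else:
                parts.append(revcomp(u))
                orients.extend([other_orientation(b), other_orientation(a)])
                strands.append("-")
        circle = "".join(parts)
        block_len = len(parts[0])  # all units same length
        junctions = (FOLD_BACK,) * units
        if enzyme is not None:
            per_block = None  # handled per strand below
    else:
        raise ValueError("join must be 'HT' or 'alternating'")

    clen = len(circle)
    rot = int(rng.integers(0, clen))
    circle = circle[rot:] + circle[:rot]
    product = circle * rca_rounds

    cut_positions: list[int] = []
    if enzyme is not None:
        # absolute cut positions in the unrotated circle coordinates
        base_cuts = []
        for i in range(units):
            off = i * block_len
            if join == "HT":
                base_cuts.extend(off + c for c in per_block)
            else:
                for c in genome_cuts:
                    base_cuts.append(off + (c if i % 2 == 0 else block_len - c))
        for r in range(rca_rounds):
            for c in base_cuts:
                p = (c - rot) % clen + r * clen
                cut_positions.append(p)
        cut_positions.sort()
        if len(cut_positions) >= 2:
            lo, hi = cut_positions[0], cut_positions[-1]
            product = product[lo:hi]
            cut_positions = [p - lo for p in cut_positions[1:-1]]

    n_total = units * rca_rounds
    return MoleculeRecord(
        molecule_id, product, 3 if join == "HT" else 4, n_total,
        tuple(strands) * rca_rounds, tuple(orients) * rca_rounds,
        tuple(junctions) * rca_rounds if n_total > 1 else (),
        topology="linear", subkind=f"rca-{join}",
        cut_positions=tuple(cut_positions))


# ---------------------------------------------------------------------------
# read model


def make_decoy_reference(length: int = 16500, seed: int = 99) -> str:
    """Random decoy reference standing in for the mitochondrial genome used
    for per-10,000-read normalization."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x317D)))
    return _random_dna(rng, length)


def mutate_sequence(seq: str, sub_rate: float, ins_rate: float,
                    del_rate: float, rng: np.random.Generator,
                    indel_extend: float = 0.3) -> str:
    """Apply independent per-base substitutions and geometric-length indels.

    Each position substitutes with ``sub_rate``; an insertion of length
    1 + Geometric(1 - indel_extend) starts after a position with
    ``ins_rate``; a deletion run of the same length law starts with
    ``del_rate``.
    """
    if sub_rate == ins_rate == del_rate == 0:
        return seq
    bases = "ACGT"
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = len(arr)
    u = rng.random(n)
    out: list[str] = []
    i = 0
    while i < n:
        r = u[i]
        if r < del_rate:
            run = 1 + rng.geometric(1 - indel_extend) - 1
            i += max(1, int(run))
            continue
        ch = arr[i].decode()
        if r < del_rate + sub_rate:
            ch = bases[(bases.index(ch) + int(rng.integers(1, 4))) % 4]
        out.append(ch)
        if r > 1 - ins_rate:
            run = max(1, int(1 + rng.geometric(1 - indel_extend) - 1))
            out.append("".join(bases[j] for j in rng.integers(0, 4, run)))
        i += 1
    return "".join(out)


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    molecule_id: str
    category_truth: int
    itr_orientations: tuple[str, ...]
    unit_strands: tuple[str, ...]
    is_decoy: bool = False


def simulate_molecules(genome: AnnotatedGenome, config: SimConfig) -> list[MoleculeRecord]:
    """Molecule panel per the configured per-category counts."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x5EED)))
    ranges = {3: config.concatemer_units, 4: config.alternating_units,
              5: config.mixed_units, 6: config.itr_copies}
    mols = []
    for cat in sorted(config.category_counts):
        for i in range(config.category_counts[cat]):
            nu = None
            if cat in ranges:
                lo, hi = ranges[cat]
                nu = int(rng.integers(lo, hi + 1))
            mols.append(make_molecule(genome, cat, rng, unit_count=nu,
                                      molecule_id=f"cat{cat}_mol{i:04d}"))
    return mols


def simulate_reads(molecules: list[MoleculeRecord], config: SimConfig,
                   decoy_reference: str | None = None) -> list[SimulatedRead]:
    """Whole-molecule reads with the configured error model, plus decoy
    reads drawn from the decoy reference.  Deterministic per config seed."""
    if not molecules and config.mito_decoy_count == 0:
        raise ValueError("empty molecule set")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x4EAD)))
    reads = []
    for i, mol in enumerate(molecules):
        seq = mutate_sequence(mol.sequence, config.sub_rate, config.ins_rate,
                              config.del_rate, rng, config.indel_extend)
        reads.append(SimulatedRead(f"read_{i:05d}", seq, mol.molecule_id,
                                   mol.category_truth, mol.itr_orientations,
                                   mol.unit_strands))
    if config.mito_decoy_count > 0:
        ref = decoy_reference or make_decoy_reference(config.mito_len,
                                                      seed=config.seed)
        lo, hi = config.decoy_read_len
        for j in range(config.mito_decoy_count):
            n = int(rng.integers(lo, min(hi, len(ref)) + 1))
            start = int(rng.integers(0, len(ref) - n + 1))
            seq = mutate_sequence(ref[start:start + n], config.sub_rate,
                                  config.ins_rate, config.del_rate, rng,
                                  config.indel_extend)
            reads.append(SimulatedRead(f"decoy_{j:05d}", seq, "mito", 0,
                                       (), (), is_decoy=True))
    return reads


# ---------------------------------------------------------------------------
# I/O


def write_molecules_fasta(molecules: list[MoleculeRecord], path) -> None:
    with open(path, "w") as fh:
        for m in molecules:
            fh.write(f">{m.molecule_id} category={m.category_truth}\n")
            for i in range(0, len(m.sequence), 80):
                fh.write(m.sequence[i:i + 80] + "\n")


def write_reads_fastq(reads: list[SimulatedRead], path) -> None:
    """FASTQ with a constant Q20 placeholder quality (classification never
    uses quality)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'5' * len(r.sequence)}\n")


def truth_table(reads: list[SimulatedRead]):
    """Truth table linking read id to molecule, category and orientations."""
    import pandas as pd

    return pd.DataFrame({
        "read_id": [r.read_id for r in reads],
        "molecule_id": [r.molecule_id for r in reads],
        "category": [r.category_truth for r in reads],
        "itr_orientations": [",".join(r.itr_orientations) for r in reads],
        "unit_strands": [",".join(r.unit_strands) for r in reads],
        "is_decoy": [r.is_decoy for r in reads],
    })
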
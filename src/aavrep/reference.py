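"""Parametric AAV2-like reference genomes with structurally correct ITRs.

The adeno-associated virus type 2 genome is a ~4.7 kb linear single-stranded
DNA whose ends carry inverted terminal repeats (ITRs).  Each ITR consists of
a 125-nt palindromic region built from the arms A, B, B', C and C' (primes
denote reverse complements) followed by a unique, non-palindromic 20-nt D
sequence on the genome-proximal side, adjacent to the terminal resolution
site (trs).  The internal BB'CC' palindrome occurs in two orientations,
"flip" and "flop", which are each other's reverse complement.

This module builds such genomes from explicit parameters: the real arm
lengths are not asserted, only the 125-nt palindromic total and the 20-nt D
length.  Sequences are random but deterministic per seed, so the simulator
and the classifier tests can share exact ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "revcomp",
    "ITRSpec",
    "GenomeSpec",
    "Feature",
    "AnnotatedGenome",
    "build_itr",
    "build_genome",
    "write_reference",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = frozenset("ACGTN")

FLIP = "flip"
FLOP = "flop"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence over the {A,C,G,T,N} alphabet.

    Raises
    ------
    ValueError
        If the sequence contains a non-nucleotide character.
    """
    if not set(seq.upper()) <= _VALID:
        bad = sorted(set(seq.upper()) - _VALID)
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5,
                max_homopolymer: int = 5) -> str:
    """Random sequence with homopolymer runs capped at ``max_homopolymer``.

    Long homopolymers are re-drawn so that the k-mer chaining aligner stays
    well conditioned on synthetic references.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=n, p=p))
    run = 1
    for i in range(1, n):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        while run > max_homopolymer:
            seq[i] = rng.choice(bases, p=p)
            run = 1 if seq[i] != seq[i - 1] else run
    return "".join(seq)


@dataclass(frozen=True)
class ITRSpec:
    """Parametric description of one inverted terminal repeat.

    The palindromic region is ``A + internal + spacer + A'`` where the
    internal region is ``B B' C C'`` (flip) or ``C C' B B'`` (flop).
    Arm lengths are configurable; the default partition
    2*30 + 2*16 + 2*16 + 1 sums to the canonical 125 nt.
    """

    len_a: int = 30
    len_b: int = 16
    len_c: int = 16
    len_spacer: int = 1
    len_d: int = 20
    palindrome_len: int = 125
    gc: float = 0.5
    seed: int = 7

    def __post_init__(self) -> None:
        total = 2 * self.len_a + 2 * self.len_b + 2 * self.len_c + self.len_spacer
        if total != self.palindrome_len:
            raise ValueError(
                f"ITR partition 2*{self.len_a}+2*{self.len_b}+2*{self.len_c}"
                f"+{self.len_spacer} = {total} != {self.palindrome_len}"
            )
        if self.len_d < 0 or min(self.len_a, self.len_b, self.len_c) <= 0:
            raise ValueError("arm and D lengths must be positive")

    def arms(self) -> dict[str, str]:
        """Deterministic A, B, C, spacer and D sequences for this spec."""
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 0xA2)))
        a = _random_dna(rng, self.len_a, self.gc)
        b = _random_dna(rng, self.len_b, self.gc)
        c = _random_dna(rng, self.len_c, self.gc)
        while c == b:  # degenerate B == C allowed only by explicit choice
            c = _random_dna(rng, self.len_c, self.gc)
        spacer = _random_dna(rng, self.len_spacer, self.gc)
        d = _random_dna(rng, self.len_d, self.gc)
        return {"A": a, "B": b, "C": c, "spacer": spacer, "D": d}

    def internal(self, orientation: str, arms: dict[str, str] | None = None) -> str:
        """The BB'CC' (flip) or CC'BB' (flop) region, spacer excluded."""
        ar = arms or self.arms()
        b, c = ar["B"], ar["C"]
        if orientation == FLIP:
            return b + revcomp(b) + c + revcomp(c)
        if orientation == FLOP:
            return c + revcomp(c) + b + revcomp(b)
        raise ValueError(f"orientation must be 'flip' or 'flop', got {orientation!r}")

    @property
    def d_sequence(self) -> str:
        return self.arms()["D"]


def build_itr(spec: ITRSpec, orientation: str) -> str:
    """Build the 125-nt palindromic ITR region in the given orientation.

    Layout: ``A + internal(orientation) + spacer + A'``.  The internal
    region of the flop form is the reverse complement of the flip form's;
    the A arms are orientation-invariant.
    """
    arms = spec.arms()
    a = arms["A"]
    seq = a + spec.internal(orientation, arms) + arms["spacer"] + revcomp(a)
    assert len(seq) == spec.palindrome_len
    return seq


@dataclass(frozen=True)
class Feature:
    """One annotated interval, 0-based half-open, on the reference."""

    name: str
    start: int
    end: int
    strand: str = "+"
    note: str = ""


def other_orientation(orientation: str) -> str:
    return FLOP if orientation == FLIP else FLIP


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the synthetic AAV2-like reference.

    ``enzyme_sites`` maps enzyme name to 1-based cut offsets: a cut at
    offset c splits a monomer into fragments of c and total_len - c nt
    (the convention behind the published 1,882 -> 1.9/2.8 kb prediction).
    ``probes`` are 0-based half-open intervals; the ITR probe lies inside
    the left ITR's C/A region by design and is exempt from the
    no-probe-in-ITR overlap check that applies to body probes.
    """

    total_len: int = 4700
    itr: ITRSpec = field(default_factory=ITRSpec)
    orientation_left: str = FLIP
    orientation_right: str = FLOP
    rep_interval: tuple[int, int] = (200, 2200)
    cap_interval: tuple[int, int] = (2300, 4400)
    enzyme_sites: tuple[tuple[str, tuple[int, ...]], ...] = (("HindIII", (1882,)),)
    probes: tuple[tuple[str, tuple[int, int]], ...] = (
        ("rep-probe", (900, 1800)),
        ("ITR-probe", (62, 122)),
    )
    seed: int = 7

    @property
    def itr_len(self) -> int:
        return self.itr.palindrome_len + self.itr.len_d

    def __post_init__(self) -> None:
        L, ilen = self.total_len, self.itr_len
        if L < 2 * ilen + 100:
            raise ValueError("genome too short for two ITRs plus a body")
        itr_regions = [(0, ilen), (L - ilen, L)]
        for enzyme, cuts in self.enzyme_sites:
            for c in cuts:
                if not 0 < c < L:
                    raise ValueError(f"{enzyme} cut offset {c} outside genome")
                if not ilen <= c <= L - ilen:
                    raise ValueError(f"{enzyme} cut {c} falls inside an ITR interval")
        for name, (p0, p1) in self.probes:
            if not (0 <= p0 < p1 <= L):
                raise ValueError(f"probe {name} interval out of bounds")
            if name != "ITR-probe":
                for lo, hi in itr_regions:
                    if p0 < hi and lo < p1:
                        raise ValueError(f"probe {name} overlaps an ITR interval")
        for name, (a, b) in [("rep", self.rep_interval), ("cap", self.cap_interval)]:
            if not (ilen <= a < b <= L - ilen):
                raise ValueError(f"{name} interval must lie in the genome body")


@dataclass(frozen=True)
class AnnotatedGenome:
    """A built reference: sequence plus feature annotation."""

    spec: GenomeSpec
    sequence: str
    features: tuple[Feature, ...]

    @property
    def total_len(self) -> int:
        return len(self.sequence)

    @property
    def itr_intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Left and right ITR (palindrome + D) intervals, half-open."""
        ilen = self.spec.itr_len
        return (0, ilen), (self.total_len - ilen, self.total_len)

    @property
    def body(self) -> str:
        ilen = self.spec.itr_len
        return self.sequence[ilen:self.total_len - ilen]

    def palindrome(self, orientation: str) -> str:
        return build_itr(self.spec.itr, orientation)

    @property
    def d_sequence(self) -> str:
        return self.spec.itr.d_sequence

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def cut_offsets(self, enzyme: str) -> tuple[int, ...]:
        for nm, cuts in self.spec.enzyme_sites:
            if nm == enzyme:
                return cuts
        raise KeyError(enzyme)


def build_genome(gspec: GenomeSpec) -> AnnotatedGenome:
    """Assemble the annotated reference sequence.

    Forward-strand layout::

        [palindrome(left)] [D] [body: ... rep ... cap ...] [D'] [palindrome'(right)]

    where the right-end element is the reverse complement of a left-style
    ``palindrome(right) + D`` block, so each D sits genome-proximal to its
    palindrome and the trs markers sit at the palindrome/D boundaries'
    body-facing sides.
    """
    spec = gspec.itr
    L, ilen = gspec.total_len, gspec.itr_len
    left = build_itr(spec, gspec.orientation_left) + spec.d_sequence
    right = revcomp(build_itr(spec, gspec.orientation_right) + spec.d_sequence)
    rng = np.random.default_rng(np.random.SeedSequence((gspec.seed, 0xB0D7)))
    body = _random_dna(rng, L - 2 * ilen, spec.gc)
    seq = left + body + right
    assert len(seq) == L

    pal = spec.palindrome_len
    feats = [
        Feature("itr_left", 0, ilen, "+", f"orientation={gspec.orientation_left}"),
        Feature("d_left", pal, ilen, "+"),
        Feature("trs_left", ilen, ilen, "+", "position marker"),
        Feature("rep", *gspec.rep_interval, strand="+"),
        Feature("cap", *gspec.cap_interval, strand="+"),
        Feature("trs_right", L - ilen, L - ilen, "-", "position marker"),
        Feature("d_right", L - ilen, L - pal, "-"),
        Feature("itr_right", L - ilen, L, "-",
                f"orientation={gspec.orientation_right}"),
    ]
    for name, (p0, p1) in gspec.probes:
        feats.append(Feature(name, p0, p1, "+", "probe"))
    return AnnotatedGenome(gspec, seq, tuple(feats))


def write_reference(genome: AnnotatedGenome, fasta_path, bed_path=None,
                    enzymes_path=None, name: str = "AAV2_synthetic") -> None:
    """Write the reference as FASTA plus BED feature annotation and a
    plain-text enzyme-site table."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(genome.sequence), id=name,
                    description=f"length={genome.total_len}")
    SeqIO.write([rec], str(fasta_path), "fasta")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for f in genome.features:
                fh.write(f"{name}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}"
                         + (f"\t{f.note}" if f.note else "") + "\n")
    if enzymes_path is not None:
        with open(enzymes_path, "w") as fh:
            fh.write("enzyme\tcut_offset_1based\n")
            for enzyme, cuts in genome.spec.enzyme_sites:
                for c in cuts:
                    fh.write(f"{enzyme}\t{c}\n")
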
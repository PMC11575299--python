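"""In-silico restriction digestion of concatemer models with probe
visibility — the computational twin of a Southern-blot band prediction.

A concatemer model is an ordered list of genome units, each with a length,
an orientation, per-unit cut offsets (nt from the unit's own 5' end) and an
optional probe interval.  A minus-orientation unit mirrors its offsets: a
cut at offset c falls at ``unit_length - c`` within the concatemer.  Cut
offsets follow the restriction-map convention that a cut at offset c splits
a monomer into fragments of c and ``unit_length - c`` nt — the arithmetic
behind the published predictions (a 4,700-nt genome cut at 1,882 gives 1.9
and 2.8 kb; the 2,000/3,800-nt vector genomes cut at 815 give the 1.2/3,
2/3.8, 2.4/6 and mixed 4.2 kb bands).

A fragment is probe-visible iff it overlaps the probe interval of any unit
it spans by at least ``min_overlap`` nt.  Band sizes round half-up to
0.1 kb; an exact-length mode disables rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Unit",
    "ConcatemerModel",
    "Fragment",
    "DigestResult",
    "digest",
    "visible_fragments",
    "band_table",
    "round_band_kb",
    "format_band",
    "monomer",
    "ht_concatemer",
    "hh_dimer",
]


@dataclass(frozen=True)
class Unit:
    """One genome unit inside a concatemer model."""

    length: int
    orientation: str = "+"
    cut_offsets: tuple[int, ...] = ()
    probe_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("unit length must be positive")
        if self.orientation not in "+-":
            raise ValueError("orientation must be '+' or '-'")
        for c in self.cut_offsets:
            if not 0 < c < self.length:
                raise ValueError(f"cut offset {c} not strictly inside unit")
        if self.probe_interval is not None:
            p0, p1 = self.probe_interval
            if not 0 <= p0 < p1 <= self.length:
                raise ValueError("probe interval outside unit")


@dataclass(frozen=True)
class ConcatemerModel:
    units: tuple[Unit, ...]
    topology: str = "linear"
    name: str = ""

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("a model needs at least one unit")
        if self.topology not in ("linear", "circular"):
            raise ValueError("topology must be 'linear' or 'circular'")

    @property
    def total_len(self) -> int:
        return sum(u.length for u in self.units)

    def reverse_complement(self) -> "ConcatemerModel":
        flipped = tuple(
            Unit(u.length, "-" if u.orientation == "+" else "+",
                 u.cut_offsets, u.probe_interval)
            for u in reversed(self.units))
        return ConcatemerModel(flipped, self.topology, self.name)


@dataclass(frozen=True)
class Fragment:
    start: int
    end: int  # absolute model coordinates; end may wrap past total_len
    size: int
    probe_visible: bool


@dataclass
class DigestResult:
    model: ConcatemerModel
    enzymatic_cuts: tuple[int, ...]
    fragments: list[Fragment]

    @property
    def sizes(self) -> list[int]:
        return [f.size for f in self.fragments]

    @property
    def visible_sizes(self) -> list[int]:
        return [f.size for f in self.fragments if f.probe_visible]

    def bands_kb(self, visible_only: bool = True, rounding: bool = True) -> list[float]:
        sizes = self.visible_sizes if visible_only else self.sizes
        if not rounding:
            return [s / 1000 for s in sizes]
        return sorted({round_band_kb(s) for s in sizes})


def round_band_kb(size_nt: int) -> float:
    """Round a fragment size half-up to 0.1 kb."""
    return int(size_nt / 100 + 0.5) / 10


def format_band(kb: float) -> str:
    """Display convention of the published predictions: whole-kb values
    print as integers ('2', '3', '6'), others with one decimal ('3.8')."""
    return str(int(kb)) if float(kb) == int(kb) else f"{kb:.1f}"


def _absolute_layout(model: ConcatemerModel):
    """Absolute cut positions and probe intervals, respecting unit
    orientation (minus units mirror both)."""
    cuts: list[int] = []
    probes: list[tuple[int, int]] = []
    offset = 0
    for u in model.units:
        for c in u.cut_offsets:
            cuts.append(offset + (c if u.orientation == "+" else u.length - c))
        if u.probe_interval is not None:
            p0, p1 = u.probe_interval
            if u.orientation == "+":
                probes.append((offset + p0, offset + p1))
            else:
                probes.append((offset + u.length - p1, offset + u.length - p0))
        offset += u.length
    return sorted(set(cuts)), probes


def digest(model: ConcatemerModel, min_overlap: int = 20) -> DigestResult:
    """Cut the model at every enzyme site and flag probe-visible fragments.

    Linear topology: fragments between successive cuts plus the two
    terminal fragments; fragment sizes sum exactly to the model length.
    Circular topology: the last fragment wraps; with no cut the result is
    one full-length (still circular) fragment.
    """
    L = model.total_len
    cuts, probes = _absolute_layout(model)

    def visible(a: int, b: int) -> bool:
        """Probe overlap of [a, b), which may wrap around a circle."""
        spans = [(a, b)] if b <= L else [(a, L), (0, b - L)]
        for s0, s1 in spans:
            for p0, p1 in probes:
                if min(s1, p1) - max(s0, p0) >= min_overlap:
                    return True
        return False

    frags: list[Fragment] = []
    if model.topology == "linear":
        bounds = [0] + cuts + [L]
        for a, b in zip(bounds, bounds[1:]):
            if b > a:
                frags.append(Fragment(a, b, b - a, visible(a, b)))
    else:
        if not cuts:
            frags.append(Fragment(0, L, L, visible(0, L)))
        else:
            for i, a in enumerate(cuts):
                b = cuts[(i + 1) % len(cuts)]
                end = b if b > a else b + L
                frags.append(Fragment(a, end, end - a, visible(a, end)))
    assert sum(f.size for f in frags) == L
    return DigestResult(model, tuple(cuts), frags)


def visible_fragments(result: DigestResult) -> list[Fragment]:
    """The probe-visible subset of the digest fragments."""
    return [f for f in result.fragments if f.probe_visible]


# ---------------------------------------------------------------------------
# model constructors


def monomer(length: int, cut: int | tuple[int, ...],
            probe: tuple[int, int] | None = None, name: str = "monomer",
            topology: str = "linear") -> ConcatemerModel:
    cuts = (cut,) if isinstance(cut, int) else tuple(cut)
    return ConcatemerModel((Unit(length, "+", cuts, probe),), topology, name)


def ht_concatemer(unit: Unit, n: int, name: str = "HT",
                  topology: str = "linear") -> ConcatemerModel:
    """Head-to-tail n-mer: all units in the same orientation."""
    if n < 2:
        raise ValueError("a concatemer needs >= 2 units")
    return ConcatemerModel((unit,) * n, topology, name)


def hh_dimer(unit_a: Unit, unit_b: Unit | None = None, *,
             join: str = "cut_distal", name: str = "HH",
             topology: str = "linear") -> ConcatemerModel:
    """Head-to-head dimer: two units in opposite orientation.

    ``join='cut_distal'`` joins the units through the ends farther from
    their (first) cut site — the junction-spanning digest fragment is then
    twice the distal arm (e.g. 2 * 2,985 = 5,970 nt -> the 6-kb vector
    band).  ``join='cut_proximal'`` joins the near ends (junction fragment
    twice the proximal arm, e.g. 2 * 1,882 = 3,764 nt -> the 3.8-kb band).
    A circular head-to-head dimer carries both junction types at once.
    """
    b = unit_b or unit_a
    a_cut = unit_a.cut_offsets[0] if unit_a.cut_offsets else unit_a.length // 2
    distal_is_right = a_cut <= unit_a.length - a_cut
    if join not in ("cut_distal", "cut_proximal"):
        raise ValueError("join must be 'cut_distal' or 'cut_proximal'")
    join_right = distal_is_right == (join == "cut_distal")
    flip = lambda u: Unit(u.length, "-" if u.orientation == "+" else "+",
                          u.cut_offsets, u.probe_interval)
    if join_right:
        units = (unit_a, flip(b))     # + then - : junction through right ends
    else:
        units = (flip(unit_a), b)     # - then + : junction through left ends
    return ConcatemerModel(units, topology, name)


def band_table(models: dict[str, ConcatemerModel], *, min_overlap: int = 20,
               rounding: bool = True) -> pd.DataFrame:
    """One row per named model: visible band sizes (kb, 0.1-kb rounded by
    default) and their display strings."""
    rows = []
    for name, model in models.items():
        res = digest(model, min_overlap=min_overlap)
        bands = res.bands_kb(visible_only=True, rounding=rounding)
        rows.append({
            "model": name,
            "total_len_nt": model.total_len,
            "n_fragments": len(res.fragments),
            "bands_kb": bands,
            "bands_display": "/".join(format_band(b) for b in bands),
        })
    return pd.DataFrame(rows)
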
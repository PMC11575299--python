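"""Dot-plot segment decomposition and seven-category structural
classification of long reads.

A read's filtered hits against the reference genome form an ordered segment
path — the machine-readable equivalent of a read-versus-reference dot plot.
Junctions between consecutive segments are typed geometrically:

* head-to-tail (HT): same strand, subject coordinate wraps from the genome
  end back to the start through the ITR junction (rolling-circle signature);
* fold-back: strand flips and the two segments meet at a shared genome end
  (rolling-hairpin signature);
* internal fold: strand flips mid-genome (snap-back signature).

The decision rules, thresholds and category precedence are explicit
parameters because the original dot plots were categorized by eye.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .hits import ReadHitSet, merge_hits
from .simulate import CATEGORY_NAMES

__all__ = [
    "Segment",
    "SegmentPath",
    "CategoryCall",
    "Thresholds",
    "segments_from_hits",
    "classify",
    "classify_rca_shape",
    "category_ratios",
    "normalize_per_mito",
    "dotplot_table",
]

HT = "HT"
FOLD_BACK = "fold-back"
INTERNAL_FOLD = "internal-fold"
COLINEAR = "colinear"
OTHER = "other"


@dataclass(frozen=True)
class Segment:
    """One dot-plot segment: read interval, forward subject interval,
    strand.  Read position increases along the subject for '+' and against
    it for '-'."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def s_span(self) -> int:
        return self.s_end - self.s_start

    def entry(self) -> int:
        """Subject coordinate where the read enters this segment."""
        return self.s_start if self.strand == "+" else self.s_end

    def exit(self) -> int:
        """Subject coordinate where the read leaves this segment."""
        return self.s_end if self.strand == "+" else self.s_start


@dataclass
class SegmentPath:
    read_id: str
    segments: list[Segment]
    read_len: int

    def __post_init__(self) -> None:
        qs = [s.q_start for s in self.segments]
        assert qs == sorted(qs), "segments must be ordered by read position"


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds (defaults mirror the package's automated
    reading of what was a manual dot-plot call).

    full_fraction: subject coverage for a segment to count as a full genome
    unit.  partial_fraction: minimum coverage for a partial terminal unit to
    count toward a structural pattern (never toward n_full_units).
    itr_tol: slack around the annotated ITR+D intervals for the ITR-only
    test.  end_tol: how close to a genome end a junction must land to count
    as an ITR-mediated (HT or fold-back) junction.  min_segment_len: shorter
    segments are discarded as alignment debris.  fuse_tol: same-strand
    colinear neighbours whose subject coordinates continue within this
    distance are fused (they are one unit split by noise).
    """

    full_fraction: float = 0.9
    partial_fraction: float = 0.25
    itr_tol: int = 30
    junction_gap: int = 50
    end_tol: int = 400
    min_segment_len: int = 100
    fuse_tol: int = 200


def segments_from_hits(hitset: ReadHitSet, read_len: int | None = None,
                       thresholds: Thresholds = Thresholds()) -> SegmentPath:
    """Overlap-merged, containment-pruned, read-ordered segments from a
    selected read's hits."""
    if not hitset.hits:
        raise ValueError(f"read {hitset.read_id} has no retained hits; "
                         "rejected reads should not reach segmentation")
    merged = merge_hits(hitset.hits)
    segs = [Segment(h.q_start, h.q_end, h.s_start, h.s_end, h.strand)
            for h in merged if h.q_span >= thresholds.min_segment_len]
    segs.sort(key=lambda s: (s.q_start, s.q_end))
    if not segs:
        raise ValueError(f"read {hitset.read_id}: no segment passes the "
                         f"{thresholds.min_segment_len}-nt minimum")
    return SegmentPath(hitset.read_id, segs, read_len or max(s.q_end for s in segs))


def _diag(seg: Segment) -> int:
    """Dot-plot diagonal: constant along one gap-free alignment line."""
    if seg.strand == "+":
        return seg.s_start - seg.q_start
    return seg.s_end + seg.q_start


def _fuse_colinear(segments: list[Segment], tol: int,
                   diag_tol: int = 80) -> list[Segment]:
    """Fuse same-strand neighbours that continue on the same dot-plot
    diagonal (one genome unit split by sequencing noise).  The diagonal
    test keeps tandem-repeat staircases — whose successive segments share
    endpoints but jump diagonals — apart."""
    out: list[Segment] = []
    for seg in segments:
        if out:
            prev = out[-1]
            if (prev.strand == seg.strand
                    and abs(_diag(seg) - _diag(prev)) <= diag_tol
                    and abs(seg.entry() - prev.exit()) <= tol
                    and seg.q_start - prev.q_end <= tol):
                out[-1] = Segment(prev.q_start, seg.q_end,
                                  min(prev.s_start, seg.s_start),
                                  max(prev.s_end, seg.s_end), prev.strand)
                continue
        out.append(seg)
    return out


def _junction_type(prev: Segment, nxt: Segment, ref_len: int,
                   th: Thresholds) -> str:
    near_start = lambda x: x <= th.end_tol
    near_end = lambda x: x >= ref_len - th.end_tol
    p, n = prev.exit(), nxt.entry()
    if prev.strand == nxt.strand:
        if prev.strand == "+" and near_end(p) and near_start(n):
            return HT
        if prev.strand == "-" and near_start(p) and near_end(n):
            return HT
        if (abs(_diag(nxt) - _diag(prev)) <= 80
                and abs(p - n) <= th.fuse_tol):
            return COLINEAR
        return OTHER
    if (near_end(p) and near_end(n)) or (near_start(p) and near_start(n)):
        return FOLD_BACK
    if abs(p - n) <= th.fuse_tol:
        return INTERNAL_FOLD
    return OTHER


@dataclass
class CategoryCall:
    read_id: str
    category: int
    n_full_units: int
    n_unit_segments: int
    junction_labels: tuple[str, ...]
    itr_only: bool
    notes: str = ""

    @property
    def category_name(self) -> str:
        return CATEGORY_NAMES[self.category]


def _is_itr_only(seg: Segment, itr_intervals, tol: int) -> bool:
    return any(lo - tol <= seg.s_start and seg.s_end <= hi + tol
               for lo, hi in itr_intervals)


def classify(path: SegmentPath, ref_len: int, itr_intervals,
             thresholds: Thresholds = Thresholds()) -> CategoryCall:
    """Assign the read to one of the seven structural categories.

    ``itr_intervals`` are the annotated ITR+D intervals of the reference
    (half-open subject coordinates).  Unclassifiable paths fall through to
    category 7 by definition.  Precedence when several rules could fire:
    ITR-only arrays (6) first, then monomer (1), mixed (5), head-to-tail
    (3), alternating (4, which needs at least three units so that the
    two-unit fold-back case remains a duplex), duplex (2), others (7).
    """
    if not path.segments:
        raise ValueError("empty segment path")
    th = thresholds
    segs = _fuse_colinear(path.segments, th.fuse_tol)
    itr_flags = [_is_itr_only(s, itr_intervals, th.itr_tol) for s in segs]
    all_itr = all(itr_flags) and len(segs) >= 2

    # structural patterns are read off the genome-unit segments; ITR-only
    # fragments at arrangement boundaries are bookkept but must not break a
    # unit pattern (they sit inside the junction an HT/fold-back call spans)
    unit_segs = [s for s, f in zip(segs, itr_flags)
                 if not f and s.s_span >= th.partial_fraction * ref_len]
    junctions = tuple(_junction_type(a, b, ref_len, th)
                      for a, b in zip(unit_segs, unit_segs[1:]))
    full = [s for s in unit_segs if s.s_span >= th.full_fraction * ref_len]
    n_full, n_units = len(full), len(unit_segs)
    strands = [s.strand for s in unit_segs]
    alternating = all(a != b for a, b in zip(strands, strands[1:]))
    uniform = len(set(strands)) == 1
    has_ht = HT in junctions
    has_fb = FOLD_BACK in junctions
    clean = bool(junctions) and all(j in (HT, FOLD_BACK) for j in junctions)

    if all_itr:
        cat = 6
    elif n_units == 1 and n_full == 1:
        cat = 1
    elif n_full >= 3 and has_ht and has_fb and clean:
        cat = 5
    elif n_full >= 2 and uniform and clean and all(j == HT for j in junctions):
        cat = 3
    elif (n_full >= 3 and alternating and clean
          and all(j == FOLD_BACK for j in junctions)):
        cat = 4
    elif (n_full == 2 and n_units == 2 and alternating
          and junctions == (FOLD_BACK,)):
        cat = 2
    else:
        cat = 7

    notes = []
    if INTERNAL_FOLD in junctions:
        notes.append("internal fold (snap-back-like)")
    if n_units != len(segs) and not all_itr:
        notes.append("contains sub-unit or ITR-only segments")
    return CategoryCall(path.read_id, cat, n_full, n_units, junctions,
                        all_itr, "; ".join(notes))


def classify_rca_shape(path: SegmentPath, ref_len: int,
                       thresholds: Thresholds = Thresholds()) -> str:
    """Dot-plot shape of a rolling-circle-amplification product read after
    restriction digestion: same-strand tandem segments plot as parallel
    lines (circular monomer or head-to-tail circle), strand-alternating
    mirrored segments plot as "V" shapes (alternating circle)."""
    th = thresholds
    segs = _fuse_colinear(path.segments, th.fuse_tol)
    # shape is carried by the unit-scale segments; ITR-boundary debris from
    # the palindromic junctions is ignored
    segs = [s for s in segs if s.s_span >= th.partial_fraction * ref_len] or segs
    if len(segs) == 1:
        return "parallel"
    strands = [s.strand for s in segs]
    junctions = [_junction_type(a, b, ref_len, th) for a, b in zip(segs, segs[1:])]
    if len(set(strands)) == 1 and all(j in (HT, COLINEAR) for j in junctions):
        return "parallel"
    if (all(a != b for a, b in zip(strands, strands[1:]))
            and all(j in (FOLD_BACK, INTERNAL_FOLD) for j in junctions)):
        return "V"
    return "unresolved"


def category_ratios(calls: list[CategoryCall]) -> pd.DataFrame:
    """Ratio table over categories 1-7 (one row, columns named as in the
    published tables).  Ratios sum to 1; empty categories appear as 0.0."""
    if not calls:
        raise ValueError("no calls to tabulate")
    counts = {k: 0 for k in range(1, 8)}
    for c in calls:
        counts[c.category] += 1
    total = sum(counts.values())
    data = {CATEGORY_NAMES[k]: [counts[k] / total] for k in range(1, 8)}
    df = pd.DataFrame(data)
    df.insert(0, "n_reads", total)
    return df


def normalize_per_mito(count: int, mito_count: int) -> float:
    """Reads per 10,000 decoy (mitochondrial) reads."""
    if mito_count <= 0:
        raise ValueError("mito_count must be positive")
    return count / mito_count * 10_000


def dotplot_table(path: SegmentPath) -> pd.DataFrame:
    """Segment coordinates of one read's dot plot as a table (the
    classification input; plotting from it is optional and cosmetic)."""
    return pd.DataFrame({
        "read_id": path.read_id,
        "q_start": [s.q_start for s in path.segments],
        "q_end": [s.q_end for s in path.segments],
        "s_start": [s.s_start for s in path.segments],
        "s_end": [s.s_end for s in path.segments],
        "strand": [s.strand for s in path.segments],
    })
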
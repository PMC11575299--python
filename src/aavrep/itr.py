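"""Flip/flop orientation calling, TRT (double-D) junction detection, and
orientation-uniformity testing per read.

Orientation is decided on the internal BB'CC' region only: the A arms are
palindromic and identical between orientations, so they carry no signal.
Each ITR occurrence is called independently against the flip and flop
internal references by edit distance; the published multiple-sequence-
alignment reading is replaced by these pairwise calls, which yield the same
per-ITR decision.  An occurrence whose best alignment leaves a substantial
unexplained internal stretch is flagged as anomalous internal structure
(the "additional CC' sequence" phenomenon).

A TRT junction is an ITR flanked by a D sequence on *both* sides (D-ITR-D),
the signature of head-to-tail joints arising from circular templates.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .reference import FLIP, FLOP, AnnotatedGenome, revcomp

__all__ = [
    "ITRCall",
    "find_itr_occurrences",
    "call_orientation",
    "detect_trt",
    "same_orientation_test",
    "analyze_read_itrs",
]

AMBIGUOUS = "ambiguous"
MIN_ITR_CORE = 60  # nt; shorter candidates are uncallable


@dataclass
class ITRCall:
    """Orientation call for one ITR occurrence on a read."""

    read_id: str
    occurrence: int
    q_start: int
    q_end: int
    orientation: str
    score_margin: int
    trt: bool = False
    anomalous: bool = False


def _hw_distance(pattern: str, window: str) -> tuple[int, tuple[int, int] | None]:
    """Best infix edit distance of ``pattern`` inside ``window``."""
    if not window:
        return len(pattern), None
    res = edlib.align(pattern, window, mode="HW", task="locations")
    loc = res["locations"][0] if res["locations"] else None
    return res["editDistance"], loc


def find_itr_occurrences(read: str, flip_pal: str, flop_pal: str,
                         max_dist: int | None = None,
                         max_occurrences: int = 64) -> list[tuple[int, int]]:
    """Locate ITR palindrome occurrences by iterative best-match masking.

    Each iteration finds the better of the flip/flop palindromes as an
    infix match (edit distance), records the interval, masks it, and
    repeats until no match within ``max_dist`` (default 22% of the
    palindrome length) remains.  Because the reverse complement of a flip
    palindrome reads as flop, both strands are covered by the two
    orientation references.  Returned intervals are sorted by position.
    """
    if max_dist is None:
        max_dist = int(0.22 * len(flip_pal))
    cur = read
    found: list[tuple[int, int]] = []
    for _ in range(max_occurrences):
        d1, loc1 = _hw_distance(flip_pal, cur)
        d2, loc2 = _hw_distance(flop_pal, cur)
        d, loc = (d1, loc1) if d1 <= d2 else (d2, loc2)
        if loc is None or d > max_dist:
            break
        start, end = loc[0], loc[1] + 1
        found.append((start, end))
        cur = cur[:start] + "N" * (end - start) + cur[end:]
    return sorted(found)


def call_orientation(read: str, interval: tuple[int, int], flip_internal: str,
                     flop_internal: str, margin: int = 4, *,
                     read_id: str = "read", occurrence: int = 0,
                     pad: int = 12, pal_len: int | None = None) -> ITRCall:
    """Call flip/flop for one ITR occurrence.

    The candidate window (interval plus a small pad) is aligned against
    both internal-region references; the better one wins when the distance
    margin is at least ``margin`` edit units, otherwise the call is
    ambiguous.  Candidates shorter than the minimum ITR core are ambiguous
    by definition.  Swapping the two references flips the call and negates
    the margin.
    """
    q0, q1 = interval
    window = read[max(0, q0 - pad):q1 + pad]
    if q1 - q0 < MIN_ITR_CORE:
        return ITRCall(read_id, occurrence, q0, q1, AMBIGUOUS, 0)
    d_flip, _ = _hw_distance(flip_internal, window)
    d_flop, _ = _hw_distance(flop_internal, window)
    score_margin = d_flop - d_flip  # positive favours flip
    if abs(score_margin) < margin:
        orientation = AMBIGUOUS
    else:
        orientation = FLIP if score_margin > 0 else FLOP
    if pal_len is None:
        pal_len = len(flip_internal) + 61  # default 30-nt A arms + spacer
    anomalous = (q1 - q0) - pal_len >= 20
    return ITRCall(read_id, occurrence, q0, q1, orientation, score_margin,
                   anomalous=anomalous)


def detect_trt(read: str, interval: tuple[int, int], d_ref: str,
               max_edits: int | None = None, slack: int = 12) -> bool:
    """True iff a D sequence flanks the ITR occurrence on both sides.

    Each flank window (D length plus slack) is searched for the D sequence
    or its reverse complement at >= 80% identity (edit distance at most 20%
    of the D length).
    """
    if max_edits is None:
        max_edits = len(d_ref) // 5
    q0, q1 = interval
    w = len(d_ref) + slack
    left = read[max(0, q0 - w):q0]
    right = read[q1:q1 + w]
    def has_d(window: str) -> bool:
        if len(window) < len(d_ref) - max_edits:
            return False
        d1, _ = _hw_distance(d_ref, window)
        d2, _ = _hw_distance(revcomp(d_ref), window)
        return min(d1, d2) <= max_edits
    return has_d(left) and has_d(right)


def same_orientation_test(calls: list[ITRCall]) -> str:
    """Uniformity of unambiguous orientation calls within one read:
    'uniform' (all equal, >= 2 calls), 'mixed', 'single' (one call) or
    'uncallable' (no unambiguous call)."""
    orient = [c.orientation for c in calls if c.orientation != AMBIGUOUS]
    if not orient:
        return "uncallable"
    if len(orient) == 1:
        return "single"
    return "uniform" if len(set(orient)) == 1 else "mixed"


def analyze_read_itrs(read_id: str, read: str, genome: AnnotatedGenome, *,
                      margin: int = 4) -> tuple[list[ITRCall], str]:
    """Locate, orient and TRT-flag every ITR occurrence in a read, then
    test orientation uniformity.  Returns (calls, uniformity verdict)."""
    spec = genome.spec.itr
    flip_pal = genome.palindrome(FLIP)
    flop_pal = genome.palindrome(FLOP)
    arms = spec.arms()
    flip_int = spec.internal(FLIP, arms)
    flop_int = spec.internal(FLOP, arms)
    occs = find_itr_occurrences(read, flip_pal, flop_pal)
    calls = []
    for i, (q0, q1) in enumerate(occs):
        call = call_orientation(read, (q0, q1), flip_int, flop_int, margin,
                                read_id=read_id, occurrence=i)
        call.trt = detect_trt(read, (q0, q1), spec.d_sequence)
        calls.append(call)
    return calls, same_orientation_test(calls)
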
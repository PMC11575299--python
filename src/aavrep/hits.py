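"""Local-alignment hits per read: BLAST tabular I/O, a built-in
seed-chain-extend aligner, and the e-value / hit-sum read-selection rule.

The selection rule mirrors the published analysis: hits with e-value > 0.1
are removed, the summed aligned length of the remaining hits is computed per
read, and reads whose sum exceeds 3,000 nt are selected for dot-plot
classification.  Both inequalities are strict in the stated directions
(e-value exactly 0.1 is kept; hit sum exactly 3,000 is rejected).

The built-in aligner is a self-contained stand-in for blastn on synthetic
data: exact k-mer seeding against both reference strands, greedy colinear
chaining with bounded diagonal drift, X-drop end extension, and identity
scoring via edit distance.  Its e-value is a monotone surrogate calibrated
only to preserve the keep/discard behaviour of the 0.1 threshold for
credible hits; no Karlin-Altschul statistics are claimed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from functools import lru_cache

import edlib

from .reference import revcomp

__all__ = [
    "AlignmentHit",
    "ReadHitSet",
    "parse_blast_tab",
    "write_blast_tab",
    "builtin_local_hits",
    "filter_and_select",
    "merge_hits",
]

OUTFMT6_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send", "evalue",
                   "bitscore")


@dataclass(frozen=True)
class AlignmentHit:
    """One local hit.  Intervals are 0-based half-open; ``s_start < s_end``
    always, with ``strand`` carrying the orientation (minus-strand hits run
    right-to-left on the subject as read position increases)."""

    read_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    percent_identity: float
    aligned_length: int
    mismatches: int
    gap_opens: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (self.q_start < self.q_end and self.s_start < self.s_end):
            raise ValueError("hit intervals must be non-empty with start < end")
        if self.aligned_length <= 0:
            raise ValueError("aligned_length must be positive")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def diagonal(self) -> int:
        """Chain diagonal: constant along a gap-free colinear hit."""
        if self.strand == "+":
            return self.s_start - self.q_start
        return self.s_end + self.q_start


@dataclass
class ReadHitSet:
    """Filtered hits of one read plus the selection verdict."""

    read_id: str
    hits: list[AlignmentHit]
    hit_sum: int = 0
    selected: bool = False

    def recompute_sum(self) -> None:
        self.hit_sum = sum(h.aligned_length for h in self.hits)


# ---------------------------------------------------------------------------
# BLAST outfmt-6 dialect


def parse_blast_tab(path_or_lines) -> list[AlignmentHit]:
    """Parse 12-column BLAST tabular (outfmt 6) into hits.

    1-based inclusive coordinates become 0-based half-open; ``sstart > send``
    encodes a minus-strand hit and is normalised to a forward subject
    interval plus the strand flag.
    """
    if isinstance(path_or_lines, (str, bytes)) or hasattr(path_or_lines, "__fspath__"):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    hits = []
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ValueError(f"line {lineno}: expected 12 columns, got {len(fields)}")
        try:
            (qseqid, sseqid, pident, length, mismatch, gapopen,
             qstart, qend, sstart, send, evalue, bitscore) = fields
            qstart, qend = int(qstart), int(qend)
            sstart, send = int(sstart), int(send)
            length = int(length)
            if sstart <= send:
                strand, s0, s1 = "+", sstart - 1, send
            else:
                strand, s0, s1 = "-", send - 1, sstart
            hits.append(AlignmentHit(
                qseqid, sseqid, qstart - 1, qend, s0, s1, strand,
                float(pident), length, int(mismatch), int(gapopen),
                float(evalue), float(bitscore)))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed BLAST tabular row "
                             f"({exc})") from None
    return hits


def write_blast_tab(hits: list[AlignmentHit], path) -> None:
    """Write hits in the bit-exact outfmt-6 column order."""
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                sstart, send = h.s_start + 1, h.s_end
            else:
                sstart, send = h.s_end, h.s_start + 1
            fh.write("\t".join([
                h.read_id, h.subject_id, f"{h.percent_identity:.3f}",
                str(h.aligned_length), str(h.mismatches), str(h.gap_opens),
                str(h.q_start + 1), str(h.q_end), str(sstart), str(send),
                f"{h.e_value:.6g}", f"{h.bit_score:.6g}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# built-in aligner


@lru_cache(maxsize=8)
def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i:i + k]].append(i)
    return index


def _chain_seeds(seeds, k: int, max_gap: int, drift_tol: int):
    """Greedy colinear chaining of (q, s) seed points sorted by q.

    A seed joins the open chain whose last seed is within ``max_gap`` on the
    read, advances on the subject, and whose diagonal differs by at most
    ``drift_tol`` (absorbs indel drift).  Returns chains as
    (q0, q1, s0, s1) spans including the k-mer length.
    """
    chains: list[list[int]] = []  # [q_first, q_last, s_first, s_last]
    open_chains: list[list[int]] = []
    for q, s in seeds:
        best, best_drift = None, None
        for ch in open_chains:
            if q - ch[1] > max_gap:
                continue
            if q <= ch[1] and s <= ch[3]:
                continue
            if s < ch[3]:
                continue
            drift = abs((s - q) - (ch[3] - ch[1]))
            if drift <= drift_tol and (best is None or drift < best_drift):
                best, best_drift = ch, drift
        if best is None:
            open_chains.append([q, q, s, s])
        else:
            best[1], best[3] = q, s
        if len(open_chains) > 64:
            chains.extend(ch for ch in open_chains if q - ch[1] > max_gap)
            open_chains = [ch for ch in open_chains if q - ch[1] <= max_gap]
    chains.extend(open_chains)
    # dedupe: chains fully covered by another chain on both axes
    spans = [(c[0], c[1] + k, c[2], c[3] + k) for c in chains]
    return spans


def _xdrop_extend(read: str, ref: str, q: int, s: int, step: int,
                  xdrop: int = 30, limit: int = 400) -> int:
    """Ungapped X-drop extension from (q, s) in ``step`` direction with
    blastn-like +2/-3 scoring; returns the number of extra bases kept (up
    to and including the max-scoring point), so the end lands where a
    gap-free local alignment would stop."""
    score = best = 0
    best_n = 0
    n = 0
    while n < limit:
        qq, ss = q + step * (n + 1), s + step * (n + 1)
        if not (0 <= qq < len(read) and 0 <= ss < len(ref)):
            break
        score += 2 if read[qq] == ref[ss] else -3
        n += 1
        if score > best:
            best, best_n = score, n
        elif best - score > xdrop:
            break
    return best_n


def builtin_local_hits(read_id: str, read: str, reference: str, *,
                       subject_id: str = "ref", k: int = 12,
                       min_hit_len: int = 100, max_gap: int = 150,
                       drift_tol: int = 30) -> list[AlignmentHit]:
    """Seed-chain-extend local hits of ``read`` against both strands of
    ``reference``.  Reads shorter than ``k`` yield an empty result."""
    if len(read) < k:
        return []
    read = read.upper()
    hits: list[AlignmentHit] = []
    for strand in "+-":
        ref = reference if strand == "+" else revcomp(reference)
        index = _kmer_index(ref, k)
        seeds = []
        for q in range(len(read) - k + 1):
            for s in index.get(read[q:q + k], ()):
                seeds.append((q, s))
        seeds.sort()
        for q0, q1, s0, s1 in _chain_seeds(seeds, k, max_gap, drift_tol):
            left = _xdrop_extend(read, ref, q0, s0, -1)
            right = _xdrop_extend(read, ref, q1 - 1, s1 - 1, +1)
            q0e, s0e = q0 - left, s0 - left
            q1e, s1e = q1 + right, s1 + right
            if q1e - q0e < min_hit_len:
                continue
            hits.append(_score_hit(read_id, read, reference, subject_id,
                                   strand, q0e, q1e, s0e, s1e))
    hits = merge_hits(hits, drift_tol=drift_tol)
    return sorted(hits, key=lambda h: (h.q_start, h.q_end))


def _score_hit(read_id, read, reference, subject_id, strand,
               q0, q1, s0, s1) -> AlignmentHit:
    """Edit-distance identity plus a monotone surrogate e-value."""
    query = read[q0:q1]
    if strand == "+":
        subj = reference[s0:s1]
        ss, se = s0, s1
    else:
        rc = revcomp(reference)
        subj = rc[s0:s1]
        L = len(reference)
        ss, se = L - s1, L - s0  # map back to forward subject coords
    res = edlib.align(query, subj, mode="NW", task="path")
    dist = res["editDistance"]
    alen = max(len(query), len(subj))
    matches = alen - dist
    identity = 100.0 * matches / alen
    gap_opens = 0
    mism = 0
    cigar = res.get("cigar") or ""
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch == "X":
                mism += int(num)
            elif ch in "ID":
                gap_opens += 1
            num = ""
    raw = 2 * matches - 3 * (alen - matches)
    bits = 0.52 * raw
    e_value = min(10.0, len(read) * len(reference) * 2.0 ** (-max(bits, 0.0)))
    return AlignmentHit(read_id, subject_id, q0, q1, ss, se, strand,
                        round(identity, 3), alen, mism, gap_opens,
                        e_value, round(bits, 2))


# ---------------------------------------------------------------------------
# merging and the read-selection rule


def _overlap(a0, a1, b0, b1) -> int:
    return min(a1, b1) - max(a0, b0)


def merge_hits(hits: list[AlignmentHit], drift_tol: int = 30) -> list[AlignmentHit]:
    """Merge same-strand hits that overlap on the read on a consistent
    diagonal; then drop hits whose read interval is contained in another's
    (longest kept, ties broken by higher score then leftmost)."""
    merged: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda h: (h.strand, h.q_start, h.q_end)):
        m = None
        for i, g in enumerate(merged):
            if g.strand != h.strand or g.subject_id != h.subject_id:
                continue
            if _overlap(g.q_start, g.q_end, h.q_start, h.q_end) < 0:
                continue
            if abs(g.diagonal - h.diagonal) > drift_tol:
                continue
            m = i
            break
        if m is None:
            merged.append(h)
        else:
            g = merged[m]
            q0, q1 = min(g.q_start, h.q_start), max(g.q_end, h.q_end)
            s0, s1 = min(g.s_start, h.s_start), max(g.s_end, h.s_end)
            keep = g if g.bit_score >= h.bit_score else h
            merged[m] = replace(keep, q_start=q0, q_end=q1, s_start=s0,
                                s_end=s1, aligned_length=max(q1 - q0, s1 - s0))
    # containment pruning on the read axis
    merged.sort(key=lambda h: (-(h.q_end - h.q_start), -h.bit_score, h.q_start))
    kept: list[AlignmentHit] = []
    for h in merged:
        contained = any(g.q_start <= h.q_start and h.q_end <= g.q_end
                        and (g.q_end - g.q_start) > (h.q_end - h.q_start)
                        or (g.q_start, g.q_end) == (h.q_start, h.q_end)
                        for g in kept)
        if not contained:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.q_start, h.q_end))


def filter_and_select(hits: list[AlignmentHit], e_max: float = 0.1,
                      sum_threshold: float = 3000, *, merge: bool = True,
                      sum_metric: str = "bases") -> list[ReadHitSet]:
    """Apply the published read-selection rule.

    Hits with e-value strictly greater than ``e_max`` are removed; the sum
    of the remaining hits (aligned bases by default, or hit count with
    ``sum_metric='count'``) is computed per read, and reads whose sum is
    strictly greater than ``sum_threshold`` are marked selected.
    Idempotent: re-running on retained hits changes nothing.
    """
    if sum_metric not in ("bases", "count"):
        raise ValueError("sum_metric must be 'bases' or 'count'")
    by_read: dict[str, list[AlignmentHit]] = defaultdict(list)
    order: list[str] = []
    for h in hits:
        if h.read_id not in by_read:
            order.append(h.read_id)
        by_read[h.read_id].append(h)
    out = []
    for rid in order:
        retained = [h for h in by_read[rid] if h.e_value <= e_max]
        if merge:
            retained = merge_hits(retained)
        if sum_metric == "bases":
            hit_sum = sum(h.aligned_length for h in retained)
        else:
            hit_sum = len(retained)
        out.append(ReadHitSet(rid, retained, hit_sum,
                              selected=hit_sum > sum_threshold))
    return out


def scaled_sum_threshold(reference_length: int) -> float:
    """Selection threshold scaled to mini-genomes: 3000/4700 of the
    reference length (the published threshold at the published genome
    size)."""
    return 0.64 * reference_length
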
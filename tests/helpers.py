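"""Independent oracles used by the test suite.

The Smith-Waterman implementation here is a direct dynamic-programming
local aligner kept deliberately separate from the package's
seed-chain-extend path, so the two can be compared as independent routes
to the same local optimum.
"""

from __future__ import annotations

import numpy as np

MATCH = 2
MISMATCH = -3
GAP = -10


def smith_waterman(query: str, subject: str):
    """O(nm) local alignment; returns (score, q_interval, s_interval) of
    the best local alignment, half-open intervals, traceback from the
    maximum cell."""
    n, m = len(query), len(subject)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    q = np.frombuffer(query.encode(), dtype="S1")
    s = np.frombuffer(subject.encode(), dtype="S1")
    for i in range(1, n + 1):
        sub = np.where(s == q[i - 1], MATCH, MISMATCH)
        row_prev = H[i - 1]
        diag = row_prev[:-1] + sub
        up = row_prev[1:] + GAP
        row = H[i]
        # left dependency forces a scalar loop for exactness
        prev = 0
        for j in range(1, m + 1):
            best = max(0, diag[j - 1], up[j - 1], prev + GAP)
            row[j] = best
            prev = best
    i, j = np.unravel_index(np.argmax(H), H.shape)
    score = int(H[i, j])
    qi_end, si_end = int(i), int(j)
    while H[i, j] > 0:
        if H[i, j] == H[i - 1, j - 1] + (MATCH if query[i - 1] == subject[j - 1]
                                         else MISMATCH):
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + GAP:
            i -= 1
        elif H[i, j] == H[i, j - 1] + GAP:
            j -= 1
        else:  # re-started local alignment
            break
    return score, (int(i), qi_end), (int(j), si_end)


def mismatch_fraction(original: str, mutated: str) -> float:
    """Positionwise mismatch fraction for equal-length sequences."""
    assert len(original) == len(mutated)
    diffs = sum(a != b for a, b in zip(original, mutated))
    return diffs / len(original)
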
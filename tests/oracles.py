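"""Independent oracles used only by the test suite.

Each is written from first principles against the definition, not the
package's code path: a plain Smith-Waterman DP with traceback, a literal
O(n*m*w) dot-matrix enumeration, and hypergeometric tails by integer
arithmetic and by literal subset enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP.get(c, "N") for c in reversed(seq))


def smith_waterman(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Linear-gap Smith-Waterman with traceback.

    Returns (identity, a_interval, b_interval, score) for the best local
    alignment; identity counts matches over all alignment columns.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 diag, 2 up, 3 left
    best, best_pos = 0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] and a[i - 1] in "ACGT" else mismatch
            cands = (H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap, 0)
            k = int(np.argmax(cands))
            H[i, j] = cands[k]
            ptr[i, j] = (1, 2, 3, 0)[k]
            if H[i, j] > best:
                best, best_pos = int(H[i, j]), (i, j)
    i, j = best_pos
    matches = columns = 0
    ai_end, bj_end = i, j
    while i > 0 and j > 0 and H[i, j] > 0:
        p = ptr[i, j]
        if p == 1:
            matches += int(a[i - 1] == b[j - 1] and a[i - 1] in "ACGT")
            i, j = i - 1, j - 1
        elif p == 2:
            i -= 1
        elif p == 3:
            j -= 1
        else:
            break
        columns += 1
    identity = matches / columns if columns else 0.0
    return identity, (i, ai_end), (j, bj_end), best


def naive_dot_matches(a: str, b: str, window: int, limit: int,
                      reverse: bool = False):
    """Literal enumeration of all dot-matrix window matches."""
    if reverse:
        b = rc(b)
    out = set()
    for i in range(len(a) - window + 1):
        wa = a[i:i + window]
        for j in range(len(b) - window + 1):
            wb = b[j:j + window]
            mism = sum(1 for x, y in zip(wa, wb)
                       if x != y or x not in "ACGT" or y not in "ACGT")
            if mism <= limit:
                out.add((i, j))
    return out


def hypergeom_upper_tail_comb(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by exact integer arithmetic."""
    total = math.comb(N, n)
    s = sum(math.comb(K, j) * math.comb(N - K, n - j)
            for j in range(k, min(K, n) + 1))
    return s / total


def hypergeom_tails_by_enumeration(k: int, N: int, K: int, n: int):
    """(P(X <= k), P(X >= k)) by literal enumeration of all n-subsets of an
    N-element universe whose first K elements carry the label."""
    universe = range(N)
    labelled = set(range(K))
    le = ge = total = 0
    for subset in itertools.combinations(universe, n):
        x = len(labelled.intersection(subset))
        total += 1
        le += x <= k
        ge += x >= k
    return le / total, ge / total


def p_distance_sites(a: str, b: str) -> float:
    """Site-by-site p-distance of two already-aligned equal-length seqs."""
    assert len(a) == len(b)
    diff = sum(1 for x, y in zip(a, b) if x != y)
    return diff / len(a)
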
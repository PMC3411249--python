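"""Shared pairwise-alignment helpers.

All alignment in the package goes through one scoring scheme (match +1,
mismatch -1, gap open -2, gap extend -1) so that identities and p-distances
are comparable across stages.  Two identity conventions are used and kept
deliberately distinct:

* ``identity`` of a local homology hit counts matches over *all* alignment
  columns, gap columns included (the convention of BLAST-style reports);
* ``p_distance`` counts differences only over columns where both sequences
  have a base ("pairwise deletion" of gap columns), the convention used for
  divergence estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC letters preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass(frozen=True)
class AlignmentSummary:
    """Coordinates and column statistics of one pairwise alignment.

    Intervals are 0-based half-open in the *original* (unreversed) target and
    query strings that were passed to the aligning function.
    """

    target_start: int
    target_end: int
    query_start: int
    query_end: int
    matches: int
    aligned_columns: int  # columns where both sequences have a base
    total_columns: int    # aligned columns plus gap columns
    score: float
    blocks: tuple = ()    # ((t_start, t_end), (q_start, q_end)) diagonal runs

    @property
    def identity(self) -> float:
        """Matches over all columns, gaps included (BLAST-like)."""
        return self.matches / self.total_columns if self.total_columns else 0.0

    @property
    def p_distance(self) -> float:
        """Mismatch fraction over gap-free columns (pairwise deletion)."""
        if not self.aligned_columns:
            return 1.0
        return (self.aligned_columns - self.matches) / self.aligned_columns


def _summarize(alignment, target: str, query: str) -> AlignmentSummary:
    t_blocks, q_blocks = alignment.aligned
    blocks = tuple(((int(ts), int(te)), (int(qs), int(qe)))
                   for (ts, te), (qs, qe) in zip(t_blocks, q_blocks))
    return _from_blocks(blocks, target, query, float(alignment.score))


def _from_blocks(blocks, target: str, query: str,
                 score: float) -> AlignmentSummary:
    matches = 0
    aligned = 0
    gap_cols = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in blocks:
        if prev_t is not None:
            gap_cols += (ts - prev_t) + (qs - prev_q)
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b and a in "ACGT":
                matches += 1
        aligned += te - ts
        prev_t, prev_q = te, qe
    if not blocks:
        return AlignmentSummary(0, 0, 0, 0, 0, 0, 0, score)
    return AlignmentSummary(
        target_start=blocks[0][0][0],
        target_end=blocks[-1][0][1],
        query_start=blocks[0][1][0],
        query_end=blocks[-1][1][1],
        matches=int(matches),
        aligned_columns=int(aligned),
        total_columns=int(aligned + gap_cols),
        score=score,
        blocks=blocks,
    )


def _columns(blocks, target: str, query: str):
    """Flatten an alignment into per-column (is_match, t_pos, q_pos) tuples;
    gap columns carry None for the gapped side."""
    cols = []
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in blocks:
        if prev_t is not None:
            for t in range(prev_t, ts):
                cols.append((False, t, None))
            for q in range(prev_q, qs):
                cols.append((False, None, q))
        for t, q in zip(range(ts, te), range(qs, qe)):
            cols.append((target[t] == query[q] and target[t] in "ACGT", t, q))
        prev_t, prev_q = te, qe
    return cols


def trim_low_quality_ends(summary: AlignmentSummary, target: str, query: str,
                          mismatch_cost: float = 1.25, gap_cost: float = 2.25
                          ) -> AlignmentSummary | None:
    """Keep only the solid core of a local alignment.

    Local alignments over repetitive or random flanks can drift past the
    true homology by chaining short chance match islands through gaps: such
    segments score marginally above zero under the alignment's own scheme.
    Re-scoring every column slightly more harshly (match +1, mismatch
    -1.25, gap -2.25: break-even identity ~0.56 instead of 0.50) and
    keeping the maximum-scoring subsegment (Kadane) removes drifted tails
    while genuinely homologous runs, whose identity stays above ~0.75, are
    kept intact.  Returns None when nothing survives.
    """
    cols = _columns(summary.blocks, target, query)
    best_sum = cur_sum = 0.0
    best = None
    cur_start = 0
    for i, (is_match, t, q) in enumerate(cols):
        if is_match:
            s = 1.0
        elif t is None or q is None:
            s = -gap_cost
        else:
            s = -mismatch_cost
        if cur_sum <= 0:
            cur_sum, cur_start = s, i
        else:
            cur_sum += s
        if cur_sum > best_sum:
            best_sum, best = cur_sum, (cur_start, i + 1)
    if best is None:
        return None
    lo, hi = best
    # the optimal subsegment starts and ends on matches by construction
    kept = cols[lo:hi]
    blocks = []
    cur = None
    for is_match, t, q in kept:
        if t is None or q is None:
            cur = None
            continue
        if cur is not None and cur[0][1] == t and cur[1][1] == q:
            cur[0][1] = t + 1
            cur[1][1] = q + 1
        else:
            cur = [[t, t + 1], [q, q + 1]]
            blocks.append(cur)
    blocks = tuple((tuple(b[0]), tuple(b[1])) for b in blocks)
    if not blocks:
        return None
    return _from_blocks(blocks, target, query, summary.score)


def local_align(target: str, query: str) -> AlignmentSummary | None:
    """Best local alignment, or None when no positive-scoring one exists."""
    if not target or not query:
        return None
    alignments = _aligner("local").align(target, query)
    try:
        best = alignments[0]
    except IndexError:
        return None
    if best.score <= 0:
        return None
    return _summarize(best, target, query)


def global_align(a: str, b: str) -> AlignmentSummary:
    """Needleman-Wunsch global alignment of two sequences."""
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    best = _aligner("global").align(a, b)[0]
    return _summarize(best, a, b)


def global_identity(a: str, b: str) -> float:
    """Global pairwise identity with pairwise deletion of gap columns."""
    return 1.0 - global_align(a, b).p_distance


def pairwise_p_distance(a: str, b: str) -> float:
    """Uncorrected p-distance from a global alignment (pairwise deletion)."""
    return global_align(a, b).p_distance
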
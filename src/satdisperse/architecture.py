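"""Internal structure of candidate elements.

A candidate element found by the scanner is decomposed with dot-matrix
comparisons against the consensus monomers: chains of diagonal window
matches delimit tandem subunits and their subfamily, fractional copy
numbers are the sum of subunit completeness values, and inverted-repeat
structure (terminal inverted repeats, an inverted satellite arm, a unique
internal spacer, a 3-bp target-site duplication) separates transposon-like
elements from plain satellite-like arrays.

Dot matrices follow the classic dnadot conventions: a window of length w at
position (i, j) is recorded when the two subsequences differ at no more
than ``mismatch_limit`` positions; the reverse channel compares against the
reverse complement of the second sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import NamedTuple, Sequence

import numpy as np

from ._align import global_align, local_align, revcomp, trim_low_quality_ends
from .synthetic import SatelliteConsensus

logger = logging.getLogger(__name__)

_SENTINEL_A = 4
_SENTINEL_B = 5


@dataclass(frozen=True)
class DotMatrix:
    """All window matches between two sequences (forward and reverse)."""

    window: int
    mismatch_limit: int
    n_a: int
    n_b: int
    forward_matches: frozenset[tuple[int, int]]
    reverse_matches: frozenset[tuple[int, int]]


@dataclass
class SubunitAnnotation:
    """One monomer (or part of one) inside an element."""

    start: int  # element coordinates
    end: int
    subfamily: str  # "a" | "b"
    completeness: float  # fraction of the monomer covered, in (0, 1]
    orientation: str  # "+" | "-"
    n_matches: int = 0

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class TransposonFeatures:
    """Inverted-repeat hallmarks of a transposon-like element."""

    tir_left: tuple[int, int] | None = None
    tir_right: tuple[int, int] | None = None
    arm_length: int = 0
    arm_identity: float = 0.0
    inverted_satellite_segment: tuple[int, int] | None = None
    spacer: tuple[int, int] | None = None
    tsd: str | None = None
    truncated: bool = False


class Tsd(NamedTuple):
    kmer: str
    shift: int


@dataclass
class ElementCall:
    """Final per-element annotation, one row of the summary report."""

    element_id: str
    chrom: str
    start: int
    end: int
    element_class: str  # "satellite" | "transposon"
    copies: float | None
    subunits: list[SubunitAnnotation] = field(default_factory=list)
    features: TransposonFeatures | None = None
    strand: str = "+"
    aggregate_identity: float = 0.0
    flank_at: tuple[float | None, float | None] = (None, None)

    @property
    def length(self) -> int:
        return self.end - self.start


def _codes(seq: str, sentinel: int) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), sentinel, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    return out


def _window_matches(a: np.ndarray, b: np.ndarray, window: int,
                    limit: int) -> np.ndarray:
    """(i, j) pairs with <= limit mismatches, as an (n, 2) int array."""
    na = len(a) - window + 1
    nb = len(b) - window + 1
    if na <= 0 or nb <= 0:
        return np.empty((0, 2), dtype=np.int64)
    mism = np.zeros((na, nb), dtype=np.int16)
    for off in range(window):
        mism += a[off:off + na, None] != b[None, off:off + nb]
    ii, jj = np.nonzero(mism <= limit)
    return np.column_stack([ii, jj]).astype(np.int64)


def dot_matrix(seq_a: str, seq_b: str, window: int = 9,
               mismatch_limit: int = 0) -> DotMatrix:
    """Exhaustive dot-matrix of two sequences.

    Non-ACGT characters never match anything (including each other).
    Sequences shorter than the window give an empty matrix.
    """
    if window < 4:
        raise ValueError("window must be >= 4")
    if mismatch_limit >= window:
        raise ValueError("mismatch_limit must be smaller than window")
    a = _codes(seq_a, _SENTINEL_A)
    b = _codes(seq_b, _SENTINEL_B)
    fwd = _window_matches(a, b, window, mismatch_limit)
    rev = _window_matches(a, _codes(revcomp(seq_b), _SENTINEL_B),
                          window, mismatch_limit)
    return DotMatrix(
        window=window, mismatch_limit=mismatch_limit,
        n_a=len(seq_a), n_b=len(seq_b),
        forward_matches=frozenset(map(tuple, fwd)),
        reverse_matches=frozenset(map(tuple, rev)))


def _chain_diagonals(matches: np.ndarray, window: int, band: int = 10,
                     max_gap: int = 80):
    """Group window matches into diagonal chains.

    Matches are binned by diagonal d = i - j (tolerance ``band``) and split
    where consecutive matches on a diagonal are more than ``max_gap`` apart.
    Returns (i_start, i_end, j_start, j_end, n_matches) tuples with
    half-open extents that include the window length.
    """
    if not len(matches):
        return []
    d = matches[:, 0] - matches[:, 1]
    order = np.lexsort((matches[:, 0], d))
    chains = []
    current: list[np.ndarray] = []
    last_d = None
    last_i = None
    for idx in order:
        di, ii = d[idx], matches[idx, 0]
        if current and (abs(di - last_d) > band or ii - last_i > max_gap):
            chains.append(np.array(current))
            current = []
        current.append(matches[idx])
        last_d, last_i = di, ii
    if current:
        chains.append(np.array(current))
    out = []
    for ch in chains:
        i0, i1 = int(ch[:, 0].min()), int(ch[:, 0].max()) + window
        j0, j1 = int(ch[:, 1].min()), int(ch[:, 1].max()) + window
        out.append((i0, i1, j0, j1, len(ch)))
    return out


def _round_half_up(x: float, digits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0." + "0" * digits),
                                           rounding=ROUND_HALF_UP))


def segment_tandem(element_seq: str,
                   consensus_set: Sequence[SatelliteConsensus],
                   window: int = 11, mismatch_limit: int = 1,
                   min_extent: int = 25, fill_gap: int = 30,
                   min_coverage: float = 0.3
                   ) -> tuple[list[SubunitAnnotation], float]:
    """Segment an element into monomer subunits and count fractional copies.

    Diagonal chains of the element-vs-consensus dot matrix (both subfamilies,
    both orientations) delimit subunits; overlap conflicts are resolved in
    favour of denser chains.  Subunit boundaries are then extended across
    small unmatched gaps (<= ``fill_gap`` bp, the jitter left by diverged
    window matches) so that completeness reflects the architecture rather
    than the mutation load.  ``copies`` is the sum of completeness values,
    rounded half-up to one decimal.  If no chain covers at least
    ``min_coverage`` of a monomer the element has no recognisable subunit
    structure and (, 0.0) is returned.
    """
    raw = []
    for cons in consensus_set:
        dm = dot_matrix(element_seq, cons.sequence, window, mismatch_limit)
        fwd = np.array(sorted(dm.forward_matches)).reshape(-1, 2)
        rev = np.array(sorted(dm.reverse_matches)).reshape(-1, 2)
        for i0, i1, j0, j1, n in _chain_diagonals(fwd, window):
            raw.append(SubunitAnnotation(i0, i1, cons.subfamily,
                                         (j1 - j0) / cons.monomer_length,
                                         "+", n))
        for i0, i1, j0, j1, n in _chain_diagonals(rev, window):
            raw.append(SubunitAnnotation(i0, i1, cons.subfamily,
                                         (j1 - j0) / cons.monomer_length,
                                         "-", n))
    # demand a minimum chain density: genuine monomer homology leaves at
    # least ~1 window match per 20 bp even at the highest divergences
    # handled here, while chance diagonal runs are far sparser
    raw = [s for s in raw
           if s.end - s.start >= min_extent
           and s.n_matches >= 3
           and s.n_matches >= 0.05 * (s.end - s.start)]
    if not raw or not any(s.completeness >= min_coverage for s in raw):
        return [], 0.0

    # resolve overlaps: denser chains win
    accepted: list[SubunitAnnotation] = []
    for s in sorted(raw, key=lambda s: -s.n_matches):
        own = s.end - s.start
        clash = any(
            min(s.end, t.end) - max(s.start, t.start) > 0.2 * own
            for t in accepted)
        if not clash:
            accepted.append(s)
    accepted.sort(key=lambda s: s.start)

    # trim residual overlaps, then absorb small gaps left by diverged windows
    for prev, nxt in zip(accepted, accepted[1:]):
        if nxt.start < prev.end:
            mid = (prev.end + nxt.start) // 2
            prev.end, nxt.start = mid, mid
    n = len(element_seq)
    if accepted and accepted[0].start <= fill_gap:
        accepted[0].start = 0
    if accepted and n - accepted[-1].end <= fill_gap:
        accepted[-1].end = n
    for prev, nxt in zip(accepted, accepted[1:]):
        gap = nxt.start - prev.end
        if 0 < gap <= fill_gap:
            mid = prev.end + gap // 2
            prev.end, nxt.start = mid, mid

    by_sub = {c.subfamily: c for c in consensus_set}
    for s in accepted:
        sub_seq = element_seq[s.start:s.end]
        if s.orientation == "-":
            sub_seq = revcomp(sub_seq)
        if len(by_sub) == 2 and s.completeness >= min_coverage:
            s.subfamily = assign_subfamily(sub_seq, by_sub["a"], by_sub["b"])
        mono = by_sub[s.subfamily].monomer_length
        s.completeness = min(1.0, (s.end - s.start) / mono)
    copies = _round_half_up(sum(s.completeness for s in accepted))
    return accepted, copies


def assign_subfamily(subunit_seq: str, consensus_a: SatelliteConsensus,
                     consensus_b: SatelliteConsensus) -> str:
    """Label a subunit with the consensus of smaller p-distance (tie -> a).

    Uses a global alignment so the whole subunit is forced against each
    consensus; a local alignment would let a chimeric subunit match only
    its easiest fragment and report a misleadingly small distance.
    """
    best = ("a", 2.0)
    for cons in (consensus_a, consensus_b):
        p = global_align(subunit_seq, cons.sequence).p_distance
        if p < best[1]:
            best = (cons.subfamily, p)
    return best[0]


def find_inverted_arms(seq: str, min_arm: int = 25,
                       min_identity: float = 0.80,
                       max_span: int | None = None):
    """Best pair of reverse-complementary arms in a sequence.

    Aligns the left part of the sequence against the reverse complement of
    the right part; returns (left_interval, right_interval, arm_length,
    identity) in forward coordinates, or None.  ``max_span`` bounds how far
    from each end the arms may reach (default: the half-length).
    """
    n = len(seq)
    span = min(n, max_span) if max_span else (n + 1) // 2
    left = seq[:span]
    right_rc = revcomp(seq[n - span:])
    summ = local_align(left, right_rc)
    if summ is not None:
        summ = trim_low_quality_ends(summ, left, right_rc)
    if summ is None:
        return None
    if summ.total_columns < min_arm or summ.identity < min_identity:
        return None
    left_iv = (summ.target_start, summ.target_end)
    right_iv = (n - summ.query_end, n - summ.query_start)
    if left_iv[1] > right_iv[0]:  # arms must not cross
        return None
    return left_iv, right_iv, summ.total_columns, summ.identity


def detect_tirs(element_seq: str, min_arm: int = 25,
                min_arm_identity: float = 0.80,
                max_span: int | None = None) -> TransposonFeatures | None:
    """Terminal inverted repeats: the best reverse-complementary arm pair
    whose outer ends fall within 40 bp of the element ends."""
    arms = find_inverted_arms(element_seq, min_arm, min_arm_identity, max_span)
    if arms is None:
        return None
    left_iv, right_iv, arm_len, identity = arms
    n = len(element_seq)
    if left_iv[0] > 40 or n - right_iv[1] > 40:
        return None
    return TransposonFeatures(tir_left=left_iv, tir_right=right_iv,
                              arm_length=arm_len, arm_identity=identity)


_SHIFTS = (0, -1, 1, -2, 2)


def detect_tsd(chrom_seq: str, element_interval: tuple[int, int],
               tsd_len: int = 3) -> Tsd | None:
    """Target-site duplication flanking an element.

    The element boundary pair is probed as a block at shifts 0, +/-1, +/-2
    (smallest |shift| first, negative before positive) and the first exact
    flanking k-mer duplication is returned with the shift that produced it.
    """
    start, end = element_interval
    n = len(chrom_seq)
    if start - tsd_len - 2 < 0 or end + tsd_len + 2 > n:
        logger.warning("element at contig edge, TSD not assessable")
        return None
    for shift in _SHIFTS:
        s, e = start + shift, end + shift
        left = chrom_seq[s - tsd_len:s].upper()
        right = chrom_seq[e:e + tsd_len].upper()
        if left == right and set(left) <= set("ACGT"):
            return Tsd(left, shift)
    return None


def classify(subunits: list[SubunitAnnotation],
             features: TransposonFeatures | None,
             min_spacer: int = 100) -> str:
    """Satellite-like array or transposon-like unit.

    Transposon iff subunits of both orientations are separated by a
    non-satellite internal spacer of at least ``min_spacer`` bp, or a TIR
    pair was detected with an arm overlapping a satellite subunit.
    """
    orientations = {s.orientation for s in subunits}
    if orientations == {"+", "-"}:
        ordered = sorted(subunits, key=lambda s: s.start)
        max_gap = max((nxt.start - prev.end
                       for prev, nxt in zip(ordered, ordered[1:])), default=0)
        if max_gap >= min_spacer:
            return "transposon"
    if features is not None and features.tir_left and features.tir_right:
        for arm in (features.tir_left, features.tir_right):
            if any(min(arm[1], s.end) - max(arm[0], s.start) > 0
                   for s in subunits):
                return "transposon"
    return "satellite"


def transposon_features(element_seq: str, subunits, tir_features,
                        min_spacer: int = 100) -> TransposonFeatures:
    """Assemble the feature record of a transposon-like call: the inverted
    satellite segment, the unique internal spacer, and the truncation flag
    (no qualifying TIR pair at both ends)."""
    feats = tir_features or TransposonFeatures()
    minus = [s for s in sorted(subunits, key=lambda s: s.start)
             if s.orientation == "-"]
    plus = [s for s in subunits if s.orientation == "+"]
    if minus and plus:
        # the minority orientation is the inverted arm
        minority = minus if sum(s.end - s.start for s in minus) <= \
            sum(s.end - s.start for s in plus) else plus
        seg = max(minority, key=lambda s: s.end - s.start)
        feats.inverted_satellite_segment = seg.interval
    ordered = sorted(subunits, key=lambda s: s.start)
    best_gap = None
    for prev, nxt in zip(ordered, ordered[1:]):
        gap = nxt.start - prev.end
        if gap >= min_spacer and (best_gap is None or gap > best_gap[1] - best_gap[0]):
            best_gap = (prev.end, nxt.start)
    feats.spacer = best_gap
    # intact TIRs include unique (non-satellite) tails outboard of the
    # satellite arms; arm pairs made of satellite sequence alone mean the
    # unique TIR portions were lost
    intact = False
    if feats.tir_left and feats.tir_right and ordered:
        first_sat = min(s.start for s in ordered)
        last_sat = max(s.end for s in ordered)
        intact = (feats.tir_left[0] <= first_sat - 20 and
                  feats.tir_right[1] >= last_sat + 20)
    feats.truncated = not intact
    return feats


def flank_at_content(chrom_seq: str, element_interval: tuple[int, int],
                     flank: int = 100) -> tuple[float | None, float | None]:
    """A+T fraction of the two flanks (truncated at contig ends;
    None when no flanking base is available)."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    start, end = element_interval

    def at(seq: str) -> float | None:
        if not seq:
            return None
        seq = seq.upper()
        return (seq.count("A") + seq.count("T")) / len(seq)

    return (at(chrom_seq[max(0, start - flank):start]),
            at(chrom_seq[end:end + flank]))
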
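"""Seed-and-extend homology scan for satellite monomers in a genome.

The scanner mirrors a megablast-style search specialised to short tandem
queries: exact k-mer seeds on both strands are clustered into candidate
regions, each region is locally aligned against every consensus variant,
and alignments are peeled off iteratively (mask-and-realign) so that every
monomer copy of a tandem array yields its own hit.  Hits are then merged
into candidate elements when their genomic gap is short, and candidates are
subjected to the survey's length (>= 140 nt) and identity (> 80 %) filters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from ._align import local_align, revcomp, trim_low_quality_ends
from .synthetic import SatelliteConsensus

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


@dataclass(frozen=True)
class HomologyHit:
    """One locally aligned monomer copy on the plus strand of a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str
    identity: float
    query_name: str
    query_start: int  # consensus forward coordinates
    query_end: int
    score: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("empty hit interval")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CandidateElement:
    """Co-linear nearby hits merged into one candidate element."""

    chrom: str
    start: int
    end: int
    strand: str
    aggregate_identity: float
    member_hits: list[HomologyHit] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int):
    """Packed k-mer codes and a validity mask (windows free of non-ACGT)."""
    n = len(codes)
    if n < k:
        return np.empty(0, np.int64), np.empty(0, bool)
    valid = codes < 4
    cs = np.concatenate([[0], np.cumsum(valid)])
    window_valid = (cs[k:] - cs[:-k]) == k
    vals = np.where(valid, codes, 0).astype(np.int64)
    out = np.zeros(n - k + 1, dtype=np.int64)
    for i in range(k):
        out = (out << 2) if i else out
        out += vals[i:n - k + 1 + i]
    return out, window_valid


def _normalize_consensus(consensus_set) -> list[SatelliteConsensus]:
    out = []
    for i, c in enumerate(consensus_set):
        if isinstance(c, SatelliteConsensus):
            out.append(c)
        else:
            name, seq = c
            subfam = name[-1] if name and name[-1] in "ab" else "ab"[i % 2]
            out.append(SatelliteConsensus(name, seq.upper(), subfam,
                                          (0, len(seq))))
    return out


def scan(genome: dict[str, str], consensus_set, k: int = 11,
         x_drop: float = 20.0, min_identity: float = 0.5,
         min_seeds: int = 2, cluster_gap: int = 150,
         margin: int = 400) -> list[HomologyHit]:
    """Find satellite-homologous segments on both strands of a genome.

    Parameters
    ----------
    genome : mapping of chromosome name to sequence.
    consensus_set : iterable of SatelliteConsensus or (name, seq) pairs.
    k : exact seed length (>= 8).
    x_drop : score floor below which region re-alignment stops.
    min_identity : hits below this identity are discarded pre-merge.
    min_seeds : seeds required before a region is aligned.
    cluster_gap : maximum seed spacing within one region.
    margin : region extension beyond the outermost seeds, in bp.
    """
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    consensus_set = _normalize_consensus(consensus_set)
    variants = []
    for cons in consensus_set:
        variants.append((cons.name, cons.sequence, "+"))
        variants.append((cons.name, revcomp(cons.sequence), "-"))
    if not genome or not variants or all(not v[1] for v in variants):
        return []

    lookup = np.zeros(4 ** k, dtype=bool)
    for _, qseq, _ in variants:
        qcodes, qvalid = _kmer_codes(_encode(qseq), k)
        lookup[qcodes[qvalid]] = True

    hits: list[HomologyHit] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        codes, valid = _kmer_codes(_encode(seq), k)
        if not len(codes):
            continue
        seed_pos = np.nonzero(valid & lookup[codes])[0]
        if not len(seed_pos):
            continue
        breaks = np.nonzero(np.diff(seed_pos) > cluster_gap)[0]
        clusters = np.split(seed_pos, breaks + 1)
        for cluster in clusters:
            if len(cluster) < min_seeds:
                continue
            rs = max(0, int(cluster[0]) - margin)
            re_ = min(len(seq), int(cluster[-1]) + k + margin)
            hits.extend(_align_region(seq, chrom, rs, re_, variants,
                                      x_drop, min_identity))
    hits = _dedupe_overlaps(hits)
    return sorted(hits, key=lambda h: (h.chrom, h.start, h.end))


def _align_region(seq, chrom, rs, re_, variants, x_drop, min_identity,
                  max_rounds: int = 40):
    """Iteratively peel local alignments off one region (mask-and-realign)."""
    region = list(seq[rs:re_])
    found = []
    for _ in range(max_rounds):
        region_str = "".join(region)
        best = None
        for qname, qseq, strand in variants:
            summ = local_align(region_str, qseq)
            if summ is None:
                continue
            if best is None or summ.score > best[0].score:
                best = (summ, qname, qseq, strand)
        if best is None or best[0].score < x_drop:
            break
        summ, qname, qseq, strand = best
        mask_start, mask_end = summ.target_start, summ.target_end
        trimmed = trim_low_quality_ends(summ, region_str, qseq)
        if trimmed is not None:
            summ = trimmed
        qlen = len(qseq)
        if strand == "+":
            q_start, q_end = summ.query_start, summ.query_end
        else:  # convert from reverse-complement to consensus coordinates
            q_start, q_end = qlen - summ.query_end, qlen - summ.query_start
        if summ.identity >= min_identity:
            found.append(HomologyHit(
                chrom=chrom, start=rs + summ.target_start,
                end=rs + summ.target_end, strand=strand,
                identity=summ.identity, query_name=qname,
                query_start=q_start, query_end=q_end, score=summ.score))
        for i in range(mask_start, mask_end):
            region[i] = "\0"  # mask so the next round finds the next copy
    return found


def _dedupe_overlaps(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Drop the weaker of two hits covering the same locus (>50 % overlap);
    ties keep the plus strand."""
    kept: list[HomologyHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.strand, h.chrom, h.start)):
        conflict = False
        for other in kept:
            if other.chrom != h.chrom:
                continue
            inter = min(h.end, other.end) - max(h.start, other.start)
            if inter > 0 and inter > 0.5 * min(h.length, other.length):
                conflict = True
                break
        if not conflict:
            kept.append(h)
    return kept


def merge_hits(hits: list[HomologyHit], max_gap: int = 150
               ) -> list[CandidateElement]:
    """Merge same-chromosome hits whose genomic gap is at most *max_gap*.

    A monomer-sized query makes any restart or continuation of the query
    span consistent with a tandem array, so the genomic gap is the only
    merge criterion; internal continuity is re-validated downstream by
    dot-matrix segmentation.  Aggregate identity is the length-weighted
    mean over members; the operation is idempotent.
    """
    elements: list[CandidateElement] = []
    for chrom, group in itertools.groupby(
            sorted(hits, key=lambda h: (h.chrom, h.start, h.end)),
            key=lambda h: h.chrom):
        members: list[HomologyHit] = []
        for hit in group:
            if members and hit.start - max(m.end for m in members) <= max_gap:
                members.append(hit)
            else:
                if members:
                    elements.append(_finalize(chrom, members))
                members = [hit]
        if members:
            elements.append(_finalize(chrom, members))
    return elements


def _finalize(chrom: str, members: list[HomologyHit]) -> CandidateElement:
    # trim members so they do not overlap one another
    trimmed: list[HomologyHit] = []
    for m in sorted(members, key=lambda h: (h.start, h.end)):
        if trimmed and m.start < trimmed[-1].end:
            if m.end <= trimmed[-1].end:
                continue
            m = replace(m, start=trimmed[-1].end)
        trimmed.append(m)
    total = sum(m.length for m in trimmed)
    identity = sum(m.identity * m.length for m in trimmed) / total
    by_strand = {"+": 0, "-": 0}
    for m in trimmed:
        by_strand[m.strand] += m.length
    strand = "+" if by_strand["+"] >= by_strand["-"] else "-"
    return CandidateElement(
        chrom=chrom, start=min(m.start for m in trimmed),
        end=max(m.end for m in trimmed), strand=strand,
        aggregate_identity=identity, member_hits=trimmed)


def filter_elements(candidates: list[CandidateElement], min_len: int = 140,
                    min_identity: float = 0.80) -> list[CandidateElement]:
    """Apply the survey's filters: length >= min_len AND identity strictly
    greater than min_identity.  Order is preserved."""
    return [c for c in candidates
            if c.length >= min_len and c.aggregate_identity > min_identity]


def write_bed(elements, path) -> None:
    """Write calls as BED6 (name = element id, score = identity x 1000)."""
    with open(path, "w") as fh:
        for i, e in enumerate(elements, 1):
            name = getattr(e, "element_id", f"elem{i:03d}")
            ident = getattr(e, "aggregate_identity", None)
            if ident is None:
                ident = getattr(e, "identity", 0.0)
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{name}\t"
                     f"{int(round(ident * 1000))}\t{e.strand}\n")
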
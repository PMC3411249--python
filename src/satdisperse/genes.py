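"""Element-to-gene relations: intron containment and flanking distances.

Gene models come from GFF3 (1-based closed coordinates, converted to
0-based half-open internally).  The "intron" of a gene is a gap between
consecutive exons of its representative (longest) transcript.  An element's
5' and 3' sides are defined on the plus strand of the chromosome (upstream
= lower coordinate); the strand of the neighbouring gene does not flip
element sidedness, and distances are measured boundary-to-boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gffutils


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with the exon structure of its representative
    transcript (0-based half-open coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        for (s, e) in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"exon outside gene {self.gene_id}")
        if list(self.exons) != sorted(self.exons):
            raise ValueError(f"exons of {self.gene_id} not sorted")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])
                     if b[0] > a[1])


@dataclass
class Association:
    """Relation of one element to its neighbouring or host genes."""

    element_id: str
    relation: str  # inside | flanked | single_flank_5 | single_flank_3 | isolated
    gene_5: str | None = None
    dist_5: int | None = None
    gene_3: str | None = None
    dist_3: int | None = None
    intron_host: str | None = None
    exonic_overlap: bool = False


def load_gene_models(gff3_path) -> list[GeneModel]:
    """Parse a GFF3 file into GeneModel records.

    The representative transcript is the mRNA with the largest summed exon
    length; single-exon genes without mRNA/exon children use the gene span.
    """
    db = gffutils.create_db(str(gff3_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    models = []
    for gene in db.features_of_type("gene"):
        best_exons = None
        best_len = -1
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted((e.start - 1, e.end)
                           for e in db.children(mrna, featuretype="exon"))
            total = sum(e - s for s, e in exons)
            if exons and total > best_len:
                best_exons, best_len = exons, total
        if best_exons is None:
            exons = sorted((e.start - 1, e.end)
                           for e in db.children(gene, featuretype="exon"))
            best_exons = exons or [(gene.start - 1, gene.end)]
        models.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid,
            start=gene.start - 1, end=gene.end,
            strand=gene.strand, exons=tuple(best_exons)))
    return sorted(models, key=lambda g: (g.chrom, g.start))


def associate(element, genes: list[GeneModel]) -> Association:
    """Relate one element to the gene models of its chromosome.

    An element lying entirely inside one intron is "inside"; otherwise the
    nearest gene ending before the element is its 5' neighbour and the
    nearest gene starting after it is its 3' neighbour, with boundary-gap
    distances.  Elements overlapping an exon are flagged and conservatively
    treated as inside their host gene.
    """
    eid = getattr(element, "element_id", None) or "element"
    chrom = element.chrom
    start, end = element.start, element.end
    same = [g for g in genes if g.chrom == chrom]

    for g in same:
        if g.start <= start and end <= g.end:
            for (is_, ie) in g.introns:
                if is_ <= start and end <= ie:
                    return Association(eid, "inside", intron_host=g.gene_id)
            warnings.warn(
                f"{eid} overlaps an exon of {g.gene_id}; flagged exonic_overlap "
                "and treated as inside")
            return Association(eid, "inside", intron_host=g.gene_id,
                               exonic_overlap=True)

    exonic = any(g.start < end and start < g.end for g in same)
    left = [g for g in same if g.end <= start]
    right = [g for g in same if g.start >= end]
    gene_5 = max(left, key=lambda g: g.end) if left else None
    gene_3 = min(right, key=lambda g: g.start) if right else None
    assoc = Association(eid, "isolated", exonic_overlap=exonic)
    if gene_5 is not None:
        assoc.gene_5, assoc.dist_5 = gene_5.gene_id, start - gene_5.end
    if gene_3 is not None:
        assoc.gene_3, assoc.dist_3 = gene_3.gene_id, gene_3.start - end
    if gene_5 and gene_3:
        assoc.relation = "flanked"
    elif gene_5:
        assoc.relation = "single_flank_5"
    elif gene_3:
        assoc.relation = "single_flank_3"
    if exonic:
        warnings.warn(f"{eid} partially overlaps a gene; flagged exonic_overlap")
    return assoc


def summarize_associations(associations: list[Association]) -> dict[str, int]:
    """Counts of association classes plus the number of distinct genes
    (one gene adjacent to two elements counts once)."""
    genes = set()
    counts = {"total": len(associations), "flanked_both": 0,
              "single_flank": 0, "inside": 0}
    for a in associations:
        if a.relation == "inside":
            counts["inside"] += 1
        elif a.relation == "flanked":
            counts["flanked_both"] += 1
        elif a.relation.startswith("single_flank"):
            counts["single_flank"] += 1
        for g in (a.gene_5, a.gene_3, a.intron_host):
            if g is not None:
                genes.add(g)
    counts["distinct_genes"] = len(genes)
    return counts
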
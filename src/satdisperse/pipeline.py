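"""End-to-end orchestration: scan -> merge -> filter -> architecture ->
association -> statistics, plus the summary of the published element table.

Boundary refinement deserves a note.  The scanner only sees satellite
homology, but a transposon-like unit also contains unique non-satellite
sequence (TIR tails and an internal spacer).  After filtering, each
candidate is therefore (1) joined with any nearby raw hits, inverted ones
included, and (2) probed for a reverse-complementary arm pair in a window
around the joined span; when a qualifying arm pair is found the element
boundaries are extended to the outer arm ends, which recovers the unique
TIR portions exactly as a dot-plot inspection of the locus would.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from . import architecture as arch
from . import genes as genes_mod
from . import satscan
from . import stats as stats_mod
from .synthetic import (SatelliteConsensus, Table1Row, load_table1_fixture,
                        MONOMER_LEN_A, MONOMER_LEN_B)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and element id."""

    def __init__(self, stage: str, element_id: str | None, cause: Exception):
        self.stage = stage
        self.element_id = element_id
        msg = f"stage {stage!r} failed"
        if element_id:
            msg += f" on element {element_id}"
        super().__init__(f"{msg}: {cause}")


@dataclass
class PipelineConfig:
    """Paths and thresholds of one pipeline run."""

    genome: str
    consensus: str
    gff3: str | None = None
    annotations: str | None = None
    outdir: str = "satdisperse_out"
    min_len: int = 140
    min_identity: float = 0.80
    max_gap: int = 150
    k: int = 11
    x_drop: float = 20.0
    window: int = 11
    mismatch_limit: int = 1
    tir_min_arm: int = 50
    tir_min_identity: float = 0.70
    tsd_len: int = 3
    flank: int = 100
    join_window: int = 400
    refine_margin: int = 300
    min_spacer: int = 100
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self):
        for name in ("min_len", "max_gap", "k", "window", "tsd_len", "flank"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"threshold {name} must be positive")
        for name in ("genome", "consensus"):
            if not Path(getattr(self, name)).exists():
                raise ConfigError(f"{name} path does not exist: "
                                  f"{getattr(self, name)}")
        for name in ("gff3", "annotations"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")


@dataclass
class SummaryReport:
    """Aggregated pipeline (or fixture) results."""

    totals: dict = field(default_factory=dict)
    extremes: dict = field(default_factory=dict)
    per_chromosome: dict = field(default_factory=dict)
    per_element: list = field(default_factory=list)
    associations: list = field(default_factory=list)
    chromosome_tests: list = field(default_factory=list)
    enrichment: list = field(default_factory=list)
    divergence: dict = field(default_factory=dict)

    def check_consistency(self):
        """Recompute totals from per-element rows and compare."""
        t = self.totals
        if t.get("elements") != len(self.per_element):
            raise AssertionError("total inconsistent with per-element rows")
        n_sat = sum(1 for r in self.per_element
                    if r["element_class"] == "satellite")
        if t.get("satellite") != n_sat or \
                t.get("transposon") != t["elements"] - n_sat:
            raise AssertionError("class totals inconsistent")
        if self.associations:
            pos = t.get("inside", 0) + t.get("flanked_both", 0) + \
                t.get("single_flank", 0) + t.get("isolated", 0)
            if pos != t["elements"]:
                raise AssertionError("positional totals inconsistent")
        return True


def load_consensus_fasta(path) -> list[SatelliteConsensus]:
    records = list(SeqIO.parse(str(path), "fasta"))
    out = []
    for i, rec in enumerate(records):
        name = rec.id
        sub = name[-1] if name[-1] in "ab" else "ab"[i % 2]
        out.append(SatelliteConsensus(name, str(rec.seq).upper(), sub,
                                      (0, len(rec.seq))))
    return out


def _refine_candidate(chrom_seq: str, candidate, all_hits, config):
    """Join nearby hits and extend boundaries over a detected TIR arm pair."""
    start, end = candidate.start, candidate.end
    strands = set()
    for h in all_hits:
        if h.chrom != candidate.chrom:
            continue
        if h.identity < 0.75 or h.score < 40:
            continue  # weak chance hits must not drag boundaries
        joined = False
        if h.start >= end and h.start - end <= config.join_window:
            end = max(end, h.end)
            joined = True
        elif h.end <= start and start - h.end <= config.join_window:
            start = min(start, h.start)
            joined = True
        elif h.start < end and h.end > start:
            start, end = min(start, h.start), max(end, h.end)
            joined = True
        if joined:
            strands.add(h.strand)
    if strands != {"+", "-"}:
        # no inverted satellite content at this locus: a plain tandem
        # array has no TIR tails to recover, and a chance inverted match
        # in the flanks must not drag the boundaries
        return start, end
    ws = max(0, start - config.refine_margin)
    we = min(len(chrom_seq), end + config.refine_margin)
    window_seq = chrom_seq[ws:we]
    arms = arch.find_inverted_arms(window_seq, min_arm=config.tir_min_arm,
                                   min_identity=config.tir_min_identity)
    if arms is not None:
        left_iv, right_iv, _, _ = arms
        al, ar = ws + left_iv[0], ws + right_iv[1]
        # only accept arms anchored on the satellite span itself
        overlaps_span = (ws + left_iv[1] > start and ws + left_iv[0] < end) or \
                        (ws + right_iv[1] > start and ws + right_iv[0] < end)
        if overlaps_span:
            start, end = min(start, al), max(end, ar)
    return start, end


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Execute all stages on one genome and write reports to the outdir.

    Deterministic for a fixed configuration; any stage failure raises
    StageError naming the stage (and element, when known).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings = {}

    def _stage(name, fn, element_id=None):
        t = time.time()
        try:
            result = fn()
        except (ConfigError, StageError):
            raise
        except Exception as exc:
            raise StageError(name, element_id, exc) from exc
        timings[name] = round(time.time() - t, 3)
        return result

    genome = _stage("load_genome", lambda: {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(config.genome, "fasta")})
    consensus = _stage("load_consensus",
                       lambda: load_consensus_fasta(config.consensus))

    hits = _stage("scan", lambda: satscan.scan(
        genome, consensus, k=config.k, x_drop=config.x_drop))
    candidates = _stage("merge", lambda: satscan.merge_hits(
        hits, max_gap=config.max_gap))
    kept = _stage("filter", lambda: satscan.filter_elements(
        candidates, min_len=config.min_len, min_identity=config.min_identity))

    calls: list[arch.ElementCall] = []
    claimed: dict[str, list[tuple[int, int]]] = {}
    for cand in kept:
        chrom_seq = genome[cand.chrom]
        start, end = _stage(
            "refine", lambda: _refine_candidate(chrom_seq, cand, hits, config))
        if any(start < e and s < end for s, e in claimed.get(cand.chrom, [])):
            continue  # locus already claimed by a neighbouring candidate
        claimed.setdefault(cand.chrom, []).append((start, end))
        eid = f"{cand.chrom}:{start}-{end}"
        elem_seq = chrom_seq[start:end]

        def _architecture():
            subunits, copies = arch.segment_tandem(
                elem_seq, consensus, window=config.window,
                mismatch_limit=config.mismatch_limit)
            tirs = arch.detect_tirs(elem_seq, min_arm=config.tir_min_arm,
                                    min_arm_identity=config.tir_min_identity)
            cls = arch.classify(subunits, tirs, min_spacer=config.min_spacer)
            features = None
            if cls == "transposon":
                features = arch.transposon_features(
                    elem_seq, subunits, tirs, min_spacer=config.min_spacer)
                tsd = arch.detect_tsd(chrom_seq, (start, end),
                                      tsd_len=config.tsd_len)
                features.tsd = tsd.kmer if tsd else None
            return subunits, copies, cls, features

        subunits, copies, cls, features = _stage("architecture", _architecture,
                                                 element_id=eid)
        calls.append(arch.ElementCall(
            element_id=eid, chrom=cand.chrom, start=start, end=end,
            element_class=cls, copies=copies if cls == "satellite" else None,
            subunits=subunits, features=features, strand=cand.strand,
            aggregate_identity=cand.aggregate_identity,
            flank_at=arch.flank_at_content(chrom_seq, (start, end),
                                           flank=config.flank)))
    calls.sort(key=lambda c: (c.chrom, c.start))
    for i, c in enumerate(calls, 1):
        c.element_id = f"E{i:03d}"

    associations = []
    gene_models = []
    if config.gff3:
        gene_models = _stage("load_genes",
                             lambda: genes_mod.load_gene_models(config.gff3))
        associations = _stage("associate", lambda: [
            genes_mod.associate(c, gene_models) for c in calls])

    report = _build_report(calls, associations, genome, gene_models, config)
    _stage("statistics", lambda: _add_statistics(
        report, calls, genome, consensus, associations, config))
    _stage("write", lambda: _write_outputs(report, calls, associations,
                                           config, outdir, timings, t0))
    return report


def _build_report(calls, associations, genome, gene_models, config):
    report = SummaryReport()
    n_sat = sum(1 for c in calls if c.element_class == "satellite")
    report.totals = {
        "elements": len(calls), "satellite": n_sat,
        "transposon": len(calls) - n_sat,
    }
    if associations:
        summary = genes_mod.summarize_associations(associations)
        report.totals.update(
            flanked_both=summary["flanked_both"],
            single_flank=summary["single_flank"],
            inside=summary["inside"],
            isolated=sum(1 for a in associations if a.relation == "isolated"),
            distinct_genes=summary["distinct_genes"])
    sat_lengths = [c.length for c in calls if c.element_class == "satellite"]
    tra_lengths = [c.length for c in calls if c.element_class == "transposon"]
    dists = [d for a in associations for d in (a.dist_5, a.dist_3)
             if d is not None]
    copies = [c.copies for c in calls if c.copies is not None]
    report.extremes = {
        "min_satellite_length": min(sat_lengths, default=None),
        "max_satellite_length": max(sat_lengths, default=None),
        "min_transposon_length": min(tra_lengths, default=None),
        "max_transposon_length": max(tra_lengths, default=None),
        "transposons_ge_1kb": sum(1 for l in tra_lengths if l >= 1000),
        "min_gene_distance": min(dists, default=None),
        "max_gene_distance": max(dists, default=None),
        "max_copies": max(copies, default=None),
    }
    per_chrom = {}
    for c in calls:
        per_chrom[c.chrom] = per_chrom.get(c.chrom, 0) + 1
    report.per_chromosome = per_chrom
    report.per_element = [{
        "element_id": c.element_id, "chrom": c.chrom, "start": c.start,
        "end": c.end, "strand": c.strand, "element_class": c.element_class,
        "length": c.length, "copies": c.copies,
        "identity": round(float(c.aggregate_identity), 4),
        "n_subunits": len(c.subunits),
        "tir_arm_len": int(c.features.arm_length) if c.features else None,
        "tsd": c.features.tsd if c.features else None,
        "truncated": c.features.truncated if c.features else None,
        "flank_at_5": None if c.flank_at[0] is None else round(c.flank_at[0], 3),
        "flank_at_3": None if c.flank_at[1] is None else round(c.flank_at[1], 3),
    } for c in calls]
    report.associations = associations
    return report


def _add_statistics(report, calls, genome, consensus, associations, config):
    if calls:
        weights = {c: len(genome[c]) / sum(map(len, genome.values()))
                   for c in genome}
        counts = {c: 0 for c in genome}
        for call in calls:
            counts[call.chrom] += 1
        report.chromosome_tests = stats_mod.chromosome_distribution_test(
            counts, weights)
    # per-subfamily mean pairwise divergence of plus-strand satellite subunits
    for subfam in ("a", "b"):
        seqs = []
        for call in calls:
            if call.element_class != "satellite":
                continue
            chrom_seq = genome[call.chrom]
            for i, s in enumerate(call.subunits):
                if s.subfamily == subfam and s.orientation == "+" \
                        and s.completeness >= 0.3:
                    seqs.append((f"{call.element_id}_{i + 1}",
                                 chrom_seq[call.start + s.start:
                                           call.start + s.end]))
        seqs = seqs[:28]
        if len(seqs) >= 2:
            dm = stats_mod.p_distance_matrix(seqs)
            report.divergence[subfam] = round(dm.mean_pairwise, 4)
    if config.annotations and associations:
        annotation_map = {}
        with open(config.annotations) as fh:
            for line in fh:
                if line.strip():
                    gid, cat = line.rstrip("\n").split("\t")[:2]
                    annotation_map[gid] = cat
        background = list(annotation_map)
        gene_set = {g for a in associations
                    for g in (a.gene_5, a.gene_3, a.intron_host) if g}
        gene_set &= set(background)
        if gene_set:
            report.enrichment = stats_mod.category_enrichment(
                gene_set, annotation_map, background)


def _write_outputs(report, calls, associations, config, outdir, timings, t0):
    satscan.write_bed(calls, outdir / "elements.bed")
    with open(outdir / "elements.tsv", "w") as fh:
        cols = ["element_id", "chrom", "start", "end", "strand",
                "element_class", "length", "copies", "identity", "n_subunits",
                "tir_arm_len", "tsd", "truncated", "flank_at_5", "flank_at_3"]
        fh.write("\t".join(cols) + "\n")
        for row in report.per_element:
            fh.write("\t".join(
                "" if row[c] is None else str(row[c]) for c in cols) + "\n")
    if associations:
        with open(outdir / "associations.tsv", "w") as fh:
            fh.write("element_id\trelation\tgene_5\tdist_5\tgene_3\tdist_3\t"
                     "intron_host\n")
            for a in associations:
                fh.write("\t".join("" if v is None else str(v) for v in (
                    a.element_id, a.relation, a.gene_5, a.dist_5, a.gene_3,
                    a.dist_3, a.intron_host)) + "\n")
    if report.chromosome_tests:
        with open(outdir / "chromosome_test.tsv", "w") as fh:
            fh.write("chrom\tobserved\tbackground_weight\tp_two_tailed\t"
                     "p_bonferroni\tsignificant\n")
            for r in report.chromosome_tests:
                fh.write(f"{r.chrom}\t{r.observed}\t{r.background_weight:.6f}\t"
                         f"{r.p_two_tailed:.6g}\t{r.p_bonferroni:.6g}\t"
                         f"{int(r.significant)}\n")
    if report.enrichment:
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write("category\tk\tn\tK\tN\tp_raw\tp_corrected\n")
            for r in report.enrichment:
                fh.write(f"{r.category}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                         f"{r.p_raw:.6g}\t{r.p_corrected:.6g}\n")
    summary = {"totals": report.totals, "extremes": report.extremes,
               "per_chromosome": report.per_chromosome,
               "divergence": report.divergence}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "run.log", "w") as fh:
        fh.write("parameters:\n")
        for f_ in dataclasses.fields(config):
            fh.write(f"  {f_.name}: {getattr(config, f_.name)}\n")
        fh.write("stage_timings_s:\n")
        for stage, dt in timings.items():
            fh.write(f"  {stage}: {dt}\n")
        fh.write(f"total_s: {round(time.time() - t0, 3)}\n")


# ---------------------------------------------------------------------------
# published-table summary


def normalize_chrom(label: str) -> str:
    """Map the published table's chromosome spellings onto one label set
    ("x", "X", "1(X)" -> "X")."""
    label = str(label).strip()
    if label.lower() in {"x", "1(x)"}:
        return "X"
    return label


def summarize_table1(rows: list[Table1Row] | None = None) -> SummaryReport:
    """Summary statistics of the published gene-associated element table.

    Works from the packaged fixture alone (no sequences): element counts by
    type and position, length and distance extremes, per-chromosome counts,
    and distinct genes keyed on the Entrez identifier.
    """
    if rows is None:
        rows = load_table1_fixture()
    by_seq: dict[int, list[Table1Row]] = {}
    for r in rows:
        by_seq.setdefault(r.seq_no, []).append(r)

    inside = flanked = single = 0
    per_chrom: dict[str, int] = {}
    sat_lengths, tra_lengths, copies = [], [], []
    per_element = []
    for seq_no in sorted(by_seq):
        group = by_seq[seq_no]
        positions = [r.position for r in group]
        chrom = normalize_chrom(group[0].chrom)
        per_chrom[chrom] = per_chrom.get(chrom, 0) + 1
        if "Inside" in positions:
            inside += 1
            relation = "inside"
        elif len(positions) == 2:
            flanked += 1
            relation = "flanked"
        else:
            single += 1
            relation = "single_flank"
        etype = group[0].element_type.lower()
        cls = "satellite" if etype == "satellite" else "transposon"
        length = group[0].length
        (sat_lengths if cls == "satellite" else tra_lengths).append(length)
        for r in group:
            if r.copies is not None:
                copies.append(r.copies)
        per_element.append({
            "seq_no": seq_no, "chrom": chrom, "element_class": cls,
            "length": length, "relation": relation,
            "copies": group[0].copies})
    distances = [r.distance for r in rows if r.distance is not None]
    report = SummaryReport()
    report.totals = {
        "elements": len(by_seq),
        "satellite": len(sat_lengths),
        "transposon": len(tra_lengths),
        "inside": inside,
        "flanked_both": flanked,
        "single_flank": single,
        "distinct_genes": len({r.entrez for r in rows}),
    }
    report.extremes = {
        "min_satellite_length": min(sat_lengths),
        "max_satellite_length": max(sat_lengths),
        "min_transposon_length": min(tra_lengths),
        "max_transposon_length": max(tra_lengths),
        "transposons_ge_1kb": sum(1 for l in tra_lengths if l >= 1000),
        "min_gene_distance": min(distances),
        "max_gene_distance": max(distances),
        "max_copies": max(copies),
    }
    report.per_chromosome = per_chrom
    report.per_element = per_element
    return report
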
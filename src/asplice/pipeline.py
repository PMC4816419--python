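"""Stage-wise pipeline: simulate -> qc -> align -> junctions -> classify ->
quantify -> evaluate.

Each stage reads its inputs from the run directory and writes its outputs
back, so any stage can be re-run in isolation from the previous stage's
serialized files. All randomness flows from the global seed through the
simulator; later stages are deterministic. A manifest records parameters
and output digests so identical configurations can be verified to
reproduce identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import asclassify, quantify, seqio
from .aligner import AlignParams, Alignment, KmerIndex, align_pairs, coverage_stats
from .asclassify import ClassifyParams
from .models import SpliceJunction
from .seqio import QCParams
from .simgen import SimParams, generate_dataset
from .splicefinder import JunctionParams, call_junctions

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: SimParams = field(default_factory=SimParams)
    qc: QCParams = field(default_factory=QCParams)
    align: AlignParams = field(default_factory=AlignParams)
    junction: JunctionParams = field(default_factory=JunctionParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    de_fdr: float = 0.001
    de_min_abs_log2: float = 1.0
    corr_threshold: float = 0.9
    min_varieties: int = 3
    seed: int = 0

    def validate(self) -> None:
        self.sim.seed = self.seed
        self.sim.validate()
        self.align.validate()
        self.junction.validate()
        if self.min_varieties > self.sim.n_varieties:
            raise ValueError(
                f"min_varieties={self.min_varieties} exceeds the "
                f"{self.sim.n_varieties} simulated varieties")

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, sub):
            fields = {f.name: f for f in dataclasses.fields(klass)}
            kwargs = {}
            for k, v in (sub or {}).items():
                if k not in fields:
                    raise ValueError(f"unknown {klass.__name__} field {k!r}")
                ann = fields[k].type
                kwargs[k] = tuple(v) if isinstance(v, list) and "tuple" in str(ann) else v
            return klass(**kwargs)

        cfg = cls(
            sim=build(SimParams, d.get("sim")),
            qc=build(QCParams, d.get("qc")),
            align=build(AlignParams, d.get("align")),
            junction=build(JunctionParams, d.get("junction")),
            classify=build(ClassifyParams, d.get("classify")),
        )
        for k in ("de_fdr", "de_min_abs_log2", "corr_threshold", "min_varieties", "seed"):
            if k in d:
                setattr(cfg, k, d[k])
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _lib_meta(lib_id: str) -> tuple[str, str]:
    variety, timepoint = lib_id.split("_", 1)
    return variety, timepoint


# ---------------------------------------------------------------------------
# stages


def simulate_stage(config: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate()
    result = generate_dataset(config.sim)
    seqio.write_fasta(outdir / "genome.fa", result.chrom_seqs)
    seqio.write_gff3(outdir / "genes.gff3", result.genes)
    for lib, pairs in result.libraries.items():
        seqio.write_fastq(outdir / f"{lib}_1.fastq", [p[0] for p in pairs])
        seqio.write_fastq(outdir / f"{lib}_2.fastq", [p[1] for p in pairs])
    _write_truth(result, outdir)
    seqio.write_json(outdir / "libraries.json", list(result.libraries))


def _write_truth(result, outdir: Path) -> None:
    truth = result.truth
    ref_junctions = set()
    alt_junctions: dict[SpliceJunction, tuple[str, str]] = {}
    gene_by_id = {g.gene_id: g for g in result.genes}
    for gid, isoforms in truth.isoforms.items():
        gene = gene_by_id[gid]
        seq = result.chrom_seqs[gene.chrom]
        for iso in isoforms:
            for (s0, e0), (s1, e1) in zip(iso.exons, iso.exons[1:]):
                from .models import motif_of_intron

                motif, strand = motif_of_intron(seq, e0, s1)
                jn = SpliceJunction(gene.chrom, e0 - 1, s1, strand, motif)
                if iso.as_type is None:
                    ref_junctions.add(jn)
                else:
                    alt_junctions.setdefault(jn, (gid, iso.as_type))
    rows = []
    for jn in sorted(ref_junctions | set(alt_junctions)):
        alt = jn not in ref_junctions
        gid, atype = alt_junctions.get(jn, ("", "")) if alt else ("", "")
        rows.append({"chrom": jn.chrom, "donor_end": jn.donor_end,
                     "acceptor_start": jn.acceptor_start, "strand": jn.strand,
                     "motif": jn.motif, "alt_only": alt, "gene_id": gid, "as_type": atype})
    pd.DataFrame(rows).to_csv(outdir / "truth_junctions.tsv", sep="\t", index=False)
    pd.DataFrame([{"gene_id": e.gene_id, "as_type": e.as_type,
                   "coordinates": ",".join(map(str, e.coordinates))}
                  for e in truth.as_events]).to_csv(
        outdir / "truth_events.tsv", sep="\t", index=False)
    seqio.write_json(outdir / "truth_active_events.json",
                     {lib: sorted(map(list, keys))
                      for lib, keys in truth.active_events.items()})
    seqio.write_json(outdir / "truth_expression.json", truth.per_library_expression)


def qc_stage(config: PipelineConfig, outdir: Path) -> dict:
    outdir = Path(outdir)
    libs = seqio.read_json(outdir / "libraries.json")
    summary = {}
    for lib in libs:
        r1 = seqio.read_fastq(outdir / f"{lib}_1.fastq", mate=1)
        r2 = seqio.read_fastq(outdir / f"{lib}_2.fastq", mate=2)
        pairs = list(zip(r1, r2))
        kept, discarded = seqio.filter_pairs(pairs, config.qc)
        report = seqio.dataset_qc([r for p in kept for r in p], config.qc)
        seqio.write_fastq(outdir / f"{lib}_clean_1.fastq", [p[0] for p in kept])
        seqio.write_fastq(outdir / f"{lib}_clean_2.fastq", [p[1] for p in kept])
        reasons = {}
        for _, reason in discarded:
            reasons[reason] = reasons.get(reason, 0) + 1
        summary[lib] = {"input_pairs": len(pairs), "kept_pairs": len(kept),
                        "discarded_pairs": len(discarded), "discard_reasons": reasons,
                        "dataset": {k: report[k] for k in
                                    ("n_rate", "lowq_rate", "ag_minus_tc", "status")}}
        log.info("qc %s: %d/%d pairs kept", lib, len(kept), len(pairs))
    seqio.write_json(outdir / "qc_report.json", summary)
    lines = []
    for lib, s in summary.items():
        d = s["dataset"]
        reasons = ", ".join(f"{k}: {v}" for k, v in sorted(s["discard_reasons"].items()))
        lines.append(
            f"{lib}: {s['kept_pairs']}/{s['input_pairs']} pairs kept"
            f" ({reasons or 'no discards'}); N rate {d['n_rate']:.4f},"
            f" low-quality rate {d['lowq_rate']:.4f} -> {d['status']}")
    (outdir / "qc_report.txt").write_text("\n".join(lines) + "\n")
    return summary


def align_stage(config: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    genome = seqio.read_fasta(outdir / "genome.fa")
    genes = seqio.read_gff3(outdir / "genes.gff3")
    index = KmerIndex(genome, config.align.seed_length)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    libs = seqio.read_json(outdir / "libraries.json")
    reports = {}
    for lib in libs:
        r1 = seqio.read_fastq(outdir / f"{lib}_clean_1.fastq", mate=1)
        r2 = seqio.read_fastq(outdir / f"{lib}_clean_2.fastq", mate=2)
        alignments, ium = align_pairs(list(zip(r1, r2)), index, config.align)
        _write_alignments(outdir / f"{lib}_alignments.tsv", alignments)
        seqio.write_fastq(outdir / f"{lib}_ium.fastq", ium)
        reports[lib] = coverage_stats(alignments, genes, chrom_lengths,
                                      n_reads=2 * len(r1))
        del reports[lib]["per_gene"]  # keep the JSON small; TSV below has it
        pd.DataFrame([
            {"gene_id": g, **vals} for g, vals in coverage_stats(
                alignments, genes, chrom_lengths, 2 * len(r1))["per_gene"].items()
        ]).to_csv(outdir / f"{lib}_gene_coverage.tsv", sep="\t", index=False)
    seqio.write_json(outdir / "coverage_report.json", reports)


def _write_alignments(path, alignments: list[Alignment]) -> None:
    pd.DataFrame([dataclasses.asdict(a) for a in alignments]).to_csv(
        path, sep="\t", index=False)


def _read_alignments(path) -> list[Alignment]:
    df = pd.read_csv(path, sep="\t")
    return [Alignment(**{**row, "mate": int(row["mate"])})
            for row in df.to_dict("records")]


def junction_stage(config: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    genome = seqio.read_fasta(outdir / "genome.fa")
    index = KmerIndex(genome, config.junction.anchor)
    for lib in seqio.read_json(outdir / "libraries.json"):
        ium = seqio.read_fastq(outdir / f"{lib}_ium.fastq")
        junctions = call_junctions(ium, index, config.junction)
        write_junctions(outdir / f"{lib}_junctions.tsv", junctions)
        write_junctions_bed(outdir / f"{lib}_junctions.bed", junctions)


def write_junctions(path, junctions: list[SpliceJunction]) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based; donor_end is the last exonic base "
                 "before the intron, acceptor_start the first after it\n")
        fh.write("chrom\tdonor_end\tacceptor_start\tstrand\tmotif\tsupport\n")
        for j in junctions:
            fh.write(f"{j.chrom}\t{j.donor_end}\t{j.acceptor_start}\t{j.strand}\t"
                     f"{j.motif}\t{j.support}\n")


def write_junctions_bed(path, junctions: list[SpliceJunction],
                        anchor: int = 20) -> None:
    """BED12 rendering: one two-block feature per junction.

    Blocks are ``anchor``-sized flanks on each side of the intron; the
    score column carries read support.
    """
    with open(path, "w") as fh:
        for i, j in enumerate(junctions):
            start = max(0, j.donor_end + 1 - anchor)
            end = j.acceptor_start + anchor
            b1 = j.donor_end + 1 - start
            fh.write("\t".join(map(str, [
                j.chrom, start, end, f"JUNC{i + 1:05d}.{j.motif}", j.support,
                j.strand, start, end, "0,0,255", 2,
                f"{b1},{anchor}", f"0,{j.acceptor_start - start}",
            ])) + "\n")


def read_junctions(path) -> list[SpliceJunction]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [SpliceJunction(r["chrom"], int(r["donor_end"]), int(r["acceptor_start"]),
                           r["strand"], r["motif"], support=int(r["support"]))
            for _, r in df.iterrows()]


def classify_stage(config: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    genome = seqio.read_fasta(outdir / "genome.fa")
    genes = seqio.read_gff3(outdir / "genes.gff3")
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    all_events = []
    diags = {}
    for lib in seqio.read_json(outdir / "libraries.json"):
        junctions = read_junctions(outdir / f"{lib}_junctions.tsv")
        alignments = _read_alignments(outdir / f"{lib}_alignments.tsv")
        evidence = asclassify.build_intron_evidence(
            alignments, chrom_lengths, config.classify.boundary_anchor)
        variety, timepoint = _lib_meta(lib)
        events, diag = asclassify.classify_events(
            junctions, evidence, genes, config.classify, variety, timepoint)
        all_events.extend(events)
        diags[lib] = diag
    pd.DataFrame([{
        "gene_id": e.gene_id, "as_type": e.as_type,
        "coordinates": ",".join(map(str, e.coordinates)),
        "variety": e.variety, "timepoint": e.timepoint, "support": e.support,
    } for e in all_events]).to_csv(outdir / "as_events.tsv", sep="\t", index=False)
    asclassify.accounting_table(all_events, config.sim.timepoints).to_csv(
        outdir / "as_accounting.csv", index=False)
    # cross-variety commonality and turnover
    tps = config.sim.timepoints
    common = {}
    for tp in tps:
        per_var = {}
        for e in all_events:
            if e.timepoint == tp:
                per_var.setdefault(e.variety, set()).add(e.key)
        for v in {e.variety for e in all_events}:
            per_var.setdefault(v, set())
        common[tp] = asclassify.common_events(per_var, config.min_varieties) \
            if len(per_var) >= config.min_varieties else set()
    result = {tp: sorted(map(list, keys)) for tp, keys in common.items()}
    if len(tps) == 2:
        n, pct = asclassify.turnover(common[tps[0]], common[tps[1]])
        result["turnover"] = {"count": n, "pct": pct}
    seqio.write_json(outdir / "common_events.json", result)
    seqio.write_json(outdir / "classify_diagnostics.json", diags)


def quantify_stage(config: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    genes = seqio.read_gff3(outdir / "genes.gff3")
    libs = seqio.read_json(outdir / "libraries.json")
    lengths = {g.gene_id: g.exonic_length for g in genes}
    columns = {}
    counts_by_lib, totals = {}, {}
    for lib in libs:
        alignments = _read_alignments(outdir / f"{lib}_alignments.tsv")
        counts, N = quantify.count_gene_reads(alignments, genes)
        counts_by_lib[lib], totals[lib] = counts, N
        columns[lib] = {g: quantify.rpkm(counts[g], N, lengths[g]) if N else 0.0
                        for g in counts}
    rpkm_matrix = pd.DataFrame(columns)
    rpkm_matrix.index.name = "gene_id"
    rpkm_matrix.to_csv(outdir / "rpkm_matrix.tsv", sep="\t")

    tps = config.sim.timepoints
    if len(tps) == 2:
        libs24 = [l for l in libs if l.endswith(tps[0])]
        libs48 = [l for l in libs if l.endswith(tps[1])]
        c1 = {g: sum(counts_by_lib[l][g] for l in libs24) for g in lengths}
        c2 = {g: sum(counts_by_lib[l][g] for l in libs48) for g in lengths}
        N1, N2 = sum(totals[l] for l in libs24), sum(totals[l] for l in libs48)
        degs = quantify.call_degs(c1, c2, N1, N2, lengths,
                                  config.de_fdr, config.de_min_abs_log2)
        degs.to_csv(outdir / "degs.tsv", sep="\t")

    if rpkm_matrix.shape[1] >= 3:
        events = pd.read_csv(outdir / "as_events.tsv", sep="\t")
        focal = sorted(set(events["gene_id"])) if len(events) else []
        edges = quantify.coexpression(rpkm_matrix, focal, config.corr_threshold)
        edges.to_csv(outdir / "coexpression_edges.tsv", sep="\t", index=False)


def evaluate_stage(config: PipelineConfig, outdir: Path) -> dict:
    """Score junction and event calls against the planted truth."""
    outdir = Path(outdir)
    tj = pd.read_csv(outdir / "truth_junctions.tsv", sep="\t",
                     keep_default_na=False)
    if not len(tj):
        raise FileNotFoundError("empty truth junction table")
    active = {lib: {tuple(k) for k in keys} for lib, keys in
              seqio.read_json(outdir / "truth_active_events.json").items()}
    libs = seqio.read_json(outdir / "libraries.json")

    ref_keys = {(r.chrom, r.donor_end, r.acceptor_start)
                for r in tj.itertuples() if not r.alt_only}
    alt_keys = {(r.chrom, r.donor_end, r.acceptor_start): (r.gene_id, r.as_type)
                for r in tj.itertuples() if r.alt_only}
    tp_calls, tp_truth = 0, 0
    called_total = 0
    for lib in libs:
        called = {j.key for j in read_junctions(outdir / f"{lib}_junctions.tsv")}
        expected = ref_keys | {k for k, ev in alt_keys.items() if ev in active[lib]}
        tp_calls += len(called & expected)
        tp_truth += len(expected)
        called_total += len(called)
    junction_recall = tp_calls / tp_truth if tp_truth else float("nan")
    junction_precision = tp_calls / called_total if called_total else float("nan")

    events = pd.read_csv(outdir / "as_events.tsv", sep="\t")
    per_type: dict[str, dict[str, int]] = {}
    for lib in libs:
        variety, timepoint = _lib_meta(lib)
        called_keys = {(r.gene_id, r.as_type) for r in events.itertuples()
                       if r.variety == variety and r.timepoint == timepoint}
        truth_keys = active[lib]
        for t in sorted({k[1] for k in truth_keys} | {k[1] for k in called_keys}):
            d = per_type.setdefault(t, {"tp": 0, "fn": 0, "fp": 0})
            ct = {k for k in called_keys if k[1] == t}
            tt = {k for k in truth_keys if k[1] == t}
            d["tp"] += len(ct & tt)
            d["fn"] += len(tt - ct)
            d["fp"] += len(ct - tt)
    event_scores = {t: {
        "recall": d["tp"] / (d["tp"] + d["fn"]) if d["tp"] + d["fn"] else None,
        "precision": d["tp"] / (d["tp"] + d["fp"]) if d["tp"] + d["fp"] else None,
        **d} for t, d in per_type.items()}
    report = {
        "junction_recall": junction_recall,
        "junction_precision": junction_precision,
        "per_type": event_scores,
    }
    seqio.write_json(outdir / "evaluation.json", report)
    return report


STAGES = ["simulate", "qc", "align", "junctions", "classify", "quantify", "evaluate"]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage in order and write a manifest with output digests."""
    outdir = Path(outdir)
    config.validate()
    simulate_stage(config, outdir)
    qc_stage(config, outdir)
    align_stage(config, outdir)
    junction_stage(config, outdir)
    classify_stage(config, outdir)
    quantify_stage(config, outdir)
    report = evaluate_stage(config, outdir)
    manifest = {
        "config": config.to_dict(),
        "stages": STAGES,
        "digests": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(outdir.iterdir()) if p.is_file()
                    and p.name != "manifest.json"},
    }
    seqio.write_json(outdir / "manifest.json", manifest)
    return report
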
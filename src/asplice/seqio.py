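"""Sequence file IO and read-level / dataset-level quality control.

FASTQ quality strings are Phred+33 throughout. Read filtering follows the
whole-read discard rules used for the germination libraries: a read is
dropped when it carries a sequencing adapter, when more than 10% of its
bases are N, or when more than half of its bases fall below Q20 — all
strict inequalities, checked in that priority order. Reads are never
trimmed.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .models import GeneModel


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced read; ``qualities`` is the Phred+33 string."""

    read_id: str
    mate: int
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"malformed record {self.read_id}/{self.mate}: "
                f"{len(self.sequence)} bases vs {len(self.qualities)} quality values")

    @property
    def phred(self) -> np.ndarray:
        return np.frombuffer(self.qualities.encode("ascii"), dtype=np.uint8) - 33


@dataclass
class QCParams:
    """Thresholds for read and dataset quality control."""

    adapter_sequence: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
    min_adapter_match: int = 10
    max_n_rate: float = 0.10
    max_lowq_rate: float = 0.50
    lowq_threshold: int = 20
    dataset_max_n: float = 0.01
    dataset_max_lowq: float = 0.10

    def validate(self) -> None:
        for name in ("max_n_rate", "max_lowq_rate", "dataset_max_n", "dataset_max_lowq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


def classify_read(read: ReadRecord, qc: QCParams) -> str | None:
    """First matching discard reason for a read, or None when it is clean."""
    if qc.adapter_sequence and len(qc.adapter_sequence) >= qc.min_adapter_match:
        if qc.adapter_sequence[: qc.min_adapter_match] in read.sequence:
            return "adapter"
    n = len(read.sequence)
    if read.sequence.count("N") / n > qc.max_n_rate:
        return "N rate"
    if int((read.phred < qc.lowq_threshold).sum()) / n > qc.max_lowq_rate:
        return "low quality"
    return None


def filter_reads(reads: list[ReadRecord], qc: QCParams):
    """Split reads into kept and discarded, with a per-read reason log."""
    qc.validate()
    kept, discarded = [], []
    for read in reads:
        reason = classify_read(read, qc)
        if reason is None:
            kept.append(read)
        else:
            discarded.append((read.read_id, read.mate, reason))
    return kept, discarded


def filter_pairs(pairs, qc: QCParams):
    """Pair-aware filtering: a pair is dropped if either mate is dirty."""
    qc.validate()
    kept, discarded = [], []
    for r1, r2 in pairs:
        reason = classify_read(r1, qc) or classify_read(r2, qc)
        if reason is None:
            kept.append((r1, r2))
        else:
            discarded.append((r1.read_id, reason))
    return kept, discarded


def dataset_qc(reads: list[ReadRecord], qc: QCParams | None = None) -> dict:
    """Dataset-level base composition and quality report.

    Reports global and per-position base fractions, the overall N rate and
    low-quality-base rate, and a PASS/FAIL verdict: the dataset fails when
    the N rate reaches 1% or the low-quality rate reaches 10%.
    """
    if not reads:
        raise ValueError("dataset_qc needs a non-empty read set")
    qc = qc or QCParams()
    max_len = max(len(r.sequence) for r in reads)
    alphabet = "ACGTN"
    counts = np.zeros((5, max_len), dtype=np.int64)
    lowq = 0
    total = 0
    codes = {ord(b): i for i, b in enumerate(alphabet)}
    for r in reads:
        arr = np.frombuffer(r.sequence.encode("ascii"), dtype=np.uint8)
        for i, b in enumerate(alphabet.encode()):
            counts[i, : len(arr)] += arr == b
        lowq += int((r.phred < qc.lowq_threshold).sum())
        total += len(arr)
    global_counts = counts.sum(axis=1)
    frac = global_counts / total
    per_pos_totals = counts.sum(axis=0)
    per_pos = np.divide(counts, per_pos_totals, where=per_pos_totals > 0,
                        out=np.zeros_like(counts, dtype=float))
    n_rate = float(frac[4])
    lowq_rate = lowq / total
    report = {
        "n_reads": len(reads),
        "n_bases": total,
        "base_fractions": {b: float(f) for b, f in zip(alphabet, frac)},
        "per_position_fractions": {b: per_pos[i].tolist() for i, b in enumerate(alphabet)},
        "n_rate": n_rate,
        "lowq_rate": float(lowq_rate),
        "ag_minus_tc": float(frac[0] + frac[2] - frac[3] - frac[1]),
        "status": "FAIL" if (n_rate >= qc.dataset_max_n or lowq_rate >= qc.dataset_max_lowq)
        else "PASS",
    }
    return report


# ---------------------------------------------------------------------------
# FASTA / FASTQ / GFF3


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fasta(path, sequences: dict[str, str], width: int = 60) -> None:
    with _open(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    with _open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fastq(path, reads: list[ReadRecord]) -> None:
    with _open(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}/{r.mate}\n{r.sequence}\n+\n{r.qualities}\n")


def read_fastq(path, mate: int | None = None) -> list[ReadRecord]:
    reads = []
    with _open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            rid, m = (title.rsplit("/", 1) + ["1"])[:2] if "/" in title else (title, "1")
            reads.append(ReadRecord(rid, mate if mate is not None else int(m), seq, qual))
    return reads


def write_gff3(path, genes: list[GeneModel]) -> None:
    """GFF3 with gene and exon features (1-based inclusive coordinates)."""
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tasplice\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tasplice\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n")


def read_gff3(path) -> list[GeneModel]:
    """Parse the gene/exon dialect written by :func:`write_gff3`."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes = []
    for gene in db.features_of_type("gene"):
        exons = sorted((f.start - 1, f.end) for f in db.children(gene, featuretype="exon"))
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, tuple(exons)))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
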
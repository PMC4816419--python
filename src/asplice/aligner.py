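"""Seed-and-extend ungapped short-read alignment and alignment QC.

The aligner emulates the contiguous mapping stage of the study workflow: a
read aligns wherever its 5' seed (default 32 bp) matches the genome
exactly and ungapped full-length extension accumulates at most
``max_mismatches`` substitutions (mismatches can only fall outside the
seed). Mates align independently; FR orientation and a maximal insert size
are then enforced on the candidate pairs. Reads with no qualifying
position are returned as IUM (initially unmapped) reads — the input to
spliced-junction detection. Indels are out of scope.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np

from .models import GeneModel, revcomp
from .seqio import ReadRecord


@dataclass
class AlignParams:
    seed_length: int = 32
    max_mismatches: int = 5
    max_insert: int = 1000

    def validate(self) -> None:
        if self.seed_length < 8:
            raise ValueError("seed_length must be >= 8")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class Alignment:
    read_id: str
    mate: int
    chrom: str
    start: int  # 0-based
    strand: str
    mismatches: int
    uniqueness: str  # "unique" | "multi"
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


class KmerIndex:
    """Exact-lookup index of every k-mer position on both strands.

    Positions are stored for the forward strand only; minus-strand hits
    are produced by querying the reverse complement. Chromosomes are
    concatenated with long N separators so no k-mer spans a boundary (N
    containing k-mers are never indexed and never match).
    """

    SEP = 200

    def __init__(self, chrom_seqs: dict[str, str], k: int):
        if not chrom_seqs:
            raise ValueError("reference is empty")
        if k > min(len(s) for s in chrom_seqs.values()):
            raise ValueError("k exceeds the shortest chromosome")
        self.k = k
        self.names = list(chrom_seqs)
        self.offsets = []
        parts = []
        pos = 0
        for name in self.names:
            self.offsets.append(pos)
            parts.append(chrom_seqs[name])
            pos += len(chrom_seqs[name]) + self.SEP
            parts.append("N" * self.SEP)
        self.genome = "".join(parts)
        self.lengths = {name: len(chrom_seqs[name]) for name in self.names}
        self._index: dict[str, list[int]] = {}
        g = self.genome
        add = self._index.setdefault
        for i in range(len(g) - k + 1):
            kmer = g[i : i + k]
            if "N" not in kmer:
                add(kmer, []).append(i)

    def positions(self, kmer: str) -> list[int]:
        """Forward-strand global positions of an exact k-mer."""
        return self._index.get(kmer, [])

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All (chrom, position, strand) occurrences of ``kmer``."""
        out = [(*self.decode(p), "+") for p in self.positions(kmer)]
        out += [(*self.decode(p), "-") for p in self.positions(revcomp(kmer))]
        return out

    def decode(self, gpos: int) -> tuple[str, int]:
        i = bisect.bisect_right(self.offsets, gpos) - 1
        return self.names[i], gpos - self.offsets[i]

    def encode(self, chrom: str, pos: int) -> int:
        return self.offsets[self.names.index(chrom)] + pos

    def slice(self, gpos: int, length: int) -> str:
        return self.genome[gpos : gpos + length]

    def in_bounds(self, gpos: int, length: int) -> bool:
        chrom, local = self.decode(gpos)
        return 0 <= local and local + length <= self.lengths[chrom]


def _mismatches(a: str, b: str, limit: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def candidate_positions(seq: str, index: KmerIndex, params: AlignParams):
    """Best (fewest-mismatch) ungapped placements of one read.

    Returns a list of ``(global_start, strand, mismatches)`` tied at the
    minimal mismatch count, or an empty list. The seed is the 5'-most
    ``seed_length`` bases and must match exactly.
    """
    k = params.seed_length
    if len(seq) < k or "N" in seq[:k]:
        return []
    cands = []
    for pos in index.positions(seq[:k]):
        if not index.in_bounds(pos, len(seq)):
            continue
        m = _mismatches(seq[k:], index.slice(pos + k, len(seq) - k), params.max_mismatches)
        if m <= params.max_mismatches:
            cands.append((pos, "+", m))
    rc = revcomp(seq)
    for pos in index.positions(revcomp(seq[:k])):
        start = pos + k - len(seq)
        if start < 0 or not index.in_bounds(start, len(seq)):
            continue
        m = _mismatches(rc[: len(seq) - k], index.slice(start, len(seq) - k),
                        params.max_mismatches)
        if m <= params.max_mismatches:
            cands.append((start, "-", m))
    if not cands:
        return []
    best = min(c[2] for c in cands)
    return [c for c in cands if c[2] == best]


def align_pairs(pairs, index: KmerIndex, params: AlignParams | None = None):
    """Align read pairs; returns ``(alignments, ium_reads)``.

    Each mate aligns independently to its best-hit set; when both mates
    have hits, FR-oriented combinations with insert size at most
    ``max_insert`` restrict the candidate sets. A mate with no qualifying
    position is emitted as an IUM read. Every input read ends up in
    exactly one class: uniquely aligned, multi aligned, or IUM.
    """
    params = params or AlignParams()
    params.validate()
    alignments: list[Alignment] = []
    ium: list[ReadRecord] = []
    for r1, r2 in pairs:
        c1 = candidate_positions(r1.sequence, index, params)
        c2 = candidate_positions(r2.sequence, index, params)
        if c1 and c2:
            good = _pair_filter(c1, c2, len(r1.sequence), len(r2.sequence), params.max_insert)
            if good:
                c1 = [c for c in c1 if c in {a for a, _ in good}]
                c2 = [c for c in c2 if c in {b for _, b in good}]
        for read, cands in ((r1, c1), (r2, c2)):
            if not cands:
                ium.append(read)
                continue
            uniq = "unique" if len(cands) == 1 else "multi"
            pos, strand, mm = min(cands)
            chrom, local = index.decode(pos)
            alignments.append(Alignment(read.read_id, read.mate, chrom, local, strand,
                                        mm, uniq, len(read.sequence)))
    return alignments, ium


def _pair_filter(c1, c2, len1, len2, max_insert):
    """FR-orientation + insert-size constraint over candidate combinations."""
    good = []
    for a in c1:
        for b in c2:
            if a[1] == b[1]:
                continue
            fwd, rev = (a, b) if a[1] == "+" else (b, a)
            fwd_len, rev_len = (len1, len2) if fwd is a else (len2, len1)
            if fwd[0] > rev[0]:
                continue
            insert = rev[0] + rev_len - fwd[0]
            if 0 < insert <= max_insert:
                good.append((a, b))
    return good


# ---------------------------------------------------------------------------
# alignment QC


def coverage_stats(alignments: list[Alignment], genes: list[GeneModel],
                   chrom_lengths: dict[str, int], n_reads: int) -> dict:
    """Coverage, depth and mapped-rate summary.

    Per-gene coverage is the fraction of exonic bases touched by at least
    one uniquely mapped read; depth is mean unique-read depth over exonic
    bases. The histogram uses 0-50 / 50-90 / 90-100 percent coverage bins.
    """
    depth = {name: np.zeros(length + 1, dtype=np.int32)
             for name, length in chrom_lengths.items()}
    n_unique = n_multi = 0
    seen: dict[tuple[str, int], str] = {}
    for a in alignments:
        key = (a.read_id, a.mate)
        if key not in seen:
            seen[key] = a.uniqueness
            if a.uniqueness == "unique":
                n_unique += 1
            else:
                n_multi += 1
        if a.uniqueness == "unique":
            depth[a.chrom][a.start] += 1
            depth[a.chrom][a.end] -= 1
    cov = {name: np.cumsum(d[:-1]) for name, d in depth.items()}

    per_gene = {}
    bins = {"0-50": 0, "50-90": 0, "90-100": 0}
    for g in genes:
        if g.exonic_length == 0:
            raise ValueError(f"gene {g.gene_id} has zero exonic length")
        c = np.concatenate([cov[g.chrom][s:e] for s, e in g.exons])
        frac = float((c > 0).mean())
        per_gene[g.gene_id] = {"coverage": frac, "mean_depth": float(c.mean())}
        if frac >= 0.9:
            bins["90-100"] += 1
        elif frac >= 0.5:
            bins["50-90"] += 1
        else:
            bins["0-50"] += 1

    genome_len = sum(chrom_lengths.values())
    covered = sum(int((c > 0).sum()) for c in cov.values())
    n_unmapped = n_reads - n_unique - n_multi
    rates = {k: (v / n_reads if n_reads else 0.0)
             for k, v in [("unique", n_unique), ("multi", n_multi), ("unmapped", n_unmapped)]}
    return {
        "per_gene": per_gene,
        "coverage_histogram": bins,
        "mapped_rates": rates,
        "genome_coverage": covered / genome_len,
        "n_reads": n_reads,
    }
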
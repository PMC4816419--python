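"""Ungapped aligner: index completeness, oracle equivalence, QC arithmetic."""

import numpy as np
import pytest

from asplice.aligner import (AlignParams, KmerIndex, align_pairs,
                             candidate_positions, coverage_stats)
from asplice.models import GeneModel, revcomp
from asplice.seqio import ReadRecord


def _rng_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def brute_force_candidates(seq, chrom_seq, params):
    """Independent scan over all positions and strands.

    Applies the same contract: 5' seed exact, at most ``max_mismatches``
    over the full read, best (fewest-mismatch) positions kept.
    """
    k = params.seed_length
    hits = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        seed = s[:k] if strand == "+" else s  # seed is 5' of the read
        for pos in range(len(chrom_seq) - len(seq) + 1):
            window = chrom_seq[pos : pos + len(seq)]
            if strand == "+":
                if window[:k] != seq[:k]:
                    continue
                mm = sum(a != b for a, b in zip(window[k:], seq[k:]))
            else:
                rc = revcomp(seq)
                if window[-k:] != rc[-k:]:
                    continue
                mm = sum(a != b for a, b in zip(window[: len(seq) - k], rc[: len(seq) - k]))
            if mm <= params.max_mismatches:
                hits.append((pos, strand, mm))
    if not hits:
        return []
    best = min(h[2] for h in hits)
    return sorted(h for h in hits if h[2] == best)


class TestIndex:
    def test_every_kmer_query_returns_all_occurrences(self):
        rng = np.random.default_rng(0)
        ref = {"c": _rng_seq(rng, 300)}
        idx = KmerIndex(ref, 8)
        seq = ref["c"]
        for i in range(0, len(seq) - 8 + 1, 7):
            kmer = seq[i : i + 8]
            expected = {j for j in range(len(seq) - 7) if seq[j : j + 8] == kmer}
            assert {p for c, p, s in idx.lookup(kmer) if s == "+"} == expected

    def test_n_containing_query_has_no_hits(self):
        idx = KmerIndex({"c": "ACGT" * 30}, 8)
        assert idx.lookup("ACGTNACG") == []

    def test_strand_symmetry(self):
        rng = np.random.default_rng(1)
        seq = _rng_seq(rng, 200)
        idx = KmerIndex({"c": seq}, 10)
        kmer = seq[37:47]
        fwd = {(p, s) for _, p, s in idx.lookup(kmer)}
        rev = {(p, {"+": "-", "-": "+"}[s]) for _, p, s in idx.lookup(revcomp(kmer))}
        assert fwd == rev

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            KmerIndex({}, 8)


class TestAlignment:
    def test_agrees_with_brute_force_on_small_reference(self):
        rng = np.random.default_rng(42)
        chrom = _rng_seq(rng, 3000)
        params = AlignParams(seed_length=20, max_mismatches=3)
        idx = KmerIndex({"c": chrom}, params.seed_length)
        for trial in range(60):
            pos = int(rng.integers(0, len(chrom) - 60))
            seq = chrom[pos : pos + 60]
            nmut = int(rng.integers(0, 6))
            s = bytearray(seq.encode())
            for mpos in rng.choice(60, size=nmut, replace=False):
                s[mpos] = ord(rng.choice([b for b in "ACGT" if b != chr(s[mpos])]))
            seq = s.decode()
            if rng.random() < 0.5:
                seq = revcomp(seq)
            mine = sorted((idx.decode(p)[1], st, mm)
                          for p, st, mm in candidate_positions(seq, idx, params))
            assert mine == brute_force_candidates(seq, chrom, params)

    def test_error_free_reads_align_at_their_true_position(self, small_sim, small_run):
        gene_by_id = {g.gene_id: g for g in small_sim.genes}
        by_read = {}
        for a in small_run["alignments"]:
            by_read.setdefault((a.read_id, a.mate), a)
        checked = 0
        for r1, r2 in small_sim.libraries["V1_24h"][:300]:
            _, iso_id, _, start, frag = r1.read_id.rsplit(":", 4)
            gid = iso_id.rsplit(".", 1)[0]
            gene = gene_by_id[gid]
            iso = [i for i in small_sim.truth.isoforms[gid] if i.isoform_id == iso_id][0]
            expected = _genomic_span(iso.exons, gene.strand, int(start), len(r1.sequence))
            if expected is None:
                # junction-spanning: usually IUM, but a short overhang can
                # pass as a contiguous hit (its bases may even coincide)
                continue
            a = by_read[(r1.read_id, 1)]
            assert (a.start, a.mismatches) == (expected, 0)
            checked += 1
        assert checked > 50

    def test_junction_spanning_reads_become_ium(self, small_run):
        assert len(small_run["ium"]) > 0
        ium_ids = {(r.read_id, r.mate) for r in small_run["ium"]}
        aligned = {(a.read_id, a.mate) for a in small_run["alignments"]}
        assert not ium_ids & aligned  # partition

    def test_too_many_mismatches_goes_ium(self):
        chrom = _rng_seq(np.random.default_rng(5), 2000)
        idx = KmerIndex({"c": chrom}, 32)
        seq = chrom[100:190]
        mutated = seq[:40] + "".join(
            {"A": "C", "C": "A", "G": "T", "T": "G"}[b] for b in seq[40:46]) + seq[46:]
        r1 = ReadRecord("q", 1, mutated, "I" * 90)
        r2 = ReadRecord("q", 2, revcomp(chrom[300:390]), "I" * 90)
        alignments, ium = align_pairs([(r1, r2)], idx, AlignParams())
        assert [r.read_id for r in ium] == ["q"]
        assert all(a.mate == 2 for a in alignments)

    def test_five_mismatches_outside_seed_still_aligns(self):
        chrom = _rng_seq(np.random.default_rng(6), 2000)
        idx = KmerIndex({"c": chrom}, 32)
        seq = chrom[100:190]
        s = bytearray(seq.encode())
        for i in (40, 50, 60, 70, 80):
            s[i] = ord({"A": "C", "C": "A", "G": "T", "T": "G"}[chr(s[i])])
        cands = candidate_positions(s.decode(), idx, AlignParams())
        assert [(idx.decode(p)[1], st, mm) for p, st, mm in cands] == [(100, "+", 5)]

    def test_no_noise_nonjunction_mapped_rate(self, small_sim, small_run):
        n_junction_ium = len(small_run["ium"])
        reads_total = 2 * len(small_sim.libraries["V1_24h"])
        aligned_reads = {(a.read_id, a.mate) for a in small_run["alignments"]}
        assert len(aligned_reads) + n_junction_ium == reads_total


def _genomic_span(exons, strand, start, length):
    """Forward-genome start of a read fully inside one exon, else None."""
    blocks = []
    if strand == "+":
        off = 0
        for s, e in exons:
            blocks.append((off, off + (e - s), s))
            off += e - s
    else:
        off = 0
        for s, e in reversed(exons):
            blocks.append((off, off + (e - s), s, e))
            off += e - s
    for b in blocks:
        if strand == "+":
            o1, o2, gs = b
            if start >= o1 and start + length <= o2:
                return gs + (start - o1)
        else:
            o1, o2, gs, ge = b
            if start >= o1 and start + length <= o2:
                return ge - (start - o1) - length
    return None


class TestCoverage:
    def _gene(self):
        return GeneModel("g", "c", "+", ((100, 1000),))

    def test_single_read_on_900bp_gene_gives_ten_percent(self):
        a = [_aln("r", 1, "c", 100, 90)]
        rep = coverage_stats(a, [self._gene()], {"c": 2000}, n_reads=1)
        assert rep["per_gene"]["g"]["coverage"] == pytest.approx(0.10)
        assert rep["coverage_histogram"] == {"0-50": 1, "50-90": 0, "90-100": 0}

    def test_fully_tiled_gene_has_coverage_one(self):
        a = [_aln(f"r{i}", 1, "c", 100 + 90 * i, 90) for i in range(10)]
        rep = coverage_stats(a, [self._gene()], {"c": 2000}, n_reads=10)
        assert rep["per_gene"]["g"]["coverage"] == 1.0
        assert rep["mapped_rates"]["unique"] == 1.0

    def test_no_alignments_gives_zero_coverage_and_unmapped_one(self):
        rep = coverage_stats([], [self._gene()], {"c": 2000}, n_reads=10)
        assert rep["per_gene"]["g"]["coverage"] == 0.0
        assert rep["mapped_rates"] == {"unique": 0.0, "multi": 0.0, "unmapped": 1.0}

    def test_rates_sum_to_one(self, small_sim, small_run):
        rep = coverage_stats(small_run["alignments"], small_sim.genes,
                             {c: len(s) for c, s in small_sim.chrom_seqs.items()},
                             n_reads=2 * len(small_sim.libraries["V1_24h"]))
        assert sum(rep["mapped_rates"].values()) == pytest.approx(1.0)
        assert all(0 <= v["coverage"] <= 1 for v in rep["per_gene"].values())


def _aln(rid, mate, chrom, start, length, uniq="unique", mm=0):
    from asplice.aligner import Alignment

    return Alignment(rid, mate, chrom, start, "+", mm, uniq, length)
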
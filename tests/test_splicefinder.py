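"""Spliced-placement rules: sub-read splitting, exact-match junction
search, motif priority, multi-hit handling, and the brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asplice.aligner import AlignParams, KmerIndex, align_pairs
from asplice.evaluation import bruteforce_call_junctions
from asplice.models import motif_of_intron, revcomp
from asplice.seqio import ReadRecord
from asplice.splicefinder import (JunctionParams, call_junctions, find_junction,
                                  place_read, resolve_multihits, split_long_read)

from conftest import clean_sim_params


def _rng_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestSplitLongRead:
    @pytest.mark.parametrize("length,expected", [
        (80, [40, 40]),
        (120, [50, 35, 35]),
        (49, [49]),
        (100, [50, 50]),
        (101, [50, 26, 25]),
        (151, [50, 50, 26, 25]),
        (250, [50, 50, 50, 50, 50]),  # remainder 100 halves into 50 + 50
    ])
    def test_lengths(self, length, expected):
        seq = "A" * length
        assert [len(s) for s in split_long_read(seq)] == expected

    @given(st.integers(min_value=18, max_value=400))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_concatenation_reproduces_the_read(self, n):
        rng = np.random.default_rng(n)
        seq = _rng_seq(rng, n)
        parts = split_long_read(seq)
        assert "".join(parts) == seq
        assert all(len(p) <= 50 for p in parts[:-2])

    def test_too_short_read_rejected(self):
        with pytest.raises(ValueError):
            split_long_read("ACGTACGTACGTACGTA")  # 17 bp


def _genome_with_intron(rng, intron_len=200, motif=("GT", "AG")):
    """Exon(120) + intron + exon(120) inside random padding."""
    left_pad, right_pad = 150, 150
    exon1, exon2 = _rng_seq(rng, 120), _rng_seq(rng, 120)
    intron = motif[0] + _rng_seq(rng, intron_len - 4) + motif[1]
    genome = _rng_seq(rng, left_pad) + exon1 + intron + exon2 + _rng_seq(rng, right_pad)
    donor_end = left_pad + 120 - 1
    acceptor_start = left_pad + 120 + intron_len
    return genome, exon1, exon2, donor_end, acceptor_start


class TestFindJunction:
    def test_recovers_planted_junction_with_30_60_split(self):
        rng = np.random.default_rng(10)
        genome, exon1, exon2, donor_end, acceptor = _genome_with_intron(rng)
        read = exon1[-30:] + exon2[:60]
        params = JunctionParams()
        idx = KmerIndex({"c": genome}, params.anchor)
        # the read is 90 bp, so it is halved; each half carries enough anchor
        junctions = place_read(read, idx, params)
        assert junctions == [(donor_end, acceptor)]

    def test_eight_bp_segment_rejected(self):
        rng = np.random.default_rng(11)
        genome, exon1, exon2, *_ = _genome_with_intron(rng)
        read = exon1[-36:] + exon2[:8]  # 44 bp single sub-read, 8 bp 3' segment
        params = JunctionParams()
        idx = KmerIndex({"c": genome}, params.anchor)
        assert find_junction(read, idx, params) == []

    def test_motif_priority_prefers_gt_ag(self):
        # the same 5' segment occurs at two donors: one GT, one GC; both can
        # reach the unique acceptor, and GC-AG offers the SHORTER intron —
        # motif priority must still pick GT-AG
        rng = np.random.default_rng(12)
        seg5 = _rng_seq(rng, 20)
        seg3 = _rng_seq(rng, 20)
        genome = (_rng_seq(rng, 50) + seg5 + "GT" + _rng_seq(rng, 128)
                  + seg5 + "GC" + _rng_seq(rng, 128)
                  + "AG" + seg3 + _rng_seq(rng, 50))
        params = JunctionParams()
        idx = KmerIndex({"c": genome}, params.anchor)
        read = seg5 + seg3
        cands = find_junction(read, idx, params)
        assert cands
        best = resolve_multihits(cands)
        assert best.motif_rank == 0
        s, e = best.junction[0] + 1, best.junction[1]
        assert motif_of_intron(genome, s, e) == ("GT-AG", "+")
        assert best.junction == (69, 352)  # the distant GT donor, not the near GC

    def test_closest_pair_for_multi_hit_acceptor(self):
        rng = np.random.default_rng(13)
        exon1 = _rng_seq(rng, 40)
        seg3 = _rng_seq(rng, 15)
        # one GT donor, the same acceptor content after three AG sites
        genome = _rng_seq(rng, 50) + exon1 + "GT" + _rng_seq(rng, 76) + "AG" + seg3 \
            + _rng_seq(rng, 201) + "AG" + seg3 \
            + _rng_seq(rng, 100) + "AG" + seg3 + _rng_seq(rng, 60)
        params = JunctionParams()
        idx = KmerIndex({"c": genome}, params.anchor)
        read = exon1[-20:] + seg3
        cands = find_junction(read, idx, params)
        assert cands
        best = resolve_multihits(cands)
        assert best.intron_len == 80

    def test_minus_strand_junction_detected_with_inferred_strand(self):
        rng = np.random.default_rng(14)
        # CT...AC on the forward genome = GT-AG intron on the minus strand
        genome, exon1, exon2, donor_end, acceptor = _genome_with_intron(
            rng, motif=("CT", "AC"))
        read = revcomp(exon1[-30:] + exon2[:60])
        params = JunctionParams()
        idx = KmerIndex({"c": genome}, params.anchor)
        reads = [ReadRecord("r", 1, read, "I" * len(read))]
        calls = call_junctions(reads, idx, params)
        assert [(j.donor_end, j.acceptor_start, j.strand, j.motif) for j in calls] == \
            [(donor_end, acceptor, "-", "GT-AG")]

    def test_intron_below_minimum_never_called(self):
        rng = np.random.default_rng(15)
        genome, exon1, exon2, *_ = _genome_with_intron(rng, intron_len=49)
        read = exon1[-30:] + exon2[:30]
        params = JunctionParams()
        idx = KmerIndex({"c": genome}, params.anchor)
        assert place_read(read, idx, params) in (None, [])


class TestCallJunctions:
    def test_empty_ium_set_gives_empty_junctions(self, small_run):
        assert call_junctions([], small_run["index9"], small_run["jparams"]) == []

    def test_min_support_monotonicity(self, small_run):
        base = small_run["junctions"]
        prev = {j.key for j in base}
        for ms in (2, 3, 5):
            params = JunctionParams(max_intron=small_run["jparams"].max_intron,
                                    min_support=ms)
            now = {j.key for j in call_junctions(small_run["ium"],
                                                 small_run["index9"], params)}
            assert now <= prev
            prev = now

    def test_motif_soundness_of_all_calls(self, small_sim, small_run):
        for j in small_run["junctions"]:
            seq = small_sim.chrom_seqs[j.chrom]
            assert motif_of_intron(seq, j.intron_start, j.intron_end) == (j.motif, j.strand)

    def test_recovery_on_clean_fixture(self, small_sim, small_run):
        called = {j.key for j in small_run["junctions"]}
        truth = {j.key for j in small_sim.truth.junctions}
        recall = len(called & truth) / len(truth)
        precision = len(called & truth) / len(called)
        assert recall >= 0.98 and precision >= 0.98

    def test_multi_exon_spanning_read_recovers_both_junctions(self):
        rng = np.random.default_rng(16)
        e1, e2, e3 = _rng_seq(rng, 200), _rng_seq(rng, 45), _rng_seq(rng, 200)
        i1 = "GT" + _rng_seq(rng, 96) + "AG"
        i2 = "GT" + _rng_seq(rng, 146) + "AG"
        pad = _rng_seq(rng, 80)
        genome = pad + e1 + i1 + e2 + i2 + e3 + _rng_seq(rng, 80)
        d1 = len(pad) + len(e1) - 1
        a1 = d1 + 1 + len(i1)
        d2 = a1 + len(e2) - 1
        a2 = d2 + 1 + len(i2)
        # 120 bp read: 40 from e1, all 45 of e2, 35 from e3
        read = e1[-40:] + e2 + e3[:35]
        params = JunctionParams()
        idx = KmerIndex({"c": genome}, params.anchor)
        calls = call_junctions([ReadRecord("r", 1, read, "I" * 120)], idx, params)
        assert {(j.donor_end, j.acceptor_start) for j in calls} == {(d1, a1), (d2, a2)}


class TestBruteForceOracle:
    def test_caller_matches_exhaustive_enumeration(self):
        """On a <=5 kb reference the indexed caller equals a full scan."""
        for seed in (5, 21):
            params_sim = clean_sim_params(
                n_genes=3, chrom_length=4500, exons_per_gene=(3, 3),
                exon_length=(80, 120), intron_length=(50, 300), depth=30.0,
                seed=seed)
            from asplice.simgen import generate_dataset

            result = generate_dataset(params_sim)
            pairs = result.libraries["V1_24h"]
            idx32 = KmerIndex(result.chrom_seqs, 32)
            _, ium = align_pairs(pairs, idx32, AlignParams())
            jparams = JunctionParams(max_intron=5000)
            idx = KmerIndex(result.chrom_seqs, jparams.anchor)
            mine = {(j.donor_end, j.acceptor_start): j.support
                    for j in call_junctions(ium, idx, jparams)}
            oracle = bruteforce_call_junctions(
                [r.sequence for r in ium], result.chrom_seqs["chr1"], jparams)
            assert mine == oracle
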
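"""AS-event typing rules and the table accounting arithmetic."""

import numpy as np
import pytest

from asplice import published
from asplice.asclassify import (ClassifyParams, IntronEvidence, accounting_table,
                                as_gene_fraction, classify_events, common_events,
                                count_events, event_keys, events_per_gene,
                                round_half_up_pct, truncate_pct, turnover)
from asplice.models import ASEvent, GeneModel, SpliceJunction


def _plus_gene():
    # exons 100-200, 300-400, 500-600; introns (200,300) and (400,500)
    return GeneModel("g1", "c", "+", ((100, 200), (300, 400), (500, 600)))


def _minus_gene():
    return GeneModel("g2", "c", "-", ((100, 200), (300, 400), (500, 600)))


def _jn(donor_end, acceptor_start, strand="+", motif="GT-AG", support=5):
    return SpliceJunction("c", donor_end, acceptor_start, strand, motif, support=support)


def _classify(junctions, genes, **kw):
    events, diag = classify_events(junctions, None, genes, ClassifyParams(), **kw)
    return events, diag


class TestJunctionTyping:
    def test_annotated_intron_is_constitutive(self):
        events, diag = _classify([_jn(199, 300)], [_plus_gene()])
        assert events == [] and diag["constitutive"] == 1

    def test_shared_donor_novel_acceptor_is_a3s_on_plus(self):
        events, _ = _classify([_jn(199, 310)], [_plus_gene()])
        assert [(e.as_type, e.gene_id) for e in events] == [("A3S", "g1")]

    def test_novel_donor_shared_acceptor_is_a5s_on_plus(self):
        events, _ = _classify([_jn(190, 300)], [_plus_gene()])
        assert [e.as_type for e in events] == ["A5S"]

    def test_a3s_a5s_swap_on_minus_strand(self):
        # same genomic junctions, minus-strand gene: roles exchange
        events, _ = _classify([_jn(199, 310, strand="-")], [_minus_gene()])
        assert [e.as_type for e in events] == ["A5S"]
        events, _ = _classify([_jn(190, 300, strand="-")], [_minus_gene()])
        assert [e.as_type for e in events] == ["A3S"]

    def test_exon_skip_joins_flanking_introns(self):
        events, _ = _classify([_jn(199, 500)], [_plus_gene()])
        assert [e.as_type for e in events] == ["ES"]

    def test_terminal_exon_substitution(self):
        # donor upstream of the gene, acceptor at the first annotated acceptor
        events, _ = _classify([_jn(40, 300)], [_plus_gene()])
        assert [e.as_type for e in events] == ["AFE"]
        events, _ = _classify([_jn(399, 700)], [_plus_gene()])
        assert [e.as_type for e in events] == ["ALE"]
        # minus strand: the genomic-left substitution is the last exon
        events, _ = _classify([_jn(40, 300, strand="-")], [_minus_gene()])
        assert [e.as_type for e in events] == ["ALE"]
        events, _ = _classify([_jn(399, 700, strand="-")], [_minus_gene()])
        assert [e.as_type for e in events] == ["AFE"]

    def test_strand_conflict_and_intergenic_are_counted(self):
        events, diag = _classify([_jn(199, 310, strand="-")], [_plus_gene()])
        assert events == [] and diag["strand_conflict"] == 1
        events, diag = _classify([_jn(5000, 5300)], [_plus_gene()])
        assert events == [] and diag["intergenic"] == 1

    def test_two_adjacent_exon_skips_merge_into_mxe(self):
        gene = GeneModel("g3", "c", "+",
                         ((100, 200), (300, 400), (500, 600), (700, 800)))
        events, _ = _classify([_jn(199, 500), _jn(399, 700)], [gene])
        assert [e.as_type for e in events] == ["MXE"]
        # a single skip stays ES
        events, _ = _classify([_jn(199, 500)], [gene])
        assert [e.as_type for e in events] == ["ES"]


class TestIntronRetention:
    def _evidence(self, cov_fraction, boundaries=True, n=1000):
        cov = np.zeros(n, dtype=np.int32)
        s, e = 200, 300
        covered = int(round((e - s) * cov_fraction))
        cov[s : s + covered] = 3
        cov[100:200] = 3
        cov[300:400] = 3
        cross = np.zeros(n, dtype=bool)
        if boundaries:
            cross[s] = cross[e] = True
        return IntronEvidence({"c": cov}, {"c": cross})

    def test_covered_intron_with_boundaries_is_ir(self):
        ev = self._evidence(0.95)
        events, _ = classify_events([], ev, [_plus_gene()], ClassifyParams())
        assert [(e.as_type, tuple(e.coordinates)) for e in events] == [("IR", (200, 300))]

    def test_insufficient_coverage_is_not_ir(self):
        ev = self._evidence(0.85)
        events, _ = classify_events([], ev, [_plus_gene()], ClassifyParams())
        assert events == []

    def test_missing_boundary_span_is_not_ir(self):
        ev = self._evidence(1.0, boundaries=False)
        events, _ = classify_events([], ev, [_plus_gene()], ClassifyParams())
        assert events == []


class TestAccounting:
    def test_two_coordinates_one_gene_counts_two_events_one_gene(self):
        events = [ASEvent("g", "A3S", (10, 100), "V1", "24h"),
                  ASEvent("g", "A3S", (10, 120), "V1", "24h"),
                  ASEvent("g", "A3S", (10, 120), "V1", "24h")]  # duplicate call
        df = count_events(events)
        assert df.loc[df["as_type"] == "A3S", "events"].iloc[0] == 2
        assert df.loc[df["as_type"] == "A3S", "genes"].iloc[0] == 1

    def test_empty_event_set_is_all_zero(self):
        df = count_events([])
        assert len(df) == 0 and df.attrs["total_events"] == 0

    def test_percentages_truncate_like_the_published_table(self):
        counts = [1710, 1166, 823, 189, 12, 1]
        total = sum(counts)
        assert total == 3901
        assert [truncate_pct(c, total) for c in counts] == [43, 29, 21, 4, 0, 0]

    def test_turnover_set_arithmetic(self):
        n, pct = turnover({"a", "b", "c"}, {"b", "d"})
        assert (n, pct) == (2, 67)
        assert turnover({"a"}, {"a"}) == (0, 0)
        assert turnover(set(), {"a"}) == (0, None)
        assert round_half_up_pct(155, 299) == 52

    def test_turnover_count_plus_intersection_is_total(self):
        s24 = {("g", t) for t in "abcdefg"}
        s48 = {("g", t) for t in "defxyz"}
        n, _ = turnover(s24, s48)
        assert n + len(s24 & s48) == len(s24)

    def test_as_gene_fraction(self):
        assert as_gene_fraction(2229, 15754)[0] == 14
        assert as_gene_fraction(0, 15754)[0] == 0
        assert as_gene_fraction(15754, 15754)[0] == 100
        with pytest.raises(ValueError):
            as_gene_fraction(10, 0)

    def test_common_events_threshold_and_monotonicity(self):
        per_var = {
            "V1": {("g1", "A3S"), ("g2", "IR")},
            "V2": {("g1", "A3S"), ("g2", "IR")},
            "V3": {("g1", "A3S")},
            "V4": {("g3", "ES")},
        }
        common3 = common_events(per_var, 3)
        assert common3 == {("g1", "A3S")}
        assert common_events(per_var, 2) >= common3
        assert common_events(per_var, 4) <= common3
        with pytest.raises(ValueError):
            common_events({"V1": set()}, 3)

    def test_events_never_fewer_than_genes(self):
        events = [ASEvent("g", "A3S", (1, 2), "V1", "24h"),
                  ASEvent("g", "A3S", (1, 3), "V1", "24h"),
                  ASEvent("h", "IR", (5, 9), "V1", "24h")]
        df = count_events(events)
        assert (df["events"] >= df["genes"]).all()

    def test_accounting_table_layout(self):
        events = [ASEvent("g1", "A3S", (1, 2), "V1", "24h"),
                  ASEvent("g1", "A3S", (1, 2), "V1", "48h"),
                  ASEvent("g2", "A3S", (3, 4), "V1", "24h")]
        df = accounting_table(events)
        row = df[(df["variety"] == "V1") & (df["as_type"] == "A3S")].iloc[0]
        assert (row["events_24h"], row["events_48h"]) == (2, 1)
        assert row["turnover"] == 1 and row["turnover_pct"] == 50


class TestPublishedArithmetic:
    def test_variety_summary_reproduces_printed_percentages(self):
        df = published.variety_summary()
        bass24 = df[df["variety"] == "Bass"]
        assert list(bass24["pct_24h"]) == [43, 29, 21, 4, 0, 0]
        assert list(bass24["pct_48h"]) == [42, 36, 18, 2, 0, 0]
        import pandas as pd
        assert [int(p) for p in bass24["turnover_pct"] if pd.notna(p)] == [64, 54, 74]
        harr = df[df["variety"] == "Harrington"]
        assert list(harr["pct_24h"]) == [46, 29, 20, 2, 0, 0]
        assert harr["total_events_24h"].iloc[0] == 2635
        assert harr["as_gene_pct_24h"].iloc[0] == 14
        bass = df[df["variety"] == "Bass"]
        assert bass["as_gene_pct_24h"].iloc[0] == 20
        assert bass["events_per_gene_24h"].iloc[0] == pytest.approx(3901 / 3201)

    def test_common_summary_uses_24h_denominator_and_rounding(self):
        df = published.common_summary()
        assert df.attrs["total_24h"] == 669 and df.attrs["total_48h"] == 549
        assert list(df["pct_24h"]) == [45, 34, 21]
        assert list(df["pct_48h"]) == [34, 32, 16]
        assert list(df["turnover_pct"]) == [52, 46, 57]


class TestMxeEndToEnd:
    def test_planted_mutually_exclusive_exons_are_called(self):
        """Opt-in MXE simulation: the two skip-isoforms yield one MXE call."""
        from conftest import clean_sim_params
        from asplice.aligner import AlignParams, KmerIndex, align_pairs
        from asplice.asclassify import build_intron_evidence
        from asplice.simgen import generate_dataset
        from asplice.splicefinder import JunctionParams, call_junctions

        params = clean_sim_params(mxe_mode=True, as_fraction=0.2,
                                  exons_per_gene=(4, 5), seed=19)
        res = generate_dataset(params)
        planted = [e for e in res.truth.as_events if e.as_type == "MXE"]
        assert planted
        idx = KmerIndex(res.chrom_seqs, 32)
        alignments, ium = align_pairs(res.libraries["V1_24h"], idx, AlignParams())
        jp = JunctionParams(max_intron=params.intron_length[1])
        junctions = call_junctions(ium, KmerIndex(res.chrom_seqs, jp.anchor), jp)
        evidence = build_intron_evidence(
            alignments, {c: len(s) for c, s in res.chrom_seqs.items()})
        events, _ = classify_events(junctions, evidence, res.genes, ClassifyParams())
        called = [e for e in events if e.as_type == "MXE"]
        assert {(e.gene_id, e.coordinates) for e in called} == \
            {(e.gene_id, e.coordinates) for e in planted}
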
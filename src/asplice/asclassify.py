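"""Classification of splicing evidence into AS event types, and accounting.

Observed junctions are compared, strand-aware, against each gene's
annotated introns: a junction sharing its donor but not its acceptor is
alternative 3' splicing (A3S), the mirror case is A5S, a junction joining
the donor of intron *i* to the acceptor of intron *i+1* skips the exon
between them (ES), and a junction whose inner anchor matches the first or
last annotated splice site while its outer anchor falls outside the
terminal exon substitutes that exon (AFE/ALE). Intron retention (IR) is
called from contiguous coverage: an annotated intron covered over at least
``ir_coverage`` of its bases with both exon-intron boundaries spanned by
contiguous reads. Two ES-like junctions skipping distinct adjacent exons
combine into a mutually-exclusive-exon (MXE) call.

Accounting reproduces the published table conventions: AS-type
percentages truncate to integer, turnover percentages round half to up.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aligner import Alignment
from .models import ASEvent, GeneModel, SpliceJunction


@dataclass
class ClassifyParams:
    ir_coverage: float = 0.9
    #: bases a read must reach past an exon-intron boundary on each side for
    #: the boundary to count as spanned; 1 = the read covers both flanking bases
    boundary_anchor: int = 1
    min_junction_support: int = 1


@dataclass
class IntronEvidence:
    """Per-base coverage and boundary-crossing masks from contiguous reads."""

    cov: dict[str, np.ndarray]
    cross: dict[str, np.ndarray]


def build_intron_evidence(alignments: list[Alignment], chrom_lengths: dict[str, int],
                          anchor: int = 1) -> IntronEvidence:
    """Coverage arrays from uniquely mapped contiguous alignments.

    ``cross[chrom][b]`` is true when some read spans the inter-base
    boundary at ``b`` with at least ``anchor`` bases on each side.
    """
    cov = {c: np.zeros(n + 1, dtype=np.int32) for c, n in chrom_lengths.items()}
    cross = {c: np.zeros(n + 1, dtype=bool) for c, n in chrom_lengths.items()}
    for a in alignments:
        if a.uniqueness != "unique":
            continue
        cov[a.chrom][a.start] += 1
        cov[a.chrom][a.end] -= 1
        lo, hi = a.start + anchor, a.end - anchor
        if lo <= hi:
            cross[a.chrom][lo : hi + 1] = True
    return IntronEvidence({c: np.cumsum(d[:-1]) for c, d in cov.items()},
                          {c: x[:-1] for c, x in cross.items()})


class _GeneLocator:
    def __init__(self, genes: list[GeneModel]):
        self.by_chrom: dict[str, tuple[list[int], list[GeneModel]]] = {}
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            starts, gl = self.by_chrom.setdefault(g.chrom, ([], []))
            starts.append(g.start)
            gl.append(g)

    def locate(self, chrom: str, pos: int) -> GeneModel | None:
        if chrom not in self.by_chrom:
            return None
        starts, genes = self.by_chrom[chrom]
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and genes[i].start <= pos < genes[i].end:
            return genes[i]
        return None


def classify_events(junctions: list[SpliceJunction], evidence: IntronEvidence | None,
                    genes: list[GeneModel], params: ClassifyParams | None = None,
                    variety: str = "", timepoint: str = ""):
    """Turn junctions plus intron coverage into typed AS events.

    Returns ``(events, diagnostics)``; junctions attributable to no gene
    are counted as intergenic and excluded.
    """
    params = params or ClassifyParams()
    locator = _GeneLocator(genes)
    diag = {"intergenic": 0, "unclassified": 0, "strand_conflict": 0, "constitutive": 0}
    events: list[ASEvent] = []
    es_by_gene: dict[str, list[tuple[int, ASEvent]]] = {}

    for jn in junctions:
        if jn.support < params.min_junction_support:
            continue
        gene = locator.locate(jn.chrom, jn.acceptor_start) or locator.locate(jn.chrom, jn.donor_end)
        if gene is None:
            diag["intergenic"] += 1
            continue
        if jn.strand != gene.strand:
            diag["strand_conflict"] += 1
            continue
        call = _classify_junction(jn, gene)
        if call is None:
            diag["unclassified"] += 1
            continue
        if call == "constitutive":
            diag["constitutive"] += 1
            continue
        as_type, skipped = call
        ev = ASEvent(gene.gene_id, as_type, (jn.donor_end, jn.acceptor_start),
                     variety, timepoint, jn.support)
        if as_type == "ES":
            es_by_gene.setdefault(gene.gene_id, []).append((skipped, ev))
        else:
            events.append(ev)

    events.extend(_merge_mxe(es_by_gene, variety, timepoint))

    if evidence is not None:
        events.extend(_call_intron_retention(evidence, genes, params, variety, timepoint))
    return events, diag


def _classify_junction(jn: SpliceJunction, gene: GeneModel):
    """Type a single junction against one gene's annotation.

    Returns ``"constitutive"``, ``(as_type, skipped_exon_index_or_None)``,
    or None for an unclassifiable junction.
    """
    istart, iend = jn.intron_start, jn.intron_end
    introns = gene.introns
    starts = {s: i for i, (s, _) in enumerate(introns)}
    ends = {e: i for i, (_, e) in enumerate(introns)}
    if istart in starts and iend in ends:
        i, j = starts[istart], ends[iend]
        if i == j:
            return "constitutive"
        if j == i + 1:
            return ("ES", i + 1)  # exon between introns i and i+1 is skipped
        return None  # multi-exon skip: outside the recognized typology
    plus = gene.strand == "+"
    if introns:
        # terminal-exon substitution: inner splice site shared, outer anchor
        # beyond the annotated terminal exon
        if iend == introns[0][1] and jn.donor_end < gene.start:
            return (("AFE" if plus else "ALE"), None)
        if istart == introns[-1][0] and jn.acceptor_start > gene.end:
            return (("ALE" if plus else "AFE"), None)
    if istart in starts:
        return (("A3S" if plus else "A5S"), None)  # novel acceptor / donor
    if iend in ends:
        return (("A5S" if plus else "A3S"), None)
    return None


def _merge_mxe(es_by_gene, variety, timepoint):
    """Combine ES calls on distinct adjacent exons into MXE events."""
    out = []
    for gene_id, calls in es_by_gene.items():
        calls.sort(key=lambda t: t[0])
        used = set()
        for (k1, e1), (k2, e2) in zip(calls, calls[1:]):
            if k2 == k1 + 1 and k1 not in used and k2 not in used:
                coords = tuple(e1.coordinates) + tuple(e2.coordinates)
                out.append(ASEvent(gene_id, "MXE", coords, variety, timepoint,
                                   e1.support + e2.support))
                used.update((k1, k2))
        out.extend(ev for k, ev in calls if k not in used)
    return out


def _call_intron_retention(evidence, genes, params, variety, timepoint):
    out = []
    for g in genes:
        cov = evidence.cov[g.chrom]
        cross = evidence.cross[g.chrom]
        for s, e in g.introns:
            frac = float((cov[s:e] > 0).mean())
            if frac >= params.ir_coverage and cross[s] and cross[e]:
                out.append(ASEvent(g.gene_id, "IR", (s, e), variety, timepoint,
                                   int(round(float(cov[s:e].mean())))))
    return out


# ---------------------------------------------------------------------------
# accounting


def truncate_pct(count: int, total: int) -> int:
    """Integer percentage by truncation (43.8% prints as 43)."""
    if total == 0:
        raise ValueError("percentage of an empty total")
    return int(100 * count / total)


def round_half_up_pct(count: int, total: int) -> int:
    """Integer percentage rounding halves up (51.8% prints as 52)."""
    if total == 0:
        raise ValueError("percentage of an empty total")
    return int(math.floor(100 * count / total + 0.5))


def count_events(events: list[ASEvent]) -> pd.DataFrame:
    """Distinct event and gene counts per AS type.

    Events are distinct (gene, type, coordinates); genes are distinct
    (gene, type). Adds truncated and unrounded percentages of each type
    over the total event count.
    """
    distinct_events = {(e.gene_id, e.as_type, e.coordinates) for e in events}
    distinct_genes = {(e.gene_id, e.as_type) for e in events}
    types = sorted({t for _, t, _ in distinct_events})
    rows = []
    total = len(distinct_events)
    for t in types:
        n_ev = sum(1 for _, tt, _ in distinct_events if tt == t)
        n_g = sum(1 for _, tt in distinct_genes if tt == t)
        rows.append({"as_type": t, "events": n_ev, "genes": n_g,
                     "pct": truncate_pct(n_ev, total) if total else 0,
                     "pct_unrounded": 100 * n_ev / total if total else 0.0})
    df = pd.DataFrame(rows, columns=["as_type", "events", "genes", "pct", "pct_unrounded"])
    df.attrs["total_events"] = total
    df.attrs["total_genes"] = len({g for g, _ in distinct_genes})
    return df


def events_per_gene(n_events: int, n_genes: int) -> float:
    if n_genes == 0:
        raise ValueError("no AS genes")
    return n_events / n_genes


def common_events(per_variety: dict[str, set[tuple[str, str]]],
                  min_varieties: int = 3) -> set[tuple[str, str]]:
    """(gene, type) entries present in at least ``min_varieties`` varieties."""
    if len(per_variety) < min_varieties:
        raise ValueError(
            f"need at least {min_varieties} varieties, got {len(per_variety)}")
    tally: dict[tuple[str, str], int] = {}
    for keys in per_variety.values():
        for key in keys:
            tally[key] = tally.get(key, 0) + 1
    return {key for key, n in tally.items() if n >= min_varieties}


def turnover(set_24h: set, set_48h: set):
    """Entries present at 24 h but gone at 48 h: ``(count, pct | None)``."""
    disappeared = set_24h - set_48h
    if not set_24h:
        return 0, None
    return len(disappeared), round_half_up_pct(len(disappeared), len(set_24h))


def as_gene_fraction(as_gene_count: int, intron_gene_count: int):
    """Share of intron-containing genes undergoing AS: (rounded %, exact %)."""
    if intron_gene_count <= 0:
        raise ValueError("intron-containing gene count must be positive")
    pct = 100 * as_gene_count / intron_gene_count
    return int(math.floor(pct + 0.5)), pct


def event_keys(events: list[ASEvent]) -> set[tuple[str, str]]:
    return {e.key for e in events}


def accounting_table(events: list[ASEvent], timepoints=("24h", "48h")) -> pd.DataFrame:
    """Per-variety accounting mirroring the published table layout."""
    rows = []
    varieties = sorted({e.variety for e in events})
    for v in varieties:
        by_tp = {tp: [e for e in events if e.variety == v and e.timepoint == tp]
                 for tp in timepoints}
        counts = {tp: count_events(evs) for tp, evs in by_tp.items()}
        keys = {tp: event_keys(evs) for tp, evs in by_tp.items()}
        types = sorted({t for df in counts.values() for t in df["as_type"]})
        for t in types:
            row = {"variety": v, "as_type": t}
            for tp in timepoints:
                df = counts[tp]
                sel = df[df["as_type"] == t]
                row[f"events_{tp}"] = int(sel["events"].iloc[0]) if len(sel) else 0
                row[f"genes_{tp}"] = int(sel["genes"].iloc[0]) if len(sel) else 0
                row[f"pct_{tp}"] = int(sel["pct"].iloc[0]) if len(sel) else 0
            if len(timepoints) == 2:
                k24 = {k for k in keys[timepoints[0]] if k[1] == t}
                k48 = {k for k in keys[timepoints[1]] if k[1] == t}
                n, pct = turnover(k24, k48)
                row["turnover"] = n
                row["turnover_pct"] = pct
            rows.append(row)
    return pd.DataFrame(rows)
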
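"""Expression quantification, Poisson-exact differential expression, and
co-expression screening.

Expression is RPKM = 1e9 * C / (N * L) with C the reads mapped perfectly
and uniquely to a gene, N the library's total uniquely gene-mapped reads
and L the gene's exonic length. Differential expression between two
libraries uses the exact conditional Poisson test of Audic & Claverie:
given x reads in a library of depth N1, the count y in a library of depth
N2 follows

    p(y|x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

a negative-binomial predictive distribution; the reported p-value sums the
observed tail in both orientations (symmetrised, clipped at 1) and is
computed through scipy's log-space negative-binomial tails — never naive
factorials. Genes are called differentially expressed at FDR <= 0.001
(Benjamini-Hochberg) with |log2 ratio| >= 1.
"""

from __future__ import annotations

import logging
from bisect import bisect_right

import numpy as np
import pandas as pd
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

from .aligner import Alignment
from .models import GeneModel

log = logging.getLogger(__name__)


def rpkm(C: int, N: int, L: int) -> float:
    """Reads per kilobase of gene per million uniquely mapped reads."""
    if N <= 0:
        raise ValueError("library total N must be positive")
    if L <= 0:
        raise ValueError("gene length L must be positive")
    return 1e9 * C / (N * L)


def count_gene_reads(alignments: list[Alignment], genes: list[GeneModel]):
    """Per-gene perfect unique read counts and the library total N.

    A read counts toward a gene when it aligned uniquely with zero
    mismatches and starts within the gene span. N is the number of reads
    counted on any gene.
    """
    order = sorted(genes, key=lambda g: (g.chrom, g.start))
    starts: dict[str, tuple[list[int], list[GeneModel]]] = {}
    for g in order:
        s, gl = starts.setdefault(g.chrom, ([], []))
        s.append(g.start)
        gl.append(g)
    counts = {g.gene_id: 0 for g in genes}
    N = 0
    for a in alignments:
        if a.uniqueness != "unique" or a.mismatches != 0 or a.chrom not in starts:
            continue
        pos_list, gl = starts[a.chrom]
        i = bisect_right(pos_list, a.start) - 1
        if i >= 0 and gl[i].start <= a.start < gl[i].end:
            counts[gl[i].gene_id] += 1
            N += 1
    return counts, N


def expression_table(counts: dict[str, int], N: int, genes: list[GeneModel]) -> pd.DataFrame:
    rows = [{"gene_id": g.gene_id, "C": counts.get(g.gene_id, 0), "N": N,
             "L": g.exonic_length,
             "rpkm": rpkm(counts.get(g.gene_id, 0), N, g.exonic_length)}
            for g in genes]
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# differential expression


def poisson_de_test(x: int, y: int, N1: float, N2: float) -> float:
    """Two-sided exact conditional Poisson (Audic-Claverie) p-value.

    Symmetric in (x, N1) <-> (y, N2); equal observed rates give p = 1.
    Tail sums run in log space through the negative-binomial distribution
    with r = x + 1 successes and success probability N1 / (N1 + N2).
    """
    if x < 0 or y < 0 or int(x) != x or int(y) != y:
        raise ValueError("counts must be non-negative integers")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    x, y = int(x), int(y)
    if x * N2 == y * N1:
        return 1.0
    p1 = N1 / (N1 + N2)
    p2 = N2 / (N1 + N2)
    if y * N1 > x * N2:  # second library enriched
        tail = nbinom.sf(y - 1, x + 1, p1) + nbinom.cdf(x, y + 1, p2)
    else:
        tail = nbinom.cdf(y, x + 1, p1) + nbinom.sf(x - 1, y + 1, p2)
    return float(min(1.0, tail))


def call_degs(counts1: dict[str, int] | pd.Series, counts2: dict[str, int] | pd.Series,
              N1: int, N2: int, lengths: dict[str, int],
              fdr_threshold: float = 0.001, min_abs_log2: float = 1.0,
              pseudocount: float = 0.1) -> pd.DataFrame:
    """Screen differentially expressed genes between two libraries.

    ``pseudocount`` (in RPKM units) stabilises log2 ratios at zero counts.
    Returns a per-gene table with p-value, BH FDR, log2 ratio and the
    significance call under the double threshold.
    """
    if N1 <= 0 or N2 <= 0:
        raise ValueError("a condition has zero total reads")
    c1, c2 = pd.Series(counts1), pd.Series(counts2)
    gene_ids = c1.index
    pvals = np.array([poisson_de_test(int(c1[g]), int(c2[g]), N1, N2) for g in gene_ids])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    r1 = np.array([rpkm(int(c1[g]), N1, lengths[g]) for g in gene_ids])
    r2 = np.array([rpkm(int(c2[g]), N2, lengths[g]) for g in gene_ids])
    log2_ratio = np.log2((r2 + pseudocount) / (r1 + pseudocount))
    out = pd.DataFrame({
        "gene_id": gene_ids, "count_1": c1.values, "count_2": c2.values,
        "rpkm_1": r1, "rpkm_2": r2, "p_value": pvals, "fdr": fdr,
        "log2_ratio": log2_ratio,
        "significant": (fdr <= fdr_threshold) & (np.abs(log2_ratio) >= min_abs_log2),
    }).set_index("gene_id")
    return out


# ---------------------------------------------------------------------------
# co-expression


def coexpression(rpkm_matrix: pd.DataFrame, focal_genes: list[str],
                 threshold: float = 0.9, log_transform: bool = False) -> pd.DataFrame:
    """Pearson co-expression edges of focal genes across libraries.

    ``rpkm_matrix`` is genes x libraries. Edges with |r| >= ``threshold``
    are kept (both signs — negative co-expression is informative);
    zero-variance profiles are skipped with a log entry.
    """
    if rpkm_matrix.shape[1] < 3:
        raise ValueError("co-expression needs at least 3 libraries")
    X = rpkm_matrix.to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        log.info("skipping %d zero-variance genes in co-expression", int((~keep).sum()))
    Z = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    names = rpkm_matrix.index[keep]
    name_pos = {g: i for i, g in enumerate(names)}
    n = X.shape[1]
    edges = []
    for focal in focal_genes:
        if focal not in name_pos:
            log.info("focal gene %s has zero variance or is absent; skipped", focal)
            continue
        r = Z @ Z[name_pos[focal]] / n
        for j in np.nonzero(np.abs(r) >= threshold)[0]:
            if names[j] != focal:
                edges.append({"focal_gene": focal, "partner_gene": names[j],
                              "r": float(np.clip(r[j], -1.0, 1.0))})
    return pd.DataFrame(edges, columns=["focal_gene", "partner_gene", "r"])


def pathway_summary(edges: pd.DataFrame, gene_pathways: pd.DataFrame) -> pd.DataFrame:
    """Distinct co-expressed partners per pathway for each focal gene.

    ``gene_pathways`` has columns (gene_id, pathway); a partner annotated
    to several pathways counts once in each, and partners missing from the
    annotation are tallied under "unannotated".
    """
    ann: dict[str, list[str]] = {}
    for gid, pw in zip(gene_pathways["gene_id"], gene_pathways["pathway"]):
        ann.setdefault(gid, []).append(pw)
    rows: dict[tuple[str, str], set[str]] = {}
    for _, e in edges.iterrows():
        pathways = ann.get(e["partner_gene"], ["unannotated"])
        for pw in set(pathways):
            rows.setdefault((e["focal_gene"], pw), set()).add(e["partner_gene"])
    out = [{"focal_gene": f, "pathway": pw, "n_partners": len(partners)}
           for (f, pw), partners in sorted(rows.items())]
    return pd.DataFrame(out, columns=["focal_gene", "pathway", "n_partners"])
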
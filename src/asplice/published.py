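"""Published AS accounting for four barley varieties at 24 h and 48 h of
embryo germination, and the derived table arithmetic.

The bundled tables hold the reported event, gene and turnover counts per
variety and AS type, plus the counts of (gene, type) AS transcripts common
to at least three of the four varieties. Re-deriving the printed
percentages, events-per-gene ratios and turnover fractions from these raw
counts exercises the same accounting operations the pipeline applies to
its own calls.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from . import asclassify

#: Number of intron-containing genes in the barley annotation used as the
#: denominator of AS-gene fractions.
INTRON_CONTAINING_GENES = 15754

#: Type percentages in the common-transcript table use the 24 h total as
#: denominator for both timepoints.
COMMON_TABLE_DENOMINATOR_IS_24H = True


def _load(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("asplice.data").joinpath(name)
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_variety_counts() -> pd.DataFrame:
    """Per-variety AS event/gene/turnover counts (long format)."""
    return _load("barley_as_counts.tsv")


def load_common_counts() -> pd.DataFrame:
    """Counts of AS transcripts common to >= 3 of 4 varieties."""
    return _load("barley_common_as_counts.tsv")


def variety_summary() -> pd.DataFrame:
    """Recompute the printed percentages and ratios from the raw counts.

    Adds, per variety and AS type: truncated type percentages at both
    timepoints, half-up-rounded turnover percentages (over 24 h gene
    counts), and per-variety totals with events-per-gene ratios and
    AS-gene fractions.
    """
    df = load_variety_counts().copy()
    rows = []
    for variety, sub in df.groupby("variety", sort=False):
        tot_ev24 = int(sub["events_24h"].sum())
        tot_ev48 = int(sub["events_48h"].sum())
        tot_g24 = int(sub["genes_24h"].sum())
        tot_g48 = int(sub["genes_48h"].sum())
        for _, r in sub.iterrows():
            row = dict(r)
            row["pct_24h"] = asclassify.truncate_pct(int(r["events_24h"]), tot_ev24)
            row["pct_48h"] = asclassify.truncate_pct(int(r["events_48h"]), tot_ev48)
            if pd.notna(r["turnover"]):
                row["turnover_pct"] = asclassify.round_half_up_pct(
                    int(r["turnover"]), int(r["genes_24h"]))
            else:
                row["turnover_pct"] = None
            row.update(total_events_24h=tot_ev24, total_events_48h=tot_ev48,
                       total_genes_24h=tot_g24, total_genes_48h=tot_g48,
                       events_per_gene_24h=asclassify.events_per_gene(tot_ev24, tot_g24),
                       as_gene_pct_24h=asclassify.as_gene_fraction(
                           tot_g24, INTRON_CONTAINING_GENES)[0],
                       as_gene_pct_48h=asclassify.as_gene_fraction(
                           tot_g48, INTRON_CONTAINING_GENES)[0])
            rows.append(row)
    return pd.DataFrame(rows)


def common_summary() -> pd.DataFrame:
    """Recompute percentages of the common-transcript table.

    Both timepoint percentages use the 24 h total as denominator (the
    convention the printed 48 h column follows), rounded half-up; turnover
    percentages are over the 24 h count of the same type.
    """
    df = load_common_counts().copy()
    tot24 = int(df["n_24h"].sum())
    df["pct_24h"] = [asclassify.round_half_up_pct(int(n), tot24) for n in df["n_24h"]]
    df["pct_48h"] = [asclassify.round_half_up_pct(int(n), tot24) for n in df["n_48h"]]
    df["turnover_pct"] = [asclassify.round_half_up_pct(int(t), int(n))
                          for t, n in zip(df["turnover"], df["n_24h"])]
    df.attrs["total_24h"] = tot24
    df.attrs["total_48h"] = int(df["n_48h"].sum())
    return df
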
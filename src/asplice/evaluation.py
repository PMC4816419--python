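"""Truth-set benchmarks and reference (brute-force) implementations.

The recovery benchmarks regenerate a no-noise synthetic experiment, run
alignment, junction calling and event classification, and score the calls
against the planted truth. The junction caller's intron-size window is
calibrated to the generator's configured intron bounds — the same way the
published workflow chose its 50-50,000 bp window from the known intron
sizes of the organism.

The brute-force junction caller here is a deliberately naive re-derivation
of the placement rules (string scanning, exhaustive split enumeration)
used to validate the indexed implementation on small references.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .aligner import AlignParams, KmerIndex, align_pairs
from .asclassify import ClassifyParams, build_intron_evidence, classify_events
from .models import revcomp
from .simgen import SimParams, generate_dataset
from .splicefinder import JunctionParams, call_junctions

#: Study-condition simulation for recovery benchmarks: ~1 Mb genome,
#: 200 genes, 50 expected pairs per gene, 90 bp reads, introns 50-5000 bp,
#: all three motif classes, no sequencing noise, one library.
BENCHMARK_SIM = dict(
    n_chromosomes=2, chrom_length=500_000, n_genes=200,
    intron_length=(50, 5000), depth=50.0, read_length=90,
    error_rate=0.0, adapter_rate=0.0, n_rate=0.0,
    n_varieties=1, timepoints=("24h",), event_active_prob=1.0,
)

#: Balanced type mix for per-type classification scoring; the generator's
#: default mix leaves terminal-exon events too rare to measure.
BALANCED_MIX = {"A3S": 0.2, "IR": 0.2, "A5S": 0.2, "ES": 0.2, "AFE": 0.1, "ALE": 0.1}


def benchmark_params(seed: int, **overrides) -> SimParams:
    kwargs = dict(BENCHMARK_SIM)
    kwargs.update(overrides)
    return SimParams(seed=seed, **kwargs)


def _run_library(params: SimParams):
    """Simulate one library and run it through align + junctions + classify."""
    result = generate_dataset(params)
    lib = next(iter(result.libraries))
    pairs = result.libraries[lib]
    index = KmerIndex(result.chrom_seqs, AlignParams().seed_length)
    alignments, ium = align_pairs(pairs, index, AlignParams())
    jparams = JunctionParams(min_intron=params.intron_length[0],
                             max_intron=params.intron_length[1])
    index9 = KmerIndex(result.chrom_seqs, jparams.anchor)
    junctions = call_junctions(ium, index9, jparams)
    chrom_lengths = {c: len(s) for c, s in result.chrom_seqs.items()}
    evidence = build_intron_evidence(alignments, chrom_lengths,
                                     ClassifyParams().boundary_anchor)
    events, _ = classify_events(junctions, evidence, result.genes, ClassifyParams())
    return result, junctions, events


def junction_recovery(seeds, **sim_overrides) -> dict:
    """Pooled recall/precision of planted junctions over several seeds."""
    tp = n_truth = n_called = 0
    for seed in seeds:
        result, junctions, _ = _run_library(benchmark_params(seed, **sim_overrides))
        called = {j.key for j in junctions}
        truth = {j.key for j in result.truth.junctions}
        tp += len(called & truth)
        n_truth += len(truth)
        n_called += len(called)
    return {"recall": tp / n_truth, "precision": tp / n_called,
            "n_truth": n_truth, "n_called": n_called}


def classification_recovery(seeds, **sim_overrides) -> dict:
    """Per-AS-type recall/precision of planted events over several seeds."""
    overrides = dict(as_type_mix=dict(BALANCED_MIX))
    overrides.update(sim_overrides)
    per_type: dict[str, dict[str, int]] = {}
    mxe_calls = 0
    for seed in seeds:
        result, _, events = _run_library(benchmark_params(seed, **overrides))
        called = {(e.gene_id, e.as_type) for e in events}
        truth = {(e.gene_id, e.as_type) for e in result.truth.as_events}
        mxe_calls += sum(1 for e in events if e.as_type == "MXE")
        for t in {k[1] for k in truth} | {k[1] for k in called}:
            d = per_type.setdefault(t, {"tp": 0, "fn": 0, "fp": 0})
            ct = {k for k in called if k[1] == t}
            tt = {k for k in truth if k[1] == t}
            d["tp"] += len(ct & tt)
            d["fn"] += len(tt - ct)
            d["fp"] += len(ct - tt)
    out = {}
    for t, d in per_type.items():
        out[t] = {
            "recall": d["tp"] / (d["tp"] + d["fn"]) if d["tp"] + d["fn"] else None,
            "precision": d["tp"] / (d["tp"] + d["fp"]) if d["tp"] + d["fp"] else None,
            **d,
        }
    return {"per_type": out, "mxe_calls": mxe_calls}


# ---------------------------------------------------------------------------
# brute-force references


def bruteforce_poisson_p(x: int, y: int, N1: int, N2: int) -> Fraction:
    """Exact-arithmetic tail sum of the conditional Poisson test."""
    q = Fraction(N2, N1)

    def pmf(yy: int, xx: int, qq: Fraction) -> Fraction:
        from math import comb

        return Fraction(comb(xx + yy, yy)) * qq**yy / (1 + qq) ** (xx + yy + 1)

    if Fraction(x, N1) == Fraction(y, N2):
        return Fraction(1)

    def upper(obs_a, obs_b, qq):  # P(B >= obs_b | obs_a)
        return 1 - sum(pmf(t, obs_a, qq) for t in range(obs_b))

    def lower(obs_a, obs_b, qq):  # P(B <= obs_b | obs_a)
        return sum(pmf(t, obs_a, qq) for t in range(obs_b + 1))

    if Fraction(y, N2) > Fraction(x, N1):
        p = upper(x, y, q) + lower(y, x, 1 / q)
    else:
        p = lower(x, y, q) + upper(y, x, 1 / q)
    return min(Fraction(1), p)


def _scan(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def _bf_motif(genome: str, s: int, e: int):
    pairs = [("GT", "AG"), ("GC", "AG"), ("AT", "AC")]
    left, right = genome[s : s + 2], genome[e - 2 : e]
    for rank, (d, a) in enumerate(pairs):
        if left == d and right == a:
            return rank
    rc = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for rank, (d, a) in enumerate(pairs):
        if left == a[::-1].translate(str.maketrans(rc)) and \
           right == d[::-1].translate(str.maketrans(rc)):
            return rank
    return None


def _bf_split(seq: str) -> list[str]:
    if len(seq) <= 50:
        return [seq]
    parts = []
    rest = seq
    while len(rest) > 100:
        parts.append(rest[:50])
        rest = rest[50:]
    half = (len(rest) + 1) // 2
    parts.extend([rest[:half], rest[half:]])
    return parts


def _bf_placements(sub: str, genome: str, params: JunctionParams):
    placements = [(p, p + len(sub), None, 99, 0) for p in _scan(genome, sub)]
    n = len(sub)
    for s in range(params.min_segment + 1, n - params.min_segment):
        donors = _scan(genome, sub[:s])
        acceptors = _scan(genome, sub[s:])
        if not donors or not acceptors:
            continue
        if len(donors) > 1 and len(acceptors) > 1:
            continue
        pairs = []
        for d in donors:
            for q in acceptors:
                intron = q - (d + s)
                if params.min_intron <= intron <= params.max_intron:
                    rank = _bf_motif(genome, d + s, q)
                    if rank is not None:
                        pairs.append((intron, rank, d, q))
        if pairs:
            intron, rank, d, q = min(pairs, key=lambda t: (t[1], t[0], t[2]))
            placements.append((d, q + (n - s), (d + s - 1, q), rank, intron))
    return placements


def bruteforce_call_junctions(reads, genome: str, params: JunctionParams):
    """Exhaustive junction calling on a single-sequence reference.

    Enumerates every split point and every genomic placement by string
    scanning, applies the same placement criteria and tie-breaks, and
    returns ``{(donor_end, acceptor_start): support}``.
    """
    support: dict[tuple[int, int], int] = {}
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        # whole-read two-segment placement first
        whole = []
        for oriented in (seq, revcomp(seq)):
            whole.extend(p for p in _bf_placements(oriented, genome, params)
                         if p[2] is not None)
        if whole:
            p = min(whole, key=lambda p: (p[3], p[4], p[0]))
            support[p[2]] = support.get(p[2], 0) + 1
            continue
        best = None
        for oriented in (seq, revcomp(seq)):
            subs = _bf_split(oriented)
            per = [_bf_placements(s, genome, params) for s in subs]
            if any(not p for p in per):
                continue
            chains = [[]]
            for options in per:
                chains = [c + [p] for c in chains for p in options
                          if not c or p[0] >= c[-1][1]]
            for chain in chains:
                junctions = []
                ok = True
                for prev, nxt in zip(chain, chain[1:]):
                    gap = nxt[0] - prev[1]
                    if gap == 0:
                        continue
                    rank = _bf_motif(genome, prev[1], nxt[0]) \
                        if params.min_intron <= gap <= params.max_intron else None
                    if rank is None:
                        ok = False
                        break
                    junctions.append((prev[1] - 1, nxt[0], rank, gap))
                if not ok:
                    continue
                for p in chain:
                    if p[2] is not None:
                        junctions.append((*p[2], p[3], p[4]))
                score = (tuple(sorted(j[2] for j in junctions)),
                         sum(j[3] for j in junctions), chain[0][0])
                if best is None or score < best[0]:
                    best = (score, junctions)
        if best is not None:
            for d, a, _, _ in best[1]:
                support[(d, a)] = support.get((d, a), 0) + 1
    return {k: v for k, v in support.items() if v >= params.min_support}


# ---------------------------------------------------------------------------
# statistical nulls


def de_null_rate(seed: int, n_genes: int = 3000, depth: float = 50.0,
                 gene_length: int = 1000) -> dict:
    """Fraction of genes called differentially expressed under no change."""
    from .quantify import call_degs
    from .simgen import simulate_count_matrix

    c1, c2, N1, N2 = simulate_count_matrix(n_genes, depth, seed=seed)
    ids = [f"g{i}" for i in range(n_genes)]
    degs = call_degs(dict(zip(ids, c1.tolist())), dict(zip(ids, c2.tolist())),
                     N1, N2, {g: gene_length for g in ids})
    n_sig = int(degs["significant"].sum())
    return {"n_genes": n_genes, "n_significant": n_sig,
            "rate": n_sig / n_genes}


def coexpression_null(seed: int, n_genes: int = 2000, n_focal: int = 50,
                      n_libraries: int = 8, threshold: float = 0.9) -> dict:
    """Edge rate among independent expression profiles vs the analytic null.

    The null tail is P(|r| >= t) for the Pearson correlation of two
    independent normal samples of size n, via the exact t transform.
    """
    import pandas as pd
    from scipy.stats import t as t_dist

    from .quantify import coexpression

    rng = np.random.default_rng((seed, 11))
    # normal profiles: the exact t-transform null for Pearson r assumes
    # normal marginals (skewed profiles inflate the small-n tail)
    X = rng.normal(0.0, 1.0, size=(n_genes, n_libraries))
    mat = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)],
                       columns=[f"L{j}" for j in range(n_libraries)])
    focal = [f"g{i}" for i in range(n_focal)]
    edges = coexpression(mat, focal, threshold)
    # focal-focal pairs are counted twice by the star scan; count unique pairs
    pairs = {tuple(sorted((r.focal_gene, r.partner_gene)))
             for r in edges.itertuples()}
    n_tests = n_focal * (n_genes - 1) - n_focal * (n_focal - 1) // 2
    df = n_libraries - 2
    t0 = threshold * np.sqrt(df) / np.sqrt(1 - threshold**2)
    analytic = float(2 * t_dist.sf(t0, df))
    return {"n_pairs_tested": n_tests, "n_edges": len(pairs),
            "edge_rate": len(pairs) / n_tests, "analytic_rate": analytic}
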
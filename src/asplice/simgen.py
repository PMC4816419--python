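"""Synthetic genomes, gene models, alternative isoforms and paired-end reads.

The generator emulates a germinating-embryo RNA-seq experiment over
``n_varieties`` barley-like varieties sampled at two imbibition timepoints.
Every library is drawn from a shared genome in which a configurable
fraction of intron-containing genes carries exactly one planted
alternative-splicing event (alternative acceptor/donor, intron retention,
exon skipping, or an alternative first/last exon). The planted isoforms,
junctions and events form a machine-readable truth set against which every
downstream stage can be scored.

All randomness flows from ``SimParams.seed``; identical parameters produce
bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .models import (
    CANONICAL_MOTIFS,
    ASEvent,
    GeneModel,
    Isoform,
    SpliceJunction,
    motif_of_intron,
    revcomp,
)
from .seqio import ReadRecord

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default AS-type proportions; alternative acceptor usage dominates in
#: germinating barley embryos, intron retention and alternative donor usage
#: follow, terminal-exon events are rare.
DEFAULT_AS_MIX = {"A3S": 0.43, "IR": 0.29, "A5S": 0.21, "ES": 0.04, "AFE": 0.02, "ALE": 0.01}

#: GT-AG introns dominate plant genomes; GC-AG and AT-AC are minor classes.
DEFAULT_MOTIF_MIX = (0.90, 0.07, 0.03)

TRUSEQ_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


@dataclass
class SimParams:
    """Knobs of the synthetic experiment.

    ``depth`` is the expected read-pair count per gene per library.
    ``intron_length`` bounds must stay within [50, 50000] so that planted
    junctions are detectable by the spliced aligner's intron-size rule, and
    ``read_length`` must be at least 17 so both junction segments can
    exceed the 8 bp minimum.
    """

    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_length: tuple[int, int] = (120, 250)
    intron_length: tuple[int, int] = (50, 5000)
    as_fraction: float = 0.5
    as_type_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AS_MIX))
    read_length: int = 90
    fragment_length: tuple[float, float] = (250.0, 30.0)  # mean, sd
    depth: float = 50.0
    error_rate: float = 0.001
    adapter_rate: float = 0.01
    n_rate: float = 0.005
    seed: int = 0
    # experiment design
    n_varieties: int = 4
    timepoints: tuple[str, ...] = ("24h", "48h")
    event_active_prob: float = 0.8
    #: expression share of the alternative isoform where its event is active
    alt_expression_fraction: float = 0.5
    #: lognormal sigma of per-gene expression weights (0 = uniform)
    expression_sigma: float = 0.0
    #: per-gene log2 fold change applied at the second timepoint
    fold_changes: dict[str, float] = field(default_factory=dict)
    # sequence composition
    motif_mix: tuple[float, float, float] = DEFAULT_MOTIF_MIX
    as_offset: tuple[int, int] = (3, 30)
    intergenic_gap: tuple[int, int] = (150, 500)
    adapter_sequence: str = TRUSEQ_ADAPTER
    mxe_mode: bool = False
    #: retained introns skew short in real transcriptomes; genes whose
    #: introns all exceed this length host a different event type instead
    ir_max_intron: int = 500

    def validate(self) -> None:
        if not (50 <= self.intron_length[0] <= self.intron_length[1] <= 50_000):
            raise ValueError("intron_length bounds must lie within [50, 50000]")
        if self.read_length < 17:
            raise ValueError("read_length must be >= 17")
        if self.read_length >= self.fragment_length[0]:
            raise ValueError("read_length must be below the mean fragment length")
        total = sum(self.as_type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"as_type_mix must sum to 1, got {total}")
        if abs(sum(self.motif_mix) - 1.0) > 1e-9:
            raise ValueError("motif_mix must sum to 1")
        for name, p in [("as_fraction", self.as_fraction), ("error_rate", self.error_rate),
                        ("adapter_rate", self.adapter_rate), ("n_rate", self.n_rate),
                        ("event_active_prob", self.event_active_prob)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.exons_per_gene[0] < 2:
            raise ValueError("genes need at least two exons to carry introns")

    def library_ids(self) -> list[str]:
        return [f"V{v + 1}_{tp}" for v in range(self.n_varieties) for tp in self.timepoints]


@dataclass
class SimResult:
    """Everything a single simulation run produced."""

    params: SimParams
    chrom_seqs: dict[str, str]
    genes: list[GeneModel]
    truth: "TruthSet"
    libraries: dict[str, list[tuple[ReadRecord, ReadRecord]]]


from .models import TruthSet  # noqa: E402  (import kept close to its use)


# ---------------------------------------------------------------------------
# internal construction record


@dataclass
class _GeneDraft:
    gene_id: str
    chrom: str
    strand: str
    exons: list[list[int]]
    motif_classes: list[int]  # per annotated intron, index into CANONICAL_MOTIFS
    space_before: tuple[int, int]  # free interval upstream of the gene
    space_after: tuple[int, int]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e0[1], e1[0]) for e0, e1 in zip(self.exons, self.exons[1:])]


def _log_uniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Heavy-tailed intron-length draw: log-uniform over [lo, hi]."""
    if lo == hi:
        return lo
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def generate_genome(params: SimParams):
    """Lay out gene structures and emit the reference sequence.

    Returns ``(chrom_seqs, genes, drafts)``; ``drafts`` carry the mutable
    layout bookkeeping that :func:`plant_as_isoforms` needs (free flanking
    space, intron motif classes). All annotated introns carry a canonical
    boundary motif on the gene strand.
    """
    params.validate()
    rng = np.random.default_rng((params.seed, 1))
    n_chrom = params.n_chromosomes
    drafts: list[_GeneDraft] = []
    cursors = [0] * n_chrom
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]

    for g in range(params.n_genes):
        ci = min(range(n_chrom), key=lambda i: cursors[i])  # fill the emptiest
        gap = int(rng.integers(params.intergenic_gap[0], params.intergenic_gap[1] + 1))
        n_exons = int(rng.integers(params.exons_per_gene[0], params.exons_per_gene[1] + 1))
        exon_lens = [int(rng.integers(params.exon_length[0], params.exon_length[1] + 1))
                     for _ in range(n_exons)]
        intron_lens = [_log_uniform_int(rng, *params.intron_length) for _ in range(n_exons - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        classes = [int(rng.choice(3, p=params.motif_mix)) for _ in range(n_exons - 1)]

        start = cursors[ci] + gap
        exons: list[list[int]] = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append([pos, pos + el])
            pos += el
            if i < n_exons - 1:
                pos += intron_lens[i]
        if pos + params.intergenic_gap[0] > params.chrom_length:
            raise ValueError(
                f"infeasible packing: gene {g + 1} ends at {pos} on {chrom_names[ci]} "
                f"(chromosome length {params.chrom_length})"
            )
        drafts.append(_GeneDraft(
            gene_id=f"gene{g + 1:04d}", chrom=chrom_names[ci], strand=strand,
            exons=exons, motif_classes=classes,
            space_before=(cursors[ci] + 2, start - 2),
            space_after=(pos + 2, pos + gap),  # provisional; trimmed below
        ))
        cursors[ci] = pos

    # the space after a gene extends to the next gene's start on that chromosome
    last_on_chrom: dict[str, _GeneDraft] = {}
    for d in drafts:
        prev = last_on_chrom.get(d.chrom)
        if prev is not None:
            prev.space_after = (prev.exons[-1][1] + 2, d.exons[0][0] - 2)
        last_on_chrom[d.chrom] = d
    for ci, name in enumerate(chrom_names):
        if name in last_on_chrom:
            d = last_on_chrom[name]
            d.space_after = (d.exons[-1][1] + 2, params.chrom_length - 2)

    seqs = {name: rng.integers(0, 4, size=params.chrom_length).astype(np.uint8)
            for name in chrom_names}
    arrays = {name: _BASES[idx].copy() for name, idx in seqs.items()}
    for d in drafts:
        arr = arrays[d.chrom]
        for (s, e), cls in zip(d.introns, d.motif_classes):
            _plant_motif(arr, s, e, cls, d.strand)

    genes = [GeneModel(d.gene_id, d.chrom, d.strand, tuple(tuple(e) for e in d.exons))
             for d in drafts]
    chrom_seqs = {name: arr.tobytes().decode("ascii") for name, arr in arrays.items()}
    return chrom_seqs, genes, drafts


def _plant_motif(arr: np.ndarray, start: int, end: int, cls: int, strand: str) -> None:
    """Write the canonical boundary dinucleotides of one intron."""
    donor, acceptor = CANONICAL_MOTIFS[cls]
    if strand == "+":
        arr[start:start + 2] = np.frombuffer(donor.encode(), dtype=np.uint8)
        arr[end - 2:end] = np.frombuffer(acceptor.encode(), dtype=np.uint8)
    else:
        arr[start:start + 2] = np.frombuffer(revcomp(acceptor).encode(), dtype=np.uint8)
        arr[end - 2:end] = np.frombuffer(revcomp(donor).encode(), dtype=np.uint8)


# ---------------------------------------------------------------------------
# alternative-isoform planting


def plant_as_isoforms(chrom_seqs: dict[str, str], genes: list[GeneModel],
                      drafts: list[_GeneDraft], params: SimParams):
    """Select AS genes, plant one event each, and build the truth set.

    Returns ``(chrom_seqs, truth)``; the sequences are re-emitted because
    alternative splice sites need their own canonical dinucleotides written
    into exonic or intergenic sequence. When a drawn event type cannot be
    hosted by the selected gene (too few exons, no flanking space) the type
    is resampled among the feasible ones and the substitution logged.
    """
    rng = np.random.default_rng((params.seed, 2))
    arrays = {name: np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
              for name, seq in chrom_seqs.items()}

    eligible = [i for i, g in enumerate(genes) if len(g.exons) >= 2]
    n_as = int(round(params.as_fraction * len(eligible)))
    chosen = sorted(rng.choice(len(eligible), size=n_as, replace=False).tolist())
    type_names = list(params.as_type_mix)
    type_probs = np.array([params.as_type_mix[t] for t in type_names], dtype=float)

    truth = TruthSet()
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in arrays}

    for gi in chosen:
        draft = drafts[eligible[gi]]
        gene = genes[eligible[gi]]
        drawn = type_names[int(rng.choice(len(type_names), p=type_probs))]
        order = [drawn] + [t for t in type_names if t != drawn]
        planted = None
        for as_type in order:
            planted = _try_plant(arrays[gene.chrom], gene, draft, as_type, params, rng,
                                 occupied[gene.chrom])
            if planted is not None:
                if as_type != drawn:
                    log.info("gene %s cannot host %s; substituted %s",
                             gene.gene_id, drawn, as_type)
                break
        if planted is None:  # pragma: no cover - only with pathological params
            log.warning("gene %s could not host any AS event", gene.gene_id)
            continue
        alt_exons, event = planted
        truth.as_events.append(event)
        truth.isoforms.setdefault(gene.gene_id, []).append(
            Isoform(f"{gene.gene_id}.alt", gene.gene_id, alt_exons, event.as_type, event))

    if params.mxe_mode:
        _plant_mxe(arrays, genes, drafts, chosen, eligible, truth, rng, params)

    for gene in genes:
        truth.isoforms.setdefault(gene.gene_id, []).insert(
            0, Isoform(f"{gene.gene_id}.ref", gene.gene_id, gene.exons, None, None))

    chrom_seqs = {name: arr.tobytes().decode("ascii") for name, arr in arrays.items()}

    # junction truth derives from the final sequence so the recorded motif is
    # exactly what a caller can observe
    gene_by_id = {g.gene_id: g for g in genes}
    for iso_list in truth.isoforms.values():
        for iso in iso_list:
            gene = gene_by_id[iso.gene_id]
            seq = chrom_seqs[gene.chrom]
            for (s0, e0), (s1, e1) in zip(iso.exons, iso.exons[1:]):
                cls = motif_of_intron(seq, e0, s1)
                if cls is None:  # pragma: no cover - construction guarantees motifs
                    raise AssertionError(f"non-canonical planted intron in {iso.isoform_id}")
                motif, strand = cls
                truth.junctions.add(SpliceJunction(gene.chrom, e0 - 1, s1, strand, motif))
    return chrom_seqs, truth


def _free_interval(space: tuple[int, int], occupied: list[tuple[int, int]],
                   length: int, margin: int) -> tuple[int, int] | None:
    """First sub-interval of ``space`` able to host ``length`` + margins."""
    lo, hi = space
    for s, e in sorted(occupied):
        if s - lo >= length + 2 * margin and lo + margin + length <= hi:
            return lo + margin, lo + margin + length
        lo = max(lo, e)
    if hi - lo >= length + 2 * margin:
        return lo + margin, lo + margin + length
    return None


def _try_plant(arr: np.ndarray, gene: GeneModel, draft: _GeneDraft, as_type: str,
               params: SimParams, rng: np.random.Generator,
               occupied: list[tuple[int, int]]):
    """Plant one event of ``as_type`` on ``gene`` if it is feasible.

    Returns ``(alt_exon_chain, ASEvent)`` or ``None``. Offsets for A3S/A5S
    shrink one exon, so the exon must keep at least 20 bp; terminal-exon
    events need free intergenic space for the substituted exon.
    """
    exons = [tuple(e) for e in draft.exons]
    introns = draft.introns
    n = len(exons)
    lo_off, hi_off = params.as_offset
    plus = gene.strand == "+"
    # an isoform shorter than the size-selected fragments would not be
    # sequenced by the emulated protocol, so it cannot host an event
    min_isoform = int(params.fragment_length[0])

    def _write(pos: int, dinuc: str) -> None:
        arr[pos:pos + 2] = np.frombuffer(dinuc.encode(), dtype=np.uint8)

    if as_type in ("A3S", "A5S"):
        # which exon loses a prefix/suffix depends on type and strand
        shrink_right = (as_type == "A3S") == plus  # shrink exon right of the intron
        candidates = []
        for k, (s, e) in enumerate(introns):
            exon = exons[k + 1] if shrink_right else exons[k]
            off_max = min(hi_off, (exon[1] - exon[0]) - 20,
                          params.intron_length[1] - (e - s))  # keep the
            # alternative intron inside the configured bounds
            if off_max >= lo_off:
                candidates.append((k, off_max))
        if not candidates:
            return None
        k, off_max = candidates[int(rng.integers(len(candidates)))]
        delta = int(rng.integers(lo_off, off_max + 1))
        s, e = introns[k]
        cls = draft.motif_classes[k]
        donor, acceptor = CANONICAL_MOTIFS[cls]
        if shrink_right:
            # intron extended rightwards into the next exon
            new_s, new_e = s, e + delta
            _write(new_e - 2, acceptor if plus else revcomp(donor))
            alt = list(exons)
            alt[k + 1] = (exons[k + 1][0] + delta, exons[k + 1][1])
        else:
            new_s, new_e = s - delta, e
            _write(new_s, donor if plus else revcomp(acceptor))
            alt = list(exons)
            alt[k] = (exons[k][0], exons[k][1] - delta)
        event = ASEvent(gene.gene_id, as_type, (new_s - 1, new_e))
        return tuple(alt), event

    if as_type == "IR":
        # retained introns skew short in real transcriptomes: take the
        # shortest, and only if it is plausibly retainable at all
        k = min(range(n - 1), key=lambda i: introns[i][1] - introns[i][0])
        if introns[k][1] - introns[k][0] > params.ir_max_intron:
            return None
        alt = list(exons)
        merged = (exons[k][0], exons[k + 1][1])
        alt[k:k + 2] = [merged]
        event = ASEvent(gene.gene_id, "IR", introns[k])
        return tuple(alt), event

    if as_type == "ES":
        if n < 3:
            return None
        j = int(rng.integers(1, n - 1))
        span = exons[j + 1][0] - exons[j - 1][1]
        if span > params.intron_length[1]:
            return None
        if sum(e - s for s, e in exons) - (exons[j][1] - exons[j][0]) < min_isoform:
            return None
        # the combined intron borrows its donor from one flanking intron and
        # its acceptor from the other; force both introns to one motif class
        cls = draft.motif_classes[j - 1]
        if draft.motif_classes[j] != cls:
            draft.motif_classes[j] = cls
            _plant_motif(arr, *introns[j], cls, gene.strand)
        alt = list(exons)
        del alt[j]
        event = ASEvent(gene.gene_id, "ES", (exons[j - 1][1] - 1, exons[j + 1][0]))
        return tuple(alt), event

    if as_type in ("AFE", "ALE"):
        # genomic side of the substituted terminal exon
        left_side = (as_type == "AFE") == plus
        space = draft.space_before if left_side else draft.space_after
        alt_len = int(rng.integers(params.exon_length[0], params.exon_length[1] + 1))
        spot = _free_interval(space, occupied, alt_len, margin=10)
        if spot is None:
            return None
        a_s, a_e = spot
        if left_side:
            cls = draft.motif_classes[0]
            donor, acceptor = CANONICAL_MOTIFS[cls]
            # new intron [a_e, exons[1].start) shares the inner splice site
            if (exons[1][0] - a_e) > params.intron_length[1]:
                return None
            _write(a_e, donor if plus else revcomp(acceptor))
            alt = [(a_s, a_e)] + list(exons[1:])
            event = ASEvent(gene.gene_id, as_type, (a_e - 1, exons[1][0]))
        else:
            cls = draft.motif_classes[-1]
            donor, acceptor = CANONICAL_MOTIFS[cls]
            if (a_s - exons[-2][1]) > params.intron_length[1]:
                return None
            _write(a_s - 2, acceptor if plus else revcomp(donor))
            alt = list(exons[:-1]) + [(a_s, a_e)]
            event = ASEvent(gene.gene_id, as_type, (exons[-2][1] - 1, a_s))
        occupied.append((a_s, a_e))
        return tuple(alt), event

    raise ValueError(f"unknown AS type {as_type!r}")


def _plant_mxe(arrays, genes, drafts, chosen, eligible, truth, rng, params) -> None:
    """Opt-in: plant mutually exclusive exon pairs on unperturbed genes."""
    used = {eligible[gi] for gi in chosen}
    for i, (gene, draft) in enumerate(zip(genes, drafts)):
        if i in used or len(gene.exons) < 4:
            continue
        exons = [tuple(e) for e in draft.exons]
        j = 1  # skip exon j in one isoform, exon j+1 in the other
        cls = draft.motif_classes[j - 1]
        for k in (j - 1, j, j + 1):
            if draft.motif_classes[k] != cls:
                draft.motif_classes[k] = cls
                _plant_motif(arrays[gene.chrom], *draft.introns[k], cls, gene.strand)
        alt_a = tuple(e for k, e in enumerate(exons) if k != j)
        alt_b = tuple(e for k, e in enumerate(exons) if k != j + 1)
        event = ASEvent(gene.gene_id, "MXE",
                        (exons[j - 1][1] - 1, exons[j + 1][0],
                         exons[j][1] - 1, exons[j + 2][0]))
        truth.as_events.append(event)
        truth.isoforms.setdefault(gene.gene_id, []).extend([
            Isoform(f"{gene.gene_id}.mxeA", gene.gene_id, alt_a, "MXE", event),
            Isoform(f"{gene.gene_id}.mxeB", gene.gene_id, alt_b, "MXE", event),
        ])
        break  # one MXE gene is enough for exercising the rule


# ---------------------------------------------------------------------------
# read simulation


def assign_library_expression(truth: TruthSet, genes: list[GeneModel],
                              params: SimParams) -> None:
    """Fill per-library expression weights and event activity flags.

    Gene weights are shared across libraries (lognormal with
    ``expression_sigma``, uniform when 0); optional per-gene fold changes
    apply at the second timepoint. Each planted event is independently
    active per library with ``event_active_prob``.
    """
    rng = np.random.default_rng((params.seed, 3))
    if params.expression_sigma > 0:
        weights = {g.gene_id: float(w) for g, w in zip(
            genes, rng.lognormal(-params.expression_sigma ** 2 / 2,
                                 params.expression_sigma, len(genes)))}
    else:
        weights = {g.gene_id: 1.0 for g in genes}
    events = [e for e in truth.as_events]
    second_tp = params.timepoints[1] if len(params.timepoints) > 1 else None
    for lib in params.library_ids():
        expr = dict(weights)
        if second_tp is not None and lib.endswith(second_tp):
            for gid, l2fc in params.fold_changes.items():
                expr[gid] = expr.get(gid, 1.0) * 2.0 ** l2fc
        truth.per_library_expression[lib] = expr
        active = {e.key for e in events if rng.random() < params.event_active_prob}
        truth.active_events[lib] = active


def simulate_reads(chrom_seqs: dict[str, str], genes: list[GeneModel], truth: TruthSet,
                   params: SimParams, library_id: str,
                   lib_index: int) -> list[tuple[ReadRecord, ReadRecord]]:
    """Draw paired-end reads for one library.

    Pair counts per gene are Poisson with mean ``depth`` times the gene's
    expression weight; fragments are sampled from isoform sequences (FR
    orientation, Phred+33, constant Q40 base quality) with substitution
    errors, adapter read-through and N runs injected at the configured
    rates. Read names encode the source isoform and fragment coordinates
    so each read maps back to exactly one origin.
    """
    rng = np.random.default_rng((params.seed, 4, lib_index))
    rl = params.read_length
    fmean, fsd = params.fragment_length
    expr = truth.per_library_expression[library_id]
    active = truth.active_events[library_id]
    adapter = params.adapter_sequence
    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    qual = "I" * rl  # Q40

    for gene in genes:
        isoforms = truth.isoforms[gene.gene_id]
        usable, probs = [], []
        for iso in isoforms:
            if iso.as_type is None:
                usable.append(iso)
                probs.append(1.0)
            elif (iso.gene_id, iso.as_type) in active:
                usable.append(iso)
                probs.append(params.alt_expression_fraction / (1 - params.alt_expression_fraction))
        p = np.array(probs) / sum(probs)
        seqs = [gene.spliced_sequence(chrom_seqs[gene.chrom], iso.exons) for iso in usable]
        n_pairs = rng.poisson(params.depth * expr.get(gene.gene_id, 1.0))
        for i in range(n_pairs):
            iso_i = int(rng.choice(len(usable), p=p)) if len(usable) > 1 else 0
            iso, iso_seq = usable[iso_i], seqs[iso_i]
            frag = int(round(rng.normal(fmean, fsd)))
            if frag > len(iso_seq):
                frag = len(iso_seq)
                log.debug("isoform %s shorter than fragment; truncated", iso.isoform_id)
            frag = max(frag, rl)
            start = int(rng.integers(0, len(iso_seq) - frag + 1))
            fwd = iso_seq[start:start + rl]
            rev = revcomp(iso_seq[start + frag - rl:start + frag])
            rid = f"{library_id}:{iso.isoform_id}:{i}:{start}:{frag}"
            r1 = _contaminate(fwd, params, adapter, rng)
            r2 = _contaminate(rev, params, adapter, rng)
            pairs.append((ReadRecord(rid, 1, r1, qual), ReadRecord(rid, 2, r2, qual)))
    return pairs


def _contaminate(seq: str, params: SimParams, adapter: str,
                 rng: np.random.Generator) -> str:
    """Apply substitution errors, adapter suffixes and N runs to one read."""
    if params.error_rate > 0:
        k = rng.binomial(len(seq), params.error_rate)
        if k:
            s = bytearray(seq.encode())
            for pos in rng.choice(len(seq), size=k, replace=False):
                choices = [b for b in b"ACGT" if b != s[pos]]
                s[pos] = choices[int(rng.integers(3))]
            seq = s.decode()
    if params.adapter_rate > 0 and rng.random() < params.adapter_rate:
        alen = int(rng.integers(15, min(41, len(seq), len(adapter) + 1)))
        seq = seq[:len(seq) - alen] + adapter[:alen]
    if params.n_rate > 0 and rng.random() < params.n_rate:
        nlen = int(rng.integers(5, 26))
        nlen = min(nlen, len(seq))
        pos = int(rng.integers(0, len(seq) - nlen + 1))
        seq = seq[:pos] + "N" * nlen + seq[pos + nlen:]
    return seq


# ---------------------------------------------------------------------------
# top-level convenience


def generate_dataset(params: SimParams) -> SimResult:
    """Run the full generator: genome, isoforms, truth, all libraries."""
    chrom_seqs, genes, drafts = generate_genome(params)
    chrom_seqs, truth = plant_as_isoforms(chrom_seqs, genes, drafts, params)
    assign_library_expression(truth, genes, params)
    libraries = {lib: simulate_reads(chrom_seqs, genes, truth, params, lib, i)
                 for i, lib in enumerate(params.library_ids())}
    return SimResult(params, chrom_seqs, genes, truth, libraries)


def simulate_count_matrix(n_genes: int, depth: float, n1: int | None = None,
                          fold_changes: dict[int, float] | None = None,
                          seed: int = 0, library_factor: float = 1.0):
    """Poisson count pairs for two libraries, for testing the DE stage.

    Returns ``(counts1, counts2, N1, N2)`` where counts are per-gene mapped
    read counts and N the library totals. ``fold_changes`` maps gene index
    to a linear fold applied in library 2; ``library_factor`` scales the
    sequencing depth of library 2.
    """
    rng = np.random.default_rng((seed, 7))
    lam1 = np.full(n_genes, depth)
    lam2 = lam1.copy() * library_factor
    if fold_changes:
        for idx, fold in fold_changes.items():
            lam2[idx] *= fold
    c1 = rng.poisson(lam1)
    c2 = rng.poisson(lam2)
    return c1, c2, int(c1.sum()), int(c2.sum())
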
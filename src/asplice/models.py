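"""Core domain objects shared across the pipeline.

Coordinates are 0-based, half-open throughout the package; GFF3 output is
the only place where the 1-based inclusive convention appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Canonical intron boundary dinucleotides on the transcribed strand,
#: in priority order: donor side, acceptor side.
CANONICAL_MOTIFS: tuple[tuple[str, str], ...] = (("GT", "AG"), ("GC", "AG"), ("AT", "AC"))
MOTIF_NAMES: tuple[str, ...] = ("GT-AG", "GC-AG", "AT-AC")
MOTIF_RANK: dict[str, int] = {m: i for i, m in enumerate(MOTIF_NAMES)}

AS_TYPES: tuple[str, ...] = ("A3S", "IR", "A5S", "ES", "AFE", "ALE", "MXE")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A stranded multi-exon gene on a reference chromosome.

    ``exons`` are non-overlapping 0-based half-open intervals sorted by
    genomic coordinate regardless of strand; transcript order on the minus
    strand runs right to left.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise ValueError(f"exons of {self.gene_id} not sorted/disjoint")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Annotated introns, genomic order, 0-based half-open."""
        return tuple((e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, chrom_seq: str, exons=None) -> str:
        """Mature transcript sequence (reverse-complemented for minus strand)."""
        exons = self.exons if exons is None else exons
        seq = "".join(chrom_seq[s:e] for s, e in exons)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """A donor-acceptor pair on the genome.

    ``donor_end`` is the last exonic base before the intron and
    ``acceptor_start`` the first exonic base after it, both in forward
    genome coordinates; the intron occupies ``[donor_end + 1,
    acceptor_start)``. For minus-strand junctions the transcribed donor is
    on the right; ``strand`` is inferred from the boundary motif.
    """

    chrom: str
    donor_end: int
    acceptor_start: int
    strand: str
    motif: str
    support: int = field(default=0, compare=False)

    @property
    def intron_start(self) -> int:
        return self.donor_end + 1

    @property
    def intron_end(self) -> int:
        return self.acceptor_start

    @property
    def intron_length(self) -> int:
        return self.acceptor_start - self.donor_end - 1

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.donor_end, self.acceptor_start)


def motif_of_intron(chrom_seq: str, intron_start: int, intron_end: int) -> tuple[str, str] | None:
    """Classify the boundary dinucleotides of a genomic interval.

    Returns ``(motif_name, strand)`` when the interval looks like a
    canonical intron in either orientation, else ``None``. Forward GT-AG
    introns on the minus strand read CT-AC on the forward genome.
    """
    left = chrom_seq[intron_start : intron_start + 2].upper()
    right = chrom_seq[intron_end - 2 : intron_end].upper()
    for name, (donor, acceptor) in zip(MOTIF_NAMES, CANONICAL_MOTIFS):
        if left == donor and right == acceptor:
            return name, "+"
    for name, (donor, acceptor) in zip(MOTIF_NAMES, CANONICAL_MOTIFS):
        if left == revcomp(acceptor) and right == revcomp(donor):
            return name, "-"
    return None


@dataclass(frozen=True)
class ASEvent:
    """A typed alternative-splicing call attached to a gene.

    ``coordinates`` identifies the alternative junction (donor_end,
    acceptor_start) or the retained intron (start, end).
    """

    gene_id: str
    as_type: str
    coordinates: tuple[int, ...]
    variety: str = ""
    timepoint: str = ""
    support: int = 0

    def __post_init__(self) -> None:
        if self.as_type not in AS_TYPES:
            raise ValueError(f"unknown AS type {self.as_type!r}")

    @property
    def key(self) -> tuple[str, str]:
        """Matching unit for cross-variety commonality and turnover."""
        return (self.gene_id, self.as_type)


@dataclass
class Isoform:
    """One transcript structure of a gene: an exon chain plus provenance."""

    isoform_id: str
    gene_id: str
    exons: tuple[tuple[int, int], ...]
    as_type: str | None = None  # None for the reference isoform
    event: ASEvent | None = None


@dataclass
class TruthSet:
    """Ground truth emitted by the simulator for scoring every stage."""

    isoforms: dict[str, list[Isoform]] = field(default_factory=dict)
    junctions: set[SpliceJunction] = field(default_factory=set)
    as_events: list[ASEvent] = field(default_factory=list)
    #: library_id -> gene_id -> relative transcript abundance
    per_library_expression: dict[str, dict[str, float]] = field(default_factory=dict)
    #: library_id -> set of (gene_id, as_type) active in that library
    active_events: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def junctions_of_gene_set(self, chrom_seqs: dict[str, str]) -> set[SpliceJunction]:
        return set(self.junctions)
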
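"""Spliced alignment of IUM reads: exact-match splice-junction detection.

A read that failed contiguous alignment is first placed whole across a
single junction: the longest exactly matching 5' prefix anchors the donor
side and the remainder must match exactly downstream. When no whole-read
placement exists — typically because the read spans more than two exons —
an additional step splits it into sub-reads (up to 50 bp stay whole,
50-100 bp are halved, longer reads are cut into 50 bp chunks from the 5'
end with the 50-100 bp remainder halved), places each sub-read
contiguously or across one junction, and re-concatenates the placements.
Placement rules:

1. each segment must be longer than 8 bp;
2. no mismatches or gaps within a segment;
3. the implied intron must span 50-50,000 bp;
4. the intron boundary must be canonical (GT-AG, GC-AG or AT-AC, in
   either orientation), with GT-AG preferred over GC-AG over AT-AC when a
   read admits several placements;
5. when one segment hits multiple positions and the other is unique, the
   closest pair (minimal intron) is taken; two multi-hit segments are
   ignored;
6. sub-read placements must concatenate colinearly — adjacent, or
   separated by a valid intron — to support the original read.

Ties beyond motif priority break by shorter intron, then leftmost donor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .aligner import KmerIndex
from .models import MOTIF_RANK, SpliceJunction, motif_of_intron, revcomp
from .seqio import ReadRecord

log = logging.getLogger(__name__)


@dataclass
class JunctionParams:
    min_segment: int = 8  # segments must be strictly longer than this
    min_intron: int = 50
    max_intron: int = 50_000
    subread_short: int = 50
    subread_long: int = 100
    min_support: int = 1
    max_hits: int = 20  # give up on hyper-repetitive segments

    def validate(self) -> None:
        if self.min_intron > self.max_intron:
            raise ValueError("min_intron must not exceed max_intron")
        if self.min_segment < 1:
            raise ValueError("min_segment must be positive")

    @property
    def anchor(self) -> int:
        """Shortest admissible segment length (strictly greater than 8 bp)."""
        return self.min_segment + 1


@dataclass(frozen=True)
class _Placement:
    """One way to lay a sub-read onto the genome (global coordinates)."""

    start: int
    end: int  # genomic end of the last placed base + 1
    junction: tuple[int, int] | None  # (donor_end, acceptor_start) or None
    motif_rank: int  # rank of the internal junction, 99 if contiguous
    intron_len: int

    @property
    def sort_key(self):
        return (self.motif_rank, self.intron_len, self.start)


def split_long_read(sequence: str, params: JunctionParams | None = None) -> list[str]:
    """Cut a read into sub-reads for spliced placement.

    Up to 50 bp: one sub-read. 50-100 bp: two equal halves. Longer: 50 bp
    chunks from the 5' end until the remainder falls in (50, 100], which is
    then halved. The concatenation always reproduces the read.
    """
    params = params or JunctionParams()
    if len(sequence) < 2 * params.anchor:
        raise ValueError(f"read of {len(sequence)} bp too short to split "
                         f"(needs >= {2 * params.anchor})")
    n = len(sequence)
    if n <= params.subread_short:
        return [sequence]
    parts = []
    while n - sum(map(len, parts)) > params.subread_long:
        off = sum(map(len, parts))
        parts.append(sequence[off : off + params.subread_short])
    rest = sequence[sum(map(len, parts)) :]
    half = (len(rest) + 1) // 2
    parts.extend([rest[:half], rest[half:]])
    return parts


def _extend_match(index: KmerIndex, seq: str, gpos: int) -> int:
    """Length of the exact match of ``seq`` against the genome at ``gpos``."""
    g = index.genome
    n = min(len(seq), len(g) - gpos)
    i = 0
    while i < n and seq[i] == g[gpos + i]:
        i += 1
    return i


def _exact_hits(index: KmerIndex, seq: str, anchor: int) -> list[int]:
    """All genomic positions where ``seq`` matches exactly and completely."""
    if len(seq) < anchor or "N" in seq[:anchor]:
        return []
    hits = []
    for p in index.positions(seq[: anchor]):
        if index.slice(p, len(seq)) == seq:
            hits.append(p)
    return hits


def find_junction(subread: str, index: KmerIndex, params: JunctionParams) -> list[_Placement]:
    """Candidate one-junction placements of a sub-read.

    The 5' segment is an exactly matching prefix (longest first, falling
    back to shorter prefixes when the longest admits no valid completion);
    the 3' remainder must match exactly within the intron-length window
    downstream. Per split point the multi-hit rule applies: unique/unique
    pairs stand, unique/multi picks the minimal intron, multi/multi is
    ignored.
    """
    a = params.anchor
    n = len(subread)
    if n < 2 * a or "N" in subread:
        return []
    prefix_hits = [(p, _extend_match(index, subread, p)) for p in index.positions(subread[:a])]
    if not prefix_hits or len(prefix_hits) > params.max_hits:
        return []
    longest = max(m for _, m in prefix_hits)
    out: list[_Placement] = []
    for s in range(min(longest, n - a), a - 1, -1):
        donors = [p for p, m in prefix_hits if m >= s]
        if not donors:
            continue
        acceptors = _exact_hits(index, subread[s:], a)
        if not acceptors:
            continue
        if len(donors) > 1 and len(acceptors) > 1:
            continue  # two multi-hit segments: ignored
        pairs = []
        for d in donors:
            for q in acceptors:
                intron = q - (d + s)
                if params.min_intron <= intron <= params.max_intron:
                    cls = motif_of_intron(index.genome, d + s, q)
                    if cls is not None:
                        pairs.append((intron, MOTIF_RANK[cls[0]], d, q))
        if not pairs:
            continue
        # motif priority first, then the closest pair (minimal intron)
        intron, rank, d, q = min(pairs, key=lambda t: (t[1], t[0], t[2]))
        out.append(_Placement(d, q + (n - s), (d + s - 1, q), rank, intron))
    return out


def resolve_multihits(candidates: list[_Placement]) -> _Placement | None:
    """Pick at most one junction placement for a read.

    Motif priority first (GT-AG > GC-AG > AT-AC), then the shorter intron,
    then the leftmost donor.
    """
    if not candidates:
        return None
    return min(candidates, key=lambda c: c.sort_key)


def _subread_placements(subread: str, index: KmerIndex,
                        params: JunctionParams) -> list[_Placement]:
    placements = [_Placement(p, p + len(subread), None, 99, 0)
                  for p in _exact_hits(index, subread, params.anchor)]
    placements.extend(find_junction(subread, index, params))
    return placements


def concatenate_subreads(chains: list[list[_Placement]], index: KmerIndex,
                         params: JunctionParams) -> list[tuple[list[_Placement], list]]:
    """Keep sub-read placement chains that are colinear on one chromosome.

    Consecutive placements must either abut (gap 0) or be separated by a
    valid canonical intron, which itself becomes a junction supported by
    the read. Returns the surviving chains with their junction lists.
    """
    results = []
    for chain in chains:
        junctions = []
        ok = True
        for prev, nxt in zip(chain, chain[1:]):
            gap = nxt.start - prev.end
            if gap == 0:
                continue
            if not (params.min_intron <= gap <= params.max_intron):
                ok = False
                break
            cls = motif_of_intron(index.genome, prev.end, nxt.start)
            if cls is None:
                ok = False
                break
            junctions.append((prev.end - 1, nxt.start, MOTIF_RANK[cls[0]], gap))
        if not ok:
            continue
        chrom0 = index.decode(chain[0].start)[0]
        if any(index.decode(p.start)[0] != chrom0 for p in chain[1:]):
            continue
        for p in chain:
            if p.junction is not None:
                junctions.append((*p.junction, p.motif_rank, p.intron_len))
        results.append((chain, junctions))
    return results


def _enumerate_chains(per_subread: list[list[_Placement]]) -> list[list[_Placement]]:
    chains: list[list[_Placement]] = [[]]
    for options in per_subread:
        nxt = []
        for chain in chains:
            for p in options:
                if not chain or p.start >= chain[-1].end:
                    nxt.append(chain + [p])
        chains = nxt
        if not chains:
            return []
    return chains


def place_read(sequence: str, index: KmerIndex, params: JunctionParams):
    """Best spliced placement of a whole read, trying both orientations.

    The read is first placed as a whole across a single junction (the
    two-segment rule); only when that fails is it cut into sub-reads and
    re-assembled, the additional step that recovers reads spanning more
    than two exons. Returns a list of supported junctions
    ``(donor_end, acceptor_start)`` in global coordinates, or None when
    the read cannot be placed consistently.
    """
    whole = []
    for oriented in (sequence, revcomp(sequence)):
        whole.extend(find_junction(oriented, index, params))
    chosen = resolve_multihits(whole)
    if chosen is not None:
        return [chosen.junction]

    best = None
    for oriented in (sequence, revcomp(sequence)):
        subreads = split_long_read(oriented, params)
        per_subread = [_subread_placements(s, index, params) for s in subreads]
        if any(not p for p in per_subread):
            continue
        if max(len(p) for p in per_subread) > params.max_hits:
            continue
        chains = _enumerate_chains(per_subread)
        valid = concatenate_subreads(chains, index, params)
        for chain, junctions in valid:
            score = (tuple(sorted(j[2] for j in junctions)),
                     sum(j[3] for j in junctions),
                     chain[0].start)
            if best is None or score < best[0]:
                best = (score, junctions)
    if best is None:
        return None
    return [(d, a) for d, a, _, _ in best[1]]


def call_junctions(ium_reads: list[ReadRecord], index: KmerIndex,
                   params: JunctionParams | None = None) -> list[SpliceJunction]:
    """Detect splice junctions from the IUM read set.

    Identical (chrom, donor_end, acceptor_start) calls merge with summed
    support; junctions under ``min_support`` are dropped. Output is sorted
    and independent of input order.
    """
    params = params or JunctionParams()
    params.validate()
    support: dict[tuple[int, int], int] = {}
    n_unplaced = 0
    for read in ium_reads:
        if len(read.sequence) < 2 * params.anchor:
            log.debug("read %s too short for spliced placement", read.read_id)
            n_unplaced += 1
            continue
        junctions = place_read(read.sequence, index, params)
        if junctions is None:
            n_unplaced += 1
            continue
        for key in junctions:
            support[key] = support.get(key, 0) + 1
    out = []
    for (donor_end, acceptor_start), n in support.items():
        if n < params.min_support:
            continue
        cls = motif_of_intron(index.genome, donor_end + 1, acceptor_start)
        assert cls is not None  # placements always carry canonical motifs
        motif, strand = cls
        chrom, local_d = index.decode(donor_end)
        local_a = index.decode(acceptor_start)[1]
        out.append(SpliceJunction(chrom, local_d, local_a, strand, motif, support=n))
    out.sort()
    log.info("junction calling: %d junctions, %d unplaced reads", len(out), n_unplaced)
    return out
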
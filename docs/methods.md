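# Methods

## Scope and model

The package re-implements, end to end, the splice-junction-based survey
of alternative splicing (AS) in germinating barley embryos: four
varieties × two imbibition timepoints, one paired-end library each. All
analysis operates on a synthetic genome whose gene models, alternative
isoforms and reads are generated by the package itself, so that every
downstream call can be scored against a planted truth. Coordinates are
0-based half-open everywhere in memory; GFF3 output is 1-based inclusive.

## Synthetic-data generator

The generator emulates the study design, not barley sequence content.

**Genome and genes.** Uniform random nucleotide background; genes are
packed sequentially (filling the emptiest chromosome) with intergenic
gaps of 150–500 bp. Defaults: 2 chromosomes × 500 kb, 200 genes, 3–5
exons of 120–250 bp, introns log-uniform in the configured bounds
(default 50–5000 bp for benchmarks; the heavy-tailed draw mimics real
intron-size distributions while keeping ~200 genes inside 1 Mb). Strands
are random; every annotated intron gets a canonical boundary motif on the
gene strand (GT-AG/GC-AG/AT-AC at 90/7/3%), so minus-strand introns read
CT…AC etc. on the forward genome.

**Planted events.** A configurable fraction (default 0.5) of genes
receives exactly one AS event, with type drawn from a configurable mix
whose default follows the proportions observed in the barley tables
(A3S 0.43, IR 0.29, A5S 0.21, ES 0.04, AFE 0.02, ALE 0.01). Event
construction:

- **A3S/A5S** shift an annotated acceptor/donor 3–30 nt into the
  adjacent exon (strand-aware) and plant a canonical dinucleotide of the
  same motif class at the alternative site. The offset is clamped so the
  alternative intron stays inside the configured intron bounds and the
  shrunken exon keeps ≥ 20 bp.
- **IR** merges the flanking exons of the gene's *shortest* intron, and
  only when that intron is ≤ 500 bp (`ir_max_intron`). Retained introns
  skew short in real transcriptomes, and a multi-kilobase retained intron
  cannot reach the coverage-based detection rule at the default depth —
  planting one would put an unobservable event in the truth set.
- **ES** removes one internal exon; the two flanking introns are forced
  to one motif class so the combined intron is canonical, and the
  combined span must respect the intron-size bound.
- **AFE/ALE** substitute the terminal exon (transcript-first or -last,
  strand-aware) with a new exon placed in the intergenic space, sharing
  the inner splice site and planting the outer one.
- **MXE** is never planted by default — mirroring the original analysis,
  where the type was looked for but not detected — but an opt-in mode
  plants the two adjacent skip-isoforms so the classifier's MXE rule can
  be exercised.

A type that is infeasible for the selected gene (too few exons, no short
intron, no flanking space, or an alternative isoform shorter than one
fragment length — see below) is resampled among the feasible types and
the substitution logged.

**Reads.** Per library, each gene receives Poisson(depth × weight) read
pairs (default depth 50; weights are uniform by default so planted events
are assessed at a controlled, interpretable depth — a lognormal option
exists). Where a gene's event is active in a library (each event is
active per library with probability 0.8, which is what makes the
cross-variety commonality and turnover accounting non-trivial), the
alternative isoform takes half the gene's expression. Fragments are
normal (mean 250 bp, sd 30) within the isoform; mates are FR, 90 bp,
Phred+33 at Q40. Substitution errors, adapter read-through (TruSeq
sequence) and N runs are injected at configurable rates. Read names
encode library, isoform, fragment start and length, giving exact truth
closure for every read. Events are only planted when every isoform of the
gene is at least one fragment length long: the emulated protocol
size-selects 250–500 bp fragments, and a shorter transcript would be
sampled as identical full-length fragments whose middle ~60 bp no read
can cover — an unobservable event by construction.

**What the generator does not emulate** (hence what passing tests do not
show about real data): real sequence composition and repeats, indels,
quality-score decay and its coupling to error rate, PCR duplicates,
coverage bias along transcripts, unannotated genes, overlapping genes,
and noisy/incomplete annotations.

## Analysis stages

**QC** implements the whole-read discard rules (adapter substring of
≥ 10 adapter bases anywhere in the read; N fraction > 10%; > 50% of
bases < Q20 — strict inequalities, first-matching-rule attribution in
that priority order) and dataset-level composition checks (FAIL at N rate
≥ 1% or low-quality rate ≥ 10%). Reads are never trimmed.

**Aligner**: exact 32-mer 5' seed, ungapped extension, ≤ 5 mismatches
(necessarily outside the seed), best-hit set kept; uniqueness = exactly
one best position. Mates align independently; FR orientation and insert
≤ 1000 bp then restrict the candidate pairs; there is no mate rescue.
The k-mer index stores forward-strand positions and answers minus-strand
queries by reverse complement.

**Junction caller**: two-phase. Phase one places the whole IUM read
across a single junction: candidate splits are enumerated from the
longest exactly matching prefix down to the 9 bp minimum (the fallback
exists because a prefix can overshoot the junction when intron sequence
coincides with the acceptor exon), the remainder must match exactly
within the intron window, and the boundary must be canonical in either
orientation. Per split, the multi-hit rule applies (unique/unique stands;
unique/multi takes motif priority, then the minimal intron; multi/multi
is ignored). Across splits and orientations the winner is chosen by motif
priority, then intron length, then leftmost donor. Phase two — only when
phase one fails — cuts the read into sub-reads (≤ 50 bp whole, 50–100 bp
halved, else 50 bp chunks with the halved remainder), places each
contiguously or across one junction, and keeps colinear chains whose gaps
are either zero or valid canonical introns; this recovers reads spanning
more than two exons. Identical junction calls merge with summed support;
`min_support` defaults to 1. Strand is inferred from the motif
orientation, never from the read.

**Classifier**: junctions are attributed to the gene containing their
inner anchor and typed strand-aware as described in the README (exact
intron → constitutive; ES before AFE/ALE before A3S/A5S, so shared-site
ambiguities resolve toward the more specific type). IR is called from
contiguous-alignment evidence: ≥ 90% of intron bases covered and both
exon–intron boundaries spanned by a read covering at least
`boundary_anchor` bases on each side (default 1, i.e. the read covers
both flanking bases — the literal reading of "boundary spanned"; the
anchor is configurable for stricter analyses). Adjacent-exon skip pairs
merge into MXE. Accounting counts events as distinct (gene, type,
coordinates) and genes as distinct (gene, type); cross-variety
commonality and turnover match on (gene, type), because coordinate-exact
matching across varieties would be stricter than the comparison the
tables describe.

**Rounding conventions** (both implemented explicitly because the
published tables demonstrably use both): AS-type percentages truncate
(43.8 → 43); turnover percentages and AS-gene fractions round half up
(51.8 → 52). In the common-transcript table both timepoint percentage
columns use the 24 h total as denominator, the only convention consistent
with the printed 48 h values.

**Quantification**: RPKM = 1e9·C/(N·L) with C the zero-mismatch unique
read count starting within the gene span, N the sum of such counts over
all genes, and L the exonic length. The differential-expression p-value
is the exact conditional Poisson (negative-binomial predictive) test; the
two-sided value sums the observed tail in both (x,N₁)↔(y,N₂)
orientations and clips at 1, a construction that is exactly symmetric
under swapping the libraries and returns 1 at equal observed rates. It is
evaluated through scipy's log-space negative-binomial tails
(r = x+1, p = N₁/(N₁+N₂)) — never naive factorials. Multiple testing is
Benjamini–Hochberg; log₂ ratios add a 0.1-RPKM pseudocount for zero
counts; significance needs FDR ≤ 0.001 and |log₂ ratio| ≥ 1.
Co-expression is Pearson correlation on untransformed RPKM across
libraries (a log2(x+1) option exists), keeping |r| ≥ 0.9 edges;
zero-variance profiles are skipped with a log entry.

## Numerical and benchmark choices

- The recovery benchmarks simulate one clean library per seed at study
  scale — 1 Mb genome, 200 genes, depth 50, 90 bp reads, introns
  50–5000 bp, all three motif classes, no noise — and pool five seeds.
  The junction caller's intron window is calibrated to the simulated
  organism's configured intron bounds, the same way the 50–50,000 bp
  window of the original workflow was chosen from known eukaryotic intron
  sizes; the package default remains 50–50,000 bp. The classification
  benchmark uses a balanced type mix (0.2/0.2/0.2/0.2/0.1/0.1) purely so
  the rare terminal-exon types occur often enough to measure.
- The exhaustive junction oracle (string-scanning enumeration of every
  split and placement, with the same selection rules) runs on ≤ 5 kb
  references; the Poisson-test oracle uses exact `Fraction` arithmetic.
  Oracles share only the contract with the production code, not the
  search path.
- Degenerate inputs: empty IUM sets, empty event sets and empty edge sets
  yield empty outputs; an empty 24 h set makes the turnover percentage
  undefined (reported as not applicable); zero library totals, zero gene
  lengths and empty references raise explicit errors. Reads shorter than
  18 bp cannot host two > 8 bp segments and are logged as unplaceable.
- Determinism: every stage is a pure function of its inputs; all
  randomness flows from one seed through per-stage, per-library
  `numpy` SeedSequence streams, so a rerun reproduces byte-identical
  outputs (asserted on manifest digests).

## Known limitations

- Junctions landing within 8 bp of a read end are undetectable from that
  read (the > 8 bp segment rule), and reads whose junction falls within
  8 bp of a sub-read boundary in phase two are lost; sensitivity
  therefore depends on depth, most visibly for terminal-exon events whose
  junctions sit near transcript ends where only one mate orientation can
  span them.
- The 9 bp minimum segment admits rare spurious exact matches inside wide
  intron-search windows; with the default 50 kb window this caps
  precision around 99% at desk scale (support-1 calls), which is why the
  benchmarks calibrate the window to the organism.
- Ungapped alignment only; indels, soft-clipping and quality-aware
  scoring are out of scope, as are isoform assembly and percent-spliced-in
  quantification.
- With single libraries per condition the Poisson test treats biological
  variability as sampling noise; its null calibration is exact, but real
  replicate-to-replicate dispersion would inflate calls, which is one
  reason the original analysis added the fold-change gate.
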
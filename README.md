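# asplice

Alternative-splicing analysis for paired-end short-read RNA-seq, built as a
fully testable pipeline around a synthetic-data generator with a planted
truth set.

The workflow mirrors how alternative splicing (AS) was surveyed in
germinating embryos of four barley varieties sampled at 24 h and 48 h of
imbibition: reads are quality-filtered, aligned ungapped to the genome,
the initially unmapped (IUM) reads are re-aligned across splice junctions
by exact two-segment matching, junctions are classified into AS event
types against the gene annotation, and gene expression is quantified for
differential-expression and co-expression screens. Because the package
ships its own genome/read simulator that records every planted isoform,
junction and event, every stage can be scored exactly — recall and
precision against ground truth rather than plausibility checks. It is
aimed at people who want a transparent, small-scale reference
implementation of this classic pipeline: to study its failure modes, to
benchmark alternatives against a known truth, or to teach it.

## Methods at a glance

**Read QC.** A read is discarded when it contains a sequencing adapter,
when its N fraction exceeds 10%, or when more than 50% of its bases are
below Q20 (strict inequalities; pairs drop together). Dataset-level checks
report base composition, the global N rate (<1% expected) and the global
low-quality rate (<10% expected).

**Contiguous alignment.** Seed-and-extend, ungapped: the 5' 32-mer of the
read must match exactly; full-length extension tolerates at most five
mismatches; mates must pair FR with insert ≤ 1000 bp. Reads with no
qualifying position are the IUM set.

**Spliced junction detection.** An IUM read is placed across a junction by
finding the longest exactly matching 5' prefix and placing the remainder
exactly downstream, subject to: each segment > 8 bp; no mismatches or gaps
within segments; intron length in [50, 50000] bp; canonical boundary
motifs with priority GT-AG > GC-AG > AT-AC (both orientations; a
minus-strand GT-AG intron reads CT…AC on the forward strand). With
multi-hit segments, a unique/multi pair resolves to the closest hit
(minimal intron); multi/multi reads are ignored. Reads that fail whole
(e.g. spanning three exons) are split into 50 bp sub-reads, placed
independently, and re-concatenated colinearly.

**Event classification.** Against annotated introns, strand-aware:
shared donor + novel acceptor → A3S; novel donor + shared acceptor → A5S;
donor of intron *i* joined to acceptor of intron *i+1* → exon skipping;
an intron covered ≥ 90% by contiguous reads with both exon–intron
boundaries spanned → intron retention; a junction sharing the first/last
annotated splice site whose outer anchor lies outside the terminal exon →
alternative first/last exon; two exon skips of distinct adjacent exons →
mutually exclusive exons. Accounting reports events (distinct
coordinates) and genes (distinct gene × type) per variety and timepoint,
(gene, type) calls common to ≥ 3 of 4 varieties, and turnover — calls
present at 24 h but gone at 48 h.

**Quantification and screens.** Expression is
`RPKM = 10^9 · C / (N · L)` with C the perfect unique read count on the
gene, N the library's uniquely gene-mapped total and L the gene length.
Differential expression uses the exact conditional Poisson test
(Audic–Claverie): given count *x* at depth N₁, the count *y* at depth N₂
follows `p(y|x) = (N₂/N₁)^y (x+y)! / (x! y! (1+N₂/N₁)^(x+y+1))`; the
two-sided p-value sums the observed tail in both orientations (computed
in log space), and genes are called at Benjamini–Hochberg FDR ≤ 0.001
with |log₂ ratio| ≥ 1. Co-expression keeps Pearson edges with r ≥ 0.9 or
r ≤ −0.9 across libraries, summarized per pathway from a user-supplied
gene→pathway table.

## Worked example

Run the whole pipeline on a small simulated experiment — 4 varieties × 2
timepoints, 40 genes on a 170 kb chromosome, depth 40 pairs per gene,
with realistic noise (0.1% substitutions, 1% adapter read-through, 0.5%
N runs):

```sh
cat > demo.yaml <<EOF
seed: 7
sim:
  n_genes: 40
  n_chromosomes: 1
  chrom_length: 170000
  intron_length: [50, 2000]
  depth: 40.0
  error_rate: 0.001
  adapter_rate: 0.01
  n_rate: 0.005
EOF
asplice run-all --config demo.yaml --out demo_run --seed 7
```

prints the truth-set evaluation of the run:

```
junction recall    0.9922
junction precision 0.9912
   A3S  recall 0.939  precision 1.000
   A5S  recall 0.947  precision 1.000
   AFE  recall 1.000  precision 1.000
    ES  recall 1.000  precision 1.000
    IR  recall 0.913  precision 1.000
```

99.2% of planted splice junctions were recovered with 99.1% precision,
and the typed AS events were recovered with perfect precision; at this
small depth a planted event occasionally lacks a spanning read, which is
exactly the kind of sensitivity limit the truth set makes visible. The
run directory holds every intermediate: filtered FASTQs and a QC report
(here: 1552 pairs in, 1503 kept — 33 adapter, 16 N-rate discards, dataset
PASS), per-library alignments and coverage, junction tables, the
`as_accounting.csv` event/gene table per variety and timepoint with
turnover percentages, the cross-variety common-event sets, an RPKM
matrix, differential-expression calls between timepoints, co-expression
edges, and `evaluation.json`. Each stage can be re-run in isolation
(`asplice qc|align|junctions|classify|quantify|evaluate --out demo_run`),
and a manifest of output digests makes reruns verifiably identical.

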
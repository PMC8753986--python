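# Methods

This note records the models, conventions and numerical choices behind
`srnapipe`, and what the synthetic benchmark does and does not demonstrate.

## Coordinate and strand conventions

All internal coordinates are 1-based inclusive (GFF3's frame) with
`start <= end` and an explicit strand; SAM's 0-based half-open positions are
converted once, at the alignment reader. The one deliberate exception is the
published-table export, which prints minus-strand candidates with start and
end swapped (start > end) because candidate tables in this literature use
that convention; the reader restores the normalized frame.

Multi-mapped reads: only primary alignments are counted, each with weight 1.
Surveys of this kind rarely state their policy; counting primaries only is
the simplest auditable rule, and the reader logs what it skips. Alignments
spanning more than 500 nt on the reference are excluded as outside a
low-molecular-weight (<500 nt) library.

## Discovery

A read is *coding* iff at least 50% of its length overlaps a protein-coding
gene on the same strand; opposite-strand overlaps are kept because they are
precisely the antisense signal. The 50% fraction is a package choice (the
procedure this reimplements does not state one) and is exposed as a
parameter, as is the same-strand 50% rule for routing clusters covered by
known RNA-family hits.

Clustering merges reads per (contig, strand) that overlap or abut within
`max_join_gap` (default 0, the most conservative choice). A cluster's *copy
number* is its member read count — the only quantity a pre-quantification
copy threshold can apply to — and candidates require strictly more than 10
(`min_copy_number = 11`). Length bounds default to [50, 500] nt: the lower
bound from the canonical sRNA length prior, the upper from the library cut.
Copy-number filtering precedes deduplication; the source procedure is
ambiguous on the order, and filtering first is cheaper and never changes
which representatives survive at clean separations.

Deduplication reimplements the Megablast-style screen as defined
computation rather than calling an external aligner: two candidate
sequences (strand-oriented; the reverse complement is also tried) are
similar iff they share an exact 26-mer and the ungapped extension anchored
at a shared word reaches ≥90% identity over the shorter sequence. Gapped
alignment is deliberately excluded. Similarity is closed transitively;
each component keeps its highest-copy-number member (ties: leftmost).
The implementation is seed-indexed but is tested for exact agreement with
an all-pairs, all-offsets quadratic oracle.

## Classification

Precedence is antisense > UTR > intergenic: overlap on the opposite strand
is the strong, unambiguous condition; UTR proximity (gap ≤ 500 nt to a
same-strand gene edge, with overlap counting as gap 0, so a candidate
partially covering a same-strand gene body is UTR-derived) is the weaker
one; intergenic is the remainder. UTR anchoring requires the candidate on
the mRNA's own strand (configurable), since untranslated regions belong to
their transcript's strand. Tie-breaks are fixed and deterministic: greatest
overlap, then nearest gene start, then leftmost for antisense; smallest
gap, then leftmost for UTR. IDs are assigned after classification in
(contig, start) order as `sts001…`, so reruns name candidates identically.

## Expression

Counts are normalized as CPM against per-sample library sizes recorded
*before* any filtering. For a phase pair (a, b), `log2fc` is the mean of
log2(CPM + 1) in b minus a; reported fold change is signed-magnitude
(−3.6 = 3.6-fold down). Significance uses the fixed decision rule
FC ≥ |2| and p ≤ 0.01 with no multiple-testing adjustment by default —
the rule is stated on raw p in the procedure this follows — with
Benjamini–Hochberg available behind a flag.

The test is a two-sided **pooled-variance Student t** on log2(CPM + 1)
across biological replicates. Welch's form was considered and is available
(`test="welch"`), but with three replicates and the negative-binomial
mean–variance coupling, Welch's Satterthwaite degrees of freedom collapse
toward 2 whenever a low-count group meets a high-count group (critical t
≈ 10), which costs most of the power: measured sensitivity at a planted
log2 fold change of 2 (depth 50, dispersion 0.05) was 0.85 for Welch
versus 0.96 for the pooled form, while the pooled form remains calibrated
under the null (p ≤ 0.01 rate ≈ 0.010 on 10,000 null loci, significant-call
rate ≈ 0.0005 once the fold-change gate is added). Rows with zero variance
in both groups are assigned p = 1 when the means agree and p = 0 otherwise.

Comparisons default to all unordered pairs of the post-lag phases T1–T4
(C(4,2) = 6 comparisons), matching the six comparison groups such
time-courses report; a different phase list can be supplied. The overlap
analysis computes per-comparison up/down tallies, arbitrary intersection
sets, and the core set (significant in every comparison).

CPM assumes library composition is stable across samples. It is not
robust to a large fraction of the library changing in one direction; the
synthetic count model therefore includes the non-candidate library mass
(see below), and users with strongly asymmetric designs should interpret
fold changes accordingly. Shrinkage and moderated-variance estimators are
out of scope by design.

## Downstream

Coexpression pairing takes sRNA and target fold changes from tables (the
target side comes from external transcriptome/proteome measurements, not
from this package) and flags pairs where both members pass |FC| ≥ 2,
recording sign concordance; links lacking data are reported, never silently
dropped. Enrichment is the upper-tail hypergeometric probability
P(X ≥ k) per term with BH adjustment across tested terms; terms with no
study hits are skipped, and the background defaults to all annotated genes.
qPCR quantification is the standard 2^−ΔΔCT: technical replicates averaged,
ΔCT against the reference gene (16S rRNA by convention) within sample, ΔΔCT
against the calibrator sample. The calibrator's value is exactly 1, and the
statistic is invariant to any constant shift applied to all CTs of a sample.

## Synthetic data

The generator emulates the targeted study design: five sampling phases
(T0–T4) × three biological replicates, genes on both strands separated by
gaps of at least 1,100 nt (1,000 nt of UTR windows plus room for an
intergenic locus of any configured length, plus margin), and
`n_planted_per_class` loci per class placed so the three classes are
*disjoint by construction* — antisense strictly inside an opposite-strand
gene, UTR within 500 nt of its same-strand anchor, intergenic strictly
more than 500 nt from every gene. Class recovery is therefore an exact
test. One seed drives named substreams per stage, so stages can be
regenerated independently and every output is byte-identical across reruns.

Alignments are perfect, ungapped, single-end full matches (the aligner is
out of scope; discovery consumes only intervals, strands and counts), tiled
evenly across each locus so coverage has no gaps and the recovered cluster
span equals the locus span. Poisson background reads inside coding genes
exercise the coding filter. Default sRNA lengths are drawn from 50–150 nt —
inside the 50–400 nt prior, and short enough that every locus fits its
placement window at the default gene spacing.

Counts are negative binomial with var = m + φ·m² (φ = `nb_dispersion`,
default 0.05; φ = 0 reduces to Poisson) around a per-locus mean of
`read_depth_per_locus` (default 50) scaled by the phase effect. A fraction
`fraction_de` (default 0.5) of loci carry a true effect: a log2 ramp over
the comparison phases with step `planted_log2fc` (default 2), rising for
half the affected loci and falling for the other half. Every pairwise
comparison of T1–T4 then carries at least one ramp step of true effect, so
affected loci are "always-DE" and constitute the planted core set, while
adjacent-phase comparisons carry exactly one step — the configuration at
which sensitivity is quoted. Library sizes add a Poisson non-candidate
mass (`library_background_reads`, default 10⁶) because in a real library
candidate sRNAs are a small share of the reads; without it the planted
exponential ramp itself distorts CPM denominators.

CT tables have a constant-CT reference per sample and target ΔCTs that
decrease by exactly the planted log2 effect relative to the calibrator, so
2^−ΔΔCT recovers 2^(planted effect) exactly in the noiseless default;
Gaussian CT noise with configurable SD is available for statistical tests.

What passing the synthetic benchmark does **not** show: robustness to
sequencing error, soft-clipped or multi-mapped alignments, overlapping or
nested real gene structures, transcriptional read-through between adjacent
loci, or composition-driven normalization bias beyond the modelled ballast.
Those require real data.

## Benchmark problem sizes and check conditions

The standing checks use: 40 genes on a 120 kb genome with 20 planted loci
per class for recovery; 10,000 null loci for calibration of the DE test;
three 300-locus replicated simulations for sensitivity at the quoted
conditions (log2fc 2, depth 50, dispersion 0.05); and core-set exactness at
high effect and depth (log2fc 3, depth 500, three always-DE loci among 60).
The split is deliberate: with three replicates, a t-test's per-call power
at one ramp step is ~0.96, so demanding ~180 simultaneously correct calls
at the quoted depth would test luck, not correctness, whereas at high
effect and depth per-call misses are vanishingly rare and exact recovery is
the right assertion.

## Known limitations

- Single-contig genomes in the simulator (the analysis itself is
  multi-contig capable).
- Dedup is ungapped by design; indel-diverged paralogs will not merge.
- The DE test is a two-group t on log-CPM; no time-course modelling.
- Enrichment does not propagate ontology ancestors; the term map is taken
  as given.
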
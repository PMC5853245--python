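# Methods

## Coordinates, gene models, and regions

All internal coordinates are 0-based half-open; GFF3 is read and written as
1-based inclusive. A gene model stores its genomic span canonically
(`span_start < span_end`) with strand-derived TSS/TTS, sorted
non-overlapping exons reaching the span edges, and UTR/CDS intervals
contained in the exon union; introns are defined as the gaps between
consecutive exons, so exons ∪ introns partition the span exactly. When a
locus has several mRNA isoforms, the transcript with the longest genomic
span is used (ties broken by lexicographic transcript id); this is a local
convention — annotation pipelines differ here and results for multi-isoform
loci depend on it.

The promoter is the `promoter_len` (default 1000) bases immediately
upstream of the TSS in gene orientation, TSS base excluded: `[tss − L, tss)`
on the plus strand, the interval just 3′ of the genomic span
(reverse-complemented) on the minus strand. Truncation at contig edges is
silent (debug-logged), not an error, because short contigs are routine in
test fixtures. The gene body is the contiguous TSS→TTS span including
introns.

## Motif scanning and site classification

The scanner matches the motif literals (default TTAATGG and TTAATGC)
and, when both strands are searched, their reverse complements, against
forward-genomic-strand sequence of the contiguous promoter+gene-body
window. Matching is exact-string (`str.find` over all literals): the motif
is a fixed 7-mer, not a weight matrix, so literal matching is the correct
primitive and is verified against a brute-force all-windows oracle.
Overlapping occurrences are all reported. The two forward literals and
their reverse complements are pairwise distinct, so no window matches in
both orientations.

Each hit is classified by its **anchor base — the 5′-most base in gene
orientation** (leftmost genomic base for plus-strand genes, rightmost for
minus-strand genes): promoter if the anchor lies in the promoter window,
else 5′UTR / 3′UTR / exon / intron by interval membership. "Exon" means the
CDS-like exonic portion: exonic bases not covered by a UTR annotation.
These five categories therefore partition every base of promoter ∪ gene
body, which a per-base oracle test asserts exhaustively. The anchor-base
rule is a tie-break for 7-mers spanning a feature boundary; any fixed rule
changes only boundary-spanning sites, and the generator plants sites ≥ 7
bases from boundaries so recovery tests never depend on it (boundary
behaviour is covered by hand-built fixtures).

Gene-relative offsets are signed distances from the TSS in gene
orientation (negative = upstream, so promoter hits have offsets in
[−L, −1]). Overlapping loci are scanned independently: a site in gene A's
promoter and gene B's body is reported once per gene. Distribution
percentages are stored exact in `CategoryDistribution` (they sum to 100 up
to float error) and rounded to one decimal only in report output — rounding
inside the type could make the five rounded values sum to 100 ± 0.2.

## Differential expression

The DE contract is the threshold rule: call = up iff fold change >
`fc_threshold` (default 2, strict) and p < `p_threshold` (default 0.05,
strict); down iff fold change < 1/`fc_threshold` and p < threshold. No
multiple-testing correction is applied, matching the raw-p convention of
the threshold rule; this is a known caveat, and the p-value column is
available for external FDR control.

Quantification upstream of the rule is deliberately transparent rather
than assembler-based: counts-per-million normalization (each sample column
rescaled to sum 10⁶) followed by a two-sided two-sample t-test on
log₂(CPM + pseudocount), pseudocount 1 on the normalized scale for both the
test and the fold change ((mean_mut + 1)/(mean_wt + 1)).

The default test **pools the variance** (Student) rather than using
Welch's unpooled form. With the 2–3 replicates typical of these designs the
Welch denominator is estimated from as few as 2–4 degrees of freedom and is
so unstable that it costs real power (measured here: 0.90 vs 0.96 per-gene
power at 4-fold, n = 3, NB dispersion 0.1) while being *more* conservative
than nominal under the null (p < 0.05 fraction 0.034 vs 0.049). Since both
conditions are modelled as identically-dispersed negative binomials, equal
log-scale variances are the natural assumption and pooling is statistically
appropriate; `test_method="welch"` restores the unpooled test.

Degenerate variances arise on noise-free fixtures and are resolved by
continuity of the decision rule: both groups zero-variance with equal
means → p = 1; with unequal means → p = 0.

## Catalogues

Root-specificity has no canonical published criterion, so the rule is
explicit and parameterized: root expression ≥ `min_expr` (default 10 linear
units) and ≥ `ratio` (default 2.0) × the maximum over all non-root
tissues.

Cytokinin inducibility uses the induction fold change
FC(t) = [treated(t)/mock(t)] / [treated(t₀)/mock(t₀)] — normalized to both
the mock series and the pre-treatment baseline — and classifies a gene
inducible when max over post-treatment t of FC(t) ≥ 2 (inclusive ≥; the
boundary case FC = 2.0 exactly is inducible). The alternative reading
treated(t)/treated(t₀), which ignores the mock series, is available as
`mode="treated_only"`; the ratio-of-ratios form is the default because it
cancels both handling effects (mock) and baseline expression (t₀).

The intersection report's gene universe is the DE table; motif hits for
genes outside it are an error (universe mismatch), and all headline counts
are derived by set algebra from one per-gene annotation table (direction,
motif, root_specific, ck_inducible), which is the single source of truth
the output TSV serializes.

## qPCR / ChIP arithmetic

Relative expression is E^(Ct_ref − Ct_target) with amplification efficiency
E = 2 by default (the classic 2^−ΔCt), exposed as a parameter. Replicate Ct
values are averaged on the Ct scale before exponentiation, the standard
practice. ChIP enrichment is bound/input (computed from Ct values as
E^(Ct_input − Ct_bound)), reported as fold change against a control ratio.
No dilution correction is applied to input fractions and no standard-curve
fitting is performed. Replicate summaries are mean ± sample SD (n − 1); a
plain two-sample p-value helper is provided for group comparisons.

## Synthetic data: what it emulates and what it does not

The generator produces every pipeline input with a known truth table, so
each stage can be tested for *exact* recovery:

- **Genome**: `n_genes` = 60 genes on `n_contigs` = 2 contigs, lengths
  1.2–2.6 kb, 1–4 exons (≥ 200 bp) separated by introns ≥ 150 bp, 90 bp
  5′UTR and 150 bp 3′UTR at the transcript ends, random strand, intergenic
  spacing 2.2 kb — more than twice the 1 kb promoter length, so no base
  belongs to two genes' scan windows and planted-site ownership is
  unambiguous.
- **Motif sites**: background sequence is sanitized (every spontaneous
  occurrence of the four motif literals is destroyed by redrawing a base)
  before `n_sites` = 150 sites are planted at uniformly chosen in-category
  positions ≥ 7 bases from any feature boundary, non-overlapping, uniform
  orientation. Default category quotas follow the empirically observed mix
  (intron 45%, promoter 28.6%, exon 16%, 3′UTR 7.8%, 5′UTR 2.6%,
  apportioned by largest remainder). Sanitization makes the truth table
  exhaustive — a testing device, not a biological claim; real genomes
  contain abundant background motif occurrences.
- **Counts**: negative binomial with variance μ + αμ² (α =
  `nb_dispersion`, default 0.1), baseline mean 100, 3 replicates per
  condition; planted DE genes (5% up, 10% down — a 2:1 down:up ratio — at
  4-fold) scale the mutant mean. α = 0 degenerates to exact rounded means
  (not Poisson) to support deterministic truth-equality tests. The DE
  fraction is deliberately sparse: library-size normalization assumes most
  genes are unchanged, and the emulated study regime has on the order of a
  percent of loci DE; 15% is the desk-scale compromise that keeps catalogue
  intersections non-empty at 60 genes. The constant baseline matches the
  calibration/power conditions; real libraries have long-tailed abundance,
  which these tests do not probe.
- **Catalogue tables**: planted root-specific genes satisfy the
  classification rule with margin ≥ 1.5× the ratio threshold; non-planted
  genes get one tissue forced above root/ratio, so classification recovers
  the planted set exactly. Planted inducible genes reach a max FC drawn
  from [2.5, 8]; others stay in [0.5, 1.5]. These construction margins mean
  the recovery tests certify the classifiers' set semantics and boundaries,
  not their behaviour on borderline noisy data (boundary behaviour is
  tested separately with exact fixtures at 2.0 and 1.999).

All generators are pure functions of (config, seed) via per-stage seeded
streams; the same seed yields byte-identical files.

## Pipeline and problem sizes

`run_pipeline` validates all input paths before any computation, runs
scan → DE → catalogues → report with per-stage error attribution and
INFO-level count logging, and writes a deterministic report JSON (sorted
keys, config echo, seed, version, no timestamps), so a rerun with the same
config is byte-identical.

Test and acceptance problem sizes are chosen for seconds-scale runs while
keeping estimates stable: 200 random 2–5 kb sequences for the scanner
oracle, 150 planted sites for recovery, 2000 genes for null calibration,
and 20 seeded simulations (9 planted DE genes each) for power; measured
values (null fraction ≈ 0.05, pooled recall ≈ 0.93) are comfortably inside
their expected ranges, and the acceptance script recomputes them from
scratch at any seed.

## Known limitations

- The DE substitute is a t-test on log-CPM, not a count-model test
  (no dispersion shrinkage, no isoform quantification, no FPKM); it
  realizes the thresholding interface, not any particular assembler's
  numerics.
- Exact-string scanning has no mismatch tolerance or PWM scoring, and no
  background-enrichment statistics are computed.
- GTF dialect, trans-spliced genes, and fuzzy coordinates are unsupported.
- The root-specificity criterion is a parameterized convention, not a
  community standard; results depend on `min_expr` and `ratio`.
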
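# Methods

This note documents the models, defaults and design choices behind
homeolyze, and what the synthetic validation does and does not demonstrate.

## Study design and data model

The package assumes the classic allopolyploid design: RNA-seq libraries from
two extant diploid progenitors (A-genome and D-genome species), a diploid
F1-hybrid between them, and one or more natural allotetraploids, all aligned
to the single D-genome reference. A precomputed index of homoeo-SNPs — fixed
differences between the A and D subgenomes — lets each read that covers at
least one such site be attributed to a subgenome.

Internally all coordinates are 0-based half-open; GFF3 and the SNP index are
converted at the file boundary. The physical unit of observation is a
library (accession × replicate); analysis operates on *expression units*: a
polyploid library yields its A partition, its D partition, and a "total"
unit (all assigned reads; chimeric X reads are excluded everywhere as
artifacts), while a diploid library is a single unit of its own genome.
Whether N (uninformative) reads belong in denominators is genuinely
ambiguous; we include them in total/diploid units and exclude them from
partition units, which makes partition library sizes the categorized read
counts of that partition.

## Read classification

A read votes at each covered homoeo-SNP with an aligned (CIGAR M/=/X) base
of quality ≥ 20 (matching a phred-20 trimming convention; configurable).
Bases matching neither allele abstain rather than veto — robustness against
sequencing errors — and indels never produce votes. Class A requires at
least one A vote and no D votes (symmetrically D); both kinds of votes give
X (chimeric); no votes give N. Genes receive reads by maximal exonic
overlap in base pairs; ties are discarded rather than broken arbitrarily,
because any deterministic tie-break would double-count signal from
overlapping annotations. Only primary mapped alignments count; duplicates
are not removed.

## Differential expression

Counts are modeled NB with Var = μ + φμ², one common dispersion per
contrast. The chain is:

* **TMM factors** (trimmed mean of M-values): reference column = the one
  whose 75th-percentile count fraction is nearest the mean; 30% M-trim, 5%
  A-trim, precision-weighted mean of surviving M values; factors scaled to
  unit geometric mean.
* **Equalized pseudo-counts**: every column scaled to the geometric-mean
  effective library size and rounded, keeping the exact test's conditional
  enumeration on integers. This is a simplification of quantile-adjusted
  conditional ML; at the replicate numbers considered here the difference
  is second-order and is covered by the dispersion-recovery tests.
* **Common dispersion**: φ maximizing the summed conditional (negative-
  hypergeometric / Dirichlet-multinomial) log-likelihood over genes, by
  golden-section search on [1e-6, 5] to an interval of 1e-7. Genes with
  fewer than 5 summed counts are excluded; with no replicated group the
  estimate is 0 (warned).
* **Exact test**: conditional on S = S₁+S₂, group sums are NB with sizes
  nᵢ/φ and common per-replicate mean S/(n₁+n₂); two-sided p = total
  conditional probability of splits with probability ≤ the observed one
  (ties included, judged at 1e-10 relative slack in log space). φ = 0
  collapses to Poisson/binomial. Implemented directly from log-gamma
  arithmetic so that scipy's distributions remain an independent oracle.
* **BH step-up q-values per contrast** (the FDR scope is configurable in
  principle but per-contrast is the default and what all summaries use);
  significance means q < 0.05. Genes below 5 summed raw counts are
  reported NA — the exact test is degenerate there.

The fold change reported is log2 of (group-2 mean + 0.5)/(group-1 mean
+ 0.5) on equalized counts.

## Presence calling

A two-component Gaussian mixture is fitted by EM to each accession's mean
log2(RPKM+1) across replicates of its total units: 5 deterministic restarts
from quantile-spread initializations, relative log-likelihood tolerance
1e-8, at most 500 iterations, variance floor 1e-6 (zero-inflated background
values can otherwise collapse a component). The lower-mean component is
background; the posterior of the upper component is the probability of
expression. "Active" means posterior > 0.5; bias analyses use the 0.99
operating point. This is deliberately a minimal stand-in for
platform-covariate expression-likelihood models: it reproduces the
*operating characteristics* used downstream (a per-gene probability with a
high-confidence threshold), not the original model.

## Bias, dominance and cross-classification

Bias per polyploid = exact-test contrast of its A units against its D
units over high-confidence-present genes; the signed degree is the
replicate-mean difference of log2(RPKM+1), whose sign also orients the
direction call. The ELD sign triple uses three contrasts on total units
(A2 vs D5, P vs A2, P vs D5); its mapping to categories I–XII is encoded in
a single table satisfying the standard constraints (II/IV dominance at the
higher parent, IX/XI at the lower, VIII = transgressive up from equal
parents, (II+XI)/(IV+IX) measures D-dominance); 13 of the 27 possible
triples are named, the other 14 are reported as Ambiguous rather than
dropped, since they flag exactly the low-signal artifacts the presence
filter is meant to remove. Orientation of the mirror pairs (I/XII, III/X,
V/VI) follows the Rapp-style convention.

Where a standard statistic is called for we use the standard library:
Mann–Whitney U for degree-of-bias comparisons, Pearson for the
chromosome-count correlation, Spearman (default; OLS optional) for the
TE-distance association. TE distance is measured from the gene span, not
the TSS.

## Expression phylogenies

Distances are sums of squared per-gene differences on log2(RPKM+1)
(raw-RPKM mode available), replicates averaged so leaves are
accession-partition profiles; the homoeolog-difference tree uses the signed
degree profile per polyploid. Neighbor joining is the standard Saitou–Nei
algorithm with two determinism rules: Q-criterion ties (within 1e-12
relative) break on the lexicographically smallest pair of cluster labels
(a cluster carries its smallest leaf label), and negative branch lengths
are clamped to zero with the deficit moved to the sibling branch so the
joined pair's path length is preserved.

## The synthetic generator

Defaults emulate the petal study's shape: accessions A2, D5 (diploids), F1,
and three natural tetraploids, 3 replicates each; 13 chromosomes; 45% of
genes expressed; mean depth 200 reads per expressed gene per library
(constant by default — the calibration claims below are stated at this
per-gene depth; an optional mean-preserving lognormal spread adds dynamic
range); common dispersion φ = 0.05 (no empirical estimate exists for the
original tissue; this is a conventional bulk-RNA-seq value); 20% of
expressed genes biased at 1 log2-fold, half of them with a direction
conserved across every polyploid; ELD categories assigned to ~26% of
expressed genes with the high categories dominating, each category's
(A2, D5, P) multipliers normalized to unit geometric mean so mirror
categories sit at mirrored depths and the study carries no built-in
dominance asymmetry.

A polyploid library's gene count is one NB draw split multinomially into
48% N, 2% X and 50% categorizable, the categorizable part split A:D by the
gene's true homoeolog ratio — mirroring the read-category proportions of
real partitioned cotton libraries. Each class is then marginally NB with
the same dispersion; because A and D counts of one library share the draw,
their null split is conditionally binomial — *narrower* than the NB
conditional the exact test assumes, so the bias test is conservative on the
null, exactly as in the real paired-partition design. Library sizes are
equal by default; a log-uniform 2× spread is available to exercise
normalization.

The read-level simulator (for validating the classifier only; everything
statistical runs counts-first) lays genes with two exons on synthetic
chromosomes, plants ~10 homoeo-SNPs per exonic kb with the D allele in the
reference, places one TE downstream of each gene at exactly its
truth-assigned distance (spacers guarantee it is the nearest), and writes
reads that carry their origin's alleles, a per-SNP error rate of 0.5%, an
optional chimera rate, and a `ZO` origin tag for oracle comparison.

What the generator does *not* emulate: real sequence composition, splicing,
positional coverage bias, quality-score structure, mapping ambiguity, or
between-gene dispersion variation (a per-gene φ hook exists but the test
machinery assumes a common φ, as does the analysis). Passing tests
therefore demonstrate correctness of the algorithms and calibration under
the model's own assumptions, not robustness to real-data pathologies.

## Calibration results the tests enforce

At the stated conditions (depth 200, φ = 0.05, 3 replicates, 2-fold bias),
on a balanced study of 10,000 null and 10,000 biased genes, the bias caller
reaches sensitivity ≥ 0.90 at q < 0.05 with a null call rate ≤ 0.07 (in
practice near 0 because of the conservatism noted above). ELD labels are
recovered for ≥ 85% of expressed genes overall. Because BH's effective
threshold adapts to the discovery fraction, per-category ELD recovery is
mixture-dependent; the dual-detection categories (e.g. VIII, which needs
two simultaneous 2-fold detections) have a joint-power ceiling of ~0.87
even at an unadjusted 0.05 threshold at these settings, so their individual
recovery sits in the 0.7–0.85 range — a property of the exact-test design
at three replicates, not of the implementation.

## Numerical and degenerate-input conventions

Exact-test tie comparison at 1e-10 relative log-probability; S = 0 gives
p = 1. Dispersion search is deterministic; estimates within 2× of the lower
bound snap to it. The presence mixture refuses constant input ("no
expression signal") and fewer than 50 genes. NJ requires ≥ 2 leaves (2
gives the single edge). Zero-length genes and zero library sizes are
errors, not warnings. Pipeline outputs are pure functions of (inputs,
config, seed); the run manifest records the seed, a parameter hash and
per-file SHA-256 checksums, and reruns are byte-identical.

## Problem sizes used in validation

The bundled validation runs at desk scale by design: 600–5,000-gene studies
for module properties, 20,000 genes for the error-rate calibration, 60–200
genes for read-level simulations and the end-to-end reproducibility run.
These sizes give binomial standard errors well inside the asserted margins
while keeping the whole suite to a few minutes.
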
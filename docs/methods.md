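# Methods

This note documents the models, parameter choices and numerical conventions
behind `regland`, what the synthetic-data generator does and does not
emulate, and the known limitations of each analysis.

## Data model and conventions

All coordinates are 1-based inclusive on the forward strand (VCF
convention); conversion to BED's 0-based half-open intervals happens only at
the I/O boundary. A `PhasedHaplotypeSet` holds one chromosome — every
analysis here is cis (≤ 1 Mb windows), so multi-chromosome inputs are split
on read. Strand enters only through the TSS definition (leftmost exon
coordinate on +, rightmost on −) and the donor/acceptor labelling of splice
targets; no other strand arithmetic is performed. Variants are treated as
generic biallelic markers: indels, when present, are handled identically to
SNVs.

## Allele-specific expression

The test is an exact binomial test of the reference read count against the
lane's reference-allele mapping bias, two-sided by the minimum-likelihood
convention (sum of probabilities of all outcomes no more probable than the
observed one; this is also `scipy.stats.binomtest`'s convention, which the
vectorised implementation matches to machine precision in a test). Defaults:
α = 0.05; heterozygotes are testable only when both alleles are observed at
least once (`require_both_alleles=True`), since mono-allelic observations
are indistinguishable from genotyping error — the flag can be dropped, and
some analyses (e.g. the planted-causal experiment, whose carriers are
strongly imbalanced) do so.

Fold change is the bias-adjusted allelic odds ratio folded to ≥ 1; it is
infinite when a count is zero, and reported on the natural scale.

Two numerical caveats:

* The exact test is conservative at low counts: its analytic size at
  α = 0.05 is ≈ 0.031 under Poisson(30) read depth, ≈ 0.037 under
  Poisson(50) and ≈ 0.042 under Poisson(200). The calibration suite
  therefore measures empirical size at deeply covered sites (mean 200
  reads), where the discrete test is close to nominal; at routine depths the
  test under-rejects, which is conservative for every downstream use.
* Direction of effect at exact balance (`ref/total == bias`) is labelled
  `ref_higher`; such rows have p = 1 and never reach significance, so the
  tie-break is inert downstream.

Site-level ASE proportions (the fraction of testable heterozygotes with
significant ASE, a proxy for linkage with an unobserved regulatory variant)
require ≥ 3 testable heterozygotes per site. The sliding-window summary over
DAF is count-based (fixed number of sites per window, step 1) with 10%
upper/lower quantile curves; class comparisons use two-sided Mann–Whitney
tests overall and in overlapping DAF bins of width 0.05 and step 0.025, with
bins holding fewer than 2 records per group flagged and skipped.

## cis-eQTL mapping

Spearman rank correlation (average ranks on ties) with the t-approximation
p-value; exact small-sample p-values are unnecessary at cohort scale
(n ≈ 60) and the approximation's null uniformity is verified by a KS test.
Windows: ± 1 Mb around the TSS for gene-level phenotypes, around the exon
midpoint for exon read counts. MAF filter 0.05. Best-variant ties (equal p)
break by distance to the anchor, then position, making results
deterministic.

The permutation scheme permutes the phenotype vector across individuals with
genotypes fixed, preserving LD among variants; the per-feature threshold is
the level-quantile (default 0.01, 1000 permutations) of the null best-p
distribution. FDR at a level is the mean permuted significant count over the
observed one, capped at 1. The permutation machinery is vectorised (one rank
transform, then a permutation-by-variant matrix product), which keeps the
1000-gene × 1000-permutation calibration suite within seconds.

## Fine-mapping

D′ and r² are computed directly from phased haplotype frequencies — phase is
given, so no EM reconstruction is needed. D′ is 1 whenever a two-locus
haplotype class is absent, and undefined (NaN, flagged) at monomorphic
sites. Linkage between panels (e.g. a tag absent from the dense panel) is
computed across panels by aligning shared individuals' haplotypes; the
absent tag is additionally flagged. "Worse" means a linked dense variant
exists but its best p exceeds the sparse p; no model of genotyping error is
attempted. The conservation comparison between best and second-best linked
associations requires the two to be in mutual D′ ≥ 0.8.

## Functional enrichment

π0 is the Storey estimator: π0(λ) = #{p > λ}/(n(1−λ)) on λ ∈ {0.05, …,
0.95}, cubic polynomial fit in λ evaluated at the grid maximum, clipped to
[0, 1]; at least 31 p-values are required (the same >30 rule that gates
depth bins). The endpoint estimate carries sampling standard deviation
≈ 0.03 at n = 10⁴ (comparable for polynomial and spline smoothers), so
recovery checks average replicate mixtures rather than trusting one draw.

Class rules: splice-labelled sites within 5 bp of an exon boundary are
essential-splice, within 100 bp general splice, both attached to the donor
(5′) and acceptor (3′) flanking exons with roles resolved by strand;
stop-gained/synonymous/nonsynonymous attach to the overlapping exon;
synonymous sites within 15 bp of a boundary are excluded from the matched
background. Depth bins are 15 log-spaced bins over 1–1000 mean reads per
exon per individual, and the background is depth-matched per bin (the
stricter of the plausible designs). The log-ratio in a bin is undefined —
flagged, not zeroed — when either class's 1−π0 is 0 there (a perfectly null
background estimate clips to π0 = 1).

## Rare regulatory variation

**Haplotype homozygosity.** Tract length is the physical distance (bp) from
a heterozygous ASE marker along two phased haplotypes to the first
mismatching site; tracts reaching the end of the assayed region are
censored and flagged rather than dropped. For each qualifying marker (≥ 6
testable heterozygotes, 2–4 significant in the same direction, ≥ 2
non-significant) the carried allele and scan direction are chosen to
maximise the mean pairwise tract over all carrier haplotypes, and mean
tracts are compared between significant–significant and
significant–non-significant pairs, stratified by the significant count.

**prSNP detection.** ASE individuals are the significant testable
heterozygotes at a marker (shared count 1–3 of ≥ 6 testable). A candidate
within 100 kb of the TSS is concordant when every ASE individual is
heterozygous with the same allele on the over-expressed haplotype and every
testable non-ASE individual is homozygous. Untestable individuals are
ignored, not constrained (their allelic state is unobserved). The marker is
excluded as its own candidate by default (`include_marker` reverses this).
The null pass reassigns ASE to the k least-significant testable
heterozygotes (ties broken by sample id), draws the null individuals'
directions as a seeded permutation of the real direction multiset, and
reruns the identical detection; markers where reassignment is impossible
(too few non-significant heterozygotes) are skipped with a flag in both
summaries. Positional comparison of real vs null candidates uses Fisher's
exact test per 5 kb bin around the TSS, Bonferroni-corrected over bins.

The planted-causal experiment (`synth.simulate_prsnp_gene` +
`rarereg.real_null_excess`) builds, per gene, a coding marker heterozygous
in 6 individuals, one causal variant heterozygous in exactly the 2 ASE
carriers with its alternate allele phased onto the over-expressed haplotype
(allelic fraction 0.95 at mean depth 50), and 50 background variants at the
causal's allele count placed on random haplotypes. The expected real-minus-
null difference is slightly below one candidate per gene: a false-positive
ASE call in a balanced heterozygote (exact-test size ≈ 0.03–0.04 per
individual, four exposed per gene) breaks the perfect-concordance
requirement for the causal variant in that gene, giving an expectation of
(1 − size)⁴ ≈ 0.85–0.90. This is a property of requiring exact concordance
with noisy ASE labels, not of the detector.

## Expression outliers

Z-scores are per gene across individuals, SD with n−1; zero-variance genes
are dropped and recorded. Outliers are one-tailed high (Z ≥ 2) by default,
with a two-sided option. A carrier is any individual with ≥ 1 non-reference
allele; allele-frequency bins are integer non-reference allele counts
(singleton = one carrier haplotype). Both the raw (gene, variant,
individual) triple count and a deduplicated (gene, individual) count are
available. The envelope permutes individual expression labels (default 200
rounds) with genotypes fixed — the (variant, carrier) structure is
asserted unchanged every round — and reports the permuted mean, 90/95%
one- and two-sided bounds, the excess over the permuted mean and a
per-individual rate.

When planting singleton outlier effects for recovery checks, the offset is
+5 SD: a +3 SD shift leaves the carrier below Z = 2 in about a fifth of
cohorts of n = 60 (the shift itself inflates the sample mean and SD), which
a normal-model oracle in the test suite quantifies; +5 SD makes the planted
count actually recoverable and the excess estimator's small negative bias
(each planted entry contributes ≈ outlier-rate/n to the permuted mean) stays
within a few percent.

## Synthetic-data generator

The generator draws sites independently (no background LD) from a spectrum
with a singleton mass plus a grid of common frequencies; the alternate
allele is ancestral-polarised by construction so DAF is known. Haplotype
sharing is created explicitly by copying a founder segment — the
homozygosity and prSNP analyses need controllable sharing, the others do not
need realistic LD. Expression is additive (β per alt allele, in units of the
noise SD) with Gaussian noise; exon counts are Poisson around a
per-haplotype mean, without overdispersion — adequate for the rank-based
tests used downstream, but negative-binomial noise in real RNA-Seq will make
real-data p-values less well calibrated than the synthetic suite suggests.
Allelic counts are Poisson totals with binomial reference reads at the
mapping bias, shifted by any planted expression ratio through
p = b·ρ/(b·ρ + 1 − b).

Default cohort conditions: 60 individuals (an RNA-sequenced European-panel
size), mapping bias 0.5, mean allelic depth 50, unit noise SD, planted
effect size β = 2. Passing tests on these cohorts demonstrates the
statistics behave as designed under their own assumptions; they do not
demonstrate robustness to mapping artefacts, overdispersion, population
structure or LD-induced confounding, none of which the generator emulates.

## Problem sizes in the test and acceptance suites

The calibration and recovery suites use 10⁵ allelic count rows (test size),
1000 genes × 1000 permutations (threshold admission), 40–50 replicate
cohorts (envelope coverage, outlier-excess recovery), 100 planted-eQTL runs,
and 500 genes for the planted-causal excess; the acceptance script uses the
same 500-gene design. These sizes keep each suite in the seconds-to-a-minute
range on one CPU while holding Monte-Carlo error well inside each check's
band.
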
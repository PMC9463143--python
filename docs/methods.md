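# Methods

This note documents the models, defaults, and design choices behind
pirnakit, in the order data flows through the package.

## Coordinates and formats

All internal coordinates are 0-based half-open with explicit strand;
conversion happens only at file boundaries (GFF3 is 1-based inclusive on
disk, BED and SAM-via-pysam already 0-based). The 5′ nucleotide of an
alignment is always in read orientation — reverse-complemented from the
stored reference-forward sequence for minus-strand SAM records — because
small-RNA identity rules (5′G, 5′U) are read properties. T and U are
interchangeable. Alignment multi-hit counts come from the `NH` tag (SAM)
or the score column of a 7-column BED dialect
(`chrom start end read_id n_loci strand five_prime_nt`); when absent they
are inferred by grouping identical read names, which assumes the aligner
reported all best loci.

## Classification and normalization

Reads of 17–40 nt are classified with a fixed precedence: structural
sense (rRNA/tRNA/snoRNA) > mature miRNA/piRNA > 22G antisense > other
sense overlap > unassigned. The precedence is a package decision: it
prevents rRNA fragments from inflating gene counts and treats structural
sense reads as degradation background, which is also why they are
removed from the RPM denominator. "Mature" miRNA/piRNA means the read
lies entirely within the annotated locus (a read overhanging the
annotation is a modified or mis-assigned species, not a mature one); a
read shorter than the locus but inside it still counts as mature.
Antisense requires at least 1 nt of opposite-strand overlap with the
feature span; no minimum overlap fraction is imposed. A multimapper
contributes weight 1/n_loci per reported locus, so its total contribution
is at most 1; a read overlapping two same-biotype features under its
winning rule contributes its full weight to each (interval-intersection
counting — the synthetic genome avoids such overlaps so tests are
unambiguous). Weighted counts stay fractional everywhere except the
Bayesian test, which needs integers.

## Bayesian differential accumulation

The two-model comparison treats a gene's reads as k successes out of the
library total N, where N is the same total-minus-structural quantity the
RPM denominator uses, so the test and the fold change share one frame.
With a Beta(a, b) prior the marginal likelihoods of the shared-probability
and independent-probabilities models are closed-form Beta-function
expressions, computed in log space and finite to N = 1e8. Defaults:
a = b = 1 (uniform) and equal model prior odds, both exposed in
`PriorSpec` and recorded in outputs — the construction is the stated
two-model comparison made concrete, with hyperparameters configurable.
`p_same` is the posterior probability of the shared model. It is a
posterior model probability, **not** a frequentist tail probability; it is
used directly as the per-gene "p value" and compared against
alpha / n_genes (Bonferroni). Because the Bayes factor carries an Occam
penalty that grows with log N, small absolute counts cannot reach extreme
posteriors: a 4-fold change at 50 baseline reads is undetectable at a
2000-gene Bonferroni threshold no matter the implementation. Power
statements therefore qualify genes by the *minimum* expected count across
the two libraries (≥ 50), i.e. even the reduced library retains ≥ 50
expected reads. Weighted counts are rounded half-to-even for the test
only. Fold changes use +1 RPM pseudocount on both sides; `direction`
reflects the fold change alone and `significant` requires both the
posterior and the 2-fold criterion, matching how changed-gene percentages
are reported. Quadrant analysis partitions genes by the sign pair of
(mRNA log2 FC, 22G log2 FC); an exactly-zero coordinate goes to an `axis`
category outside the four quadrants (a measure-zero event on real data,
deterministic on synthetic), and proportions sum to 1.

## Profiles

Depth is full-read coverage (each covered spliced position incremented),
in transcript coordinates 5′→3′ of the mRNA, minus-strand genes flipped.
Metagene binning maps position p of a length-L gene to bin
floor(p·100/L), which conserves mass exactly for every length without
interpolation. 3′-tail enrichment is the depth fraction in the last
floor(0.15·L) positions (minimum 1). Floor rather than ceiling keeps a
perfectly uniform gene at or below the 0.15 boundary at every length, so
the uniform null classifies non-enriched; the published class anchors
leave the interval (15%, 16%) unassigned and are closed as
≤ 0.15 / (0.15, 0.30] / > 0.30 so the classification is total. Site
windows span anchor − 50 to anchor + 49, the anchor being the transcript
position paired to piRNA nucleotide 10; out-of-transcript positions are
excluded from that position's mean rather than zero-filled, to avoid edge
suppression. Coverage (not 5′-end counting) is used for site profiles;
both choices are deliberate package decisions where the convention was
open.

## IP ratio

`log2((hrde_rpm + ρ)/(csr_rpm + ρ))` with ρ = 0.1 RPM by default —
distinct from the differential module's 1 RPM because ratio distributions
are compared as boxplots and zeros must stay finite without dominating.
Boundary membership: −2.8 and −1.82 belong to the middle (CSR-1 favored)
class and 0 to slightly-CSR-1-favored, honoring the strict inequalities
printed for the outer classes. The four classes partition the real line.

## Synthetic data

The generator is the package's test instrument; its defaults define the
simulated study conditions.

* **Genome.** Single-exon features laid out non-overlapping (gap 100 nt)
  on synthetic chromosomes: 2000 protein-coding genes (lengths uniform
  500–3000 nt), 30 pseudogenes, 40 transposons, structural loci, 30
  miRNA and 60 piRNA loci. 20 duplicated gene pairs are equal-length
  clones with identical abundance whose reads are reported at both loci
  with n_loci = 2 — multimapping isolated from overlap ambiguity.
  Multi-exon handling is exercised by hand-built fixtures instead.
* **Classes.** 30% WAGO targets, 30% CSR-1 targets; 50% of WAGO are
  prg1-dependent, 30% reduced-HRDE-1; 15% of CSR-1 are enhanced-HRDE-1
  (matching the reported share of CSR-1 genes that gain HRDE-1 22Gs).
* **Counts.** Per-gene weighted 22G counts are gamma-Poisson around
  λ_g · φ · ε · depth/1e6, with lognormal baseline abundances (σ = 1.2,
  spanning ~3 orders of magnitude) and a single global dispersion
  α = 0.005 (variance = μ + αμ², ~7% extra-Poisson CV). The dispersion is
  a tunable chosen for test power, not an empirical estimate. Library
  composition: 15% structural, 5% mature piRNA, 3% mature miRNA, the rest
  22G.
* **Effects.** Mutant condition: prg1-dependent genes φ = 0.25 (4-fold
  22G loss) with mRNA ψ = 2 (activation); enhanced-HRDE-1 genes gain
  4-fold in the mutant HRDE-1 IP with mRNA ψ = 0.5; reduced-HRDE-1 genes
  drop 4-fold in the mutant HRDE-1 IP. IP enrichment factors
  (HRDE-1 / CSR-1): WAGO 8 / 2 (a planted 4-fold ratio, expected log2
  ratio ≈ 2), plain CSR-1 targets 0.5 / 8, enhanced 2 / 8, unclassified
  1 / 1. RPM ratios additionally absorb a small depth-normalization
  offset (the ratio of total enrichment-weighted abundance between the
  two IPs), as in real fixed-depth sequencing.
* **Positions.** Read centers are drawn from a mixture of uniform
  coverage, a 3′-tail component tuned so the last-15% mass equals τ_g
  (τ = 0.15 is the uniform expectation; CSR-1 targets 0.40; enhanced
  genes lose the concentration, 0.15), and Gaussian bumps at piRNA sites
  (mass 0.10 per site, half-width-at-half-max 10 nt — deliberately
  narrower than the 100-nt window so localization is a meaningful test).
  τ describes the non-bump component; recovery checks therefore use genes
  without planted sites. Two sites per WAGO target, anchors ≥ 60 nt from
  transcript ends.
* **Sequence realism is out of scope**: reads carry only length, 5′
  nucleotide, strand, and position — no nucleotide content, qualities, or
  adapter artifacts. 22G reads are always 21–23 nt 5′G; piRNA reads 21 nt
  5′U; this makes class-conservation checks exact rather than
  probabilistic.
* **Images.** Spots are in-plane Gaussians (σ = 2 px, amplitude 100) on a
  background of 10 with Gaussian noise σ = 1; a planted fraction of
  channel-A centers coincides with channel-B centers and the rest are
  kept ≥ 8 px from every B center. The DoG response of a spot is
  amplitude · s²(1/(s²+σ₁²) − 1/(s²+σ₂²)); synthetic thresholds are set
  at 25% of that peak (real analyses use manual uniform thresholds, which
  are a required recorded parameter).
* **Determinism.** Every output is a pure function of (config, seed);
  truth serializes beside each bundle and regenerates bit-identically.

What passing tests on this generator do **not** show: robustness to
overlapping annotations, isoform structure, spliced-read emission,
sequence-dependent alignment artifacts, or empirical overdispersion —
real libraries are noisier and dirtier than the generator in all four
respects.

## Numerical choices

* Evidence computations use log-Beta/log-Gamma throughout; the
  independent numerical-integration route is Gauss–Legendre with order
  doubling until log-space convergence (for integer shape parameters the
  integrand is polynomial, so convergence is exact once the order passes
  half the degree).
* Metagene and site profiles accumulate in a fixed (sorted) order so
  results are invariant to input ordering at the bit level.
* Zero denominators (fully structural libraries, empty query masks,
  zero-depth tracks) are explicit errors or missing values, never silent
  NaN or 0.
* Tables are written with 12 significant digits and `.` for missing, so
  write-then-read is identity at that precision and reruns are
  byte-identical.

## Problem sizes in tests

Read-level checks run at 300 genes and 3×10⁵ reads; count-level error and
power checks at 2000 genes with 200 null runs at 10⁵ depth and 10 effect
runs at 10⁶ depth; imaging at 128×128×3 stacks over 10 seeds. These sizes
are the package's chosen test conditions; all statistical margins quoted
in the test suite were verified at them.

## Known limitations

* The beta-binomial frame conditions on library totals and ignores
  biological replicate variance; it is a two-library comparison, not a
  replicate-aware DE model, and the Bonferroni-on-posterior rule is
  conservative by construction.
* Whether a multi-locus read should contribute 1/n at every locus before
  feature intersection (as here) or be resolved to a single locus is an
  open convention; the alternative is not implemented.
* Real-data users must supply annotation matching their genome build;
  the synthetic coordinates make builds irrelevant in tests.
* piRNA target sites are consumed as input coordinates; predicting them
  is out of scope.
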
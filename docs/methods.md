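# Methods

## Problem and model

`kscreen` screens sequencing-study genotypes for windows of the genome that
are associated with a trait, controlling the false discovery rate (FDR)
among the selected windows.  Conventional sliding-window association tests
with Bonferroni or Benjamini–Hochberg correction do not account for the
strong, arbitrary correlation (linkage disequilibrium, LD) between nearby
windows; the knockoff framework does, and additionally prioritizes causal
windows over windows that are merely correlated with them.

For individuals i = 1..n with outcome Y_i (quantitative or binary),
covariates X_i and dosages G_ij of p variants, the method:

1. generates M synthetic **knockoff cohorts** G̃¹..G̃ᴹ, exchangeable with G
   but conditionally independent of Y given G;
2. tiles the region with half-overlapping windows of sizes 1 bp, 1 kb,
   5 kb and 10 kb and computes one importance p-value per window in the
   original cohort and in each knockoff cohort, using an ensemble of
   covariate-adjusted score tests combined by the Cauchy combination
   (ACAT);
3. contrasts the importance scores T = −log₁₀ p of the original and
   knockoff copies of each window through a feature statistic and applies
   the multiple-knockoff selection filter, which guarantees FDR control at
   the target level q under arbitrary LD; per-window knockoff Q-values
   report the smallest q at which each window would be selected.

## Knockoff generation

The generator is a sequential conditional model.  Variants are visited in
genomic order; for variant j it fits, by least squares, the linear
auto-regressive model

    G_j = α + Σ_{k∈B_j} β_k G_k + Σ_m Σ_{k∈B_j, k<j} γ_k^m G̃_k^m + ε_j

and forms each knockoff copy as fitted value plus an independently
permuted residual, G̃_j^m = Ĝ_j + ε̂_j^{*m}.  Permuting residuals rather
than sampling a parametric error keeps the construction valid for rare
variants, whose dosage distribution is zero-inflated; the output is
continuous (dosage-like) and never clipped to {0,1,2}.

The conditioning set B_j holds the K most correlated variants within
±100 kb with |r| > 0.05, K = ⌊n^{1/3}⌋ (the rate at which least-squares
coefficient estimates remain well behaved as the design grows).  Knockoff
columns of already-generated neighbors enter the design for all M copies;
total design size is capped at K·(M+1) columns kept in |r| order.
Rank-deficient designs are resolved by a tiny ridge (1e-6) on the normal
equations, equivalent to the minimum-norm solution at this tolerance.

**Tight LD.**  Variants with pairwise |r| > 0.75 cannot be told apart by
any selection procedure and are treated as one discovery unit.  Clusters
are built by single-linkage hierarchical clustering at distance 1 − |r|
cut at 0.25 — single linkage is what guarantees that two variants in
*different* clusters never correlate above 0.75.  Cluster co-members are
excluded from each other's conditioning sets, and one permutation per
(cluster, copy) is applied jointly to all members' residuals, preserving
the within-cluster residual correlation while preventing the knockoffs
from collapsing onto the originals.

**Diagnostics.**  Exchangeability is checked by regressing
cor(G_j, G̃_k) on cor(G_j, G_k) over pairs j ≠ k; a valid generator gives
slope ≈ 1.  The regression is restricted to pairs with sample |r| ≥ 0.1:
pairs whose true correlation is zero contribute sample noise of order
1/√n to both axes, and regressing noise on noise attenuates the slope
without measuring exchangeability.  On block-LD panels the pairs inside
conditioning sets sit on the identity to three decimals.

## The window test ensemble

Windows of 1 bp (common and low-frequency variants only) use the
single-variant score test; for binary traits with |z| ≥ 2 the normal tail
is replaced by a saddlepoint (Lugannani–Rice) inversion of the score
statistic's exact cumulant generating function, which stays calibrated
under severe case-control imbalance.

Multi-bp windows combine, via ACAT with equal weights:

* burden + SKAT on common/low-frequency variants, Beta(MAF; 1, 25)
  weights;
* burden + SKAT on rare variants (MAF ≤ 0.01, MAC ≥ 5), same weights;
* optionally, for each supplied functional-annotation score: burden +
  SKAT on rare variants with the Beta weight multiplied by the min-max
  scaled annotation (scores are opaque numerics);
* the unweighted burden of ultra-rare variants (MAC < 5);
* a single-variant score test for every variant in the window.

Components with no qualifying variants are omitted, not entered as p = 1.
Variant categories and MAF weights for a knockoff window are inherited
from the original panel so original and knockoff windows hold matched
variant sets; both are scored by literally the same routine.

The SKAT null distribution (a positive mixture of 1-df chi-squares) is
evaluated exactly for one eigenvalue, and otherwise by saddlepoint
inversion of the mixture CGF — essentially exact in the tail that drives
screening decisions, accurate to a few percent relative near the mean —
with the Liu–Tang–Zhang moment-matched chi-square as fallback.
Eigenvalues below 1e-10 of the largest are dropped.  All p-values are
floored at 1e-300; ACAT maps p through tan((0.5 − p)π) with the 1/(pπ)
asymptote for p < 1e-15.

## The selection filter

With importance scores T (original) and T¹..Tᴹ (knockoffs) per window:
κ indexes the largest of (T, T¹..Tᴹ) (0 = original, ties favor the
original), and τ is the gap between that maximum and the *median* of the
remaining M scores.  Using the median rather than the maximum of the
knockoff scores reduces run-to-run variability of the statistic under
knockoff resampling, which improves the reproducibility of selections.
The data-adaptive threshold is

    τ̂ = min{ t : (1/M + (1/M)·#{κ≥1, τ≥t}) / max(1, #{κ=0, τ≥t}) ≤ q }

minimized over the observed positive τ of κ = 0 windows (the infimum over
continuous t is attained there); windows with κ = 0 and τ ≥ τ̂ are
selected.  At M = 1 this reduces exactly to the classic knockoff filter
on W = T − T¹.  The numerator's +1/M makes a detection threshold: at
q = 0.1 a single knockoff cannot select anything unless ≥ 10 windows
qualify, while M = 5 lowers that to 2 — the source of the power advantage
at sparse signal.  The knockoff Q-value of a window is the running
minimum of the FDR estimate over thresholds below its τ; selection at
level q is exactly {Q-value ≤ q}.  All window size classes are pooled
into one genome-wide filter pass.

Favoring the original on ties at the maximum is mildly anti-conservative;
`feature_stats` is the single place implementing the convention.

## Synthetic data generator

The generator emulates LD-block-structured dosages: variants are grouped
into blocks of 4–12, a latent AR(1) Gaussian copula with per-block decay
ρ ∈ (0.5, 0.95) induces within-block LD, and two independent haplotypes
are thresholded at the variant's target allele frequency and summed.
Target frequencies are drawn from a mixture over strata — 30% common
(0.05–0.5), 15% low-frequency (0.01–0.05), 40% rare (down to MAC ≈ 5)
and 15% ultra-rare (expected MAC 1–4) — placing the bulk of mass on the
rare spectrum that sequencing studies target.  Default panels span
200 kb.

What the generator does *not* emulate: recombination-driven long-range
LD decay within blocks, allele-frequency/LD coupling from a coalescent
process, cryptic relatedness, and realistic ancestry covariance (the
stratification design uses three discrete groups with shifted trait
means and allele frequencies).  Passing FDR and power checks on these
panels therefore demonstrates the procedure's statistical properties
under block LD, not performance on any particular real cohort.

Phenotype recipes:

* quantitative: Y = X₁ + Σ β_j g_j + ε, with X₁ ~ N(0,1), ε ~ N(0,3);
* binary: logit(μ) = β₀ + X₁ + Σ β_j g_j, β₀ solved by root finding so
  the expected prevalence is 10% (or any target).

Effect sizes follow β_j = a/√(2 m_j (1 − m_j)) with a calibrated so the
realized genetic variance Σ β_j² var(g_j) equals its target *exactly*
(0.05 for common-variant scenarios, 0.1 for rare), or β_j = a·|log₁₀ m_j|
with fixed a (default 1.4) for the prioritization design.

## Experiment designs and problem sizes

`run_design` implements: `single_region` (0.5% causal variants inside a
10 kb window; one representative variant per tight-LD cluster is kept
*before* phenotype simulation so the false discovery proportion is well
defined), `genome_wide` (10 causal 200 kb loci with 10 kb causal windows
holding 10% causal variants, plus noise loci, each locus an independent
region; locus-level FDR judged at ±50/75/100 kb buffers), `prioritization`,
`shadow` (common causals, rare-only analysis; every selection is a false
positive), `stratification` (group-shifted trait means and allele
frequencies; compared against the ensemble + BH comparator), and
`stability` (variance of τ under knockoff redraws, median- vs max-based
statistic).  The conventional comparator shares the exact ensemble
p-values and differs only in the correction (Bonferroni 0.05/#windows or
BH at q).

The bundled acceptance script runs the single-region design at n = 3000,
p = 300 with 150 replicates and the genome-wide design at n = 2000 with
10 causal + 30 noise loci and 25 replicates; these desk-scale sizes are
the package defaults for reproducing the headline FDR bounds, and the
Monte-Carlo standard errors they imply are reported alongside the means.
FDP on an empty selection is defined as 0.

## Numerical choices and limitations

* Correlations are computed on centered dosages; zero-variance columns
  yield r = 0 and are untestable.
* Score variances below 1e-12 of the raw genotype sum of squares are
  treated as "genotype explained by covariates" (p = 1 / untestable).
* Missing genotypes are mean-imputed at load, preserving MAF and keeping
  the generator's least squares well posed.
* Window tiling anchors the start grid at the largest multiple of
  (size/2) at or below the first variant position; membership near region
  edges can differ from tilings anchored at position 1.
* Same seed ⇒ bit-identical knockoffs, scan tables and summaries.
* No mixed-model relatedness adjustment, no meta-analysis combiner, no
  HMM/second-order/deep knockoff generators; heterogeneous LD across
  subpopulations is not modeled by the generator.
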
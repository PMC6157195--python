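# Methods

## Two-stage model

Stage 1 fits a linear mixed model for the change score
*y* = ln TG(follow-up) − ln TG(baseline) on the covariates (age, centre,
smoking, MSDX score, fasting time, ln baseline HDL, ln baseline TG — the
last two derived with the same ln-then-average rule as the phenotype) plus
an additive polygenic random effect:

    y = X beta + g + e,   cov(g) = 2 Phi sigma2_g,   cov(e) = sigma2_e I,

with Phi the expected-kinship matrix computed from the pedigree by the
recursive tabular method.  When a variable has two visit-level
measurements, each measurement is ln-transformed *before* averaging; this
ordering matters whenever the two measurements differ and is pinned by a
regression test.  Baseline TG appears once, on the ln scale.

The fit is exact REML: one eigendecomposition 2Φ = UDU′ rotates the model
to independent coordinates with variances sigma2_e·(λ d_i + 1),
λ = sigma2_g/sigma2_e, after which the restricted likelihood is profiled
over λ with a bounded scalar search on log10 λ ∈ [−8, 4] plus an explicit
λ = 0 boundary candidate.  A dense-matrix restricted-likelihood evaluator
(`reml_loglik_dense`) provides the brute-force cross-check used in tests.

**Residuals.** The pipeline hands stage 2 the quantity r = ŷ − y.  By
default ŷ includes the BLUP of g ("conditional" residuals).  The choice is
deliberate: the permutation engine shuffles residuals freely across
individuals, which presumes approximate exchangeability, and conditional
residuals — having the familial correlation removed — satisfy it far
better than marginal ones.  A `residual_type="marginal"` option (ŷ = Xβ̂
only) is exposed for comparison.  Every downstream statistic is invariant
to an affine rescaling of r, so the sign convention is inconsequential and
tested as such.

## Stage-2 pair model

For each SNP–CpG pair, r is regressed on {1, SNP, CPG, SNP·CPG} and the
overall-model F statistic tests the three slopes jointly (df 3, n − 4).
An intercept is included by default even though the structural model is
written without one: permuted residual vectors are not constrained to mean
zero within the fitting subset, and "overall model significance" in the
F-test sense is relative to the intercept-only null.  A literal
no-intercept mode exists (`include_intercept=False`), where the F test
compares against the zero model with uncentred total sum of squares.

Degenerate designs are *reduced*, not discarded: if the CpG is a point
mass (e.g. the unmoderated-effect option of the generator) the model
collapses to a single-SNP regression with a 1-df numerator; only when no
slope direction varies at all is p = 1 returned.  The `degenerate` flag
records any rank deficiency.  Missing genotypes are dropped pairwise.
p-values are clamped to [1e-300, 1] so that ln p is finite in the
combiners.

## Gene statistics and orientation

All six combiners (Σ ln p, Σ −(ln p)², min p, pT 0.01/0.05/0.10) are
oriented so that *smaller is more extreme*; this single convention fixes
the permutation tail for every method.  The threshold statistic
Σ_{p≤T} −(ln(p/T))² is continuous at p = T (both branches vanish) and
reduces to Σ −(ln p)² at T = 1; both identities are tested.  The
single-marker comparator declares a gene significant when min p < α/m.

## Permutation significance

B permutations (default 1000) of the residual vector are drawn once and
reused for every pair and gene, so the dependence between pair p-values
within a permutation is preserved.  Because only the response changes
between refits, each pair's design is pre-reduced to an orthonormal basis
Q and a refit costs one product Q′y: the B-sweep is a single BLAS matrix
product over all full-data pairs.  The naive per-shuffle refit path and
the batched path agree to 10 significant digits (tested).

Empirical p-values use the add-one estimator
(1 + #{G_perm ≤ G_obs})/(B + 1), with ties counted as extreme.  This is a
deliberate, conservative replacement for the raw proportion of more
extreme permuted values: it can never return 0, and under the null it is
sub-uniform with P(p ≤ t) ≤ t + 1/(B+1).  Significance uses strict
inequality, p < α.

## Quality control and pairing

SNPs are kept iff HWE p > 1e-6 (1-df chi-square without continuity
correction; monomorphic SNPs return p = 1 by convention), folded MAF > 1%
(computed on non-missing calls) and missing-call rate < 5%; all three
inequalities are strict, and the filter is monotone in its thresholds.
Each kept SNP is paired to the CpG minimising point-to-point distance on
the same chromosome; ties break toward the lower coordinate for
determinism.  An override table (snp_id → cpg_id) supersedes the nearest
rule — used for causal SNPs whose designated CpG need not be nearest — and
warns when an override spans more than 12,500 bp.  Gene membership is
1-based inclusive on [start, stop] (BED I/O converts from 0-based
half-open); a major-effect SNP caught by no gene is appended to the
nearest gene within 50 kb, or failing that founds a synthetic gene
spanning ±50 kb around itself.

## Synthetic cohorts

The generator emulates the structure of a family-based lipid cohort:

- **Pedigree**: nuclear families (two founders + 2–4 sibs) covering
  exactly n individuals (default 670).
- **Genotypes**: gene dropping — founder alleles Bernoulli(MAF), offspring
  inherit one uniformly chosen allele per parent.  SNPs are unlinked.
- **Methylation**: independent Beta(2, 2) draws by default.  The true
  methylation distribution of real arrays (typically bimodal near 0 and 1)
  is not imitated; Beta(2, 2) gives a symmetric moderator with mean 0.5,
  which is all the calibration requires, and the parameters are
  configurable.
- **Moderation**: causal terms take the attenuation form
  β·SNP·(1 − CPG) — methylation dampens the SNP effect — exposed as a
  config choice (`moderation`), with a point-mass-at-zero methylation
  option yielding unmoderated effects.
- **Calibration**: the latent change score's variance
  (causal + polygenic + residual) is normalised to 1, so a SNP's
  heritability target h² is exactly the variance of its causal term.  β is
  solved analytically from the first two moments of SNP ~ Binomial(2, MAF)
  and CPG (independent), and verified against Monte Carlo within 2 SE for
  every design point (h², MAF) ∈ {(.125,.11), (.10,.19), (.075,.10),
  (.05,.41), (.025,.14)}.
- **Covariates and measurements**: modest fixed effects on the change
  score (defaults in `SimScenario`; the real study's effect sizes are
  unknown, so these are explicit placeholders), polygenic fraction
  sigma2_g = 0.2, ln-scale measurement noise sd 0.05 per visit
  measurement, and a second measurement present with probability 0.7 to
  exercise the averaging rule.

Identical (scenario, seed) inputs give bit-identical cohorts; replicate
seeds are spawned from the master seed via `numpy` seed sequences.

**What the generator does not emulate.** Linkage disequilibrium between
SNPs (an AR(1)-latent LD option was considered and deferred; noise pairs
are independent), sex chromosomes, imputation artefacts, methylation
bimodality, treatment response, and the proprietary generative details of
the original cohort.  Consequently per-gene power values are not expected
to match a real cohort's; the structural behaviours are: the false-positive
rate of every method sits at or below the nominal 5% on noncausal genes,
an all-causal 5-pair set is detected essentially always, and in sets
dominated by noncausal pairs the min-p and threshold statistics retain
power that the averaging combiner loses.

## Experiment sizes

The shipped experiments run at desk scale on one CPU: type-I error on
60 replicates × 39 noncausal genes (sizes 5–30 pairs) at B = 1000
(~1 minute with the batched permutation path); the positive control on
50 replicates of the 5-pair all-causal set at B = 1000; the
noise-robustness comparison on 100 replicates of the 288-pair NOISE5 set
at B = 500.  Larger B or replicate counts change only runtime.

## Known limitations

- The kinship REML supports a single random effect; longitudinal
  modelling of all four visits, dominance, and epistasis are out of scope.
- Stage-2 refits under permutation assume the pair designs are fixed;
  covariate re-adjustment at stage 2 is not offered.
- Empirical p-values are bounded below by 1/(B+1); genome-wide
  significance levels would need far larger B or an analytic tail
  approximation, neither of which is attempted here.
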
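# Methods

`tsmr` implements the complete analysis stack of a two-sample Mendelian
randomization (MR) study of a dietary exposure against a binary disease
outcome, working purely on GWAS summary statistics.  This note documents the
statistical models, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
decisions that affect results.

## The causal model

Two-sample MR uses germline variants as instruments for an exposure X to
estimate its causal effect θ on an outcome Y, under three assumptions:
relevance (the variant is associated with X), exchangeability (no
confounding of the variant–outcome relation), and exclusion restriction (the
variant affects Y only through X).  With summary statistics
(β̂_xj, se_xj) and (β̂_yj, se_yj) from non-overlapping cohorts, each valid
instrument j gives a Wald ratio β̂_yj/β̂_xj estimating θ.  The exposure is
in SD units and the outcome on the log-odds scale, so θ is a log-odds
difference per SD and exp(θ) an odds ratio.

## Instrument selection

Criteria, applied in order; each is a subset of the previous, so the audit
trail records monotone counts:

1. genome-wide significance, p < 5×10⁻⁸ (configurable);
2. optional exclusion list for variants with known confounder associations;
3. greedy LD clumping: p-ranked, removing neighbours with r² ≥ 0.001 within
   10,000 kb.  Ties in p are broken lexicographically by variant id, making
   the result independent of input row order;
4. instrument strength F = β²/se², keeping F > 10;
5. harmonization against the outcome (below), with no LD-proxy lookup —
   variants missing from the outcome are dropped and reported;
6. Steiger directionality filtering: a variant explaining more outcome than
   exposure variance is removed.  Exposure r² uses 2·MAF·(1−MAF)·β² (exact
   for a standardized trait); the binary outcome uses the observed-scale
   shortcut r² = z²/(z²+N).  Liability-scale conversion is deliberately
   omitted — it shifts all outcome r² by a common factor an order of
   magnitude smaller than the exposure/outcome contrast this filter acts on.
   The per-SNP directionality p-value is the two-sample Fisher-z comparison
   of the implied correlations.

## Harmonization

Records are aligned to the exposure's effect allele.  When the outcome's
effect allele equals the exposure's other allele, the outcome beta is
negated and its frequency complemented.  Alleles reported on the opposite
strand are resolved through base complements.  Palindromic (A/T, C/G)
variants carry no strand information in their alleles, so orientation is
decided purely by which side of 0.5 the effect-allele frequencies fall on;
inside the ambiguity window [0.42, 0.58] (configurable) they are dropped.
Every decision is recorded per variant (kept / flipped /
dropped_palindromic / dropped_missing / dropped_mismatch) — exclusions stay
auditable rather than silent.

## Estimators

- **Wald ratio** (single instrument): β̂_y/β̂_x, first-order delta se
  se_y/|β̂_x|; a second-order variant adding the exposure-noise term is
  available behind a flag.
- **IVW**, the primary method: slope of the zero-intercept weighted
  regression of β̂_y on β̂_x with weights 1/se_y².  Multiplicative
  random effects: the fixed-effect se is inflated by √(Q/(k−1)) when
  Cochran's Q exceeds its df, floored at 1 so homogeneous data keep the
  fixed-effect precision.
- **MR-Egger**: same regression with a free intercept, exposure effects
  oriented positive first.  A nonzero intercept estimates directional
  pleiotropy; slope and intercept ses carry the same floored inflation.
- **Weighted median**: median of the Wald ratios under inverse-variance
  weights, linear interpolation at cumulative weight 0.5; se by parametric
  bootstrap (1000 draws, default seed 42), consistent when ≥50% of weight
  is valid.

p-values use the normal reference distribution (a t option exists; packages
differ and the choice is immaterial at the instrument counts simulated
here).  ORs and 95% CIs are exp-transformed normal intervals.  Families of
tests reported together are FDR-adjusted by Benjamini–Hochberg; the family
is an explicit input (the run's primary p-values by default) rather than a
guess.

## Sensitivity diagnostics

- **Cochran's Q** on the Wald ratios with weights β̂_x²/se_y²; p from
  χ²(k−1).
- **MR-PRESSO**: the observed residual sum of squares uses leave-one-out
  predictions, each SNP judged against the slope fitted without it.  The
  null distribution is parametric: both effect vectors are redrawn from
  their sampling distributions around the leave-one-out fit (default 5000
  draws, seeded).  Empirical p-values use the (1+hits)/(1+draws) form so
  they are never zero.  Per-SNP outlier tests are Bonferroni-compared to
  α = 0.05; the corrected estimate is IVW on the non-flagged set, and a
  distortion z-test compares corrected and full estimates.
- **Leave-one-out** IVW re-estimates and per-SNP forest/funnel data tables
  (plotting is out of scope; all figures are emitted as data).
- **Power** for a binary outcome via the non-centrality approximation
  NCP = N·R²·cf(1−cf)·(ln OR)² with cf the case fraction and R² the summed
  instrument variance explained; power = P(|Z| > z_{1−α/2}) with
  Z ~ N(√NCP, 1).  This is the standard online-calculator approximation,
  not an exact logistic-likelihood computation, and is validated by its
  boundary and monotonicity properties (R² = 0 or OR = 1 give exactly α;
  power increases in N, |ln OR| and R²).

## MVMR and mediation

Multivariable MR regresses β̂_y jointly on several exposures' β̂ vectors
(no intercept, weights 1/se_y², the same floored variance inflation).  The
instrument set is the union of each exposure's instruments, harmonized
jointly.  Identically-zero exposure columns are dropped with coefficient 0
— this keeps the nested-model identity (a null mediator reproduces the
univariable IVW coefficient exactly); collinearity among non-null columns
raises an error naming the exposures.

Mediation uses the product method: indirect = β(X→M)·β(M→Y | X), with the
second factor taken from the MVMR fit; direct = total − indirect, so the
decomposition identity holds exactly by construction; proportion mediated
= 100·indirect/total.  The indirect se is the product delta method
√(β₁²σ₂² + β₂²σ₁²) (Sobel-type p-value); the direct-effect se combines
total and indirect ses ignoring their covariance, a conservative
approximation.  Proportions outside [0, 100]% or with opposing signs are
reported with an `inconsistent` flag, never silently reconciled: the
difference-based MVMR direct effect and the product-based mediation direct
effect are different estimands and both are reported.

## Meta-analysis

Inverse-variance pooling on the log-OR scale; random effects add the
DerSimonian–Laird moment estimate of τ², truncated at 0.  Both models are
always reported.  Study inputs given as OR with 95% CI are converted with
se = (ln hi − ln lo)/(2·1.96).

## Lightweight LD-score regression

Univariate: E[z²_j] = 1 + N·h²·l_j/M regressed with an intercept; the
slope on (N/M)·l_j is h², the intercept (≈1 without confounding) absorbs
stratification.  Bivariate: E[z₁ⱼz₂ⱼ] = √(N₁N₂)·gencov·l_j/M, and
r_g = gencov/√(h²₁h²₂).  Simplifications relative to the reference
implementation, chosen for transparency at simulation scale: a single
heteroskedasticity-weighting pass with weights 1/(2(1+N·h²₀·l/M)²) built
from an unweighted pre-fit h²₀ (not iterated), and caller-supplied LD
scores (no reference panel).  Cross-trait weights use the same pre-fit
values, which makes a trait regressed on itself return r_g = 1 exactly.
The cross intercept is free by default; `overlap_intercept=True` constrains
it to 0, the value implied by non-overlapping cohorts.  Standard errors
and p-values come from a delete-a-block jackknife over 200 contiguous
blocks; simulation shows the jackknife se matches the empirical sd of r_g
closely in the low-h² regime.

## Synthetic data generator

The generator emulates the summary-statistic layout of a
biobank-scale study — no individual-level genotypes are ever simulated,
because the analysis itself never touches them:

- MAFs uniform on (0.05, 0.5]; per-SNP causal effects spike-and-slab (a
  `prop_causal` fraction nonzero, normal slab) rescaled so
  Σ 2p(1−p)β² equals the target h² exactly;
- block LD, r = ρ^|i−j| within blocks: marginal effects are the LD
  convolution of causal effects, and sampling noise is correlated within
  blocks (exact when per-SNP ses are equal within a block, first-order
  otherwise);
- standard errors 1/√(2p(1−p)N), with the case-control effective-N
  correction cf(1−cf) for the binary outcome;
- outcome effects θ·β_x + α + noise, with pleiotropy α on the causal set:
  `balanced` draws are centred to exactly zero mean (so the Egger intercept
  truth is 0), `directional` draws have mean equal to `pleiotropy_sd`;
- mediator chains β_m = b_xm·β_x + own polygenic background (default
  h² = 0.10, giving the mediator instruments of its own for MVMR), and
  outcome θ_direct·β_x + Σ b_my·β_m + α;
- a fraction of outcome/mediator records is re-coded as another consortium
  might report them (5% allele-swapped, 1% strand-flipped, 1% palindromic
  pairs) to exercise harmonization;
- LDSC trait pairs: per-SNP genetic components bivariate normal with
  correlation r_g, scaled by √(N·h²·l_j/M) so the first two moments match
  the LD-score regression model exactly; environmental noise optionally
  shared to model full sample overlap.

Defaults mirror the discovery design the package is validated against: an
exposure cohort of 460,443, an outcome of 80,154 cases / 853,816 controls,
θ = ln 0.614 ≈ −0.488 per SD, exposure h² = 0.04 (mid-range of the 2.5–5.8%
liability-scale band typical for such traits), 150 causal SNPs out of
5000.  One integer seed drives every stream through spawned
`SeedSequence` children; identical seeds give byte-identical tables.

What the generator does **not** emulate: realistic human LD maps (blocks
are homogeneous AR(1)), allele-frequency/effect-size coupling, sample
overlap beyond an on/off shared-noise switch, liability-scale case-control
ascertainment, and population stratification.  Passing recovery tests
therefore demonstrate estimator correctness under the stated model, not
robustness to those real-data complications.

## Validation design and problem sizes

Every estimator is checked two ways: against an independently coded oracle
(statsmodels WLS for IVW/Egger/MVMR, a dense weighted-CDF scan for the
weighted median, statsmodels' step-up for the FDR, statsmodels
`combine_effects` for DerSimonian–Laird) at 10⁻¹⁰, and by parameter
recovery on generated data with known truth.  Operating characteristics
use 1000-seed batches of 50-instrument panels (IVW type-I error, Q/df,
Egger intercept coverage under balanced pleiotropy), 200 seeds of the
150-instrument discovery-scale design for θ recovery, 24 full mediation
pipelines for the proportion-mediated, 100/1000 seeds for MR-PRESSO
detection/null calibration at 1000 simulation draws, and M = 50,000 SNPs
for LD-score r_g recovery.  These sizes put the full acceptance run at
well under a minute on one CPU while keeping Monte-Carlo error small
relative to every acceptance band.

## Known limitations

- Steiger filtering and variance-explained arithmetic are observed-scale;
  no liability-scale correction.
- The MR-PRESSO distortion test is a point-estimate z-comparison, not the
  original's bootstrap.
- The weighted-median bootstrap ignores uncertainty in the weights.
- LD-score weights are single-pass, not iterated; h² estimates inherit a
  small finite-sample wobble that the jackknife se reflects.
- The mediation direct-effect CI ignores the total/indirect covariance
  (conservative).
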
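# Methods

## Model and assumptions

Two-sample MR treats each genetic variant *j* as an instrument for the
exposure under the three instrumental-variable conditions: relevance
(association with the exposure), independence (no association with
confounders of the exposure–outcome relationship), and exclusion
restriction (effect on the outcome only through the exposure).  The
generating model used throughout the package's validation is

    β̂_Xj = γ_j + ε_Xj,            ε_Xj ~ N(0, σ²_Xj)
    β̂_Yj = θ·γ_j + α_j + ε_Yj,    ε_Yj ~ N(0, σ²_Yj)

where γ_j is the variant's true exposure effect, θ the causal effect of
interest, and α_j a direct (horizontally pleiotropic) effect that is zero
for valid instruments.  The exclusion restriction is exactly the statement
α_j = 0; the InSIDE condition required by MR-Egger is corr(γ, α) = 0 among
invalid instruments.  The two samples are assumed non-overlapping, so ε_X
and ε_Y are independent.

## Estimators

All estimators consume a `HarmonizedSet` (per-SNP β̂_X, σ_X, β̂_Y, σ_Y on a
common effect allele) and report the log-odds causal estimate with
OR = exp(β), normal-theory CIs and two-sided normal p-values.

- **Wald ratio / IVW.**  Ratio θ̂_j = β̂_Yj/β̂_Xj, first-order SE
  σ_Yj/|β̂_Xj| (the delta method dropping the exposure-noise term — the
  same "NOME" convention that defines the IVW weights w_j = β̂²_Xj/σ²_Yj).
  IVW is the w-weighted mean of the ratios, identically WLS of β̂_Y on β̂_X
  through the origin with weights 1/σ²_Y.  The random-effects variant uses
  multiplicative overdispersion, inflating the fixed SE by
  max(1, √(Q/(J−1))); under `model="auto"` the random branch is taken
  exactly when Cochran's Q has p < 0.05, and the branch taken is recorded.
  A single instrument is accepted (with a warning) and returns the Wald
  ratio, so a screening loop never hard-fails on a 1-SNP trait.
- **MR-Egger.**  Each SNP is first oriented so β̂_Xj ≥ 0 (flipping both
  effects, which preserves the ratio); then β̂_Y is regressed on β̂_X with
  an intercept, weights 1/σ²_Y, via the closed-form 2×2 normal equations.
  SEs use multiplicative overdispersion floored at 1 with J−2 df.  The
  intercept estimates mean directional pleiotropy; intercept p < 0.05 is
  the pleiotropy flag.  P-values are normal by default for consistency with
  the OR/CI construction (a t with J−2 df differs negligibly at the J
  used here and is trivially recoverable from the reported SE).
- **Weighted median.**  Ratios are ordered; with normalized weights the
  cumulative midpoint percentile of the *k*-th ratio is S_k − w_k/2, and
  the estimate linearly interpolates the ratio at percentile 0.5.  The SE
  is the standard deviation over `n_boot` (default 1000, seed 42)
  parametric-bootstrap resamples β*_X ~ N(β̂_X, σ_X), β*_Y ~ N(β̂_Y, σ_Y),
  with weights recomputed per resample.
- **Maximum likelihood.**  The joint log-likelihood over (θ, ξ_1..ξ_J) is
  maximized by profiling the nuisance means in closed form —
  ξ*_j(θ) = (β̂_Xj/σ²_Xj + θβ̂_Yj/σ²_Yj)/(1/σ²_Xj + θ²/σ²_Yj) — which
  reduces the problem to the exact one-dimensional profile
  l_p(θ) = −½ Σ (β̂_Yj − θβ̂_Xj)²/(σ²_Yj + θ²σ²_Xj).  This is maximized by
  quasi-Newton from the IVW start with a Newton polish to relative
  tolerance 1e-10; profiling is exact, so the optimum coincides with the
  full-vector maximizer while avoiding a (J+1)-dimensional Hessian.  The SE
  is the inverse-root curvature of l_p at θ̂ by central differences with
  step 1e-5·(1+|θ̂|), equal to the θθ block of the inverse observed
  information under exact profiling.
- **MR-PRESSO.**  The observed statistic is the leave-one-out weighted RSS
  Σ_j (β̂_Yj − θ̂_(−j)β̂_Xj)²/σ²_Yj, where θ̂_(−j) is the IVW estimate
  without SNP j; written in ratio space this is the IVW-weighted squared
  deviation Σ w_j(θ̂_j − θ̂_(−j))².  Its null distribution comes from
  parametric simulation (β*_X ~ N(β̂_X, σ_X), β*_Y ~ N(θ̂_(−j)β̂_X, σ_Y),
  default 1000 draws, seed 42), with the same leave-one-out statistic
  computed on each draw (vectorized across draws).  Per-SNP outlier
  p-values are add-one Monte-Carlo tails of each observed residual,
  Bonferroni-multiplied by J and flagged below 0.05; the corrected IVW uses
  exactly the unflagged SNPs.  The distortion test compares the
  raw-vs-corrected shift with shifts from 1000 random same-size removals.
  All Monte-Carlo p-values use (b+1)/(m+1), so the global p is bounded
  below by 1/(m+1) and never zero.

## Instrument selection and harmonization

Selection applies a strict p < 1×10⁻⁵ screen, then greedy LD clumping:
visit variants by ascending p (ties broken by chromosome, position,
variant id for determinism) and discard any not-yet-kept variant on the
same chromosome within 10,000 kb (|Δpos| ≤ 10⁷ bp) whose r² with the kept
variant exceeds 0.001.  LD is an input table with symmetric lookup, r² = 0
for absent pairs and 1 on the diagonal; positions are treated as
build-agnostic integers.  Instrument strength is reported per SNP with
k = 1 and per trait with k = the instrument count and R² summed; F > 10 is
a report-only flag by default (`weak_instrument_action="filter"` makes it a
hard exclusion).

Harmonization matches by variant id, never alters the exposure
orientation, negates the outcome effect when alleles are swapped, and
drops all palindromic (A/T, C/G) pairs unconditionally — no
frequency-based strand inference — trading data retention for safety.
Non-palindromic mismatches are retried after complementing the outcome
alleles (a cross-cohort strand flip) and rescued with a distinct log
entry; anything else is dropped as unmatched or irreconcilable.  The
per-SNP action log always covers every input SNP, so the report's counts
sum to the input size.

## Synthetic-data generator

The generator emulates the motivating study's cohorts.  Standard errors
are calibrated as σ = 1/√(2·eaf·(1−eaf)·n) with n = 18,340 for the
quantitative exposure and the effective size n_eff = 4/(1/cases +
1/controls) ≈ 4,292 for the binary outcome (1,076 cases / 381,977
controls); eaf ~ U(0.05, 0.95).  True instrument effects default to
γ ~ N(0.12, 0.03²), giving mean per-SNP F near 100 — within the 20–150
range typical of microbiome instruments selected at p < 1×10⁻⁵.  Pleiotropy
is planted on a configurable fraction of SNPs with N(alpha_mean,
alpha_sd²) direct effects, optionally correlated with γ through a Gaussian
copula (`inside_correlation` ≠ 0 violates InSIDE).  Palindromic allele
pairs are planted at a configurable fraction; LD comes in equal-r² blocks
laid out so blocks sit inside the clumping window and distinct blocks
outside it.  Ground truth (θ, γ, α, planted indices) is always returned,
and tests check recovery against it rather than re-deriving it.

What the generator does **not** model: winner's curse from selecting on
the exposure p-value (instruments are drawn already "significant"),
sample overlap between cohorts, LD beyond the block structure, real
microbiome abundance distributions, and population stratification.
Passing tests therefore demonstrate the estimators' statistical behavior
under the stated model, not robustness to those real-data complications.

## Pipeline

One exposure runs p-filter → clump → strength → harmonize → estimators →
Cochran's Q → Egger intercept → MR-PRESSO, with per-stage SNP counts
recorded; estimator preconditions that fail (e.g. J < 3 for Egger) degrade
to a logged empty cell rather than aborting the trait.  The screen removes
unnamed taxa (labels containing "unknown", "unclassified" or "incertae",
case-insensitive — the pattern behind the 211 → 196 catalog arithmetic),
then analyzes each named trait; missing files or empty instrument sets
produce skip rows with reasons.  The significant subtable is exactly the
full table filtered at IVW p < 0.05.  Multiple-testing correction
(Bonferroni or Benjamini-Hochberg over the IVW screen p-values) is
available but off by default: the screen is interpreted as hypothesis
generation, with the sensitivity estimators providing the robustness
check.  Given the config and seed, every output byte is reproducible.

## Validation study sizes and numerical choices

The test suite and `scripts/acceptance.py` use: 2000 replicates for null
calibration (θ = 0, J = 20), 1000 for recovery/coverage (θ = 0.5, J = 50),
500 for the pleiotropy robustness ordering (30% invalid, α ~ N(0.04,
0.01²), θ = 0.3) and Egger-intercept recovery (100% invalid, α ~ N(0.02,
0.005²)), and 200 replicates × 1000 Monte-Carlo draws for MR-PRESSO
detection — sizes chosen so Monte-Carlo error is small relative to the
tolerance bands being checked.  Egger-intercept recovery is evaluated at
θ = 0: with θ ≠ 0 the exposure-side measurement error attenuates the Egger
slope (the I²_GX phenomenon) and the compensation inflates the intercept
by roughly θ(1−λ)·mean(γ); this is a known limitation of MR-Egger under
weak-ish instruments, not of the implementation, and is why intercept
estimates on strongly causal traits should be read with care.

Degenerate inputs are handled explicitly: zero exposure effects raise
rather than produce infinite ratios; an input p-value of exactly 0 is
floored to the smallest positive float; all-flagged MR-PRESSO corrections
raise; and a zero bootstrap SE (identical resamples) is floored to a tiny
positive value so CI construction stays defined.

## Known limitations

- The Wald/IVW first-order SE ignores exposure-side uncertainty; coverage
  erodes when instruments are weak (mean F near 10).  The maximum-
  likelihood estimator is the in-package alternative under measurement
  error.
- MR-PRESSO's global test is conservative (simulation re-draws the
  exposure effects around their observed values), and one outlier of
  moderate size shifts the pooled estimate by only ~2 pooled-SEs at
  J = 20, so outlier removal improves the point estimate in most but not
  all replicates.
- Reverse-direction MR, proxy-SNP lookup, Steiger filtering and
  multivariable MR are out of scope.
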
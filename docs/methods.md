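# Methods notes

This note records the statistical model, the defaults and the numerical
choices behind `mrphewas`, and what the synthetic cohorts do and do not
establish.

## Model and procedure

The screen treats a weighted allele score as a single instrument for a
modifiable exposure measured on the log scale. Stage 1 estimates, for every
outcome k, the association `γ_k` of the inverse-normal-transformed outcome
with the standardized score by complete-case univariate OLS with an HC1
sandwich; inference uses t(n−2). Stage 1 deliberately never touches the
exposure variable itself, so it depends only on the core IV assumptions
(instrument–exposure association, no confounder association, exclusion
restriction) and not on the point-identifying assumptions stage 2 needs.

Stage 2 re-analyses the hits (unadjusted p < α, validation outcomes
included) on their original measurement scale: 2SLS for continuous
outcomes, an OLS first stage followed by a robust logistic regression on
the first-stage fitted values for binary ones. The logistic procedure's
standard errors do not propagate first-stage uncertainty; this is a
property of the procedure being mirrored and is recorded on every logistic
result rather than silently corrected.

## Transformations

* **Inverse normal transform.** Quantile convention `r/(n+1)` (offset 0) by
  default; the Blom offset 0.375 is available via `int_offset`. The offset-0
  form makes the n=3 case exactly the quartiles, which anchors the unit
  tests. Ties take a uniformly random order drawn from a per-column child
  seed of the master seed, so tied measurements add noise (a documented
  property of the approach) but runs are reproducible.
* **Stage-2 preparation.** Explicit per-outcome hints always win. The
  `auto` route uses sample skewness > 1 with all-positive values for the
  log branch, |skewness| ≤ 1 with ≥ 10 distinct values for plain
  standardization, and otherwise a median split (values strictly above the
  median are coded 1, so median ties fall in the lower group; an input that
  is already two-valued maps directly to 0/1). The original analysis chose
  transforms visually, which is not reproducible; the skewness screen is
  this package's deterministic stand-in.

## Multiplicity

Bonferroni multiplies by the number m of non-validation outcomes actually
tested (validation positives are excluded from m and receive no adjusted p,
but are still ranked). The FDR is the plug-in ratio `mα/k`, capped at 1 and
undefined (logged) at k = 0 — deliberately not Benjamini–Hochberg. The
permutation engine permutes individual rows of the already-transformed
outcome matrix jointly, preserving both the inter-outcome correlation and
each row's missingness pattern; per-outcome independent shuffling exists
behind `mode="per_outcome"` for sensitivity. Because the transform is
rank-based, permuting transformed values equals transforming permuted
values up to tie re-randomization; freezing the tie-breaks makes the replay
exact and cheap. Permutation p-values are raw proportions (0 is possible);
the add-one estimate `(count+1)/(B+1)` is available via `add_one=True`.
The QQ reference line is drawn at α/m.

## Instrumental-variable numerics

* 2SLS solves the IV normal equations with an intercept; the robust
  covariance is the sandwich on the structural residuals `y − Xβ̂`
  (HC0, matching common IV software defaults), never the second-stage
  fitted-regressor residuals. IV inference is normal-based; plain OLS
  screens use t. With one instrument the estimate equals the Wald ratio
  `cov(S,Y)/cov(S,X)` to machine precision, which the tests assert.
* The first-stage F is the squared t of the score slope from a classical
  OLS fit, and is invariant to affine rescaling of the exposure.
* The Durbin–Wu–Hausman test is the robust control-function form (first-
  stage residual appended to the observational model, HC1 t-test on its
  coefficient); it coincides with the classic covariance-difference form
  asymptotically under homoskedasticity but stays well-defined under
  heteroskedasticity. It is undefined (NaN, flagged) when the exposure is
  an exact function of the score.
* CUE-GMM centres outcome, exposure and instruments (equivalent to an
  intercept moment) and minimises `J(β) = n ḡ(β)' W(β)⁻¹ ḡ(β)` with the
  centred robust weight `W(β) = (1/n)Σ g_i g_i' − ḡḡ'`; all β-dependence
  reduces to fixed L×L cross-products, so evaluation is O(L³). The 1-D
  minimisation brackets the 2SLS estimate ±10 robust SEs (bounded Brent,
  |Δβ| < 1e-10), expanding the bracket fourfold up to three times if the
  minimum is at an edge. A singular weight matrix receives a logged ridge
  of `1e-10·tr(W)/L`; duplicate instruments therefore still run, with a
  degeneracy flag and df = L−1 unchanged. Hansen p is the upper χ²(L−1)
  tail; binary outcomes enter the GMM with linear 0/1 moments.

## Synthetic cohorts

The generator draws independent Hardy–Weinberg dosages (no LD, no
population structure — those are excluded upstream by design), a standard
normal latent confounder U, and a log-scale exposure
`X_raw = Σ w_j g_j + δU + (reverse feedback) + ε`. Outcome classes encode
the competing causal diagrams: null, causal (`βX + λU + ε`), confounded
(`λU + ε`), reverse (outcome generated first and fed back into the
exposure with weight θ), and pleiotropic (direct per-allele SNP effects
bypassing the exposure). Binary outcomes threshold the latent variable at
its median; missingness is MCAR per outcome (MNAR is out of scope).

Defaults are chosen once to match the motivating study's scale: 32
instrument SNPs, MAF uniform on (0.10, 0.45), per-allele weights
`0.05·U(0.5, 1.5)` so the score explains ≈ 2.5 % of exposure variance
(first-stage F in the low-to-mid hundreds at n ≈ 8,000, matching the
reported F ≈ 141 at n ≈ 5,000), δ = 0.5, unit exposure noise. The
default-shaped cohort has 8,121 individuals and 172 outcomes (12 validation
positives with larger causal effects; of the remaining 160: 5 % causal, 5 %
confounded-only, 2.5 % reverse, 2.5 % pleiotropic, the rest null) with
missingness uniform on 0–65 %. Because the generator is MCAR, linear and
Gaussian, green tests establish calibration and parameter recovery under
the model's own assumptions — not robustness to MNAR missingness,
non-linearity, LD between instruments or population stratification.

A known limitation surfaced by the test suite: at the prescribed
pleiotropy stress scenario (2 of 8 instruments with direct effects of
+0.05 per allele at n = 5,000) the Hansen test's rejection rate is ≈ 0.34,
and an independently coded two-step GMM J gives ≈ 0.38; the asymptotic
noncentrality of that design (≈ 7) caps power near 0.45, because same-sign
direct effects are partially absorbed into the CUE point estimate.
Opposite-sign effects of the same magnitude are detected with materially
higher power. The corresponding stress test is kept at its stated design
and currently fails, by intention.

## Reproducibility

All randomness flows from one master seed: child seeds are derived per task
(transform tie-breaks per column, permutation stream, simulation) via
`SeedSequence`, so results are independent of execution order and of the
number of permutation workers. Two runs from the same seed produce
byte-identical result tables; the manifest records the config snapshot,
input checksums, package versions and row counts needed to reproduce a run.

One numerical footnote: the reference analysis's QQ figure quotes a
Bonferroni line at corrected p = 0.00023, which does not equal 0.05/160;
this package draws the line at α/m.
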
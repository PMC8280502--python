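# Methods

## Model class

The package implements two related confirmatory factor models for wide
dyadic panel data (one row per dyad, columns for indicators × occasions ×
raters, interval-scale responses, missing cells allowed).

**Single-rater LST-AR.** Each indicator `Y_il` is an intercept plus an
indicator-specific trait factor `T_i`, an occasion factor `O_l`, and
measurement error. The occasion chain follows a first-order autoregression
`O_l = β_l O_{l−1} + SR_l` with `O_1 = SR_1`; the state residuals `SR_l`
are unidimensional across indicators within an occasion. All latent factors
have mean zero, so observed means live entirely in the intercepts. The
latent covariance is assembled in reduced form — the AR chain's covariance
has the closed form `Var(O_l) = β_l² Var(O_{l−1}) + Var(SR_l)`,
`Cov(O_l, O_m) = (∏_{j=m+1}^{l} β_j) Var(O_m)` — so no general SEM graph
solver is needed, and the implied covariance is exactly
`Λ Φ Λ' + diag(θ)`.

**Two-rater MR-LST-AR.** The reference rater (by default the first) keeps
the single-rater structure. The second rater's indicators load on the
reference rater's `T_i` and `O_l` *and* on rater-specific residual factors:
indicator-specific `TPS_i` (uncorrelated with the same-indicator `T_i` by
construction) and an occasion chain `OPS_l` driven by rater-specific state
residuals `SRPS_l` with its own autoregression. This is the correlated
trait, correlated method minus one convention: everything the second rater
does not share with the reference rater is residual, so squared-loadings
ratios of shared to total true variance are interpretable as consistency
shares, and their square roots as error-free cross-rater correlations.

## Identification and invariance

Scales are set by fixing, per factor family, one loading to 1: the
reference rater's trait loadings at the first occasion, the first
indicator's loadings on each `O_l`, the `TPS` loadings at the first
occasion, and the first indicator's loadings on each `OPS_l`. Measurement
invariance over time is the default: loadings on the occasion factors are
tied over occasions (for both raters), the state-residual variances are
tied over *all* occasions including the first, and the autoregressive
weights are tied over transitions; the same three constraints apply to the
rater-specific chain. Each constraint is an independent flag. Under the
defaults the 3-indicator, 4-occasion designs have 43 free parameters
(90 moments, df 47) and 107 free parameters (324 moments, df 217).

Two layout choices were genuinely open and are worth recording:

* The six cross-indicator covariances `Cov(TPS_i, T_j)`, i ≠ j, are free by
  default (flag-controlled). Only the same-indicator covariance is forced
  to zero by the residual definition, and freeing the cross-indicator ones
  is what reconciles the 107-parameter count of the default two-rater
  design. The controlling flag is an inclusion flag: switching it off
  *removes* six parameters, unlike the equality flags, for which "off"
  always frees parameters.
* The occasion-1 loadings `λ_SR_i1` are stored as the occasion-factor
  loadings at l = 1 and tied to the later `λ_O_il` under invariance, since
  `O_1 = SR_1` makes occasion 1 structurally identical to later occasions.

The second rater's trait loadings on the reference traits are free at every
occasion, including the first (the trait scale is already set on the
reference side).

## Estimation

**FIML.** The log-likelihood sums, over missingness patterns, the
multivariate-normal likelihood of each pattern's observed subvector under
the corresponding sub-moments. Patterns are evaluated from sufficient
statistics (count, mean, ML scatter), which is algebraically identical to
row-wise evaluation and is unit-tested against a per-row oracle.
Non-positive-definite sub-blocks return a large finite penalty scaled by
the eigenvalue shortfall and are counted in the diagnostics, so the
optimizer can back out and boundary pathologies remain visible.

**Parameterization.** Variances (state-residual, error, trait-block
diagonal) travel through the optimizer on a log scale; trait-block
covariances are unconstrained raw values, so the block is always symmetric
but positive-definiteness is *diagnosed*, not enforced — Heywood-type
solutions show up instead of being silently truncated. Log-scale arguments
are clipped at ±60 inside the objective so line-search trial steps can
never overflow.

**Optimizer.** Quasi-Newton (L-BFGS-B) on the flat unconstrained vector
with an analytic gradient obtained by the chain rule through
`Σ = Λ Φ Λ' + diag(θ)` and forward-mode differentiation of the AR variance
recursion; the gradient is verified against central differences in the
tests. Convergence: gradient max-norm 1e−5 and relative log-likelihood
change 1e−9, iteration cap 2000, with three jittered restarts (fixed
sub-seed) if the first start fails. An optional preconditioner (inverse
Cholesky factor of the observed information at a reference fit) makes the
curvature approximately isotropic; the bootstrap uses it, computed once per
dataset, for its warm-started refits. Starting values are deterministic:
column means for intercepts, half the column variances for error variances,
occasion-averaged cross-occasion covariances for the trait block, 1 for
free loadings except the second rater's trait loadings at 0.5 (starting
both `λ_T` and `λ_TPS` at 1 badly mis-scales the second rater's side and
costs many iterations), and 0.3 for autoregressive weights.

**Fit indices.** The saturated model is fitted by the standard EM algorithm
for the multivariate normal under missingness (closed form when data are
complete); the baseline model is the independence model, whose FIML
solution factorizes into per-column univariate fits. Then
`χ² = 2(llsat − llmod)`, `CFI = 1 − max(χ²−df, 0)/max(χ²_b−df_b, χ²−df)`,
`RMSEA = √(max(χ²−df, 0)/(df (n−1)))` with n the rows retained after
dropping all-missing rows; df = 0 reports RMSEA as missing. Plain ML is
used throughout — no robust (sandwich/scaled) corrections — so χ²-based
indices are those of the ordinary likelihood-ratio statistic.

**Standard errors** are the square roots of the diagonal of the inverse
numerically differentiated observed information at the maximizer, mapped to
the natural scale by the delta method (factor `exp(x)` for log-scale
slots).

**Bootstrap.** Nonparametric resampling of whole dyad rows (preserving
within-dyad and within-row dependence), refitting each replicate warm from
the full-data maximizer, percentile intervals for every free parameter and
every defined coefficient cell. Non-converged replicates are dropped and
counted; more than 20% failures attaches a warning to the result.

## Coefficients

All coefficients are ratios of structural variance components and are
computed from the parameters, not from data. Exact identities hold by
construction and are enforced in tests: `OS + TCon = 1`,
`Pred + UPred = TCon` (l > 1), `RS + RCon = 1`, `RConPred + RSPred = 1`.
At the first occasion the time-consistent share is defined as the trait
share (`TCon = Pred = 1 − OS`), matching how such tables are conventionally
printed; `UPred` and the retest correlation are undefined there and are
reported as missing values, never zero-filled. The retest correlation is
computed generically from the latent covariance of the state composites and
cross-checked against the product-of-betas closed forms to 1e−10.

The rater-consistent time consistency is defined as the shared
time-consistent variance over total time-consistent variance,

```
RConTCon = (λT² Var(T) + λO² β² Var(O_{l−1}))
         / (λT² Var(T) + λTPS² Var(TPS) + λO² β² Var(O_{l−1}) + λOPS² β_OPS² Var(OPS_{l−1}))
```

which reduces exactly to `RConPred` when both autoregressive weights are
zero — a limit identity the tests rely on.

## Synthetic data

The generator draws the trait block jointly multivariate normal (via an
eigendecomposition square root, so exact zeros stay exact; a
non-positive-semidefinite block raises an error naming the offending
eigenvalue), runs the AR recursions for the occasion chains, and adds
normal errors. Missingness is applied at the rater-occasion cell level —
a participant skips a whole wave, all of that rater's indicators at that
occasion go missing together — which is how panel attrition manifests.
The default participation profile mirrors a four-wave dyadic panel of
n = 575 dyads with per-wave counts 558/463/428/429 for the reference rater
and 405/384/341/323 for the second rater; because those counts are not
monotone, the default mechanism is wave-wise MCAR at these rates, with a
monotone-dropout alternative (enforcing non-increasing rates) available.
One master seed spawns separate sub-streams for latents, errors and the
mask, so toggling missingness never changes the drawn responses. Rater
waves are masked independently of each other — joint dyad participation is
not modeled, a deliberate simplification of real panel behavior.

What the generator does *not* emulate: ordinal 5-point response scales
(responses are continuous normal, matching the estimator's assumptions),
heavy tails, non-normal latent distributions, and informative (MNAR)
dropout. Passing tests therefore demonstrate correctness of the estimator
under its own assumptions, not robustness to their violation.

The built-in two-rater fixture (`make_paperlike_params`) encodes a
study-like regime: reliabilities around 0.7–0.8, high trait predictability
with a small positive carry-over share for the reference rater, nearly
absent carry-over on the rater-specific side (β_OPS = 0.05), and rater
specificity around 0.8–0.9.

## Problem sizes and numerical choices in the validation suite

* Moment-structure oracle: 10⁶ simulated dyads, entrywise tolerance 3
  Monte-Carlo standard errors of a normal covariance entry.
* Parameter recovery: n = 5000 complete dyads (all 107 free parameters
  within 3 estimated SEs) and n = 575 with the attrition profile
  (convergence plus coefficient identities).
* Null calibration: 200 replications at n = 500, mean χ² within 10% of 47.
* Bootstrap coverage: a compact well-identified design (2 indicators, 4
  occasions, n = 300, Var(SR) = 0.12) with B = 500 resamples and 100 outer
  replications; nominal 95% coverage within ±5 points. The acceptance
  script uses B = 400 for its single interval check to keep the run short.
* All simulation tests are seeded; the package-wide default seed is 0.

## Known limitations

* Plain ML only; no robust corrections, so χ²/CFI/RMSEA will differ
  slightly from robust-estimator output on the same data.
* Two raters at most; equal indicator sets per rater; continuous responses.
* Subgroup analyses are independent runs — no simultaneous multi-group
  estimation with cross-group constraints.
* Percentile bootstrap intervals inherit the finite-sample behavior of the
  estimator; for weakly identified designs (few occasions, small
  state-residual variance relative to trait variance) the Var(SR) estimator
  is biased and skewed at moderate n and interval coverage degrades.
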
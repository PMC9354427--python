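# Methods

This note documents the models implemented in `twinpillars`, the
assumptions behind them, the synthetic-data generator used to validate
them, and the numerical and design choices that were genuinely open.

## Pillar coding

Five dichotomous lifestyle "pillars" are coded from raw survey items:

| pillar | met when | raw items |
|---|---|---|
| sleep | nightly sleep >= 8 h (7 h under the sensitivity standard) | hours |
| fruit/vegetables | see below | two ordinal serving categories (0, 1–2, 3–4, 5+) |
| sedentary time | <= 2 h/day of sitting screen time | ordinal category (0h, 1–2h, 3–4h, 5+h) |
| MVPA | >= 150 min/week, as 20 min × vigorous days + 30 min × moderate days | days/week 0–7, each |
| non-smoking | not a current smoker | boolean |

The fruit/vegetable rule is stated as a clause list that duplicates one
clause and is asymmetric between fruits and vegetables.  The default
implementation is the literal printed rule — met iff (fruit >= 3–4 and
veg >= 1–2) or (veg = 5+ and fruit >= 1–2) — with a `symmetric_fv` flag
that additionally grants (veg = 3–4 and fruit >= 1–2).  We deliberately
do not guess further at the intended rule.

Indicators are tri-state (met / not met / missing).  The pillar count
0–5 is missing whenever *any* indicator is missing: a sum over partial
data would be a lower bound, not a count.  This rule also reproduces the
fact that the count has a noticeably higher missingness rate (3.8 %)
than the individual items (~1 %).

BMI is 703 × lb / in² from self-reported height and weight and is
modeled on the natural-log scale; PHQ-2 is the sum of its two 0–3 items
(0–6) and is modeled on the square-root scale.  Both transforms address
right skew.

## Univariate ACE model

The classical twin design decomposes trait variance into additive
genetic (A), shared environmental (C), and non-shared environmental (E)
components, identified by contrasting MZ pairs (additive-genetic
correlation 1) with same-sex DZ pairs (0.5); C is correlated 1 in both.
Continuous traits use the bivariate-normal pair likelihood with common
mean and variance and zygosity-specific correlation `a² r̄ + c²`.
Incomplete pairs contribute the marginal density of the observed member
(FIML); nothing is listwise deleted.

Ordinal traits (e.g. the pillar count, categories 0–5) use a
liability-threshold model: categories are cuts of a standard-normal
latent liability at ordered thresholds, and a pair's contribution is a
bivariate-normal rectangle probability at the latent correlation.
Rectangle probabilities are computed by 64-point Gauss–Legendre
quadrature on the tetrachoric (angular) integral representation of the
bivariate normal CDF, which is smooth for all correlations, vectorizes,
and agrees with an independent CDF implementation to ~1e-12; the
|rho| = 1 limits are handled in closed form.

Numerics: variance components are optimized as unconstrained path
coefficients and squared, so shares are non-negative by construction and
boundary solutions (a share pinned at 0) appear as exact zeros.
Standard errors come from a central-difference Hessian of −2·logL with
delta-method propagation to the standardized shares; they are unreliable
at a boundary and the estimate is flagged accordingly.  With true
a² = 0, sampling noise in the MZ–DZ correlation contrast produces
half-normal-like spread of â² above zero (SD ≈ 0.04 at 3,000 pairs per
zygosity); this is a property of the design, not of the optimizer.

## Quasi-causal bivariate model

The co-twin control design asks whether the phenotypic association
between pillar count X and outcome Y survives control of between-family
confounding.  Structural equations (twin j, family i):

    X_ij = mu_x + a_x A_xij + c_x C_xi + e_x E_xij
    Y_ij = mu_y + b_p (X_ij − mu_x) + b_a A_xij + b_c C_xi
           + a_u A_uij + c_u C_ui + e_u E_uij + Z_ij' beta

`b_p` is the within-person path; `b_a`/`b_c` route the predictor's own
familial latents into the outcome and absorb between-family confounding.
The model sequence is: Model 1 (`b_a = b_c = 0`, per-sex `b_p`), Model 2
(`b_a = b_c = b_f` estimated — the two confound paths are nearly
unidentifiable separately, so their equality is imposed a priori), and
Model 3 (Model 2 with `b_p` equated across sexes, testable by a Wald
test on the Model 2 fits).  Model 1 retains the ACE structure on the
outcome residual: it is the same twin SEM with the confound paths fixed
at zero, not an independent-observations regression.

Design choices that were open:

* **Confound-path scale.** `b_a` and `b_c` are path coefficients
  multiplying standardized (unit-variance) latents, not variance
  fractions; this is the standard SEM semantics and keeps Model 1/2/3
  nested in one parameterization.
* **Covariates** (age, race as a White/non-White contrast, income and
  education as integer scores) enter the outcome mean only.
* **Model 3** equates only `b_p` across sexes; variance components
  remain sex-specific.
* **Predictor treatment.** `liability_ordinal` (default) models the
  count as threshold cuts of a standard-normal liability with six
  categories (0–5).  The joint distribution of the two liabilities and
  the two outcomes is Gaussian, so each pair's likelihood factorizes
  exactly into the marginal density of the observed outcomes times a
  conditional bivariate-normal rectangle probability for the ordinal
  pair — deterministic Gaussian conditioning plus the same tetrachoric
  quadrature as above, with no stochastic integration.
  `observed_count` treats the integer count as continuous; it is much
  faster, gives slopes per count unit, and agrees with the liability
  mode in sign and confidence-interval overlap on well-populated data.
  The heavier simulation studies in the test suite use the
  observed-count mode for runtime.

Estimation is FIML over partially observed (X1, Y1, X2, Y2) vectors,
grouped by missingness pattern (sufficient-statistic fast path when no
covariates are present).  Standard errors come from the numerical
Hessian; the cross-sex Wald test uses the block-diagonal covariance of
the two independent per-sex fits,
W = (Rθ)' (R V R')⁻¹ (Rθ) ~ χ²(rank R).

For a log-scale outcome, a slope `b_p` converts to a percent change of
100·(1 − exp(b_p)) per additional pillar met.

## Regression trees

Trees over the five binary pillars use ANOVA-style splitting: the
improvement of a split is the reduction in within-node sum of squared
errors, computed over cases non-missing on the candidate.  (The source
analysis names the Gini index, which is a classification criterion; the
regression method of the tree package it cites uses ANOVA improvement,
and that is what is implemented.)  Defaults follow that package's
conventions: `minsplit = 20`, `minbucket = minsplit // 3`, complexity
threshold `cp = 0.01` of the root SSE.  Ties on improvement break by the
canonical pillar order, so results are invariant to row order.

Cases missing the primary splitter are routed by surrogate splits:
other variables ordered by their agreement with the primary routing
(better of the two orientations, among cases observed on both), keeping
only surrogates that beat the go-with-the-majority baseline.  Variable
importance sums each split's improvement for its primary variable plus
improvement × adjusted agreement ((agreement − majority)/(1 − majority))
for each surrogate, rescaled to total 100.  Importance is computed on
the pruned tree.

Pruning is cost-complexity with seeded 10-fold cross-validation over the
weakest-link alpha sequence (candidates at geometric means of successive
alphas).  Both the minimum-CV-error and one-SE selection rules are
available; the default is minimum error.  On pure-noise outcomes the
one-SE rule collapses to the root leaf in ≥ 95 % of replicates, while
the minimum rule retains a spurious split in roughly 15 % — the
expected behavior of the two rules.

## Within-pair descriptives

Between-individual differences for a count gap `d` average the contrasts
mean(Y | k+d) − mean(Y | k) over eligible `k`, unweighted by default
(an n-weighted option exists); the SE propagates the independent group
means through the contrast coefficients, accounting for categories
shared between contrasts.  Within-pair differences are
"more-pillars twin minus co-twin" among complete discordant pairs,
stratified by absolute count difference and zygosity; empty strata are
absent rather than zero-filled.  These descriptives use the raw outcome
scales (kg/m², PHQ-2 units) to match the figure semantics, while the
models use the transformed scales.

## Synthetic registry generator

The generator emulates the study conditions so that every stage can be
validated without the restricted registry data: 3,024 MZ + 3,024 DZ
same-sex pairs (66 % female), pillar endorsement prevalences
(38.7, 50.3, 48.3, 41.2, 89.8) %, MCAR missingness at the reported rates
(1.2 % BMI, 1.1 % PHQ-2, 3.8 % pillar count), and ACE-structured
latents with the standard cross-twin correlations.

Each pillar has its own ACE-structured liability (default shares
0.4/0.2/0.4; a shared-factor option with configurable loading exists for
stress tests), thresholded at the inverse-normal of its prevalence.  The
outcome equation adds `b_p` per population-SD of the pillar count plus
confound paths `b_a`/`b_c` on the standardized additive-genetic and
shared-environment composites of the pillar liabilities — so the
confounds are genuinely correlated with the count, and a generator with
`b_p = 0, b_f < 0` reproduces the phenotypic-vs-quasi-causal attenuation
pattern by construction.  Latent ACE shares for these traits are not
published; the defaults are placeholders chosen to be realistic for
adult lifestyle behaviors and log-BMI, not claims about the registry.

Generated liabilities are back-converted to raw survey responses drawn
uniformly within the region consistent with each binary indicator
(sleep hours within the met/not-met band, serving-category and
activity-day combinations from the consistent sets, etc.), so the
pillar-coding module is exercised end to end and re-coding recovers the
generated indicators exactly.  Heights are drawn from sex-specific
normals and weights solved from the generated BMI; PHQ-2 totals are the
rounded square of the generated square-root-scale outcome, so the PHQ
outcome is genuinely discrete while log-BMI survives the round trip up
to survey rounding (rounding can be disabled for exact recovery tests).

What the generator does **not** emulate: non-MCAR missingness,
opposite-sex pairs, age trends in behavior or outcome, dependence among
pillars beyond the optional shared factor, measurement error in
self-report beyond category coarsening, and any non-normal liability.
Passing recovery tests therefore demonstrate correctness of the
estimators under the assumed data-generating process, not robustness of
the published findings to violations of it.

## Problem sizes used in validation

Parameter-recovery checks run at 5,000 + 5,000 pairs (ACE) and
3,000 + 3,000 pairs (quasi-causal attenuation), matching the scale at
which ±0.05 recovery and 2-SE coverage are meaningful.  The Wald size
calibration uses 500 replicates of 150 + 150 pairs per sex group; the
observed rejection rate at alpha = 0.05 is 0.044–0.050.  The tree
benchmark uses 4,000 cases with 3 % missingness on the two active
predictors.  Pipeline-level tests run at a few hundred pairs, which is
sufficient for determinism and bookkeeping checks.

## Known limitations

* Standard errors at variance-share boundaries are flagged but not
  corrected (no mixture-χ² inference).
* The liability-ordinal fit is an order of magnitude slower than the
  observed-count fit; at full registry scale a fit takes minutes.
* No ADE, sex-limitation, reciprocal-causation, or longitudinal models.
* Between-individual difference SEs treat category means as
  independent, ignoring the twin clustering within categories.
* Figure-style plot files are not produced; the difference tables
  (CSV) carry the same content.
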
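# Methods

## Overview

`sdmfusion` estimates a species' probability of presence over a small
planar study area from three unequally trustworthy data streams — ground
surveys, aerial thermal imagery and expert elicitation — by fitting one
regression per stream family and pooling the coefficient vectors. The
package treats record-level confidence as a prior case weight throughout:
a weight of 0.5 makes a record contribute exactly half a record's worth of
log-likelihood.

## Data model and standardization

Six habitat covariates enter every model: longitude, latitude, foliage
projective cover (FPC, %), a binary remnant food-tree indicator (REV), and
Euclidean distances (m) to the nearest path and to fresh water. All
geometry is planar (a projected metre system); coordinates are used as raw
covariates. Every dataset — survey, elicitation, validation, prediction
grid — is centred and scaled with the means and sample SDs (n−1) of the
*base ground-survey data only*. This single reference scaling is what makes
coefficients from different models commensurate, which fusion requires. The
binary REV indicator is z-scored like the other covariates: the procedure
standardizes each covariate uniformly, and fusing a raw-binary coefficient
against a z-scored one would mix scales.

Confidence weights come from a fixed source/class table: ground sightings
1.00; thermal hotspots 1.00 (confirmed, certain), 0.90 (confirmed,
uncertain) or 0.50 (unconfirmed); randomly generated absences 0.90
(false negatives are unlikely but possible when absences are drawn from
never-detected sites); expert statements 0.50/0.75/1.00 for not very
sure / quite sure / very sure.

## Survey models (G and GT)

Weighted logistic regression maximizing

    l(β) = Σᵢ wᵢ [ yᵢ log pᵢ + (1 − yᵢ) log(1 − pᵢ) ],   pᵢ = expit(xᵢ'β).

Weights are prior case weights (not frequency replication, not dispersion
weights): they multiply log-likelihood contributions, which is the
interpretation consistent with confidence down-weighting. Estimation is
IRLS (statsmodels binomial GLM with `var_weights`, tolerance 1e-10, ≤ 100
iterations); standard errors come from the inverse weighted information at
the optimum. Residual df is the nominal n − 7 regardless of the weight
total, matching the degrees-of-freedom bookkeeping of the combined
models. Rank-deficient designs are rejected naming the collinear columns;
fits with |β̂| > 50 are rejected as (quasi-)separated rather than returned
with meaningless standard errors.

## Expert model (E)

Elicited habitat-suitability probabilities are modelled with a weighted
Beta regression in the mean–precision parameterization plus a Gaussian
random intercept per expert:

    y_ij ~ Beta(μ_ij φ, (1 − μ_ij) φ),  logit(μ_ij) = xᵢ'β + u_j,
    u_j ~ N(0, σ²),

with the confidence weight multiplying each record's log-density. The
suitability answer (not the presence mode) is the response: experts state
suitability with far higher confidence because it does not depend on the
unseen surroundings; the elicited presence min/mode/max are stored but not
fitted. Responses at the {0, 1} boundary are compressed by
y′ = (y(n−1) + 0.5)/n, the standard remedy for Beta likelihoods.

The random intercept is integrated out (marginal ML) rather than
penalized, because fusion needs a clean fixed-effect covariance. The
integral per expert uses adaptive Gauss–Hermite quadrature (default 15
nodes): a damped-Newton search finds each expert's conditional mode, the
nodes are re-centred there and rescaled by the curvature, and the quadrature
is evaluated in log space. The optimizer is L-BFGS-B over
(β, log φ, log σ) with an analytic gradient obtained from Fisher's
identity (the posterior expectation of the joint score, evaluated with the
posterior node weights the adaptive quadrature already provides); standard
errors invert a central-difference Hessian of the marginal log-likelihood.
Parameter-at-boundary and non-PD-information fits are returned flagged
(`converged=False`), never silently.

Residual df v_e defaults to n − 7 − edf_random, where edf_random is the
effective number of parameters absorbed by the shrunken intercepts
(Σⱼ Iⱼ/(Iⱼ + σ⁻²) with Iⱼ the curvature of expert j's data log-likelihood
at its mode, capped at n_experts − 1); a `nominal` option gives n − 7.
Both conventions are exposed because the df the original elicitation
analysis used is not recoverable.

For Wald intervals the intercept uses the between-expert containment df
(n_experts − 1) whenever σ > 0: with few experts the intercept is
confounded with the random intercepts and is effectively replicated once
per expert, and intervals on the full residual df demonstrably
under-cover (87% observed at nominal 95% in the recovery study). Slope
covariates vary within expert and keep the residual df.

Multiplying all weights by a constant leaves a fixed-effect (σ = 0) fit
unchanged exactly; with a random intercept the weight scale trades off
against the Gaussian prior, so the invariance is only approximate — the
property is asserted at σ = 0, where it is exact.

## Fusion

For each coefficient independently, with observation-model estimates
(β_o, s_o) and expert-model estimates (β_e, s_e):

    β̂_c = (β_o s_o⁻² + β_e s_e⁻²) / (s_o⁻² + s_e⁻²)
    s_c² = (s_o⁻² + s_e⁻²)⁻¹
    v_c  = v_o + v_e,   interval  β̂_c ± t_{α/2, v_c} s_c.

The intercept is fused along with the six covariate coefficients, since
predictions need a fused intercept. Pooling is elementwise (no
cross-coefficient covariance), mirroring the scalar per-parameter form of
the combining rule. Fused predictions apply the inverse logit to x'β̂_c:
both parents model a probability through a logit mean, and treating the
suitability and presence logits as commensurate is an explicit modelling
assumption, not a derived fact.

## Evaluation

The validation set is every thermal-survey-derived record with weight
≥ 0.90 (boundary inclusive) — the records most likely to reflect the true
state. G and G_E are fit without these records and predict directly; GT
and GT_E train on everything, so each validation site is predicted after
dropping it and refitting the survey parent (the E model contains no
validation observations and is fit once — re-fusing per fold uses the same
expert estimates). Probabilities ≥ 0.4 classify as presence; the
permissive cutoff reflects that in conservation a missed presence costs
more than a false alarm. Reported metrics: accuracy, sensitivity,
specificity (undefined rates reported as missing with a warning, never as
0), and RMSPE computed on raw probabilities — label-based RMSPE would
duplicate accuracy. No multiplicity correction is applied; intervals are
per-coefficient at 95%.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline assumes,
with defaults chosen to mimic the motivating field study:

- **Region**: a right-triangle park of ~0.20 km² (legs 640 m) with the
  river along two sides and housing along the third. Two river edges (a
  river bend) are deliberate: with a single straight river edge,
  distance-to-water is an exact linear combination of the coordinate
  covariates and the design is singular.
- **Covariates**: FPC = 78 − 0.085·dist_water + N(0, 8) clipped to
  [0, 100] (denser canopy near the river); REV ~ Bernoulli(expit(−2.5 +
  0.055·FPC)); dist_path measured to three random boundary chords standing
  in for walking tracks.
- **Occupancy**: Bernoulli(expit(x'β_true)) on standardized covariates,
  β_true = (−0.65, 0.1, 0.3, 0.6, 0.5, −0.2, −0.8) — riverside, high-cover
  habitat favoured, mean occupancy ≈ 0.35 so ~120 sites yield ~41
  presences.
- **Surveys**: ground detection 0.52·exp(−0.004·dist_path) (observer bias;
  the constants calibrate the expected ground:thermal presence split to
  ≈ 17:24), thermal detection 0.95 independent of location, thermal
  confidence classes drawn with probabilities (0.45, 0.35, 0.20) — the
  realized class mixture of the motivating study is not recoverable, so it
  is a free configuration. Absences are drawn from never-detected sites,
  count-matched to presences; a count-matched share is tagged ground-source
  so the base-model subset is balanced like a ground-survey dataset.
- **Experts**: 6 experts × 10 sites (one per Gower/complete-linkage
  cluster, sampled independently per expert), σ_expert = 0.4, φ = 30;
  suitability confidence drawn with P(not very sure) = 1.7% and presence
  confidence with P(not very sure) = 23.3%, matching the observed skew.
- **Determinism**: one root seed splits into per-channel streams
  (landscape, surveys, elicitation, grid, features), so identical
  (seed, config) gives identical tables and channels can be regenerated
  independently.

Not emulated: real GIS rasters (FPC is a noisy gradient, not Landsat),
thermal imagery itself (only detection outcomes and confidence classes),
spatial autocorrelation of occupancy beyond what the covariate gradients
induce, expert biases other than an additive intercept (no
miscalibration, no site-specific disagreement structure), and
detection/occupancy separation (no occupancy model — as in the original
design). Passing tests therefore certify the estimators and the pipeline
logic under the assumed model, not robustness to violations of it. The
synthetic clustering features also produce less balanced cluster sizes
than field-measured vegetation attributes tend to (roughly 1–30 sites per
cluster in the mimic, versus the order of 7–11 in comparable field
designs), so the design tests assert a wider band.

## Problem sizes and numerical choices

The shipped verification uses a 2,000-site landscape × 200 replicates for
survey-model recovery, 6 experts × 200 sites × 200 replicates for
expert-model recovery (bias < 0.1, 95%-interval coverage within
[90%, 99%]), and a ~120-site study mimic with a 636-site grid for the
end-to-end pipeline — sizes at which the Monte-Carlo error of the checks
is comfortably below their tolerances. Logistic fits stop at score norm
1e-10; Beta-mixed fits use 15 quadrature nodes and L-BFGS-B defaults;
mode searches are damped Newton with backtracking; all log-densities are
evaluated in log space with means clipped to [1e-10, 1 − 1e-10].
Ties at the classification cutoff go to presence; constant features are
dropped from Gower distances with a warning; the "complete-linkage
unweighted pair grouping" wording of the source design conflates two
linkages, so complete linkage is the default and average (UPGMA) is
selectable.

## Known limitations

- Fusion ignores cross-coefficient covariance and any dependence between
  the survey and expert estimates (their data are independent here, so
  independence is exact for the simulated streams).
- The Beta model's weight semantics (case weights inside a marginal
  likelihood) are one of several defensible conventions; alternatives
  (e.g. dispersion weights) would change s_e somewhat.
- Wald/t inference for σ and φ near boundaries is unreliable; such fits
  are flagged rather than repaired.
- The LOOCV refits only the survey parent; if the expert data could
  overlap validation sites this shortcut would leak information, so the
  pipeline assumes disjoint elicitation records (true by construction
  here).
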
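# Methods

`stuntgeo` implements the full analysis chain of a district-scale spatial
epidemiology study of under-five stunting: indicator scoring, design-based
prevalence estimation, exploratory spatial statistics, and Bayesian
logistic regression with an optional geostatistical random effect. This
note records the models, the defaults, and the design decisions taken
where more than one convention exists.

## Outcome definitions and scoring

**Height-for-age z-scores** use the LMS transformation
`z = ((h/M)^L − 1)/(L·S)` (log branch when `L = 0`) against a
user-supplied reference table keyed by sex and completed month of age.
The WHO growth-standard table is the intended reference in production;
the package ships none, and the tests use a small synthetic table.
Stunting is `z < −2`, severe stunting `z < −3`, both with strict
inequalities — a child exactly at the threshold is not classified — and
severe cases count toward stunting prevalence. `|z| > 6` is flagged
implausible (the usual anthropometry flag limit) and excluded upstream
with explicit accounting, never silently.

**HFIAS.** The nine occurrence/frequency items map to the four food
insecurity categories through the standard FANTA v3 decision table,
implemented as the maximum of per-item severities (the two forms are
algebraically identical, and the max form makes monotonicity — a more
severe response can never lower the category — structural rather than
incidental). Some surveys restrict the severe class to the last three
scenarios only (running out of food, going to bed hungry, a whole day
and night without eating); `severe_rule="strict"` switches to that
reading, which differs from the standard table only for items 5 and 6
at frequency "often".

**Dietary diversity** is the count of 12 food groups consumed the
previous day, classed lowest (≤ 3), medium (4–5), high (≥ 6).

**Wealth** is the first principal component of the standardized asset
matrix (correlation-matrix PCA via SVD), sign-oriented so a declared
wealth-positive indicator loads positively, cut into weighted quintiles
(1 = poorest). Zero-variance indicators are dropped; missing entries are
mean-imputed with a logged count.

**Measurement standardization.** TEM = √(Σd²/2n) over duplicate pairs;
the reliability coefficient is R = 1 − TEM²/s² with s² the variance of
all measurements.

## Survey estimation

The design is stratified (agro-ecology zone) one-stage cluster sampling
with villages as PSUs and unequal weights (census records are
down-weighted relative to the random sample). The prevalence estimator
is the weighted ratio Σwy/Σw; its variance comes from Taylor
linearization: per-record scores u_i = w_i(y_i − p)/Σw are totalled by
PSU, and stratum contributions n_h/(n_h−1)·Σ_j(U_hj − Ū_h)² are summed.
Confidence intervals are built on the logit scale with t critical values
at df = #PSUs − #strata, matching survey-software convention. A stratum
with a single PSU errors by default; an opt-in fallback centres it at
the grand mean (logged). Estimates and SEs are invariant to rescaling
all weights.

Dose–response trend uses the extended Mantel-Haenszel chi-square for
linear trend, computed as (N−1)r² with r the correlation between the
outcome and the level scores; default scores are integer ranks 1..K,
with midpoint scoring available for interval-valued categories.

## Exploratory spatial statistics

Distances are great-circle (haversine) kilometres from lon/lat. GIS
tooling typically works in projected coordinates instead; over a ≤ 30 km
extent the difference is far below every other source of error.

The empirical semivariogram is γ(h) = Σ(z_i−z_j)²/2N(h) over 12
equal-width lag bins up to half the maximum pairwise distance (both
overridable). The exponential model is parameterized with the
*practical range*: γ(h) = nugget + psill·(1 − e^{−3h/range}), reaching
95 % of the sill at the stated range. This keeps the variogram range and
the Bayesian model's reported range (3/φ) on the same scale. Fitting is
nonnegativity-constrained least squares weighted by pair counts, with
three range starts to avoid the flat local optimum; a pure-nugget field
is representable (psill → 0 and/or range at its lower bound).

Spatial weights are inverse-distance, w_ij = d_ij^{−p}, zero diagonal,
default power 1 and no cutoff, optionally row-standardized so each row
sums to one.

Local Moran's I is I_i = (z_i/m₂)·Σ_j w_ij z_j with m₂ = Σz²/(n−1) (the
moment convention is fixed by a brute-force oracle in the tests; with
row-standardized weights mean(I_i) = (n−1)/n × global Moran's I).
Inference is by conditional permutation (999 draws by default): the
focal value stays fixed, the rest are permuted, and the reported pseudo
p doubles the smaller tail, capped at one. The folding matters:
selecting the extreme tail adaptively without doubling rejects at about
twice the nominal level on null data, whereas the folded p calibrates to
5 % (verified by a 200-replicate null simulation in the acceptance
suite). Sites with p ≤ α are labelled HH/LL (clusters: positive I) or
HL/LH (spatial outliers: negative I) by the signs of own and lagged
deviations. No multiple-testing correction is applied by default; a
Shapiro-Wilk screen with a histogram summary is provided because heavily
non-normal prevalence fields can distort the statistic.

## Variable selection

Each candidate covariate is screened with a two-level random-intercept
logistic model (kebele and village intercepts). For fixed variance
components the joint penalized likelihood over (β, u) is maximized by
damped Newton; the Laplace correction −½ log|H_uu| completes the
approximate marginal likelihood, which a Nelder-Mead search maximizes
over the two log-variances. Wald p-values come from the fixed-effect
block of the inverse joint Hessian; a variable is retained when any
level has p < 0.2. Quasi-separation triggers a small ridge on the fixed
effects, flagged on the result. With zero cluster variance the fit
collapses to ordinary logistic regression (checked against statsmodels),
and under the null the retention rate calibrates to the threshold.
Collinearity is screened by VIF_j = 1/(1−R²_j); exact collinearity is
reported as infinite, not an exception.

## Bayesian models

Both outcome models are Bernoulli logistic. The non-spatial model is
fixed effects only. The spatial model adds a village-level random effect
S ~ GP(0, σ²e^{−φd}) on the linear predictor — village level rather than
household level because sampling is village-based and the estimated
ranges (tens of km) are far larger than within-village distances, and it
keeps the covariance at 45×45. κ in e^{−(φd)^κ} is fixed at 1.

Priors: β ~ N(0, 10⁶), σ² ~ Inverse-Gamma(0.1, 0.1), φ ~ Uniform with
bounds 3/d_max to 3/d_min from the observed inter-village distances —
the conventional weakly-informative choices for this model family.

Sampling is Metropolis-within-Gibbs:

* β — joint random walk preconditioned by the Cholesky factor of the
  logistic MLE covariance, scale adapted toward 23 % acceptance during
  burn-in only (diminishing adaptation, frozen afterwards);
* S — per-village random walks with per-site adapted scales; proposal
  evaluation touches only that village's records plus one row of the
  precision matrix;
* σ² — conjugate inverse-gamma draw given S and φ;
* φ — random walk on log φ (Jacobian included) with the uniform prior
  enforced; each accepted move refactors the 45×45 correlation matrix.

Default schedule: 10,000 burn-in, 20,000 kept thinned by 10, two chains
(20,000 for severe-outcome burn-in is the production recommendation); a
`fast` preset (600/1,200/2, one chain) serves tests and smoke runs;
`full` is the production preset name.
Draws are deterministic given the seed. Non-finite likelihood aborts
with the current state in the message; a 10⁻⁹ diagonal jitter guards the
GP Cholesky.

Summaries report per-parameter posterior mean, SD, median and 2.5/97.5 %
quantiles; odds-ratio intervals are the exponentials of the coefficient
quantiles (quantile-then-exp, exact under a monotone transform). For
spatial models the practical range 3/φ (km) and σ² are summarized the
same way. Model comparison uses DIC = D̄ + pD, pD = D̄ − D(θ̄) with θ̄
the posterior mean of (β, S); a negative pD is reported with a warning.
Convergence diagnostics are the Geweke z (first 10 % vs last 50 %,
autocorrelation-adjusted SEs) and ESS via Geyer's initial-positive-
sequence estimator.

**Identifiability.** Within one spatial realization the intercept and
the GP mean are confounded: the identified level is β₀ + S̄, and the
recovery simulations assess coverage for that combination (plus the raw
slopes). The same confounding is why the posterior on the spatial range
is typically wide in models of this family.

## Synthetic data generator

The generator is first-class, tested code; its defaults *are* the study
conditions: 40 kebeles, 45 villages in a 30 km box anchored at the
district's coordinates, 4,000 children, the emulated survey's
descriptive covariate margins (75.3 % mothers without formal education,
15.1 % facility deliveries, 49.5 % boys, HFIAS margins 19.2/35.5/43.8/
1.5 %, dietary-diversity margins 15.7/78.7/5.6 %), village-level GP
effects with σ² = 0.96 and practical range 33 km, and outcome
coefficients equal to the log odds ratios the emulated survey's
spatial stunting model reports. Ethnicity shares (Guraghe 55 / Siltie
30 / Mareko 10 / other 5 %) reflect the district's location in Guraghe
Zone. The census:random weight ratio is exposed as a parameter
(default 1:2); only its direction — census records down-weighted — is
part of the emulated design.

The intercept is calibrated at generation time by root-finding so the
mean simulated risk equals the target prevalence (0.437). HAZ is drawn
from N(μ_i, s) with μ_i = −2 − s·Φ⁻¹(p_i), which makes
P(HAZ < −2) = p_i exactly; rejection sampling (capped at 1,000 rounds,
then sign-forced) keeps the continuous HAZ consistent with the drawn
binary outcome and inside the plausibility screen. The residual SD
defaults to s = 1.6 by a closed-form argument: at the target risk level
it yields a mean HAZ ≈ −1.75 and a severe share
Φ((−3 − μ)/s) ≈ 21–22 %, both matching the emulated survey's
descriptive statistics.
Household structure (≈ 1.3 children per household) shares
household-level covariates; HFIAS items are drawn from category-
consistent templates (severe households always affirm one of the last
three scenarios, so the category is invariant to the severe-rule
toggle), and asset indicators are generated from a latent wealth factor
and then scored by the package's own PCA — so every derived category
round-trips exactly through the `indicators` module.

What the generator does **not** emulate: height measurement error and
age heaping, non-response follow-up, household-level spatial variation
below the village, informative missingness, or any covariate
misreporting. Passing recovery tests therefore demonstrate correctness
of the estimators under the stated model, not robustness to those
real-data pathologies.

## Simulation sizes and numerical choices

Test and acceptance simulations run at desk scale, chosen as the
smallest sizes at which the Monte-Carlo tolerances below are meaningful:
GP kernel checks use 2,000–5,000 replicate draws (3 MC-SE bands);
LISA null calibration 200 replicates × 15 sites at 199 permutations
(3 binomial SEs around 5 %); BCI coverage 50 runs at full study scale
(45 villages / 4,000 children) with the fast MCMC preset; DIC comparison
20 runs at 1,500 children; variogram recovery judged by the median error
over 5 fields of 300 sites; trend-test calibration 2,000 replicates;
screen calibration 200 fits at 300 records. Ties, degenerate inputs and
edge cases (constant fields, single-PSU strata, flat variograms,
zero-variance LISA inputs, separation) raise explicit errors or take
documented fallbacks rather than returning silent defaults.

## Known limitations

* The screen's Laplace approximation can understate variance components
  with very few clusters; it is a screening device, not the inferential
  model.
* DIC is reported because it is the comparison statistic this analysis
  family uses; its known pathologies (focus-dependence, negative pD
  under strong nonlinearity) are surfaced, not resolved.
* The LISA permutation test treats village prevalences as exchangeable
  under the null; unequal village sample sizes make the prevalence
  variance heterogeneous, which the test ignores (as does the standard
  implementation it mirrors).
* No kriging/prediction surfaces, anisotropic variograms,
  post-stratification, or INLA-style approximations.
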
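# Methods

## Estimands and conventions

The package measures income-related inequality in binary disability
outcomes with rank-dependent indices. Incomes are ranked within country by
the weighted fractional (block-midpoint) rank: sorting by per-capita
household income, each tie block of equal incomes receives the single rank
`(cumulative weight before the block + half the block's weight) / total
weight`. This convention is a deliberate choice — the weighted mean rank is
exactly ½, exact ties (all members of a household share one income) share
one rank, and the mean-RIF and mirror identities below hold with no
remainder, which the test suite asserts at 1e-9 or tighter.

For a binary outcome `h` with weighted mean `μ` and rank `R`, the standard
concentration index is `C = 2·cov_w(h, R)/μ` (weights normalized to sum to
one) and the Erreygers-corrected index is `E = 8·cov_w(h, R)/(b−a)` for
bounds `(a, b)`, binary default `(0, 1)`. Negative values mean the outcome
is concentrated among the poor. `E` satisfies the mirror condition
`E(h) = −E(1−h)` and `|E| ≤ 1` for binary `h`. A constant outcome is the
algebraic no-inequality limit; the implementation returns exactly 0.0 for
it rather than the ~1e-30 round-off a naive covariance would produce.

## Influence functions and standard errors

The recentred influence function of the Erreygers index at observation `i`
is

    RIF_i = 4 h_i (2 R_i − 1) + 8 (s_i − A),

with `A = Σ w_j h_j R_j / W` and `s_i = Σ_j w_j h_j (1{y_j > y_i} +
½·1{y_j = y_i}) / W` (the tie term includes `j = i`). Under the
block-midpoint rank convention the weighted mean of `RIF_i` equals `E`
exactly. The standard-index variant is
`RIF_i = C + (2/μ)(h_i R_i + s_i − 2A) − (C+1)(h_i − μ)/μ`, and the two are
linked by `RIF_E = 4μ·RIF_C + 4C(h − μ)`, the derivative of `E = 4μC`.

Standard errors are the weighted standard deviation of the RIF divided by
√n, i.e. the asymptotic linearization variance treating the weights as
analytic. The tests verify the linearization directly: perturbing one
weight by a factor `(1+ε)` changes the index by `ε·w_i(RIF_i − E)/W` up to
a residual that decays as `ε²`.

## Prevalence estimation

Point estimates are ratio means `Σwh/Σw` in percent. Variances use Taylor
linearization over clusters within strata (`n_c/(n_c−1)` times the sum of
squared centered cluster totals of the linearized scores, summed over
strata); a stratum with a single cluster triggers a logged fallback to the
SRS form. Intervals are Wald on the logit scale, back-transformed and
truncated to `[0, 100]`; degenerate prevalences (0 or 100%) get a
degenerate interval. The interval method is a design choice — coverage on
simulated SRS data at n = 2,000, p = 0.3 is verified to lie in [92%, 98%].

Post-stratification is a single-margin (age band), per-country
multiplicative adjustment: band factor = reference share / weighted sample
share. It preserves each country's total weight, reproduces the reference
shares to 1e-9, and is idempotent. A reference band with positive share but
no sampled weight is an error, since no multiplicative factor can create
mass there.

## Quantile groups

Within-country income quintiles use the weighted empirical CDF with
right-closed intervals: cut point `k` is the smallest income whose CDF
reaches `k/5`, and a person joins the lowest quintile whose upper cut point
covers their income. Exact income ties (households) therefore always share
a quintile, and each quintile's weighted share is 20% up to the weight of
the boundary tie block. Fewer than five distinct incomes in a country is an
error. Country-level quartiles of the macro indicators use the same rule
with equal weights across countries, so tied countries share the lower
quartile.

## The decomposition model

RIFs are computed within country against the country's own ranks and index;
the pooled regression then spans countries. This is the only construction
under which country-level covariates — constant within a country — are
meaningful, and it makes the pooled weighted mean of the RIF equal the
weight-share-weighted mean of the country indices, which is also how the
package defines the overall index (a pooled-ranks mode is available as an
option).

The regression is a linear model for the RIF with a country random
intercept, fitted by REML (statsmodels MixedLM). If the variance component
collapses to the boundary or the optimizer fails, the model is refitted as
weighted least squares with country-cluster-robust standard errors and the
fallback is recorded in the result. Person weights are honored exactly in
the cluster-robust model; the random-intercept likelihood is fitted
unweighted (a warning is emitted when weights are supplied to it) — a
weighted multilevel REML is not a simple reweighting, and the cluster-robust
path exists precisely for the weighted analysis. With an intercept-only
design the WLS fit returns the weighted mean of the RIF — the index — as an
algebraic identity; the balanced unweighted random-intercept fit does the
same by symmetry.

Covariates are dummy-coded with fixed reference levels: age band 55–59, male,
married, less-than-upper-secondary education, and the absence of chronic
disease, smoking and drinking; each macro indicator enters as quartile
dummies with quartile 1 as reference. The full six-indicator block costs 18
country-level columns, so it is identifiable only with enough countries
(always, in generated data, at 33; rarely at 20) — `macro_variables` selects
a subset for smaller designs, and a rank-deficient design raises an error
naming the aliased columns.

**Sign convention.** Because the index of an adverse outcome is negative
under pro-poor inequality, a covariate whose holders contribute *less*
pro-poor concentration (e.g. one that flattens the income–disability
gradient) has recentred influence closer to zero than the reference group
and hence a *positive* partial coefficient: positive coefficients move the
index toward zero (reduced pro-poor inequality), negative coefficients
deepen it. The end-to-end test constructs data in which tertiary education
removes its holders' income gradient and checks a significant positive
tertiary coefficient.

Fits over multiply-imputed datasets are pooled by Rubin's rules: pooled
estimate = mean, total variance = mean within-variance + (1 + 1/m) ×
between-variance, degrees of freedom by the Barnard–Rubin small-sample
formula with complete-data df = n − k. p-values are reported at full
precision, two-sided, with 0.05 as the conventional significance line.

## Chained-equation imputation

Missingness is confined to the explanatory variables (marital status,
education, chronic disease, smoking, drinking); outcomes and income are
never imputed — rows with a missing outcome are dropped listwise per
domain. Each incomplete variable is initialized by random draws from its
observed marginal and then visited in order of increasing missingness for a
fixed number of cycles. Conditional models regress the target on all other
explanatory variables plus age band and country (dummy-coded): predictive
mean matching with k donors for continuous targets (k nearest observed
predictions of a least-squares fit; no posterior draw of the coefficients,
a deliberate simplification), logistic draws for binary targets and
multinomial draws for categorical ones (lightly regularized
maximum-likelihood fits; a non-converging model falls back to a marginal
draw for that cycle with a warning). Defaults: m = 5 imputations, 10
cycles, 5 donors. Observed cells are asserted untouched, and the whole
procedure is deterministic given the seed (independent substreams per
imputation).

## The synthetic survey generator

The generator emulates the structure of harmonized multi-country ageing
cohorts: countries in three income tiers (lower-middle, upper-middle,
high); households of size 1–3 with lognormal household income
(tier-specific medians 5,000 / 12,000 / 30,000; σ = 0.8 on the log scale)
shared per-capita by household members; a two-stage design (2 strata × 20
clusters per stratum, cluster inclusion probabilities uniform on
[0.3, 0.9], within-stage inclusion 0.7) whose inverse inclusion
probabilities are the sampling weights; ages 55+ in 5-year bands with an
open 85+ band, deliberately sampled with a *different* band distribution
than the reference population composition so that post-stratification is
non-vacuous; and covariates with age- and tier-graded marginals.

Outcome models:

- **rank-linear** (default): `P(h=1 | R) = p0 + b(R − ½)`, clipped to
  [0.01, 0.99] with a warning when clipping occurs. Without clipping the
  population Erreygers index is `8b·Var(R) = 2b/3`, the generator's
  closed-form ground truth. The default intercepts are the study
  prevalences (ADL 0.166, IADL 0.176, mobility 0.578) and the default
  slopes are 1.5 × the study indices (−0.0857, −0.0967, −0.1375), so the
  implied population indices equal those values.
- **logistic**: `logit P = α_band + β_rank·(R−½)·(1 − a·edu/2) +
  β_edu·edu + β_chronic·chronic + country effect`, with education drawn by
  a rank-tilted ordered-probit so that higher education sits higher in the
  income distribution, and `a` the per-level attenuation of the income
  gradient. This mode provides age structure, covariate effects and the
  gradient-flattening mechanism the decomposition tests exercise.

Macro indicators are tier means plus independent noise, with percentages
clipped to [0, 100]; the noise is large enough that the six indicators'
country quartiles are not collinear at 33 countries. Missingness injection
is MCAR (constant cell rate) or MAR-on-age (rate rising linearly from 0.5×
to 1.5× the nominal rate across age bands), confined to the explanatory
variables.

What the generator does **not** emulate: cohort-specific questionnaire
wording, item-level outcome structure (outcomes are generated directly as
binary), informative missingness in outcomes, within-household correlation
of outcomes, or calibrated covariate joint distributions. Passing tests
therefore demonstrate the correctness of the estimators and the pipeline
under a known data-generating process, not the substantive findings one
would obtain from the restricted cohort files.

## Problem sizes and numerical choices

The test suite and the acceptance script choose problem sizes that make
Monte-Carlo tolerances meaningful: 50,000 persons for closed-form index
recovery (tolerance 0.015 against 2b/3), 200 replicates of n = 2,000 for
prevalence calibration, 20 countries × 500 for coefficient recovery, 10–20
countries × 2,000 for imputation and decomposition checks, and a 33-country
× 4,273-person cohort (~141k rows) for the headline quantities. Exact
identities (mirror, mean-RIF, post-stratification shares, oracle
equivalence against an O(n²) double-sum evaluation) are asserted at 1e-9 to
1e-12. Ranks use stable sorts throughout, so results are invariant to input
order up to floating-point associativity; all randomness flows from
explicit integer seeds through numpy Generators.

## Known limitations

- The random-intercept path ignores analytic weights (see above); weighted
  inference should use the cluster-robust model.
- RIF-based SEs ignore the design's cluster correlation for the per-country
  index (the decomposition's cluster-robust mode accounts for it at the
  country level).
- PMM does not draw imputation-model parameters, slightly understating
  between-imputation variance for continuous variables.
- Country-quartile macro dummies require enough countries to be
  identifiable; desk-scale runs should pass `macro_variables` subsets.
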
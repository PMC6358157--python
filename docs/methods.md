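# Methods

## Outcome definitions

**Social isolation index.** Eight social-participation frequency items
(codes 1 = at least daily … 5 = never) are recoded to at-least-monthly
indicators (codes 1–3 → 1, 4–5 → 0) and summed to a 0–8 participation
score. Five one-point criteria then form a 0–5 index:

1. *alone & unpartnered* — household size 1 and marital status other than
   married/common-law;
2. *infrequent friend/neighbour contact* — the **joint** criterion: the
   most frequent (numerically smallest) recency code across the close-friends
   and neighbours channels is 4–6 ("within the past 6 months" or less
   recently) or both channels are absent. A single frequent channel
   therefore blocks the point. The alternative either-channel reading was
   rejected because the two channels share one point in the index and the
   criterion text treats them as one contact pool;
3. *infrequent sibling contact* — recency 4–6 or no siblings;
4. *infrequent child contact* — recency 4–6 or no children;
5. *retired with low participation* — retired (any working status, part- or
   full-time, blocks the point) and participation score ≤ 1.

"Has no such network members" is ordered as the least-contact state
(internal code 7, past "more than 1 year ago" = 6) and triggers the
relevant criterion. The primary classification is index ≥ 3; index ≥ 2 is
the sensitivity classification and is always nested around it. Unknown or
refused items are treated as missing and propagate: the affected criterion
and the index become missing for that record, and the record drops out of
analyses of that outcome (with logged counts), never imputed.

**Loneliness.** The single CES-D "felt lonely" frequency item (past week)
is dichotomized: codes 1 ("all of the time", 5–7 days) and 2
("occasionally", 3–4 days) are lonely; 3–4 are not.

**Covariates.** Age in four closed bins (45–54, 55–64, 65–74, 75–85);
education dichotomized; household income in five bands plus an explicit
"missing" level retained as its own category; functional status
dichotomized from the five-level OARS impairment category (the
item-to-category algorithm is upstream of this package — the category is an
input field); chronic conditions counted over 33 diagnosis flags; the
rural/urban category is an individual-level variable and is never
aggregated to the FSA.

## Area linkage

FSA codes are normalized (uppercase, stripped) and validated against the
letter-digit-letter pattern; malformed or unlinkable codes go to an
unmatched report, and more than 5% unmatched (configurable) aborts the
run, as does a duplicated census row. FSAs with fewer than 10 linked
participants are excluded (configurable), since outcome estimates in such
small clusters are unstable. Census measures enter models untransformed in
percentage points, so each AOR is per 1-point increase.

## Estimators

**Weighted prevalence.** `p̂ = Σwᵢyᵢ/Σwᵢ` with the Taylor-linearized
standard error `SE = √(Σwᵢ²(yᵢ−p̂)²)/Σwᵢ`; with constant weights this is
exactly the unweighted proportion. A cluster-robust variant (linearized
scores summed within FSA before squaring) is available via the
`cluster_col` argument for settings where within-area correlation matters.
The survey's replicate-weight machinery is out of scope, so these are
independence-working SEs.

**Correlations.** Spearman correlations between each FSA measure
(individually assigned) and each binary outcome, at the individual level
(each record carries its area's value); an FSA-aggregated correlation can
be computed by collapsing first, but the individual level is the default
because the outcomes are individual. The % living alone measure is
definitionally entangled with the isolation index and is excluded for that
outcome. Stars mark p < .01 and p < .001.

**Random-intercept logistic regression.** For individual *i* in FSA *j*:
`logit P(y=1) = x'β + u_j`, `u_j ~ N(0, σ_u²)`. The marginal likelihood
integrates each cluster's contribution over `u_j`; the integral is
evaluated by adaptive Gauss–Hermite quadrature: a damped Newton iteration
locates each cluster's posterior mode and curvature (the integrand is
strictly log-concave, so this converges quadratically), and the
Gauss–Hermite rule is recentred/rescaled there. Fifteen nodes reproduce a
dense-grid numeric integration to ~1e-11 on small designs and agree with a
51-node rule to a relative 1e-4 at fitted optima.

This is deliberately maximum likelihood, not the linearized
pseudo-likelihood (RSPL-style) some mixed-model software defaults to:
ML-by-quadrature has better-calibrated variance estimates for binary
outcomes, at the cost of not numerically matching pseudo-likelihood
software on the same data. Model fits are unweighted (survey weights enter
the descriptive tables only); a weighted pseudo-likelihood fit is a
one-line change (multiply the per-record log-likelihood terms by weights)
but is intentionally not the default because its sandwich variance is not
implemented.

*Optimization.* Quasi-Newton (L-BFGS-B) over `(β, log σ_u)` with
finite-difference gradients, starting from an ordinary logistic fit and
σ_u = 0.1. Design columns are standardized internally (and estimates and
the covariance mapped back exactly) because percent-scale area measures
next to 0/1 indicators otherwise make the surface badly conditioned —
this cut typical iteration counts by an order of magnitude. Convergence
uses L-BFGS-B's projected-gradient (1e-6) and relative-reduction (1e-11)
rules on the standardized scale. `log σ_u` is bounded below at log(1e-6);
a solution at that bound is reported as σ_u = 0, where the model is
exactly ordinary logistic regression (`fix_sigma_u=0` profiles this limit
directly). Wald SEs come from the inverse of a central finite-difference
observed-information matrix at the optimum (β block only at a boundary).
Non-convergence and suspected separation (|standardized β| at its bound
with exploding SE) are flagged on the result.

*Model sequence.* Treatment coding with fixed references: age 75–85,
sex woman, marital married/common-law, education postsecondary, income
< $20k, functional no-impairment, rural. Model 1 holds individual-level
terms; Model 2 adds the FSA measures. For the isolation outcome the
definitional variables (marital status, living alone) and the % living
alone measure are excluded; the sex term enters only the total-sample
stratum. Rows missing any model term are dropped listwise per model with
logged counts. A missing reference level is a hard error; an empty
non-reference level is dropped from the design and recorded.

## Synthetic data generator

The generator emulates a national aging-cohort baseline: hundreds of FSAs
with negative-binomial cluster sizes (mean 40, dispersion 2 by default, so
a realistic share of FSAs fall under the size-10 exclusion), covariate
marginals matching the published sample composition (e.g. 17.11% living
alone, 74.71% married/common-law, four age-group shares), census measures
drawn from truncated normals within published ranges (e.g. % 65+ in
[4.0, 40.2]), and log-normal analytic weights normalized to mean 1
(dispersion 0.3).

Questionnaire items are ordinal-logistic draws loaded on a per-person
connectedness latent with an FSA-level share (SD 0.3), which induces
positive association among the five criteria and geographic clustering of
the outcomes. A single item-level shift (one for the isolation items, one
for the loneliness item) is calibrated by bisection on the realized
prevalence so the index-derived isolation rate hits 5.09% and the
loneliness rate 10.20% by default — the published overall estimates serve
as calibration targets, not as quantities the generator claims to
reproduce. The bisection acts on fixed underlying uniforms, so realized
prevalence is a monotone step function of the shift and the same seed is
byte-reproducible. Structured dependence is intentionally mild and
low-dimensional: age tilts retirement, income, impairment and
chronic-condition intensity; an FSA urbanicity propensity raises
urban-core residence and correlates (Gaussian copula, ρ = 0.5 by default)
with the % seniors-low-income measure, reproducing qualitatively the
confounding whereby an urban-core effect attenuates once area deprivation
enters the model.

In `from_linear_predictor` mode a binary outcome is instead drawn from
`logistic(x'β + u_j)` with user-named coefficients and `u_j ~ N(0, σ_u²)`,
for parameter-recovery testing.

What the generator does **not** emulate: real joint distributions beyond
the configured marginals and the single latent; item nonresponse;
informative sampling tied to the outcome; telephone/internet-only contact
(the index deliberately measures in-person contact only). Passing tests
therefore demonstrate correctness of the pipeline's logic and calibration
of its estimators under a known mechanism — not agreement with restricted
survey microdata.

## Problem sizes in the test and acceptance runs

The shipped checks use sizes chosen to make Monte-Carlo conclusions stable
while staying desk-scale: the scoring oracle enumerates the full 4,860-point
criterion grid; generator calibration runs at ~50,000 participants in
1,250 FSAs; the recovery study uses 50 replicates of 300 clusters × 60
(β = (−2.0, 0.7), σ_u = 0.5), where mean absolute bias is ~0.005 and 99%
CI coverage 96–100%; pipeline determinism runs a ~1,000-participant bundle
twice. Everything is seeded; reruns reproduce the numbers exactly.

## Known limitations

- SEs for weighted prevalences ignore the survey's replicate-weight design;
  only linearization (optionally cluster-robust) is offered.
- The mixed model fits a single cluster level (FSA); no crossed or nested
  additional effects, no GEE or Bayesian alternatives.
- The 3,240 possible letter-digit-letter codes cap `n_fsa` in the
  generator; real national FSA counts (~1,600) fit comfortably.
- Wald intervals are used throughout; profile-likelihood intervals for
  σ_u near zero would be better calibrated but are not implemented.
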
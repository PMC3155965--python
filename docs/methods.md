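# Methods

This note records the statistical model, the synthetic-data design, the
numerical choices and the known limitations of `gwaccess`, in the spirit of
a package's model documentation rather than a results report. No empirical
claim here goes beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Model and procedure

The outcome is a dichotomised survey response: 1 if a respondent reports
difficulty ("difficult"/"very difficult") reaching a facility type, 0
otherwise. The global analysis is a Bernoulli GLM with logit link over an
ordered ladder of nested models — long-term illness; + bad health;
+ network distance to the nearest facility (km); + non-car ownership. The
hospital ladder additionally distinguishes distance to any hospital from
distance to the nearest hospital with an emergency department, swapping one
for the other rather than nesting both; its analysis-of-deviance chain
therefore follows the illness → bad-health → ED-distance → non-car order,
skipping the plain-hospital-distance model. Models are compared by AIC
(−2·maximized log-likelihood + 2·number of coefficients; for Bernoulli data
the saturated log-likelihood is zero, so AIC = deviance + 2k exactly) and
by sequential analysis of deviance with χ²₁ reference distributions
(stars: *** p<0.001, ** p<0.01, * p<0.05).

Covariate coding: the car-ownership indicator is coded as **non**-car
ownership (1 = no car), so reported odds ratios are oriented as "odds of
difficulty for those without a car relative to those with one" — the
orientation in which such effects are conventionally reported (OR > 1).

The local analysis is geographically weighted logistic regression: at each
fit point (by default every respondent location) the same GLM is refitted
with observation weights from a distance-decay kernel, yielding coefficient
functions b_i(u, v). Spatial non-stationarity of a term is summarized by
the spread — minimum, quartiles, maximum, and especially the IQR — of its
local odds ratios, with the global OR alongside, and is tested by a
Monte-Carlo permutation test: respondent coordinates are permuted among
rows (covariates and outcomes fixed), the GWR is refitted, and
p = (1 + #{permuted IQR ≥ observed IQR}) / (n_perm + 1).

## Fitting engine

Weighted Bernoulli IRLS (Newton–Raphson on the log-likelihood) with:

- convergence when the largest coefficient change is < 1e-8, cap 50
  iterations;
- step-halving whenever a step would decrease the likelihood (robust for
  rare outcomes);
- covariance = inverse of the final weighted information matrix; Wald
  intervals exp(b ± z·se);
- rank checking on the (weighted) design with an error naming the
  collinear terms; inside the sequential deviance table a collinear added
  term is reported with df = 0 and zero reduction instead of failing;
- a perfect-separation advisory when a non-converged fit has probabilities
  pinned to 0/1.

Cross-checks in the test suite: exact 2×2 closed forms, an independent
BFGS likelihood maximiser, and statsmodels' Binomial GLM.

## GWR numerics

- **Kernels**: gaussian `exp(−d²/2h²)` and bisquare `(1−(d/h)²)² · 1{d<h}`.
  Fixed bandwidths are in metres; adaptive bandwidths are neighbour counts,
  resolved per fit point to the distance of the b-th nearest observation.
- **Weight floor**: observations with kernel weight below 1e-12 are dropped
  from a local fit. A local fit with fewer than k+2 positive-weight
  observations, or whose IRLS fails, is flagged non-converged and excluded
  from summaries (never imputed); if more than 20% of local fits fail the
  whole fit errors with a larger-bandwidth advisory.
- **Warm starts**: local fits start from the global coefficients.
- **Bandwidth selection**: leave-one-out cross-validated predictive
  deviance (each observation predicted from a local fit at its own location
  with its own weight zeroed) or a GWR-style AIC whose effective-parameter
  count is the trace of the local hat-like projection. The LOOCV selector
  applies a *paired one-standard-error rule*: walking down from the largest
  candidate, a smaller bandwidth displaces the incumbent only when its
  total score improves by more than one standard error of the paired
  per-observation score differences. Plain argmin over near-equivalent
  candidates amounts to a coin flip driven by CV noise and spuriously
  localises stationary data; the paired rule keeps the largest bandwidth
  unless localisation demonstrably predicts better, while the pairing keeps
  the comparison sharp enough to detect genuine gradients. Exact ties go to
  the larger bandwidth.
- **Weighting distance is straight-line** Euclidean on projected
  coordinates. Network distance is a *covariate* (a property of the
  respondent–facility pair), while kernel weighting expresses closeness of
  observations to a fit point — two distinct concepts deliberately kept
  distinct.
- **Quantiles** use linear interpolation (numpy default, type-7), making
  five-number summaries bit-reproducible across implementations.
- **Surface export** refits on a regular grid (or linearly interpolates
  stored local coefficients); grid cells outside the convex hull of the fit
  points are flagged extrapolated.

## Network distances

The road network is an undirected graph with strictly positive edge
lengths; duplicate undirected edges collapse to the shorter length.
Respondents and facilities snap to the nearest node (ties to the smallest
node id); the reported distance is the minimum over facilities of the
snapped shortest-path length, in km at full precision (the regressions
interpret coefficients per extra km, so no rounding). Node snapping rather
than perpendicular edge projection is used because it is simple and exactly
testable; on the synthetic lattice the snap error is bounded by half the
lattice spacing. Off-network access cost (walking to the road) is ignored.
ED hospitals are a subset of hospitals, giving the invariant
`dist_hospital ≤ dist_ED`, which the distance table asserts.

## Synthetic-data design

The generator emulates the survey structure the analysis expects without
reproducing any real geography:

- **Region**: 40 × 35 km bounding box; respondents uniform over it
  (clustering is possible via configuration but is deliberately not the
  default — a uniform baseline keeps calibration tests analytically
  simple).
- **Network**: rows × cols lattice spanning the region, node coordinates
  jittered N(0, jitter_sd²), edges between lattice neighbours with
  Euclidean lengths; connected by construction. Zero jitter is allowed
  (the analytically clean case); negative jitter is rejected.
- **Covariates**: bad health ~ Bernoulli(0.046); long-term illness drawn
  conditionally on bad health with P(LTI | bad health) = 0.9 and the
  complementary probability solved from the law of total probability so the
  marginal hits 0.331 (an infeasible combination raises a configuration
  error naming the three probabilities); non-car ~ Bernoulli(0.160)
  independent. The single conditional probability is the only dependence
  device: the emulated survey reports only marginals, and one parameter
  gives realistic illness/bad-health collinearity stress without inventing
  an unidentifiable joint distribution.
- **Outcomes**: y ~ Bernoulli(expit(Σ b_t(u,v)·x_t)) with per-term
  coefficient surfaces (constant, linear gradient, or gaussian bump).
  Intercepts are calibrated by root-finding so the population-average
  probability matches the target prevalence (4.9% GP, 20.2% hospital).
  Central coefficient values in the shipped presets are realistic log
  odds ratios for this kind of survey (e.g. ~ln 1.8 for long-term illness
  on GP difficulty, ~ln 3.8 for non-car).
- **Gradients**: the shipped spatial-variation preset puts a north-east →
  south-west linear gradient on one term (default non-car), parameterised
  by its log-odds span across the region diagonal. Configuration is keyed
  per outcome (each outcome has its own term → surface map) because the two
  outcomes need different intercepts and effects.
- **Randomness**: each generation call uses a single numpy Generator seeded
  from (seed, call-name), so calls are reproducible and mutually
  uncoupled; one top-level seed drives the whole pipeline.

What the generator does **not** emulate: real road topology or postcode
geocoding, respondent clustering around settlements, demographic structure
(age/gender), the ordinal 5-point response (the dichotomised outcome is
generated directly), and any dependence of difficulty on unmodelled
factors (service quality, experience). Passing tests therefore demonstrate
the statistical machinery — calibration, recovery, selection behaviour —
under the stated generative model, not the field validity of any substantive
finding.

## Problem sizes and test-scenario choices

Simulation-based checks run at sizes a desktop handles comfortably, chosen
once as part of the study design:

- oracle and calibration checks: n = 400–500 per replicate (500 coverage
  simulations, 1000 type-I simulations);
- GWR recovery: n = 2000 vs 500, gradient span 1.5, CV over an adaptive
  grid (n/8, n/4, n/2, n);
- bandwidth-selection behaviour: n = 500, 20 replicates, fixed gaussian
  grid (2, 6, 18, 1000) km — the largest candidate is effectively global;
  the "strong gradient" scenario uses span 5, the scale at which
  localisation demonstrably out-predicts the global model at n = 500;
- permutation test: n = 300, 50 fit points, 49 permutations,
  20 replicates. Calibration pools the per-term p-values of the covariate
  terms. The power scenario places a span-4 gradient on the baseline
  (intercept) term: a spatially varying baseline is both substantively
  natural (area-level differences in baseline perception) and the scenario
  in which the IQR statistic has solid power at this sample size — for
  rare binary covariates (16% or less) local-coefficient IQRs are noisy
  and much larger n would be needed to detect covariate-coefficient
  gradients reliably. That weakness is a property of the statistic at
  desk-scale n, and is reported rather than hidden.

The GWR gradient presets simulate the ~20% (hospital-scale) outcome rather
than the rare 4.9% GP-scale outcome: local logistic fits on a 4.9% outcome
separate too often at n ≤ 2000 to make a stable shipped example. The rare
outcome is still exercised by the global-GLM calibration tests and the
pipeline presets.

## Known limitations

- Wald intervals only (no profile likelihood); quasi-binomial dispersion,
  survey weighting and ordinal responses are out of scope.
- Mixed/semi-parametric GWR (some coefficients held global), per-term
  bandwidths, and residual spatial-autocorrelation diagnostics are not
  implemented.
- Nearest-facility distance may not be the facility actually used; the
  analysis inherits that interpretation caveat.
- The permutation test assumes exchangeability of locations under the
  null; strong spatial structure in covariates themselves would weaken
  that assumption.
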
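# gwaccess

Global and geographically weighted logistic regression for *perceived*
access to health facilities.

## The problem

Health-access research usually splits into two camps: GIS studies that
measure geographic access (road distances, travel times, catchments) and
survey studies that measure perceived access and its socio-economic
correlates. This package implements an analysis that joins them: survey
respondents report whether they find it difficult to reach their GP surgery
or hospital, and that binary response is modelled against their health
status, car ownership and the road-network distance to the nearest
facility — first globally, then locally, asking where in the study region
each relationship is stronger or weaker than its global average.

It is written for epidemiologists and health-geography analysts who want a
tested, scriptable version of this workflow, including a synthetic-data
generator that reproduces the statistical structure of a county-scale
attitudes survey (~8,500 respondents, a rare GP-difficulty outcome near
4.9%, a commoner hospital-difficulty outcome near 20.2%, covariate
prevalences 33.1% / 4.6% / 16.0%) so the entire pipeline runs and is
testable without any restricted survey data.

## The models

**Global ladder.** With y the 0/1 difficulty response, the logistic GLM

    logit P(y = 1) = b0 + b1·x1 + b2·x2 + b3·x3 + b4·x4

is grown term by term — x1 long-term illness (0/1), x2 bad health (0/1),
x3 network distance to the nearest facility (km), x4 non-car ownership
(0/1) — giving a ladder of nested models compared by AIC
(−2·log-likelihood + 2k) and by a sequential analysis of deviance with
χ² tests. exp(b) is the odds ratio per unit increase; intervals are Wald,
on the log-odds scale. Fitting is by iteratively reweighted least squares
with step-halving, supporting per-observation weights.

**Geographically weighted regression (GWR).** The coefficients become
functions of location:

    logit P(y = 1) = b0(u,v) + b1(u,v)·x1 + … + b4(u,v)·x4

estimated at each fit point by a weighted logistic fit whose observation
weights decay with distance from the fit point (gaussian
`exp(−d²/2h²)` or bisquare `(1−(d/h)²)²` kernels; fixed or adaptive
bandwidth, selectable by leave-one-out cross-validated deviance with a
paired one-standard-error rule, or by a GWR-style AIC). The spread —
especially the inter-quartile range — of the local odds ratios across fit
points summarizes spatial non-stationarity, and a Monte-Carlo permutation
test (coordinates shuffled among rows) gives per-term p-values for it.

Network distances are shortest paths (Dijkstra) on an undirected road graph
with respondents and facilities snapped to their nearest node; ED hospitals
are a subset of hospitals, so `dist_hospital ≤ dist_ED` always.

## Worked example

`examples/03_glm_ladder.py` simulates a 5,000-respondent survey with
network distances and fits the GP-difficulty ladder:

```
Model 4: AIC 1706.1  <- best AIC
    x1_lti           OR  1.49  [1.12, 1.99]
    x2_bad_health    OR  2.62  [1.66, 4.16]
    x3_dist_gp_km    OR  1.36  [1.28, 1.45]
    x4_non_car       OR  4.55  [3.45, 6.00]

Analysis of deviance (terms added sequentially):
  NULL             df 0  resid dev   1925.8  reduction
  x1_lti           df 1  resid dev   1907.0  reduction    18.81 ***
  x2_bad_health    df 1  resid dev   1896.3  reduction    10.78 **
  x3_dist_gp_km    df 1  resid dev   1799.1  reduction    97.19 ***
  x4_non_car       df 1  resid dev   1696.1  reduction   102.98 ***
```

Every covariate earns its place: distance raises the odds of perceived
difficulty by ~36% per km, and respondents without a car have ~4.5× the
odds of reporting difficulty. `examples/04_gwr_analysis.py` continues to
the local analysis on data where the non-car coefficient truly varies in
space:

```
term                min     q1    med     q3    max  global    iqr
x1_lti             0.90   0.99   1.08   1.18   1.33    1.10   0.19
x2_bad_health      1.08   1.47   2.00   2.43   2.82    1.75   0.97
x4_non_car         0.95   1.10   1.31   1.54   1.95    1.39   0.44
permutation p-values (IQR statistic, 49 permutations):
  intercept        0.16
  x1_lti           0.22
  x2_bad_health    0.04
  x4_non_car       0.04
```

The spatially varying non-car effect shows a far wider local-OR spread
than the constant long-term-illness effect, and the permutation test
flags it.

Other entry points: `examples/01_simulate_survey.py` (generator
calibration), `examples/02_network_distances.py` (road vs straight-line
distance), `examples/05_full_pipeline.py` (one-config end-to-end run), and
a thin CLI:

```bash
gw-access simulate --n 2000 --seed 1 --out-dir results/
gw-access fit-glm --survey results/survey.csv --ladder both --out-dir results/
gw-access fit-gwr --survey results/survey.csv --model model9 --bandwidth auto --out-dir results/
gw-access run --config pipeline.yaml
```

Quantiles throughout (including the Table-4-style summaries) use linear
interpolation (numpy's default, the type-7 convention), so summaries are
reproducible bit-for-bit across implementations.

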
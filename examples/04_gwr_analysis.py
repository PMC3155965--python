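"""Geographically weighted logistic regression on a spatial gradient.

Simulates hospital-difficulty data in which the non-car-ownership
coefficient rises from the north-east to the south-west while the other
coefficients stay constant, selects a bandwidth by leave-one-out
cross-validation, fits a local model at every respondent location, and
summarizes the spread of the local odds ratios — the analogue of reporting
quartiles and IQR per term, where a large IQR flags spatial
non-stationarity.  Ends with a Monte-Carlo permutation test.
"""
import numpy as np

from gwaccess import (
    KernelSpec,
    ModelSpec,
    fit_gw_logistic,
    generate_respondents_and_facilities,
    gradient_config,
    nonstationarity_test,
    select_bandwidth,
    simulate_outcomes,
    summarize_odds_ratios,
)

config = gradient_config(n_respondents=2000, seed=3, gradient_span=3.0)
dataset, _ = generate_respondents_and_facilities(config, seed=3)
dataset = simulate_outcomes(
    dataset, config.surfaces["y2_hospital_difficulty"], "y2_hospital_difficulty", 3
)
spec = ModelSpec(
    "hospital", "y2_hospital_difficulty", ("x1_lti", "x2_bad_health", "x4_non_car")
)

selected = select_bandwidth(
    dataset, spec, "gaussian", "adaptive", search_grid=[250, 500, 1000, 2000]
)
print(f"cross-validated adaptive bandwidth: {selected.bandwidth:.0f} neighbours")

kernel = KernelSpec("gaussian", "adaptive", 500)  # map-scale smoothing
result = fit_gw_logistic(dataset, spec, kernel)
print(f"local fits converged: {result.n_converged}/{len(result.local_fits)}")
print(f"{'term':16s} {'min':>6} {'q1':>6} {'med':>6} {'q3':>6} {'max':>6} "
      f"{'global':>7} {'iqr':>6}")
for r in summarize_odds_ratios(result):
    print(f"{r.term:16s} {r.min:6.2f} {r.q1:6.2f} {r.median:6.2f} {r.q3:6.2f} "
          f"{r.max:6.2f} {r.global_or:7.2f} {r.iqr:6.2f}")

rng = np.random.default_rng(3)
fit_points = dataset.data[["u", "v"]].to_numpy()[rng.choice(2000, 50, replace=False)]
pvals = nonstationarity_test(
    dataset, spec, kernel, n_perm=49, seed=3, fit_points=fit_points
)
print("permutation p-values (IQR statistic, 49 permutations):")
for term, p in pvals.items():
    print(f"  {term:16s} {p:.2f}")
# The non-car term (the one whose coefficient truly varies) shows a much
# wider local-OR spread than long-term illness and a permutation p-value
# at the rejection threshold.  Note the bad-health spread: at 4.6%
# prevalence its local fits are intrinsically noisy, so a wide raw IQR
# alone is weak evidence — the permutation null accounts for that
# noise, which is why the test, not the IQR, settles non-stationarity.
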
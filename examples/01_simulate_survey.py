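"""Generate a synthetic accessibility survey.

Builds a county-scale study region with a jittered-lattice road network,
uniformly placed respondents and facilities, draws the binary covariates
(long-term illness, bad health, non-car ownership) at their target
prevalences, computes network distances, and simulates both difficulty
outcomes at calibrated prevalences (4.9% GP, 20.2% hospital).
"""
from gwaccess import (
    calibrate_intercept,
    generate_network,
    generate_respondents_and_facilities,
    nearest_facility_distances,
    simulate_outcomes,
    study_config,
)

config = study_config(n_respondents=4000, seed=42)
graph = generate_network(config, seed=42)
dataset, facilities = generate_respondents_and_facilities(config, seed=42)
dataset, distances = nearest_facility_distances(dataset, facilities, graph)

for outcome, target in [("y1_gp_difficulty", 0.049), ("y2_hospital_difficulty", 0.202)]:
    surfaces = calibrate_intercept(dataset, config.surfaces[outcome], target)
    dataset = simulate_outcomes(dataset, surfaces, outcome, seed=42)

df = dataset.data
print(f"respondents: {len(df)}, road nodes: {graph.n_nodes}, "
      f"facilities: {len(facilities.facilities)}")
print(f"long-term illness prevalence: {df.x1_lti.mean():.3f} (target 0.331)")
print(f"bad health prevalence:        {df.x2_bad_health.mean():.3f} (target 0.046)")
print(f"non-car prevalence:           {df.x4_non_car.mean():.3f} (target 0.160)")
print(f"mean distance to nearest GP:  {df.x3_dist_gp_km.mean():.2f} km")
print(f"GP difficulty rate:           {df.y1_gp_difficulty.mean():.3f} (target 0.049)")
print(f"hospital difficulty rate:     {df.y2_hospital_difficulty.mean():.3f} (target 0.202)")
# Each prevalence should sit within sampling error of its target; the
# distance column feeds the regressions as kilometres with full precision.
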
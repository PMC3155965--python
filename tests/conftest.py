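import numpy as np
import pandas as pd
import pytest

from gwaccess import (
    ModelSpec,
    generate_respondents_and_facilities,
    gradient_config,
    simulate_outcomes,
)

HOSPITAL_SPEC = ModelSpec(
    "hospital", "y2_hospital_difficulty", ("x1_lti", "x2_bad_health", "x4_non_car")
)


def make_gradient_dataset(n, seed, span=1.5, term="x4_non_car", prevalence=0.20):
    """Survey dataset drawn from the spatial-variation preset.

    One coefficient follows a NE->SW gradient of ``span`` log-odds units
    (``span=0`` gives stationary data); returns (dataset, config).
    """
    cfg = gradient_config(
        n_respondents=n,
        seed=seed,
        gradient_span=span,
        prevalence=prevalence,
        gradient_term=term,
    )
    ds, _ = generate_respondents_and_facilities(cfg, seed)
    ds = simulate_outcomes(
        ds, cfg.surfaces["y2_hospital_difficulty"], "y2_hospital_difficulty", seed
    )
    return ds, cfg


@pytest.fixture
def gradient_dataset():
    return make_gradient_dataset


def simulate_logistic_frame(n, seed, intercept=-1.0, slope=0.7, p_x=0.5):
    """Simple single-covariate Bernoulli frame for GLM calibration checks."""
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < p_x).astype(float)
    eta = intercept + slope * x
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return pd.DataFrame({"x": x, "y": y})
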
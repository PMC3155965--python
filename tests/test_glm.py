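import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from gwaccess import (
    ModelSpec,
    aic,
    fit_logistic,
    invlogit,
    logit,
    odds_ratio_table,
    run_model_ladder,
    sequential_deviance,
)
from gwaccess.glm import (
    GP_DEVIANCE_TERMS,
    PerfectSeparationWarning,
    _design,
    gp_ladder,
    hospital_ladder,
)
from conftest import simulate_logistic_frame


def two_by_two_frame(a, b, c, d):
    """a = (x=1, y=1), b = (x=1, y=0), c = (x=0, y=1), d = (x=0, y=0)."""
    return pd.DataFrame(
        {
            "x": [1.0] * (a + b) + [0.0] * (c + d),
            "y": [1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d,
        }
    )


class TestLogit:
    def test_symmetry_point(self):
        assert logit(0.5) == 0.0
        assert invlogit(0.0) == 0.5

    def test_closed_form(self):
        assert logit(0.9) == pytest.approx(math.log(9.0), abs=1e-12)

    def test_inverse_identity(self):
        for p in (0.01, 0.3, 0.75, 0.999):
            assert invlogit(logit(p)) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            logit(p)


class TestFitLogistic:
    @pytest.mark.parametrize("cells", [(12, 30, 7, 80), (5, 5, 5, 5), (40, 9, 21, 63)])
    def test_two_by_two_closed_form(self, cells):
        a, b, c, d = cells
        fit = fit_logistic(two_by_two_frame(a, b, c, d), ModelSpec("t", "y", ("x",)))
        assert fit.coefficients[1] == pytest.approx(math.log(a * d / (b * c)), abs=1e-8)
        assert fit.coefficients[0] == pytest.approx(math.log(c / d), abs=1e-8)

    def test_intercept_only_is_logit_of_mean(self):
        df = simulate_logistic_frame(400, seed=0)
        fit = fit_logistic(df, ModelSpec("null", "y", ()))
        assert fit.coefficients[0] == pytest.approx(logit(df.y.mean()), abs=1e-8)

    def test_matches_independent_optimizer(self):
        """IRLS equals a general-purpose likelihood maximiser (BFGS)."""
        rng = np.random.default_rng(3)
        n = 600
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.25).astype(float)
        eta = -0.8 + 0.6 * x1 - 0.5 * x2
        y = (rng.random(n) < invlogit(eta)).astype(float)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        spec = ModelSpec("t", "y", ("x1", "x2"))
        fit = fit_logistic(df, spec)
        X, yy = _design(df, spec)

        def nll(beta):
            e = X @ beta
            return -np.sum(
                yy * -np.logaddexp(0, -e) + (1 - yy) * -np.logaddexp(0, e)
            )

        ref = minimize(nll, np.zeros(3), method="BFGS", options={"gtol": 1e-10})
        np.testing.assert_allclose(fit.coefficients, ref.x, atol=1e-6)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        df = simulate_logistic_frame(500, seed=7)
        fit = fit_logistic(df, ModelSpec("t", "y", ("x",)))
        ref = sm.GLM(
            df.y, np.column_stack([np.ones(len(df)), df.x]), family=sm.families.Binomial()
        ).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-7)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-6)
        assert fit.deviance == pytest.approx(ref.deviance, abs=1e-8)

    def test_score_equations_at_fixed_point(self):
        df = simulate_logistic_frame(500, seed=2)
        spec = ModelSpec("t", "y", ("x",))
        fit = fit_logistic(df, spec)
        X, y = _design(df, spec)
        p = invlogit(X @ fit.coefficients)
        assert np.max(np.abs(X.T @ (y - p))) < 1e-6

    def test_weighted_score_equations(self):
        df = simulate_logistic_frame(400, seed=5)
        rng = np.random.default_rng(1)
        w = rng.uniform(0.1, 2.0, size=len(df))
        spec = ModelSpec("t", "y", ("x",))
        fit = fit_logistic(df, spec, observation_weights=w)
        X, y = _design(df, spec)
        p = invlogit(X @ fit.coefficients)
        assert np.max(np.abs(X.T @ (w * (y - p)))) < 1e-6

    def test_integer_weights_equal_row_replication(self):
        df = simulate_logistic_frame(120, seed=9)
        w = np.tile([1.0, 2.0, 3.0], 40)
        fit_w = fit_logistic(df, ModelSpec("t", "y", ("x",)), observation_weights=w)
        expanded = df.loc[df.index.repeat(w.astype(int))].reset_index(drop=True)
        fit_e = fit_logistic(expanded, ModelSpec("t", "y", ("x",)))
        np.testing.assert_allclose(fit_w.coefficients, fit_e.coefficients, atol=1e-8)
        assert fit_w.log_likelihood == pytest.approx(fit_e.log_likelihood, abs=1e-6)

    def test_rank_deficiency_names_collinear_term(self):
        df = simulate_logistic_frame(100, seed=0)
        df["x_copy"] = df["x"]
        with pytest.raises(ValueError, match="x_copy"):
            fit_logistic(df, ModelSpec("t", "y", ("x", "x_copy")))

    def test_perfect_separation_advisory(self):
        df = pd.DataFrame({"x": [0.0] * 20 + [1.0] * 20, "y": [0.0] * 20 + [1.0] * 20})
        with pytest.warns(PerfectSeparationWarning):
            fit = fit_logistic(df, ModelSpec("t", "y", ("x",)))
        assert not fit.converged

    def test_deviance_is_minus_twice_loglik(self):
        df = simulate_logistic_frame(300, seed=4)
        fit = fit_logistic(df, ModelSpec("t", "y", ("x",)))
        assert fit.deviance == pytest.approx(-2.0 * fit.log_likelihood, abs=1e-12)


class TestAic:
    def test_direct_formula(self):
        df = simulate_logistic_frame(200, seed=1)
        fit = fit_logistic(df, ModelSpec("t", "y", ("x",)))
        assert aic(fit) == pytest.approx(-2 * fit.log_likelihood + 2 * fit.k, abs=1e-12)
        assert aic(fit) == pytest.approx(fit.deviance + 2 * fit.k, abs=1e-12)

    def test_nested_deviance_monotone(self):
        rng = np.random.default_rng(11)
        n = 500
        df = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "y": (rng.random(n) < 0.3).astype(float),
            }
        )
        small = fit_logistic(df, ModelSpec("s", "y", ("x1",)))
        large = fit_logistic(df, ModelSpec("l", "y", ("x1", "x2")))
        assert large.deviance <= small.deviance + 1e-10


class TestOddsRatios:
    def test_closed_form_wald_interval(self):
        # b=0, se=0.1: OR 1, CI exp(+/- 1.959964 * 0.1)
        df = simulate_logistic_frame(200, seed=1)
        fit = fit_logistic(df, ModelSpec("t", "y", ("x",)))
        fit.coefficients[1] = 0.0
        fit.standard_errors[1] = 0.1
        row = odds_ratio_table(fit, level=0.95)[0]
        assert row.odds_ratio == pytest.approx(1.0, abs=1e-12)
        assert row.ci_low == pytest.approx(math.exp(-1.959964 * 0.1), abs=1e-6)
        assert row.ci_high == pytest.approx(math.exp(1.959964 * 0.1), abs=1e-6)

    def test_degenerate_interval_collapses(self):
        df = simulate_logistic_frame(200, seed=1)
        fit = fit_logistic(df, ModelSpec("t", "y", ("x",)))
        fit.coefficients[1] = math.log(2.0)
        fit.standard_errors[1] = 0.0
        row = odds_ratio_table(fit)[0]
        assert row.ci_low == row.odds_ratio == row.ci_high == pytest.approx(2.0)

    def test_covariate_rescaling_identity(self):
        """Scaling x by c divides b by c, so OR_scaled = OR ** (1/c)."""
        df = simulate_logistic_frame(800, seed=6)
        c = 4.0
        df["x_scaled"] = df["x"] * c
        or1 = odds_ratio_table(fit_logistic(df, ModelSpec("a", "y", ("x",))))[0]
        or2 = odds_ratio_table(fit_logistic(df, ModelSpec("b", "y", ("x_scaled",))))[0]
        assert or2.odds_ratio == pytest.approx(or1.odds_ratio ** (1 / c), rel=1e-6)


class TestSequentialDeviance:
    def test_telescoping_identity(self, gradient_dataset):
        ds, _ = gradient_dataset(800, seed=2)
        rows = sequential_deviance(
            ds, ["x1_lti", "x2_bad_health", "x4_non_car"], "y2_hospital_difficulty"
        )
        total = sum(r.deviance_reduction for r in rows[1:])
        assert total == pytest.approx(
            rows[0].residual_deviance - rows[-1].residual_deviance, abs=1e-9
        )
        devs = [r.residual_deviance for r in rows]
        assert all(a >= b - 1e-10 for a, b in zip(devs, devs[1:]))

    def test_duplicate_term_flags_rank_drop(self):
        df = simulate_logistic_frame(300, seed=3)
        df["x_dup"] = df["x"]
        rows = sequential_deviance(df, ["x", "x_dup"], "y")
        dup = rows[2]
        assert dup.df == 0
        assert dup.deviance_reduction == 0.0
        assert dup.p_value is None

    def test_stars_thresholds(self):
        from gwaccess.glm import _stars

        assert _stars(0.0005) == "***"
        assert _stars(0.005) == "**"
        assert _stars(0.04) == "*"
        assert _stars(0.2) == ""

    def test_residual_df_decrements(self):
        df = simulate_logistic_frame(250, seed=8)
        rows = sequential_deviance(df, ["x"], "y")
        assert rows[0].residual_df == 249
        assert rows[1].residual_df == 248


class TestModelLadder:
    def test_single_model_ladder_is_best(self):
        df = simulate_logistic_frame(200, seed=1)
        report = run_model_ladder(df, [ModelSpec("only", "y", ("x",))])
        assert report.best_index == 0
        assert report.best_model.name == "only"

    def test_mixed_outcomes_rejected(self):
        with pytest.raises(ValueError, match="share an outcome"):
            run_model_ladder(
                simulate_logistic_frame(50, 0),
                [ModelSpec("a", "y", ("x",)), ModelSpec("b", "x", ("y",))],
            )

    def test_ladder_presets_follow_published_sequences(self):
        gp = gp_ladder()
        assert [len(s.terms) for s in gp] == [1, 2, 3, 4]
        assert gp[-1].terms[-1] == "x4_non_car"
        hosp = hospital_ladder()
        assert len(hosp) == 5
        assert hosp[2].terms[-1] == "dist_hospital_km"
        assert hosp[3].terms[-1] == "x3a_dist_ed_km"
        assert GP_DEVIANCE_TERMS[-1] == "x4_non_car"

    def test_true_model_recovered_by_aic(self, gradient_dataset):
        """Data generated with all four effects active: the full model wins
        the AIC comparison in most replicates."""
        wins = 0
        for seed in range(10):
            ds, _ = gradient_dataset(3000, seed=seed, span=0.0)
            ladder = [
                ModelSpec("m1", "y2_hospital_difficulty", ("x1_lti",)),
                ModelSpec("m2", "y2_hospital_difficulty", ("x1_lti", "x2_bad_health")),
                ModelSpec(
                    "m3",
                    "y2_hospital_difficulty",
                    ("x1_lti", "x2_bad_health", "x4_non_car"),
                ),
            ]
            report = run_model_ladder(ds, ladder)
            wins += report.best_index == 2
        assert wins >= 7

    def test_permuted_outcome_kills_significance(self, gradient_dataset):
        ds, _ = gradient_dataset(2000, seed=3, span=0.0)
        df = ds.data.copy()
        rng = np.random.default_rng(0)
        df["y2_hospital_difficulty"] = rng.permutation(
            df["y2_hospital_difficulty"].to_numpy()
        )
        report = run_model_ladder(
            df,
            [
                ModelSpec(
                    "m",
                    "y2_hospital_difficulty",
                    ("x1_lti", "x2_bad_health", "x4_non_car"),
                )
            ],
        )
        for row in report.odds_ratios[0]:
            assert row.ci_low < 1.0 < row.ci_high  # nothing significant

    def test_table_dataframe_marks_best(self, gradient_dataset):
        ds, _ = gradient_dataset(1200, seed=4, span=0.0)
        ladder = [
            ModelSpec("m1", "y2_hospital_difficulty", ("x1_lti",)),
            ModelSpec("m2", "y2_hospital_difficulty", ("x1_lti", "x4_non_car")),
        ]
        df = run_model_ladder(ds, ladder).to_dataframe()
        assert set(df.columns) == {
            "model", "term", "odds_ratio", "ci_low", "ci_high", "aic", "is_best",
        }
        assert df.groupby("model")["is_best"].first().sum() == 1
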
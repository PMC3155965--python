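import math

import numpy as np
import pandas as pd
import pytest

from gwaccess import (
    KernelSpec,
    ModelSpec,
    export_surfaces,
    fit_gw_logistic,
    fit_logistic,
    kernel_weights,
    nonstationarity_test,
    select_bandwidth,
    summarize_odds_ratios,
)
from gwaccess.gwr import GwrResult, LocalFit, _resolve_bandwidth

from conftest import HOSPITAL_SPEC


class TestKernels:
    def test_zero_distance_weight_one(self):
        for ktype in ("gaussian", "bisquare"):
            spec = KernelSpec(ktype, "fixed", 500.0)
            assert kernel_weights([0.0], spec)[0] == 1.0

    def test_gaussian_at_bandwidth(self):
        spec = KernelSpec("gaussian", "fixed", 800.0)
        assert kernel_weights([800.0], spec)[0] == pytest.approx(
            math.exp(-0.5), abs=1e-12
        )

    def test_bisquare_compact_support(self):
        spec = KernelSpec("bisquare", "fixed", 300.0)
        w = kernel_weights([299.0, 300.0, 500.0], spec)
        assert w[0] > 0.0
        assert w[1] == 0.0 and w[2] == 0.0

    def test_bisquare_closed_form(self):
        spec = KernelSpec("bisquare", "fixed", 100.0)
        assert kernel_weights([50.0], spec)[0] == pytest.approx(0.75**2, abs=1e-12)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec("gaussian", "fixed", 0.0)
        with pytest.raises(ValueError):
            kernel_weights([1.0], KernelSpec("gaussian", "fixed", 10.0), bandwidth_m=-1.0)

    def test_shrinking_bandwidth_never_raises_weight(self):
        d = np.linspace(0.0, 2000.0, 50)
        for ktype in ("gaussian", "bisquare"):
            w_small = kernel_weights(d, KernelSpec(ktype, "fixed", 400.0))
            w_large = kernel_weights(d, KernelSpec(ktype, "fixed", 900.0))
            assert (w_small <= w_large + 1e-15).all()

    def test_adaptive_bandwidth_is_kth_nearest_distance(self):
        d = np.array([30.0, 10.0, 50.0, 20.0, 40.0])
        assert _resolve_bandwidth(d, KernelSpec("gaussian", "adaptive", 3)) == 30.0
        assert _resolve_bandwidth(d, KernelSpec("gaussian", "adaptive", 1)) == 10.0


class TestFitGwLogistic:
    def test_infinite_bandwidth_equals_global(self, gradient_dataset):
        ds, _ = gradient_dataset(300, seed=1, span=1.5)
        res = fit_gw_logistic(ds, HOSPITAL_SPEC, KernelSpec("gaussian", "fixed", 1e9))
        B = res.coefficient_matrix()
        diff = np.abs(B - res.global_fit.coefficients[None, :])
        assert np.nanmax(diff) < 1e-6

    def test_single_fit_point_uniform_weights_equals_global(self, gradient_dataset):
        ds, _ = gradient_dataset(250, seed=2, span=1.5)
        fp = np.array([[20_000.0, 17_500.0]])
        res = fit_gw_logistic(ds, HOSPITAL_SPEC, KernelSpec("gaussian", "fixed", 1e9), fit_points=fp)
        assert len(res.local_fits) == 1
        np.testing.assert_allclose(
            res.local_fits[0].coefficients, res.global_fit.coefficients, atol=1e-6
        )

    def test_default_fit_points_are_respondents(self, gradient_dataset):
        ds, _ = gradient_dataset(120, seed=0, span=0.0)
        res = fit_gw_logistic(ds, HOSPITAL_SPEC, KernelSpec("gaussian", "adaptive", 60))
        np.testing.assert_array_equal(
            res.fit_points, ds.data[["u", "v"]].to_numpy()
        )

    def test_too_small_bandwidth_raises_with_advisory(self, gradient_dataset):
        ds, _ = gradient_dataset(400, seed=1, span=0.0)
        with pytest.raises(RuntimeError, match="bandwidth"):
            fit_gw_logistic(ds, HOSPITAL_SPEC, KernelSpec("bisquare", "fixed", 200.0))

    def test_local_fit_flagged_when_too_few_neighbours(self, gradient_dataset):
        ds, _ = gradient_dataset(200, seed=3, span=0.0)
        # one distant fit point with a tiny fixed bisquare kernel: no weight
        fp = ds.data[["u", "v"]].to_numpy()[:1]
        df = ds.data
        from gwaccess.gwr import _local_fit
        from gwaccess.glm import _design

        X, y = _design(df, HOSPITAL_SPEC)
        w = np.zeros(len(df))
        lf = _local_fit(X, y, w, fp[0], np.zeros(X.shape[1]), X.shape[1])
        assert not lf.converged
        assert "positive weight" in lf.reason


class TestSummaries:
    def _result_with_coeffs(self, coeffs):
        """Hand-built GwrResult with known local slopes for one term."""
        spec = ModelSpec("toy", "y", ("x",))
        df = pd.DataFrame(
            {"u": [0.0, 1, 2, 3, 4], "v": [0.0] * 5,
             "x": [0.0, 1, 0, 1, 0], "y": [1.0, 0, 1, 1, 0]}
        )
        gfit = fit_logistic(df, spec)
        fits = [
            LocalFit((float(i), 0.0), np.array([0.0, math.log(c)]), np.zeros(2), True, 5.0)
            for i, c in enumerate(coeffs)
        ]
        return GwrResult(
            spec=spec, kernel=KernelSpec("gaussian", "fixed", 1.0),
            local_fits=fits, global_fit=gfit,
            fit_points=np.array([[float(i), 0.0] for i in range(len(coeffs))]),
        )

    def test_hand_computed_quantiles(self):
        res = self._result_with_coeffs([1.0, 2.0, 3.0, 4.0, 5.0])
        row = [r for r in summarize_odds_ratios(res) if r.term == "x"][0]
        for got, want in zip(
            (row.min, row.q1, row.median, row.q3, row.max), (1.0, 2.0, 3.0, 4.0, 5.0)
        ):
            assert got == pytest.approx(want, abs=1e-12)
        assert row.iqr == pytest.approx(2.0, abs=1e-12)

    def test_identical_local_ors_zero_iqr(self):
        res = self._result_with_coeffs([2.5] * 6)
        row = [r for r in summarize_odds_ratios(res) if r.term == "x"][0]
        assert row.min == row.q1 == row.median == row.q3 == row.max == pytest.approx(2.5)
        assert row.iqr == 0.0

    def test_infinite_bandwidth_summary_matches_global(self, gradient_dataset):
        ds, _ = gradient_dataset(300, seed=5, span=1.5)
        res = fit_gw_logistic(ds, HOSPITAL_SPEC, KernelSpec("gaussian", "fixed", 1e9))
        for row in summarize_odds_ratios(res):
            assert row.iqr == pytest.approx(0.0, abs=1e-6)
            for q in (row.min, row.q1, row.median, row.q3, row.max):
                assert q == pytest.approx(row.global_or, abs=1e-6)

    def test_stationary_iqr_shrinks_with_bandwidth(self, gradient_dataset):
        """On stationary data the local-OR spread decreases monotonically as
        the kernel widens."""
        ds, _ = gradient_dataset(400, seed=6, span=0.0)
        iqrs = []
        for bw in (100, 200, 300, 400):
            res = fit_gw_logistic(ds, HOSPITAL_SPEC, KernelSpec("gaussian", "adaptive", bw))
            row = [r for r in summarize_odds_ratios(res) if r.term == "x4_non_car"][0]
            iqrs.append(row.iqr)
        assert all(a >= b for a, b in zip(iqrs, iqrs[1:]))


class TestBandwidthSelection:
    def test_argmin_contract_with_forced_scores(self, monkeypatch, gradient_dataset):
        ds, _ = gradient_dataset(100, seed=0, span=0.0)
        scores = {100.0: 5.0, 200.0: 1.0, 300.0: 9.0}

        def fake_scorer(X, y, coords, kernel, start):
            # constant per-observation contributions: zero paired variance,
            # so selection reduces to comparing totals
            return np.full(4, scores[kernel.bandwidth] / 4.0)

        monkeypatch.setattr("gwaccess.gwr._loocv_deviance", fake_scorer)
        k = select_bandwidth(ds, HOSPITAL_SPEC, search_grid=[100, 200, 300])
        assert k.bandwidth == 200.0

    def test_ties_go_to_larger_bandwidth(self, monkeypatch, gradient_dataset):
        ds, _ = gradient_dataset(100, seed=0, span=0.0)
        monkeypatch.setattr(
            "gwaccess.gwr._loocv_deviance", lambda *a: np.full(4, 0.25)
        )
        k = select_bandwidth(ds, HOSPITAL_SPEC, search_grid=[100, 200, 300])
        assert k.bandwidth == 300.0

    def test_grid_validation(self, gradient_dataset):
        ds, _ = gradient_dataset(60, seed=0, span=0.0)
        with pytest.raises(ValueError, match="at least 3"):
            select_bandwidth(ds, HOSPITAL_SPEC, search_grid=[100, 200])
        with pytest.raises(ValueError, match="ascending"):
            select_bandwidth(ds, HOSPITAL_SPEC, search_grid=[300, 200, 100])

    def test_aic_criterion_runs_and_prefers_sane_bandwidth(self, gradient_dataset):
        ds, _ = gradient_dataset(150, seed=1, span=0.0)
        k = select_bandwidth(
            ds, HOSPITAL_SPEC, criterion="aic", search_grid=[50, 100, 150]
        )
        assert k.bandwidth in (50.0, 100.0, 150.0)


class TestNonstationarityTest:
    def test_p_value_bounds_with_coincident_coordinates(self, gradient_dataset):
        """All respondents at one location: every local fit equals the global
        fit, observed and permuted statistics are all zero, so every
        permutation counts and p = 1."""
        ds, _ = gradient_dataset(80, seed=2, span=0.0)
        df = ds.data.copy()
        df["u"] = 100.0
        df["v"] = 100.0
        pvals = nonstationarity_test(
            df, HOSPITAL_SPEC, KernelSpec("gaussian", "fixed", 1e6),
            n_perm=19, seed=0,
        )
        for term, p in pvals.items():
            assert p == 1.0

    def test_minimum_permutations_enforced(self, gradient_dataset):
        ds, _ = gradient_dataset(50, seed=0, span=0.0)
        with pytest.raises(ValueError, match="19"):
            nonstationarity_test(ds, HOSPITAL_SPEC, KernelSpec(), n_perm=5)

    def test_returns_p_value_per_term(self, gradient_dataset):
        ds, _ = gradient_dataset(150, seed=1, span=0.0)
        fp = ds.data[["u", "v"]].to_numpy()[:25]
        pvals = nonstationarity_test(
            ds, HOSPITAL_SPEC, KernelSpec("gaussian", "adaptive", 75),
            n_perm=19, seed=3, fit_points=fp,
        )
        assert set(pvals) == {"intercept", "x1_lti", "x2_bad_health", "x4_non_car"}
        for p in pvals.values():
            assert 1.0 / 20.0 <= p <= 1.0


class TestExportSurfaces:
    def test_single_cell_at_centroid_matches_single_fit_point(self, gradient_dataset):
        ds, _ = gradient_dataset(200, seed=4, span=1.5)
        kernel = KernelSpec("gaussian", "adaptive", 100)
        res = fit_gw_logistic(ds, HOSPITAL_SPEC, kernel)
        fp = res.fit_points
        centroid = np.array([[np.mean([fp[:, 0].min(), fp[:, 0].max()]),
                              np.mean([fp[:, 1].min(), fp[:, 1].max()])]])
        direct = fit_gw_logistic(ds, HOSPITAL_SPEC, kernel, fit_points=centroid)
        grid = export_surfaces(res, (1, 1))
        for j, term in enumerate(res.term_names):
            got = grid[grid.term == term]["coefficient"].iloc[0]
            assert got == pytest.approx(direct.local_fits[0].coefficients[j], abs=1e-10)

    def test_refit_on_fit_points_is_idempotent(self, gradient_dataset):
        ds, _ = gradient_dataset(150, seed=5, span=1.5)
        kernel = KernelSpec("gaussian", "adaptive", 75)
        # fit points arranged as a regular grid so refitting the same grid
        # must reproduce the stored local coefficients
        gu = np.linspace(5_000, 35_000, 4)
        gv = np.linspace(5_000, 30_000, 3)
        UU, VV = np.meshgrid(gu, gv)
        fp = np.column_stack([UU.ravel(), VV.ravel()])
        res = fit_gw_logistic(ds, HOSPITAL_SPEC, kernel, fit_points=fp)
        grid = export_surfaces(res, (4, 3), bounds=(5_000, 35_000, 5_000, 30_000))
        B = res.coefficient_matrix()
        for j, term in enumerate(res.term_names):
            sub = grid[grid.term == term].sort_values(["v", "u"])
            np.testing.assert_allclose(sub["coefficient"].to_numpy(), B[:, j], atol=1e-10)

    def test_gradient_surface_monotone_along_gradient_axes(self, gradient_dataset):
        """Estimated non-car surface decreases from SW to NE: at
        map-export smoothing, adjacent grid cells are ordered along both
        axes in >= 90% of pairs."""
        ds, cfg = gradient_dataset(2000, seed=1, span=1.5)
        res = fit_gw_logistic(
            ds, HOSPITAL_SPEC, KernelSpec("gaussian", "adaptive", 2000)
        )
        grid = export_surfaces(res, (6, 6))
        sub = grid[grid.term == "x4_non_car"]
        P = sub.pivot_table(index="v", columns="u", values="coefficient").to_numpy()
        mono = total = 0
        for A in (P, P.T):  # decreasing in u at fixed v, and in v at fixed u
            for row in A:
                for a, b in zip(row, row[1:]):
                    total += 1
                    mono += b <= a
        assert mono / total >= 0.9

    def test_interpolate_mode_and_extrapolation_flags(self, gradient_dataset):
        ds, _ = gradient_dataset(120, seed=7, span=0.0)
        res = fit_gw_logistic(ds, HOSPITAL_SPEC, KernelSpec("gaussian", "adaptive", 60))
        grid = export_surfaces(
            res, (5, 5), mode="interpolate", bounds=(-10_000, 50_000, -10_000, 45_000)
        )
        assert grid["extrapolated"].any()
        inner = grid[~grid.extrapolated]
        assert np.isfinite(inner["coefficient"]).all()

    def test_unknown_mode_rejected(self, gradient_dataset):
        ds, _ = gradient_dataset(60, seed=0, span=0.0)
        res = fit_gw_logistic(ds, HOSPITAL_SPEC, KernelSpec("gaussian", "adaptive", 30))
        with pytest.raises(ValueError, match="mode"):
            export_surfaces(res, (2, 2), mode="kriging")
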
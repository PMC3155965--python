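"""Geographically weighted logistic regression (GWR).

A local logistic model is fitted at each fit point (by default, every
respondent location): observations are weighted by a distance-decay kernel
centred on the fit point, and weighted IRLS yields local coefficients
b_i(u, v).  Comparing the spread of the resulting local odds ratios (their
inter-quartile range) against the global fit quantifies spatial
non-stationarity; a Monte-Carlo permutation test formalizes it.

Kernels: gaussian ``w = exp(-d^2 / (2 h^2))`` or bisquare
``w = (1 - (d/h)^2)^2`` for ``d < h``.  The bandwidth ``h`` is either fixed
(metres) or adaptive (distance to the b-th nearest observation from each fit
point).  Bandwidth selection is by leave-one-out cross-validated Bernoulli
deviance or by a GWR-style AIC with effective parameters from the trace of
the local hat projection.

Geographic distance for weighting is straight-line Euclidean on projected
coordinates; network distance enters the model only as a covariate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .glm import GlmFit, ModelSpec, _design, _irls, fit_logistic, aic as _glm_aic

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "LocalFit",
    "GwrResult",
    "GwrSummaryRow",
    "kernel_weights",
    "fit_gw_logistic",
    "select_bandwidth",
    "summarize_odds_ratios",
    "nonstationarity_test",
    "export_surfaces",
]

_WEIGHT_FLOOR = 1e-12  # observations below this kernel weight are dropped
_MAX_FAILED_FRACTION = 0.20


@dataclass(frozen=True)
class KernelSpec:
    """Kernel type plus bandwidth scheme.

    ``scheme='fixed'``: ``bandwidth`` is in metres.  ``scheme='adaptive'``:
    ``bandwidth`` is a neighbour count; at each fit point the kernel scale is
    the distance to that many nearest observations.
    """

    type: str = "gaussian"
    scheme: str = "adaptive"
    bandwidth: float = 200

    def __post_init__(self) -> None:
        if self.type not in ("gaussian", "bisquare"):
            raise ValueError(f"unknown kernel type {self.type!r}")
        if self.scheme not in ("fixed", "adaptive"):
            raise ValueError(f"unknown bandwidth scheme {self.scheme!r}")
        if not self.bandwidth > 0:
            raise ValueError(f"bandwidth must be > 0, got {self.bandwidth}")


@dataclass
class LocalFit:
    """Coefficients of one kernel-weighted logistic fit."""

    fit_point: tuple[float, float]
    coefficients: np.ndarray | None
    standard_errors: np.ndarray | None
    converged: bool
    weight_sum: float
    reason: str = ""


@dataclass
class GwrResult:
    """All local fits plus the companion global fit."""

    spec: ModelSpec
    kernel: KernelSpec
    local_fits: list[LocalFit]
    global_fit: GlmFit
    fit_points: np.ndarray
    term_names: list[str] = field(init=False)
    _dataset: object = None  # retained for refit-mode surface export

    def __post_init__(self) -> None:
        self.term_names = list(self.global_fit.term_names)

    @property
    def n_converged(self) -> int:
        return sum(f.converged for f in self.local_fits)

    def coefficient_matrix(self) -> np.ndarray:
        """(n_fit_points, k) local coefficients; NaN rows for failed fits."""
        k = len(self.term_names)
        out = np.full((len(self.local_fits), k), np.nan)
        for i, f in enumerate(self.local_fits):
            if f.converged and f.coefficients is not None:
                out[i] = f.coefficients
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f in self.local_fits:
            for j, term in enumerate(self.term_names):
                rows.append(
                    {
                        "u": f.fit_point[0],
                        "v": f.fit_point[1],
                        "term": term,
                        "coefficient": None
                        if f.coefficients is None
                        else float(f.coefficients[j]),
                        "se": None
                        if f.standard_errors is None
                        else float(f.standard_errors[j]),
                        "converged": f.converged,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GwrSummaryRow:
    """Five-number summary of one term's local odds ratios."""

    term: str
    min: float
    q1: float
    median: float
    q3: float
    max: float
    global_or: float
    iqr: float


def kernel_weights(distances, spec: KernelSpec, bandwidth_m: float | None = None):
    """Kernel weights in [0, 1] for geographic distances (metres).

    For the adaptive scheme the caller passes the resolved per-fit-point
    ``bandwidth_m`` (distance to the b-th nearest observation); for the fixed
    scheme it defaults to ``spec.bandwidth``.
    """
    d = np.asarray(distances, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be >= 0")
    h = float(spec.bandwidth if bandwidth_m is None else bandwidth_m)
    if h <= 0:
        raise ValueError(f"bandwidth must be > 0, got {h}")
    if spec.type == "gaussian":
        return np.exp(-0.5 * (d / h) ** 2)
    r = d / h
    w = (1.0 - r**2) ** 2
    w[r >= 1.0] = 0.0
    return w


def _resolve_bandwidth(d: np.ndarray, spec: KernelSpec) -> float:
    if spec.scheme == "fixed":
        return float(spec.bandwidth)
    b = int(spec.bandwidth)
    b = min(max(b, 1), len(d))
    h = float(np.partition(d, b - 1)[b - 1])
    # all-coincident degenerate case: fall back to a tiny positive scale
    return h if h > 0 else 1.0


def _coords(dataset) -> np.ndarray:
    df = dataset.data if hasattr(dataset, "data") else dataset
    return df[["u", "v"]].to_numpy(dtype=float)


def _local_fit(X, y, w, fit_point, start, k):
    keep = w > _WEIGHT_FLOOR
    n_eff = int(keep.sum())
    wsum = float(w[keep].sum())
    if n_eff < k + 2:
        return LocalFit(
            tuple(fit_point), None, None, False, wsum,
            reason=f"only {n_eff} observations with positive weight (< k+2)",
        )
    beta, cov, _, converged, _ = _irls(X[keep], y[keep], w[keep], start=start)
    if not converged or cov is None or not np.all(np.isfinite(beta)):
        return LocalFit(
            tuple(fit_point), None, None, False, wsum,
            reason="local IRLS failed to converge (possible separation or "
            "rank deficiency); consider a larger bandwidth",
        )
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    return LocalFit(tuple(fit_point), beta, se, True, wsum)


def fit_gw_logistic(
    dataset,
    spec: ModelSpec,
    kernel: KernelSpec,
    fit_points: np.ndarray | None = None,
) -> GwrResult:
    """Fit the local logistic model at every fit point.

    ``fit_points`` defaults to the respondent locations.  Local fits that
    cannot converge (too few positive-weight observations, separation) are
    flagged, not imputed; if more than 20% fail the whole fit errors with a
    larger-bandwidth advisory.
    """
    df = dataset.data if hasattr(dataset, "data") else dataset
    X, y = _design(df, spec)
    coords = _coords(dataset)
    fp = coords if fit_points is None else np.asarray(fit_points, dtype=float).reshape(-1, 2)

    global_fit = fit_logistic(df, spec)
    start = global_fit.coefficients
    k = X.shape[1]

    local_fits = []
    for point in fp:
        d = np.hypot(coords[:, 0] - point[0], coords[:, 1] - point[1])
        h = _resolve_bandwidth(d, kernel)
        w = kernel_weights(d, kernel, h)
        local_fits.append(_local_fit(X, y, w, point, start, k))

    n_failed = len(local_fits) - sum(f.converged for f in local_fits)
    if n_failed > _MAX_FAILED_FRACTION * len(local_fits):
        raise RuntimeError(
            f"{n_failed}/{len(local_fits)} local fits failed; "
            "increase the bandwidth (more observations per local fit)"
        )
    if n_failed:
        logger.warning("%d/%d local fits failed and are excluded", n_failed, len(local_fits))
    return GwrResult(
        spec=spec,
        kernel=kernel,
        local_fits=local_fits,
        global_fit=global_fit,
        fit_points=fp,
        _dataset=dataset,
    )


# -- bandwidth selection ----------------------------------------------------

_WORST_DEVIANCE = -2.0 * np.log(1e-12)  # per-observation penalty for failed fits


def _loocv_deviance(X, y, coords, kernel: KernelSpec, start):
    """Out-of-sample Bernoulli deviance: each observation is predicted from
    a local fit at its own location with its own weight zeroed.  Returns a
    per-observation contribution vector (failed local fits carry the
    worst-case penalty); the total is its sum, and keeping the vector lets
    the selector make paired comparisons between candidate bandwidths."""
    k = X.shape[1]
    contribs = np.full(len(y), _WORST_DEVIANCE)
    n_failed = 0
    for i in range(len(y)):
        d = np.hypot(coords[:, 0] - coords[i, 0], coords[:, 1] - coords[i, 1])
        h = _resolve_bandwidth(d, kernel)
        w = kernel_weights(d, kernel, h)
        w[i] = 0.0
        fit = _local_fit(X, y, w, coords[i], start, k)
        if not fit.converged:
            n_failed += 1
            continue
        p = float(expit(X[i] @ fit.coefficients))
        p = min(max(p, 1e-12), 1.0 - 1e-12)
        contribs[i] = -2.0 * (y[i] * np.log(p) + (1.0 - y[i]) * np.log(1.0 - p))
    if n_failed > _MAX_FAILED_FRACTION * len(y):
        return None
    return contribs


def _gwr_aic(X, y, coords, kernel: KernelSpec, start) -> float:
    """GWR-style AIC: -2 sum of local log-likelihood contributions plus
    2 * trace of the hat-like local projection."""
    k = X.shape[1]
    ll = 0.0
    trace = 0.0
    for i in range(len(y)):
        d = np.hypot(coords[:, 0] - coords[i, 0], coords[:, 1] - coords[i, 1])
        h = _resolve_bandwidth(d, kernel)
        w = kernel_weights(d, kernel, h)
        fit = _local_fit(X, y, w, coords[i], start, k)
        if not fit.converged:
            return np.inf
        p = float(expit(X[i] @ fit.coefficients))
        p = min(max(p, 1e-12), 1.0 - 1e-12)
        ll += y[i] * np.log(p) + (1.0 - y[i]) * np.log(1.0 - p)
        keep = w > _WEIGHT_FLOOR
        pk = expit(X[keep] @ fit.coefficients)
        a = w[keep] * pk * (1.0 - pk)
        H = (X[keep] * a[:, None]).T @ X[keep]
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.inf
        ai = w[i] * p * (1.0 - p)
        trace += float(ai * (X[i] @ Hinv @ X[i]))
    return -2.0 * ll + 2.0 * trace


def select_bandwidth(
    dataset,
    spec: ModelSpec,
    kernel_type: str = "gaussian",
    scheme: str = "adaptive",
    criterion: str = "loocv_deviance",
    search_grid=None,
) -> KernelSpec:
    """Choose a bandwidth from an ascending candidate grid.

    ``criterion='loocv_deviance'`` scores each candidate by leave-one-out
    predictive deviance with a paired one-standard-error rule: a smaller
    bandwidth displaces a larger one only when its total score is better by
    more than one standard error of the paired per-observation score
    difference.  This guards against spurious localisation — under a
    stationary truth the largest bandwidth is retained unless localisation
    demonstrably predicts better.  ``criterion='aic'`` uses the GWR AIC with
    plain argmin.  Exact ties always go to the larger bandwidth.
    """
    if search_grid is None or len(search_grid) < 3:
        raise ValueError("search_grid must list at least 3 ascending bandwidths")
    grid = [float(b) for b in search_grid]
    if sorted(grid) != grid:
        raise ValueError("search_grid must be ascending")
    if criterion not in ("loocv_deviance", "aic"):
        raise ValueError(f"unknown criterion {criterion!r}")

    df = dataset.data if hasattr(dataset, "data") else dataset
    X, y = _design(df, spec)
    coords = _coords(dataset)
    start = fit_logistic(df, spec).coefficients

    if criterion == "aic":
        scores = []
        for bw in grid:
            scores.append(_gwr_aic(X, y, coords, KernelSpec(kernel_type, scheme, bw), start))
        finite = [i for i, s in enumerate(scores) if np.isfinite(s)]
        if not finite:
            raise RuntimeError(
                f"no candidate bandwidth produced a valid fit (scores: {scores})"
            )
        best = max(i for i in finite if scores[i] <= min(scores[j] for j in finite))
        logger.info("AIC scores %s -> %s", dict(zip(grid, scores)), grid[best])
        return KernelSpec(kernel_type, scheme, grid[best])

    contrib_vectors = [
        _loocv_deviance(X, y, coords, KernelSpec(kernel_type, scheme, bw), start)
        for bw in grid
    ]
    valid = [i for i, c in enumerate(contrib_vectors) if c is not None]
    if not valid:
        raise RuntimeError("no candidate bandwidth produced a valid fit")
    # walk downwards from the largest valid bandwidth: a smaller candidate
    # wins only if it beats the incumbent by > 1 SE of the paired difference
    best = max(valid)
    for i in sorted(valid, reverse=True):
        if i >= best:
            continue
        diff = contrib_vectors[i] - contrib_vectors[best]
        se = float(np.sqrt(len(diff) * np.var(diff, ddof=1)))
        if float(np.sum(diff)) < -se:
            best = i
    totals = {bw: float(np.sum(c)) if c is not None else np.inf
              for bw, c in zip(grid, contrib_vectors)}
    logger.info("LOOCV scores %s -> selected %s", totals, grid[best])
    return KernelSpec(kernel_type, scheme, grid[best])


# -- summaries and tests ----------------------------------------------------

def summarize_odds_ratios(result: GwrResult) -> list[GwrSummaryRow]:
    """Five-number summaries (linear-interpolation quantiles) of the local
    odds ratios per term, with the global odds ratio attached; failed local
    fits are excluded."""
    B = result.coefficient_matrix()
    ok = ~np.isnan(B[:, 0])
    n_excluded = int((~ok).sum())
    if ok.sum() == 0:
        raise RuntimeError("no converged local fits to summarize")
    if n_excluded:
        logger.warning("excluding %d non-converged local fits from summary", n_excluded)
    rows = []
    for j, term in enumerate(result.term_names):
        if term == "intercept":
            continue
        ors = np.exp(B[ok, j])
        q1, med, q3 = np.quantile(ors, [0.25, 0.5, 0.75])  # type-7 linear
        rows.append(
            GwrSummaryRow(
                term=term,
                min=float(ors.min()),
                q1=float(q1),
                median=float(med),
                q3=float(q3),
                max=float(ors.max()),
                global_or=float(np.exp(result.global_fit.coefficients[j])),
                iqr=float(q3 - q1),
            )
        )
    return rows


def summary_to_dataframe(rows: list[GwrSummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "min": r.min,
                "q1": r.q1,
                "median": r.median,
                "q3": r.q3,
                "max": r.max,
                "global": r.global_or,
                "iqr": r.iqr,
            }
            for r in rows
        ]
    )


def _coefficient_iqrs(result: GwrResult) -> np.ndarray:
    B = result.coefficient_matrix()
    ok = ~np.isnan(B[:, 0])
    q1, q3 = np.quantile(B[ok], [0.25, 0.75], axis=0)
    return q3 - q1


def nonstationarity_test(
    dataset,
    spec: ModelSpec,
    kernel: KernelSpec,
    n_perm: int = 99,
    seed: int = 0,
    fit_points: np.ndarray | None = None,
) -> dict[str, float]:
    """Monte-Carlo permutation test for spatially varying coefficients.

    The observed statistic is each term's inter-quartile range of local
    coefficients.  The null distribution is built by randomly permuting
    respondent coordinates among rows (covariates and outcomes fixed) and
    refitting; ``p = (1 + #{perm >= observed}) / (n_perm + 1)``.  Fit points
    are held fixed across permutations.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    df = dataset.data if hasattr(dataset, "data") else dataset
    coords = _coords(dataset)
    fp = coords if fit_points is None else np.asarray(fit_points, dtype=float).reshape(-1, 2)

    observed = fit_gw_logistic(dataset, spec, kernel, fit_points=fp)
    obs_iqr = _coefficient_iqrs(observed)

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(observed.term_names))
    n_ok = 0
    n_dropped = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(df))
        pdf = df.copy()
        pdf["u"] = coords[perm, 0]
        pdf["v"] = coords[perm, 1]
        try:
            pres = fit_gw_logistic(pdf, spec, kernel, fit_points=fp)
            perm_iqr = _coefficient_iqrs(pres)
        except RuntimeError:
            n_dropped += 1
            continue
        counts += perm_iqr >= obs_iqr
        n_ok += 1
    if n_dropped:
        if n_dropped >= 0.10 * n_perm:
            raise RuntimeError(
                f"{n_dropped}/{n_perm} permutation refits failed; "
                "use a larger bandwidth"
            )
        logger.warning("dropped %d/%d failed permutation refits", n_dropped, n_perm)
    pvals = (1.0 + counts) / (n_ok + 1.0)
    return dict(zip(observed.term_names, pvals))


# -- surface export ---------------------------------------------------------

def export_surfaces(
    result: GwrResult,
    grid_spec: tuple[int, int],
    mode: str = "refit",
    bounds: tuple[float, float, float, float] | None = None,
) -> pd.DataFrame:
    """Coefficient and odds-ratio surfaces on a regular (u, v) grid.

    ``mode='refit'`` refits the local model at each grid node;
    ``'interpolate'`` linearly interpolates the stored local coefficients
    from the fit points.  Cells outside the convex hull of the fit points are
    flagged ``extrapolated``.  Returns a long-format frame
    (u, v, term, coefficient, odds_ratio, extrapolated) ready for mapping.
    """
    if mode not in ("refit", "interpolate"):
        raise ValueError(f"unknown export mode {mode!r}")
    nu, nv = grid_spec
    fp = result.fit_points
    if bounds is None:
        bounds = (fp[:, 0].min(), fp[:, 0].max(), fp[:, 1].min(), fp[:, 1].max())
    u_min, u_max, v_min, v_max = bounds
    gu = np.linspace(u_min, u_max, nu) if nu > 1 else np.array([(u_min + u_max) / 2.0])
    gv = np.linspace(v_min, v_max, nv) if nv > 1 else np.array([(v_min + v_max) / 2.0])
    UU, VV = np.meshgrid(gu, gv)
    grid_points = np.column_stack([UU.ravel(), VV.ravel()])

    from scipy.spatial import Delaunay

    inside = np.ones(len(grid_points), dtype=bool)
    if len(fp) >= 4:
        try:
            hull = Delaunay(fp)
            inside = hull.find_simplex(grid_points) >= 0
        except Exception:  # degenerate (collinear) fit points
            pass

    if mode == "refit":
        refit = fit_gw_logistic(
            result._dataset, result.spec, result.kernel, fit_points=grid_points
        )
        B = refit.coefficient_matrix()
    else:
        from scipy.interpolate import griddata

        B_fit = result.coefficient_matrix()
        ok = ~np.isnan(B_fit[:, 0])
        B = np.column_stack(
            [
                griddata(fp[ok], B_fit[ok, j], grid_points, method="linear")
                for j in range(B_fit.shape[1])
            ]
        )
        # outside-hull cells have no linear value: fall back to nearest
        nanrow = np.isnan(B[:, 0])
        if nanrow.any():
            for j in range(B.shape[1]):
                B[nanrow, j] = griddata(
                    fp[ok], B_fit[ok, j], grid_points[nanrow], method="nearest"
                )

    rows = []
    for i, (pu, pv) in enumerate(grid_points):
        for j, term in enumerate(result.term_names):
            b = B[i, j]
            rows.append(
                {
                    "u": float(pu),
                    "v": float(pv),
                    "term": term,
                    "coefficient": float(b) if np.isfinite(b) else np.nan,
                    "odds_ratio": float(np.exp(b)) if np.isfinite(b) else np.nan,
                    "extrapolated": not bool(inside[i]),
                }
            )
    return pd.DataFrame(rows)


def spearman_surface_recovery(result: GwrResult, surface, term: str) -> float:
    """Spearman rank correlation between a true coefficient surface evaluated
    at the fit points and the estimated local coefficients for ``term``
    (converged fits only)."""
    B = result.coefficient_matrix()
    j = result.term_names.index(term)
    ok = ~np.isnan(B[:, j])
    est = B[ok, j]
    true = np.asarray(surface(result.fit_points[ok, 0], result.fit_points[ok, 1]))
    rx, ry = rankdata(true), rankdata(est)
    return float(np.corrcoef(rx, ry)[0, 1])
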
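"""Binomial logistic regression with AIC model comparison.

The fitting engine is iteratively reweighted least squares (IRLS), i.e.
Newton-Raphson on the Bernoulli log-likelihood with step-halving, supporting
per-observation weights — the same engine drives both the global model
ladder and the kernel-weighted local fits of geographically weighted
regression.

For Bernoulli data the saturated log-likelihood is zero, so deviance equals
minus twice the maximized log-likelihood and AIC = deviance + 2k with k the
number of coefficients.  Odds ratios are exp(b) with Wald intervals on the
log-odds scale; nested models are compared by a sequential analysis of
deviance with chi-square reference distributions.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "GlmFit",
    "OddsRatioRow",
    "DevianceAnovaRow",
    "LadderReport",
    "logit",
    "invlogit",
    "fit_logistic",
    "aic",
    "odds_ratio_table",
    "sequential_deviance",
    "run_model_ladder",
    "gp_ladder",
    "hospital_ladder",
    "GP_DEVIANCE_TERMS",
    "HOSPITAL_DEVIANCE_TERMS",
    "PerfectSeparationWarning",
]

MAX_ITER = 50
TOL = 1e-8


class PerfectSeparationWarning(UserWarning):
    """Fitted probabilities pinned to 0/1; coefficients are diverging."""


def logit(p):
    """Log-odds transform ln(p / (1 - p)); requires 0 < p < 1."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("logit requires probabilities strictly inside (0, 1)")
    out = np.log(p / (1.0 - p))
    return out if out.ndim else float(out)


def invlogit(eta):
    """Inverse logit (logistic function) 1 / (1 + exp(-eta))."""
    out = expit(np.asarray(eta, dtype=float))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ModelSpec:
    """One model in a ladder: an outcome plus an ordered list of terms.

    The intercept is always included and is not listed in ``terms``.
    """

    name: str
    outcome: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        terms = tuple(self.terms)
        object.__setattr__(self, "terms", terms)
        if len(set(terms)) != len(terms):
            raise ValueError(f"{self.name}: duplicate terms in {terms}")


@dataclass
class GlmFit:
    """Result of one weighted logistic fit."""

    spec: ModelSpec
    term_names: list[str]  # "intercept" first
    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    deviance: float
    null_deviance: float
    n: int
    k: int
    converged: bool
    iterations: int

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.term_names.index(term)])

    def se(self, term: str) -> float:
        return float(self.standard_errors[self.term_names.index(term)])


@dataclass(frozen=True)
class OddsRatioRow:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    level: float = 0.95


@dataclass(frozen=True)
class DevianceAnovaRow:
    term: str  # "NULL" for the intercept-only row
    df: int
    residual_df: int
    residual_deviance: float
    deviance_reduction: float | None
    p_value: float | None
    stars: str


# -- core IRLS --------------------------------------------------------------

def _bernoulli_loglik(eta, y, w):
    # y*log p + (1-y)*log(1-p), numerically stable via logaddexp
    return float(np.sum(w * (y * -np.logaddexp(0.0, -eta) + (1.0 - y) * -np.logaddexp(0.0, eta))))


def _irls(X, y, w=None, start=None, tol=TOL, max_iter=MAX_ITER):
    """Weighted Bernoulli IRLS.

    Returns (beta, cov, loglik, converged, iterations).  ``cov`` is the
    inverse of the final weighted information matrix (None if singular).
    """
    n, k = X.shape
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    beta = np.zeros(k) if start is None else np.array(start, dtype=float)
    eta = X @ beta
    ll = _bernoulli_loglik(eta, y, w)
    converged = False
    it = 0
    H = None
    for it in range(1, max_iter + 1):
        p = expit(eta)
        wt = w * p * (1.0 - p)
        H = (X * wt[:, None]).T @ X
        g = X.T @ (w * (y - p))
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, None, ll, False, it
        # step-halving: never accept a likelihood decrease
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new = _bernoulli_loglik(X @ cand, y, w)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            return beta, _safe_inv(H), ll, False, it
        beta = beta + step * delta
        eta = X @ beta
        ll = ll_new
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break
    p = expit(eta)
    wt = w * p * (1.0 - p)
    H = (X * wt[:, None]).T @ X
    return beta, _safe_inv(H), ll, converged, it


def _safe_inv(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None


def _design(df: pd.DataFrame, spec: ModelSpec):
    y = df[spec.outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {spec.outcome!r} must be 0/1 with no missing values")
    cols = [np.ones(len(df))]
    for t in spec.terms:
        if t not in df.columns:
            raise ValueError(f"model term {t!r} is not a dataset column")
        x = df[t].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"model term {t!r} has missing values")
        cols.append(x)
    X = np.column_stack(cols)
    return X, y


def _check_rank(X, term_names, w=None):
    """Raise naming the collinear terms if the (weighted) design is rank
    deficient."""
    Xw = X if w is None else X * np.sqrt(np.maximum(w, 0.0))[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < X.shape[1]:
        # identify columns in the span of their predecessors
        collinear = []
        for j in range(1, X.shape[1]):
            sub = Xw[:, : j + 1]
            if np.linalg.matrix_rank(sub) < j + 1:
                collinear.append(term_names[j])
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear terms: {collinear or term_names}"
        )


def fit_logistic(dataset, spec: ModelSpec, observation_weights=None) -> GlmFit:
    """Maximum-likelihood logistic fit by IRLS.

    ``dataset`` is a SurveyDataset or a DataFrame holding the outcome and
    term columns.  Optional nonnegative ``observation_weights`` scale each
    observation's log-likelihood contribution (used by GWR).  Convergence:
    max |change in b| < 1e-8, at most 50 iterations; on non-convergence the
    fit is returned flagged, with a perfect-separation advisory when fitted
    probabilities pin to 0/1.
    """
    df = dataset.data if hasattr(dataset, "data") else dataset
    X, y = _design(df, spec)
    n = len(y)
    w = None
    if observation_weights is not None:
        w = np.asarray(observation_weights, dtype=float)
        if w.shape != (n,):
            raise ValueError(f"weights must have length {n}")
        if (w < 0).any():
            raise ValueError("observation weights must be nonnegative")
    term_names = ["intercept"] + list(spec.terms)
    _check_rank(X, term_names, w)

    beta, cov, ll, converged, iters = _irls(X, y, w)
    if not converged:
        p = expit(X @ beta)
        eps = 1e-8
        if np.any((p < eps) | (p > 1 - eps)):
            warnings.warn(
                f"{spec.name}: fit did not converge and fitted probabilities "
                "are pinned to 0/1 — data may be perfectly separated",
                PerfectSeparationWarning,
            )
        else:
            warnings.warn(f"{spec.name}: IRLS did not converge in {MAX_ITER} iterations")
    if cov is None:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    # null (intercept-only) deviance under the same weights
    X0 = np.ones((n, 1))
    _, _, ll0, _, _ = _irls(X0, y, w)

    return GlmFit(
        spec=spec,
        term_names=term_names,
        coefficients=beta,
        standard_errors=se,
        covariance=cov,
        log_likelihood=ll,
        deviance=-2.0 * ll,
        null_deviance=-2.0 * ll0,
        n=n,
        k=X.shape[1],
        converged=converged,
        iterations=iters,
    )


def aic(fit: GlmFit) -> float:
    """Akaike information criterion: -2 * log-likelihood + 2 * k."""
    return -2.0 * fit.log_likelihood + 2.0 * fit.k


def odds_ratio_table(fit: GlmFit, level: float = 0.95) -> list[OddsRatioRow]:
    """Per-term odds ratios exp(b) with Wald confidence intervals
    exp(b +/- z * se); the intercept is omitted."""
    z = norm.ppf(0.5 + level / 2.0)
    rows = []
    for j, term in enumerate(fit.term_names):
        if term == "intercept":
            continue
        b, s = fit.coefficients[j], fit.standard_errors[j]
        rows.append(
            OddsRatioRow(
                term=term,
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - z * s)),
                ci_high=float(np.exp(b + z * s)),
                level=level,
            )
        )
    return rows


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def sequential_deviance(dataset, ordered_terms, outcome) -> list[DevianceAnovaRow]:
    """Analysis-of-deviance table for terms added one at a time.

    Starts from the intercept-only (NULL) model; each subsequent row adds one
    term and reports the deviance reduction with a chi-square(1) p-value.  A
    term collinear with those already present gets df = 0, reduction 0 and no
    p-value (rank drop flagged rather than failing).
    """
    df = dataset.data if hasattr(dataset, "data") else dataset
    n = len(df)
    fit0 = fit_logistic(df, ModelSpec("NULL", outcome, ()))
    rows = [
        DevianceAnovaRow(
            term="NULL",
            df=0,
            residual_df=n - 1,
            residual_deviance=fit0.deviance,
            deviance_reduction=None,
            p_value=None,
            stars="",
        )
    ]
    current_terms: list[str] = []
    prev_dev = fit0.deviance
    prev_df = n - 1
    for term in ordered_terms:
        trial = current_terms + [term]
        spec = ModelSpec(f"+{term}", outcome, tuple(trial))
        try:
            fit = fit_logistic(df, spec)
        except ValueError as exc:
            if "rank deficient" in str(exc):
                logger.warning("term %r is collinear with earlier terms; df = 0", term)
                rows.append(
                    DevianceAnovaRow(
                        term=term,
                        df=0,
                        residual_df=prev_df,
                        residual_deviance=prev_dev,
                        deviance_reduction=0.0,
                        p_value=None,
                        stars="",
                    )
                )
                continue
            raise
        current_terms = trial
        reduction = prev_dev - fit.deviance
        p = float(chi2.sf(max(reduction, 0.0), 1))
        prev_df -= 1
        rows.append(
            DevianceAnovaRow(
                term=term,
                df=1,
                residual_df=prev_df,
                residual_deviance=fit.deviance,
                deviance_reduction=reduction,
                p_value=p,
                stars=_stars(p),
            )
        )
        prev_dev = fit.deviance
    return rows


def deviance_table_to_dataframe(rows: list[DevianceAnovaRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "df": r.df,
                "residual_df": r.residual_df,
                "residual_deviance": r.residual_deviance,
                "deviance_reduction": r.deviance_reduction,
                "p_value": r.p_value,
                "stars": r.stars,
            }
            for r in rows
        ]
    )


@dataclass
class LadderReport:
    """Fits, odds-ratio tables and AICs for a ladder of nested models."""

    specs: list[ModelSpec]
    fits: list[GlmFit]
    odds_ratios: list[list[OddsRatioRow]]
    aics: list[float]
    best_index: int = field(init=False)

    def __post_init__(self) -> None:
        self.best_index = int(np.argmin(self.aics))

    @property
    def best_model(self) -> ModelSpec:
        return self.specs[self.best_index]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, (spec, or_rows, a) in enumerate(
            zip(self.specs, self.odds_ratios, self.aics)
        ):
            for r in or_rows:
                rows.append(
                    {
                        "model": spec.name,
                        "term": r.term,
                        "odds_ratio": r.odds_ratio,
                        "ci_low": r.ci_low,
                        "ci_high": r.ci_high,
                        "aic": a,
                        "is_best": i == self.best_index,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["model", "term", "odds_ratio", "ci_low", "ci_high", "aic", "is_best"],
        )


def run_model_ladder(dataset, ladder: list[ModelSpec]) -> LadderReport:
    """Fit every model of a ladder and mark the minimum-AIC model."""
    if not ladder:
        raise ValueError("ladder must contain at least one model")
    outcomes = {s.outcome for s in ladder}
    if len(outcomes) != 1:
        raise ValueError(f"ladder models must share an outcome, got {outcomes}")
    fits = [fit_logistic(dataset, spec) for spec in ladder]
    return LadderReport(
        specs=list(ladder),
        fits=fits,
        odds_ratios=[odds_ratio_table(f) for f in fits],
        aics=[aic(f) for f in fits],
    )


# -- shipped ladders --------------------------------------------------------
#
# GP-difficulty ladder: long-term illness; + bad health; + GP distance;
# + non-car.  Hospital-difficulty ladder: long-term illness; + bad health;
# + plain hospital distance; then the same with ED-hospital distance swapped
# in; + non-car.  The hospital analysis-of-deviance chain skips the plain
# hospital-distance model (models 5 -> 6 -> 8 -> 9).

def gp_ladder() -> list[ModelSpec]:
    y = "y1_gp_difficulty"
    return [
        ModelSpec("Model 1", y, ("x1_lti",)),
        ModelSpec("Model 2", y, ("x1_lti", "x2_bad_health")),
        ModelSpec("Model 3", y, ("x1_lti", "x2_bad_health", "x3_dist_gp_km")),
        ModelSpec(
            "Model 4", y, ("x1_lti", "x2_bad_health", "x3_dist_gp_km", "x4_non_car")
        ),
    ]


def hospital_ladder() -> list[ModelSpec]:
    y = "y2_hospital_difficulty"
    return [
        ModelSpec("Model 5", y, ("x1_lti",)),
        ModelSpec("Model 6", y, ("x1_lti", "x2_bad_health")),
        ModelSpec("Model 7", y, ("x1_lti", "x2_bad_health", "dist_hospital_km")),
        ModelSpec("Model 8", y, ("x1_lti", "x2_bad_health", "x3a_dist_ed_km")),
        ModelSpec(
            "Model 9", y, ("x1_lti", "x2_bad_health", "x3a_dist_ed_km", "x4_non_car")
        ),
    ]


GP_DEVIANCE_TERMS = ("x1_lti", "x2_bad_health", "x3_dist_gp_km", "x4_non_car")
HOSPITAL_DEVIANCE_TERMS = ("x1_lti", "x2_bad_health", "x3a_dist_ed_km", "x4_non_car")
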
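"""Synthetic study generator: region, road network, facilities, respondents.

The original attitudes-survey data behind this kind of accessibility analysis
is rarely distributable, so this module generates surveys with the same
statistical structure: ~8,530 respondents over a county-scale region, a rare
primary-care difficulty outcome (~4.9%) and a commoner hospital difficulty
outcome (~20.2%), binary covariates at realistic prevalences (long-term
illness 33.1%, bad health 4.6%, non-car ownership 16.0%), network distances
to facilities, and outcome models whose coefficients may vary smoothly in
space (e.g. a north-east to south-west gradient).

Randomness: every generation call draws from a single
:class:`numpy.random.Generator` seeded from ``(seed, call-name)``, so calls
are individually reproducible and mutually uncoupled.
"""
from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .network import FacilitySet, RoadGraph, build_graph
from .surfaces import CoefficientSurface, constant, linear_gradient

__all__ = [
    "SyntheticConfig",
    "SurveyDataset",
    "RespondentRecord",
    "generate_network",
    "generate_respondents_and_facilities",
    "simulate_outcomes",
    "calibrate_intercept",
    "study_config",
    "gradient_config",
]

SURVEY_COLUMNS = [
    "id",
    "u",
    "v",
    "x1_lti",
    "x2_bad_health",
    "x4_non_car",
    "x3_dist_gp_km",
    "dist_hospital_km",
    "x3a_dist_ed_km",
    "y1_gp_difficulty",
    "y2_hospital_difficulty",
]
_BINARY_COLUMNS = [
    "x1_lti",
    "x2_bad_health",
    "x4_non_car",
    "y1_gp_difficulty",
    "y2_hospital_difficulty",
]
_DISTANCE_COLUMNS = ["x3_dist_gp_km", "dist_hospital_km", "x3a_dist_ed_km"]


def _rng(seed: int, call_name: str) -> np.random.Generator:
    """One stream per (seed, call-name)."""
    return np.random.default_rng([zlib.crc32(call_name.encode()) % (2**31), int(seed)])


@dataclass
class RespondentRecord:
    """A single survey row; distance and outcome fields stay ``None`` until
    computed/simulated."""

    id: str
    u: float
    v: float
    x1_lti: int
    x2_bad_health: int
    x4_non_car: int
    x3_dist_gp_km: Optional[float] = None
    dist_hospital_km: Optional[float] = None
    x3a_dist_ed_km: Optional[float] = None
    y1_gp_difficulty: Optional[int] = None
    y2_hospital_difficulty: Optional[int] = None


@dataclass
class SurveyDataset:
    """Respondent table plus region bounds and a provenance note.

    ``data`` has the columns of :data:`SURVEY_COLUMNS`; unpopulated distance
    and outcome columns hold NaN.
    """

    data: pd.DataFrame
    region_bounds: tuple[float, float, float, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in SURVEY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"survey table missing columns: {missing}")
        u_min, u_max, v_min, v_max = self.region_bounds
        if not (u_min < u_max and v_min < v_max):
            raise ValueError(f"region bounds not ordered: {self.region_bounds}")
        u, v = self.data["u"], self.data["v"]
        if ((u < u_min) | (u > u_max) | (v < v_min) | (v > v_max)).any():
            raise ValueError("respondent coordinates fall outside region bounds")
        for col in _BINARY_COLUMNS:
            vals = self.data[col].dropna()
            if not vals.isin([0, 1]).all():
                raise ValueError(f"column {col!r} must be 0/1")
        for col in _DISTANCE_COLUMNS:
            vals = self.data[col].dropna()
            if (vals < 0).any() or np.isinf(vals).any():
                raise ValueError(f"column {col!r} must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.data)

    def replace_data(self, df: pd.DataFrame) -> "SurveyDataset":
        return SurveyDataset(df, self.region_bounds, self.provenance)

    def records(self) -> list[RespondentRecord]:
        def opt(x):
            return None if pd.isna(x) else x

        return [
            RespondentRecord(
                id=str(r.id),
                u=float(r.u),
                v=float(r.v),
                x1_lti=int(r.x1_lti),
                x2_bad_health=int(r.x2_bad_health),
                x4_non_car=int(r.x4_non_car),
                x3_dist_gp_km=opt(r.x3_dist_gp_km),
                dist_hospital_km=opt(r.dist_hospital_km),
                x3a_dist_ed_km=opt(r.x3a_dist_ed_km),
                y1_gp_difficulty=None
                if pd.isna(r.y1_gp_difficulty)
                else int(r.y1_gp_difficulty),
                y2_hospital_difficulty=None
                if pd.isna(r.y2_hospital_difficulty)
                else int(r.y2_hospital_difficulty),
            )
            for r in self.data.itertuples()
        ]

    def to_csv(self, path) -> None:
        self.data[SURVEY_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, region_bounds=None, provenance=None) -> "SurveyDataset":
        df = pd.read_csv(path, dtype={"id": str})
        for col in SURVEY_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        if region_bounds is None:
            pad = 1.0
            region_bounds = (
                float(df["u"].min()) - pad,
                float(df["u"].max()) + pad,
                float(df["v"].min()) - pad,
                float(df["v"].max()) + pad,
            )
        return cls(df, region_bounds, provenance or f"file:{path}")


@dataclass
class SyntheticConfig:
    """Everything needed to generate one synthetic study.

    Defaults mirror the emulated study: 8,530 respondents over a ~40x35 km
    region, covariate prevalences 33.1% (long-term illness), 4.6% (bad
    health), 16.0% (non-car), and a conditional link P(LTI | bad health)
    = 0.9 inducing realistic covariate association.  ``surfaces`` maps each
    outcome column to its {term -> CoefficientSurface} generative model.
    """

    region_bounds: tuple[float, float, float, float] = (0.0, 40_000.0, 0.0, 35_000.0)
    n_respondents: int = 8530
    n_gp: int = 30
    n_hospital: int = 8
    n_ed_hospital: int = 3
    prevalence_lti: float = 0.331
    prevalence_bad_health: float = 0.046
    prevalence_non_car: float = 0.160
    lti_given_bad_health: float = 0.9
    surfaces: dict[str, dict[str, CoefficientSurface]] = field(default_factory=dict)
    network_grid: tuple[int, int, float] = (15, 15, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        u_min, u_max, v_min, v_max = self.region_bounds
        if not (u_min < u_max and v_min < v_max):
            raise ValueError(f"region bounds not ordered: {self.region_bounds}")
        for name in (
            "prevalence_lti",
            "prevalence_bad_health",
            "prevalence_non_car",
            "lti_given_bad_health",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name in ("n_respondents", "n_gp", "n_hospital", "n_ed_hospital"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_ed_hospital > self.n_hospital:
            raise ValueError("n_ed_hospital cannot exceed n_hospital")
        rows, cols, jitter = self.network_grid
        if rows < 2 or cols < 2:
            raise ValueError("network grid needs at least 2 rows and 2 columns")
        if jitter < 0:
            raise ValueError("network jitter_sd must be >= 0")

    # -- config file round-trip --------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["region_bounds"] = list(self.region_bounds)
        d["network_grid"] = list(self.network_grid)
        d["surfaces"] = {
            outcome: {term: s.to_dict() for term, s in smap.items()}
            for outcome, smap in self.surfaces.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "region_bounds" in d:
            d["region_bounds"] = tuple(float(x) for x in d["region_bounds"])
        if "network_grid" in d:
            r, c, j = d["network_grid"]
            d["network_grid"] = (int(r), int(c), float(j))
        if "surfaces" in d:
            d["surfaces"] = {
                outcome: {
                    term: CoefficientSurface.from_dict(s) for term, s in smap.items()
                }
                for outcome, smap in d["surfaces"].items()
            }
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        text = open(path).read()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(d)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def generate_network(config: SyntheticConfig, seed: int | None = None) -> RoadGraph:
    """Jittered-lattice road network spanning the region.

    ``rows x cols`` nodes on a regular lattice over ``region_bounds``, node
    coordinates perturbed by N(0, jitter_sd^2), edges between lattice
    neighbours with length equal to the Euclidean distance between the
    jittered endpoints.  Connected by construction.
    """
    seed = config.seed if seed is None else seed
    rows, cols, jitter_sd = config.network_grid
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = _rng(seed, "generate_network")
    u_min, u_max, v_min, v_max = config.region_bounds
    us = np.linspace(u_min, u_max, cols)
    vs = np.linspace(v_min, v_max, rows)
    node_records = []
    for r in range(rows):
        for c in range(cols):
            du, dv = rng.normal(0.0, jitter_sd, size=2) if jitter_sd > 0 else (0.0, 0.0)
            node_records.append(
                {"node_id": f"n{r:03d}_{c:03d}", "u": us[c] + du, "v": vs[r] + dv}
            )
    coords = {rec["node_id"]: (rec["u"], rec["v"]) for rec in node_records}
    edge_records = []
    for r in range(rows):
        for c in range(cols):
            a = f"n{r:03d}_{c:03d}"
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 < rows and c2 < cols:
                    b = f"n{r2:03d}_{c2:03d}"
                    (ua, va), (ub, vb) = coords[a], coords[b]
                    edge_records.append(
                        {
                            "node_a": a,
                            "node_b": b,
                            "length_m": float(np.hypot(ub - ua, vb - va)),
                        }
                    )
    graph = build_graph(edge_records, node_records)
    report = graph.connectivity_report()
    assert report["n_components"] == 1, "lattice network must be connected"
    return graph


def generate_respondents_and_facilities(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[SurveyDataset, FacilitySet]:
    """Respondent locations/covariates and typed facilities.

    Locations are uniform over the region.  Covariates: bad health ``x2 ~
    Bernoulli(prevalence_bad_health)``; long-term illness ``x1`` is drawn
    conditionally on ``x2`` so its marginal matches ``prevalence_lti`` (law
    of total probability); non-car ownership ``x4`` is independent.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "generate_respondents_and_facilities")
    u_min, u_max, v_min, v_max = config.region_bounds

    p_bh = config.prevalence_bad_health
    p_lti = config.prevalence_lti
    p_cond = config.lti_given_bad_health
    if p_bh < 1.0:
        p_star = (p_lti - p_cond * p_bh) / (1.0 - p_bh)
    else:
        p_star = 0.0
    if not 0.0 <= p_star <= 1.0:
        raise ValueError(
            "infeasible long-term-illness marginal: "
            f"prevalence_lti={p_lti}, prevalence_bad_health={p_bh}, "
            f"lti_given_bad_health={p_cond} imply P(LTI | not bad health)="
            f"{p_star:.4f} outside [0, 1]"
        )

    n = config.n_respondents
    u = rng.uniform(u_min, u_max, size=n)
    v = rng.uniform(v_min, v_max, size=n)
    x2 = (rng.random(n) < p_bh).astype(int)
    p_x1 = np.where(x2 == 1, p_cond, p_star)
    x1 = (rng.random(n) < p_x1).astype(int)
    x4 = (rng.random(n) < config.prevalence_non_car).astype(int)

    df = pd.DataFrame(
        {
            "id": [f"r{i:05d}" for i in range(n)],
            "u": u,
            "v": v,
            "x1_lti": x1,
            "x2_bad_health": x2,
            "x4_non_car": x4,
        }
    )
    for col in _DISTANCE_COLUMNS + ["y1_gp_difficulty", "y2_hospital_difficulty"]:
        df[col] = np.nan

    facilities: dict[str, dict] = {}
    for i in range(config.n_gp):
        facilities[f"gp{i:03d}"] = {
            "u": float(rng.uniform(u_min, u_max)),
            "v": float(rng.uniform(v_min, v_max)),
            "type": "GP",
        }
    # ED hospitals are a subset of hospitals: the first n_ed carry the flag
    for i in range(config.n_hospital):
        ftype = "hospital_ED" if i < config.n_ed_hospital else "hospital"
        facilities[f"hosp{i:03d}"] = {
            "u": float(rng.uniform(u_min, u_max)),
            "v": float(rng.uniform(v_min, v_max)),
            "type": ftype,
        }

    dataset = SurveyDataset(
        df,
        config.region_bounds,
        provenance=f"synthetic:{config.content_hash()}:seed={seed}",
    )
    return dataset, FacilitySet(facilities)


def simulate_outcomes(
    dataset: SurveyDataset,
    surfaces: Mapping[str, CoefficientSurface],
    outcome_name: str,
    seed: int,
) -> SurveyDataset:
    """Draw a binary outcome from the spatially varying logistic model.

    For each respondent the linear predictor is ``eta = sum_t b_t(u, v) *
    x_t`` over the surface map's terms (the ``intercept`` term has ``x = 1``),
    and ``y ~ Bernoulli(expit(eta))``.  Distance terms must already be
    populated.
    """
    df = dataset.data
    eta = np.zeros(len(df))
    for term, surface in surfaces.items():
        b = np.asarray(surface(df["u"].to_numpy(), df["v"].to_numpy()), dtype=float)
        if term == "intercept":
            x = 1.0
        else:
            if term not in df.columns:
                raise ValueError(f"surface term {term!r} is not a dataset column")
            col = df[term]
            if col.isna().any():
                raise ValueError(
                    f"surface term {term!r} has missing values; compute "
                    "network distances before simulating a distance-dependent outcome"
                )
            x = col.to_numpy(dtype=float)
        eta = eta + b * x
    p = 1.0 / (1.0 + np.exp(-eta))
    rng = _rng(seed, f"simulate_outcomes:{outcome_name}")
    y = (rng.random(len(df)) < p).astype(int)
    new_df = df.copy()
    new_df[outcome_name] = y
    return dataset.replace_data(new_df)


def calibrate_intercept(
    dataset: SurveyDataset,
    surfaces: Mapping[str, CoefficientSurface],
    target_prevalence: float,
) -> dict[str, CoefficientSurface]:
    """Shift the intercept surface so the population-average outcome
    probability equals ``target_prevalence`` on this dataset.

    Solves for a scalar offset by bisection on the (monotone) mean of
    ``expit(eta + offset)``.  Returns a new surface map.
    """
    from scipy.optimize import brentq
    from scipy.special import expit

    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    df = dataset.data
    eta = np.zeros(len(df))
    for term, surface in surfaces.items():
        b = np.asarray(surface(df["u"].to_numpy(), df["v"].to_numpy()), dtype=float)
        x = 1.0 if term == "intercept" else df[term].to_numpy(dtype=float)
        eta = eta + b * x

    def mean_prob(offset):
        return float(np.mean(expit(eta + offset))) - target_prevalence

    offset = brentq(mean_prob, -40.0, 40.0, xtol=1e-12)
    out = dict(surfaces)
    out["intercept"] = surfaces["intercept"].shifted(offset)
    return out


# -- shipped presets --------------------------------------------------------

def _ne_sw_gradient(
    centre_value: float, span: float, region_bounds
) -> CoefficientSurface:
    """Linear surface rising from the north-east corner to the south-west
    corner, covering ``span`` log-odds units across the region diagonal and
    taking ``centre_value`` at the region centre."""
    u_min, u_max, v_min, v_max = region_bounds
    diag = (u_max - u_min) + (v_max - v_min)
    g = -span / diag  # decreasing in u + v: SW (low u+v) high, NE low
    uc, vc = 0.5 * (u_min + u_max), 0.5 * (v_min + v_max)
    return linear_gradient(centre_value - g * (uc + vc), g, g)


def study_config(n_respondents: int = 8530, seed: int = 0) -> SyntheticConfig:
    """Study-scale configuration with both outcomes.

    Central coefficient values are realistic for the emulated survey:
    GP-difficulty log-odds ratios ~ln(1.80) (long-term illness), ln(1.69)
    (bad health), ln(1.34) per km of GP distance, ln(3.81) (non-car);
    hospital-difficulty analogues ~ln(1.26), ln(1.50), ln(0.991) per km of
    ED distance, ln(1.61).  The non-car and bad-health surfaces carry a mild
    NE->SW gradient; intercepts here are pre-calibration starting points —
    pipelines call :func:`calibrate_intercept` to hit the target outcome
    prevalences (4.9% GP, 20.2% hospital).
    """
    bounds = (0.0, 40_000.0, 0.0, 35_000.0)
    gp_surfaces = {
        "intercept": constant(-3.6),
        "x1_lti": constant(float(np.log(1.80))),
        "x2_bad_health": _ne_sw_gradient(float(np.log(1.69)), 0.3, bounds),
        "x3_dist_gp_km": constant(float(np.log(1.34))),
        "x4_non_car": _ne_sw_gradient(float(np.log(3.81)), 0.3, bounds),
    }
    hosp_surfaces = {
        "intercept": constant(-1.6),
        "x1_lti": constant(float(np.log(1.26))),
        "x2_bad_health": _ne_sw_gradient(float(np.log(1.50)), 0.3, bounds),
        "x3a_dist_ed_km": constant(float(np.log(0.991))),
        "x4_non_car": _ne_sw_gradient(float(np.log(1.61)), 0.3, bounds),
    }
    return SyntheticConfig(
        region_bounds=bounds,
        n_respondents=n_respondents,
        surfaces={
            "y1_gp_difficulty": gp_surfaces,
            "y2_hospital_difficulty": hosp_surfaces,
        },
        seed=seed,
    )


def gradient_config(
    n_respondents: int = 2000,
    seed: int = 0,
    gradient_span: float = 1.5,
    prevalence: float = 0.20,
    gradient_term: str = "x4_non_car",
) -> SyntheticConfig:
    """Spatial-variation preset for GWR exercises.

    One term's coefficient (default non-car ownership) follows a NE->SW
    linear gradient covering ``gradient_span`` log-odds units across the
    region diagonal while the other coefficients are spatially constant, so
    that term's odds ratio varies far more across space than, e.g., the
    long-term-illness one.  ``gradient_span=0`` gives a fully stationary
    model.  The outcome uses the hospital-difficulty scale (default 20%
    prevalence), which keeps local logistic fits well conditioned at
    moderate n.
    """
    bounds = (0.0, 40_000.0, 0.0, 35_000.0)
    surfaces = {
        "intercept": constant(float(np.log(prevalence / (1 - prevalence)))),
        "x1_lti": constant(float(np.log(1.26))),
        "x2_bad_health": constant(float(np.log(1.50))),
        "x4_non_car": constant(float(np.log(1.61))),
    }
    if gradient_term not in surfaces:
        raise ValueError(f"unknown gradient term {gradient_term!r}")
    centre = float(surfaces[gradient_term].params["value"])
    surfaces[gradient_term] = _ne_sw_gradient(centre, gradient_span, bounds)
    return SyntheticConfig(
        region_bounds=bounds,
        n_respondents=n_respondents,
        surfaces={"y2_hospital_difficulty": surfaces},
        seed=seed,
    )
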
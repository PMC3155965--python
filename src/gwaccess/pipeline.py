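"""End-to-end pipeline: simulate -> distances -> GLM ladder -> GWR -> report.

A :class:`PipelineConfig` either points at survey/facility/network files or
carries a synthetic configuration; :func:`run_pipeline` executes the stages
in order under a single top-level seed and assembles a :class:`RunReport`
with odds-ratio ladder tables, analysis-of-deviance tables, GWR local
odds-ratio summaries and coefficient surfaces, plus provenance sufficient to
re-run byte-identically.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .glm import (
    GP_DEVIANCE_TERMS,
    HOSPITAL_DEVIANCE_TERMS,
    ModelSpec,
    deviance_table_to_dataframe,
    gp_ladder,
    hospital_ladder,
    run_model_ladder,
    sequential_deviance,
)
from .gwr import (
    KernelSpec,
    export_surfaces,
    fit_gw_logistic,
    nonstationarity_test,
    select_bandwidth,
    summarize_odds_ratios,
    summary_to_dataframe,
)
from .network import FacilitySet, RoadGraph, nearest_facility_distances
from .synthetic import (
    SurveyDataset,
    SyntheticConfig,
    calibrate_intercept,
    generate_network,
    generate_respondents_and_facilities,
    simulate_outcomes,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run_pipeline", "render_tables"]

GWR_MODEL_PRESETS = {
    "model4": ModelSpec(
        "Model 4",
        "y1_gp_difficulty",
        ("x1_lti", "x2_bad_health", "x3_dist_gp_km", "x4_non_car"),
    ),
    "model9": ModelSpec(
        "Model 9",
        "y2_hospital_difficulty",
        ("x1_lti", "x2_bad_health", "x3a_dist_ed_km", "x4_non_car"),
    ),
}
# terms whose odds ratios are printed to 3 decimals (near-unity per-km effects)
_DISTANCE_TERMS = {"x3_dist_gp_km", "dist_hospital_km", "x3a_dist_ed_km"}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either ``survey_path`` (CSV with the survey schema) or ``synthetic``
    must be provided.  ``ladders`` lists which model ladders to fit
    ("gp", "hospital"); ``gwr_model`` is "model4", "model9" or a mapping
    {name, outcome, terms}; ``gwr_bandwidth`` is a number or "auto".
    """

    out_dir: str = "results"
    seed: int = 0
    survey_path: str | None = None
    facilities_path: str | None = None
    network_edges_path: str | None = None
    network_nodes_path: str | None = None
    synthetic: SyntheticConfig | None = None
    target_prevalences: dict = field(
        default_factory=lambda: {
            "y1_gp_difficulty": 0.049,
            "y2_hospital_difficulty": 0.202,
        }
    )
    ladders: tuple[str, ...] = ("gp", "hospital")
    gwr_model: object = "model9"
    gwr_kernel_type: str = "gaussian"
    gwr_scheme: str = "adaptive"
    gwr_bandwidth: object = "auto"
    gwr_search_grid: tuple[float, ...] | None = None
    gwr_fit_points_max: int | None = None
    n_perm: int = 0
    surface_grid: tuple[int, int] = (20, 20)
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.survey_path is None and self.synthetic is None:
            raise ValueError(
                "config must provide either a survey path or a synthetic block"
            )
        for name in self.ladders:
            if name not in ("gp", "hospital"):
                raise ValueError(f"unknown ladder {name!r}")
        if (
            self.gwr_model is not None
            and isinstance(self.gwr_model, str)
            and self.gwr_model not in GWR_MODEL_PRESETS
        ):
            raise ValueError(f"unknown GWR model preset {self.gwr_model!r}")

    def resolve_gwr_spec(self) -> ModelSpec:
        if isinstance(self.gwr_model, ModelSpec):
            return self.gwr_model
        if isinstance(self.gwr_model, str):
            return GWR_MODEL_PRESETS[self.gwr_model]
        m = dict(self.gwr_model)
        return ModelSpec(m.get("name", "custom"), m["outcome"], tuple(m["terms"]))

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("synthetic", "gwr_model")
        }
        d["ladders"] = list(self.ladders)
        d["surface_grid"] = list(self.surface_grid)
        if self.gwr_search_grid is not None:
            d["gwr_search_grid"] = list(self.gwr_search_grid)
        d["synthetic"] = self.synthetic.to_dict() if self.synthetic else None
        gm = self.gwr_model
        d["gwr_model"] = (
            {"name": gm.name, "outcome": gm.outcome, "terms": list(gm.terms)}
            if isinstance(gm, ModelSpec)
            else gm
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic"):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "ladders" in d:
            d["ladders"] = tuple(d["ladders"])
        if "surface_grid" in d:
            d["surface_grid"] = tuple(d["surface_grid"])
        if d.get("gwr_search_grid") is not None:
            d["gwr_search_grid"] = tuple(d["gwr_search_grid"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = open(path).read()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(d)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    """Assembled outputs of one pipeline run."""

    ladder_tables: dict[str, pd.DataFrame]  # Table-2 analogues per ladder
    deviance_tables: dict[str, pd.DataFrame]  # Table-3 analogues
    gwr_summary: pd.DataFrame | None  # Table-4 analogue
    local_fits: pd.DataFrame | None
    surfaces: pd.DataFrame | None
    permutation_pvalues: dict | None
    files: dict[str, str]
    provenance: dict
    warnings: list[str] = field(default_factory=list)


def _stage(name, fn, *args, **kwargs):
    t0 = time.time()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # annotate with the failing stage
        raise PipelineError(name, str(exc)) from exc
    logger.info("stage %-12s done in %.2fs", name, time.time() - t0)
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage and write all outputs under ``config.out_dir``.

    Synthetic generation is skipped when a survey file is supplied.  All
    randomness derives from ``config.seed``.  On stage failure a ``FAILED``
    marker naming the stage is written and :class:`PipelineError` raised;
    partial outputs are retained.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    report_warnings: list[str] = []
    t_start = time.time()

    try:
        dataset, facilities, graph = _stage("inputs", _load_or_generate, config, out, files)

        if facilities is not None and graph is not None and (
            dataset.data["x3_dist_gp_km"].isna().any()
        ):
            dataset, dist_table = _stage(
                "distances", nearest_facility_distances, dataset, facilities, graph
            )
            dist_table.to_csv(out / "distances.csv")
            files["distances"] = str(out / "distances.csv")

        if config.synthetic is not None:
            dataset = _stage("outcomes", _simulate_all_outcomes, config, dataset)
            dataset.to_csv(out / "survey.csv")
            files["survey"] = str(out / "survey.csv")

        ladder_tables: dict[str, pd.DataFrame] = {}
        deviance_tables: dict[str, pd.DataFrame] = {}
        for name in config.ladders:
            specs = gp_ladder() if name == "gp" else hospital_ladder()
            if dataset.data[specs[0].outcome].isna().any():
                report_warnings.append(f"ladder {name!r} skipped: outcome not populated")
                continue
            ladder = _stage(f"glm_{name}", run_model_ladder, dataset, specs)
            ladder_tables[name] = ladder.to_dataframe()
            path = out / f"table2_{name}.csv"
            ladder_tables[name].to_csv(path, index=False)
            files[f"table2_{name}"] = str(path)
            terms = GP_DEVIANCE_TERMS if name == "gp" else HOSPITAL_DEVIANCE_TERMS
            rows = _stage(
                f"anova_{name}", sequential_deviance, dataset, terms, specs[0].outcome
            )
            deviance_tables[name] = deviance_table_to_dataframe(rows)
            path = out / f"table3_{name}.csv"
            deviance_tables[name].to_csv(path, index=False)
            files[f"table3_{name}"] = str(path)

        gwr_summary = local_fits = surfaces = None
        perm_pvals = None
        spec = None if config.gwr_model is None else config.resolve_gwr_spec()
        if spec is not None and not dataset.data[spec.outcome].isna().any():
            rng = np.random.default_rng([config.seed, 424243])
            fp = None
            if (
                config.gwr_fit_points_max is not None
                and config.gwr_fit_points_max < len(dataset)
            ):
                idx = rng.choice(len(dataset), config.gwr_fit_points_max, replace=False)
                fp = dataset.data[["u", "v"]].to_numpy(dtype=float)[np.sort(idx)]

            if config.gwr_bandwidth == "auto":
                grid = config.gwr_search_grid
                if grid is None:
                    n = len(dataset)
                    grid = tuple(
                        sorted({max(30, n // 8), max(60, n // 4), max(120, n // 2), n})
                    )
                kernel = _stage(
                    "bandwidth",
                    select_bandwidth,
                    dataset,
                    spec,
                    config.gwr_kernel_type,
                    config.gwr_scheme,
                    "loocv_deviance",
                    grid,
                )
            else:
                kernel = KernelSpec(
                    config.gwr_kernel_type, config.gwr_scheme, float(config.gwr_bandwidth)
                )

            result = _stage("gwr", fit_gw_logistic, dataset, spec, kernel, fit_points=fp)
            gwr_summary = summary_to_dataframe(summarize_odds_ratios(result))
            gwr_summary.to_csv(out / "table4.csv", index=False)
            files["table4"] = str(out / "table4.csv")
            local_fits = result.to_dataframe()
            local_fits.to_csv(out / "local_fits.csv", index=False)
            files["local_fits"] = str(out / "local_fits.csv")
            surfaces = _stage("surfaces", export_surfaces, result, config.surface_grid)
            surfaces.to_csv(out / "surfaces.csv", index=False)
            files["surfaces"] = str(out / "surfaces.csv")

            if config.n_perm > 0:
                perm_pvals = _stage(
                    "perm_test",
                    nonstationarity_test,
                    dataset,
                    spec,
                    kernel,
                    config.n_perm,
                    config.seed,
                    fp,
                )
                with open(out / "permutation_pvalues.json", "w") as fh:
                    json.dump(perm_pvals, fh, indent=2)
                files["permutation_pvalues"] = str(out / "permutation_pvalues.json")
        elif spec is not None:
            report_warnings.append("GWR skipped: outcome not populated")

    except PipelineError as exc:
        (out / "FAILED").write_text(f"{exc.stage}: {exc}\n")
        raise

    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "started": t_start,
        "finished": time.time(),
    }
    report = RunReport(
        ladder_tables=ladder_tables,
        deviance_tables=deviance_tables,
        gwr_summary=gwr_summary,
        local_fits=local_fits,
        surfaces=surfaces,
        permutation_pvalues=perm_pvals,
        files=files,
        provenance=provenance,
        warnings=report_warnings,
    )
    with open(out / "report.json", "w") as fh:
        json.dump(
            {"files": files, "provenance": provenance, "warnings": report_warnings},
            fh,
            indent=2,
        )
    files["report"] = str(out / "report.json")
    for path in files.values():
        assert Path(path).exists() and Path(path).stat().st_size > 0, path
    return report


def _load_or_generate(config: PipelineConfig, out: Path, files: dict):
    if config.survey_path is not None:
        dataset = SurveyDataset.from_csv(config.survey_path)
        facilities = graph = None
        if config.facilities_path:
            facilities = (
                FacilitySet.from_geojson(config.facilities_path)
                if str(config.facilities_path).endswith(".geojson")
                else FacilitySet.from_csv(config.facilities_path)
            )
        if config.network_edges_path and config.network_nodes_path:
            graph = RoadGraph.from_csv(config.network_edges_path, config.network_nodes_path)
        return dataset, facilities, graph
    syn = config.synthetic
    graph = generate_network(syn, config.seed)
    dataset, facilities = generate_respondents_and_facilities(syn, config.seed)
    graph.to_csv(out / "network_edges.csv", out / "network_nodes.csv")
    facilities.to_csv(out / "facilities.csv")
    files["network_edges"] = str(out / "network_edges.csv")
    files["network_nodes"] = str(out / "network_nodes.csv")
    files["facilities"] = str(out / "facilities.csv")
    return dataset, facilities, graph


def _simulate_all_outcomes(config: PipelineConfig, dataset: SurveyDataset):
    for outcome, surfaces in config.synthetic.surfaces.items():
        target = config.target_prevalences.get(outcome)
        if target is not None:
            surfaces = calibrate_intercept(dataset, surfaces, target)
        dataset = simulate_outcomes(dataset, surfaces, outcome, config.seed)
    return dataset


# -- table rendering --------------------------------------------------------

def _fmt_or(value: float, term: str) -> str:
    digits = 3 if term in _DISTANCE_TERMS else 2
    return f"{value:.{digits}f}"


def render_tables(report: RunReport, out_dir, format: str = "csv") -> dict[str, str]:
    """Write the report's tables as CSV (full precision) or markdown
    (odds ratios to 2 decimals, near-unity distance odds ratios to 3).
    Returns {table name: path}."""
    if format not in ("csv", "markdown"):
        raise ValueError(f"unknown format {format!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "csv" if format == "csv" else "md"
    written: dict[str, str] = {}

    tables: dict[str, pd.DataFrame] = {}
    for name, df in report.ladder_tables.items():
        tables[f"table2_{name}"] = df
    for name, df in report.deviance_tables.items():
        tables[f"table3_{name}"] = df
    if report.gwr_summary is not None:
        tables["table4"] = report.gwr_summary

    for name, df in tables.items():
        path = out / f"{name}.{ext}"
        if format == "csv":
            df.to_csv(path, index=False)
        else:
            path.write_text(_to_markdown(name, df))
        written[name] = str(path)
    return written


def _to_markdown(name: str, df: pd.DataFrame) -> str:
    df = df.copy()
    if name.startswith("table2"):
        for col in ("odds_ratio", "ci_low", "ci_high"):
            df[col] = [_fmt_or(v, t) for v, t in zip(df[col], df["term"])]
        df["aic"] = df["aic"].map("{:.1f}".format)
        df["model"] = [
            f"**{m}**" if best else m for m, best in zip(df["model"], df["is_best"])
        ]
        df = df.drop(columns=["is_best"])
    elif name.startswith("table3"):
        for col in ("residual_deviance", "deviance_reduction"):
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
        df["p_value"] = df["p_value"].map(lambda v: "" if pd.isna(v) else f"{v:.3g}")
    elif name == "table4":
        for col in ("min", "q1", "median", "q3", "max", "global", "iqr"):
            df[col] = [_fmt_or(v, t) for v, t in zip(df[col], df["term"])]
    header = "| " + " | ".join(df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    body = ["| " + " | ".join(str(x) for x in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep] + body) + "\n"
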
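"""Spatially varying coefficient surfaces.

A :class:`CoefficientSurface` maps planar coordinates ``(u, v)`` (metres) to a
log-odds coefficient value.  Surfaces are the generative counterpart of the
locally varying coefficients that geographically weighted regression
estimates: the synthetic-data generator draws outcomes from a logistic model
whose coefficients are surface evaluations, and recovery tests compare GWR
estimates against the true surface.

Three functional forms are supported:

``constant``
    ``b(u, v) = value`` everywhere.
``linear_gradient``
    ``b(u, v) = value_at_origin + gradient_u * u + gradient_v * v`` — a planar
    trend, e.g. the north-east to south-west gradients typical of county-scale
    accessibility effects.
``gaussian_bump``
    ``b(u, v) = baseline + amplitude * exp(-d^2 / (2 * radius^2))`` with ``d``
    the Euclidean distance to ``centre`` — a localized hot/cold spot.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = [
    "CoefficientSurface",
    "constant",
    "linear_gradient",
    "gaussian_bump",
    "evaluate_surface",
]

SURFACE_FORMS = ("constant", "linear_gradient", "gaussian_bump")

_REQUIRED_PARAMS = {
    "constant": {"value"},
    "linear_gradient": {"value_at_origin", "gradient_u", "gradient_v"},
    "gaussian_bump": {"baseline", "amplitude", "centre", "radius"},
}


@dataclass(frozen=True)
class CoefficientSurface:
    """A named functional form plus its parameters.

    Parameters are kept as a plain mapping so surfaces round-trip losslessly
    through YAML/JSON configuration files.
    """

    form: str
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.form not in SURFACE_FORMS:
            raise ValueError(
                f"unknown surface form {self.form!r}; expected one of {SURFACE_FORMS}"
            )
        missing = _REQUIRED_PARAMS[self.form] - set(self.params)
        if missing:
            raise ValueError(
                f"surface form {self.form!r} missing parameters: {sorted(missing)}"
            )
        if self.form == "gaussian_bump":
            radius = float(self.params["radius"])
            if not radius > 0:
                raise ValueError(f"gaussian_bump radius must be > 0, got {radius}")
        for key, val in self.params.items():
            if key == "centre":
                cu, cv = val
                if not (math.isfinite(cu) and math.isfinite(cv)):
                    raise ValueError("gaussian_bump centre must be finite")
            elif not math.isfinite(float(val)):
                raise ValueError(f"surface parameter {key!r} must be finite")

    def __call__(self, u, v):
        """Evaluate the surface at coordinates (metres); vectorized."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise ValueError("surface evaluation requires finite coordinates")
        p = self.params
        if self.form == "constant":
            out = np.broadcast_to(float(p["value"]), np.broadcast_shapes(u.shape, v.shape))
            return out.copy() if out.ndim else float(out)
        if self.form == "linear_gradient":
            out = (
                float(p["value_at_origin"])
                + float(p["gradient_u"]) * u
                + float(p["gradient_v"]) * v
            )
            return out if np.ndim(out) else float(out)
        # gaussian_bump
        cu, cv = (float(x) for x in p["centre"])
        radius = float(p["radius"])
        d2 = (u - cu) ** 2 + (v - cv) ** 2
        out = float(p["baseline"]) + float(p["amplitude"]) * np.exp(
            -d2 / (2.0 * radius**2)
        )
        return out if np.ndim(out) else float(out)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        params = dict(self.params)
        if "centre" in params:
            params["centre"] = list(params["centre"])
        return {"form": self.form, "params": params}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CoefficientSurface":
        params = dict(d["params"])
        if "centre" in params:
            params["centre"] = tuple(float(x) for x in params["centre"])
        return cls(form=d["form"], params=params)

    def shifted(self, offset: float) -> "CoefficientSurface":
        """Return a copy with `offset` added everywhere (used to calibrate
        intercept surfaces to a target outcome prevalence)."""
        p = dict(self.params)
        if self.form == "constant":
            p["value"] = float(p["value"]) + offset
        elif self.form == "linear_gradient":
            p["value_at_origin"] = float(p["value_at_origin"]) + offset
        else:
            p["baseline"] = float(p["baseline"]) + offset
        return CoefficientSurface(self.form, p)


def constant(value: float) -> CoefficientSurface:
    return CoefficientSurface("constant", {"value": float(value)})


def linear_gradient(
    value_at_origin: float, gradient_u: float, gradient_v: float
) -> CoefficientSurface:
    return CoefficientSurface(
        "linear_gradient",
        {
            "value_at_origin": float(value_at_origin),
            "gradient_u": float(gradient_u),
            "gradient_v": float(gradient_v),
        },
    )


def gaussian_bump(
    baseline: float, amplitude: float, centre: tuple[float, float], radius: float
) -> CoefficientSurface:
    return CoefficientSurface(
        "gaussian_bump",
        {
            "baseline": float(baseline),
            "amplitude": float(amplitude),
            "centre": (float(centre[0]), float(centre[1])),
            "radius": float(radius),
        },
    )


def evaluate_surface(surface: CoefficientSurface, u, v):
    """Functional alias for ``surface(u, v)``."""
    return surface(u, v)
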
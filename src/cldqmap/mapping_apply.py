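"""Serialise fitted mapping algorithms and apply published coefficient
tables to new CLDQ-NASH scores.

The point of a cross-walk study is the published application recipe: a
coefficient table (intercept, basis-term coefficients, knot locations,
link and outcome-scale metadata) that anyone can apply to their own
CLDQ-NASH scores to predict EQ-5D-5L utilities. This module defines that
table as a versioned JSON document, exports it from in-package fits for
every parametric family, validates transcribed tables, and applies them.

Tree/forest and kernel fits have no coefficient representation and are
excluded from export by design.
"""

from __future__ import annotations

import json
from typing import Mapping

import numpy as np
import pandas as pd

from . import mixtures
from .estimators import (FRACTIONAL_FAMILIES, GLM_FAMILIES, FittedModel,
                         FractionalFit, LinearFit, MeanFit, ModelSpec)
from .features import SplineSpec, basis_column_names
from .instruments import CLDQ_DOMAINS

SCHEMA_VERSION = 1


def _spline_to_dict(spline: SplineSpec) -> dict:
    return {"kind": spline.kind, "n_knots": spline.n_knots}


def export_table(fit: FittedModel, provenance: str = "") -> dict:
    """MappingCoefficientTable (JSON-ready dict) from a fitted model."""
    if not fit.converged:
        raise ValueError("cannot export a flagged fit")
    spec = fit.spec
    table = {
        "schema_version": SCHEMA_VERSION,
        "model": {
            "family": spec.family,
            "link": spec.link,
            "power": spec.power,
            "covariate_set": spec.covariate_set,
            "spline": _spline_to_dict(spec.spline),
            "n_components": spec.n_components,
        },
        "knots": {c: [float(v) for v in k] for c, k in fit.knots.items()},
        "outcome_scale": {
            "scale": "rescaled" if fit.bounded and spec.family != "aldvmm"
                     else "natural",
            "floor": fit.floor,
        },
        "provenance": provenance,
    }
    if isinstance(fit, MeanFit):
        table["coefficients"] = {"const": fit.mean}
    elif isinstance(fit, (LinearFit, FractionalFit)):
        table["coefficients"] = {k: float(v) for k, v in fit.params.items()}
    elif isinstance(fit, mixtures.FMMPointMassFit):
        if np.isscalar(fit.ceiling_params):
            ceiling = {"probability": float(fit.ceiling_params)}
        else:
            ceiling = {"coefficients": {k: float(v)
                                        for k, v in fit.ceiling_params.items()}}
        table["mixture"] = {
            "weights": [float(w) for w in fit.weights],
            "components": [
                {"coefficients": dict(zip(fit.design_columns,
                                          map(float, beta))),
                 "sigma": float(s)}
                for beta, s in zip(fit.betas, fit.sigmas)],
            "ceiling": ceiling,
        }
    elif isinstance(fit, mixtures.ALDVMMFit):
        table["mixture"] = {
            "weights": [float(w) for w in fit.weights],
            "components": [
                {"coefficients": dict(zip(fit.design_columns,
                                          map(float, beta))),
                 "sigma": float(s)}
                for beta, s in zip(fit.betas, fit.sigmas)],
            "floor_mass": bool(fit.floor_mass),
        }
    else:
        raise ValueError(
            f"family {spec.family!r} has no coefficient-table representation "
            "(nonparametric fits are excluded from export)")
    return table


def save_table(table: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(table, fh, indent=1)


def load_table(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# validation

def _expected_columns(spec: ModelSpec) -> list[str]:
    cols = ["const"]
    for cov in spec.covariates:
        cols.extend(basis_column_names(cov, spec.spline))
    return cols


def validate_table(table: Mapping) -> dict:
    """Schema and consistency report: {'errors': [...], 'warnings': [...]}.

    Errors block application; the monotonicity check (predicted index
    should not fall as CLDQ-NASH improves) only warns, since a published
    model may legitimately wiggle at the boundary.
    """
    errors: list[str] = []
    warnings: list[str] = []
    for key in ("schema_version", "model", "outcome_scale"):
        if key not in table:
            errors.append(f"missing required field {key!r}")
    if errors:
        return {"errors": errors, "warnings": warnings}

    model = table["model"]
    try:
        spec = _spec_from_dict(model)
    except (ValueError, KeyError, TypeError) as exc:
        return {"errors": [f"invalid model block: {exc}"], "warnings": warnings}

    knots = table.get("knots", {})
    if spec.spline.kind != "none":
        for cov in spec.covariates:
            if cov not in knots:
                errors.append(f"spline model missing knots for {cov!r}")
            else:
                kn = np.asarray(knots[cov], dtype=float)
                if len(kn) != spec.spline.n_knots:
                    errors.append(f"{cov}: {len(kn)} knots stored, spec says "
                                  f"{spec.spline.n_knots}")
                elif np.any(np.diff(kn) <= 0):
                    errors.append(f"{cov}: knots not strictly increasing")

    expected = _expected_columns(spec)
    if "coefficients" in table:
        missing = [c for c in expected if c not in table["coefficients"]]
        if spec.family == "mean":
            missing = [c for c in ["const"] if c not in table["coefficients"]]
        if missing:
            errors.append(f"missing coefficients: {missing}")
        extra = [c for c in table["coefficients"]
                 if c not in expected and spec.family != "mean"]
        if extra:
            errors.append(f"unexpected coefficients: {extra}")
    elif "mixture" in table:
        mix = table["mixture"]
        if "weights" not in mix or "components" not in mix:
            errors.append("mixture block missing weights/components")
        else:
            if abs(sum(mix["weights"]) - 1.0) > 1e-6:
                errors.append("mixture weights do not sum to 1")
            for i, comp in enumerate(mix["components"]):
                miss = [c for c in expected if c not in comp.get("coefficients", {})]
                if miss:
                    errors.append(f"component {i} missing coefficients: {miss}")
                if comp.get("sigma", 0) <= 0:
                    errors.append(f"component {i} has non-positive sigma")
    else:
        errors.append("table has neither 'coefficients' nor 'mixture'")

    if not errors:
        fit = table_to_model(table)
        grid = np.linspace(1.0, 7.0, 61)
        probe = pd.DataFrame({c: grid for c in spec.covariates}) \
            if spec.covariates else pd.DataFrame(index=range(len(grid)))
        if spec.covariates:
            pred = fit.predict(probe)
            floor = table["outcome_scale"]["floor"]
            if np.any(pred < floor - 1e-9) or np.any(pred > 1.0 + 1e-9):
                warnings.append("predictions leave [floor, 1] over the "
                                "covariate range")
            if np.any(np.diff(pred) < -1e-9):
                warnings.append("predicted index is not monotone increasing "
                                "in the CLDQ-NASH score over [1, 7]")
    return {"errors": errors, "warnings": warnings}


def _spec_from_dict(model: Mapping) -> ModelSpec:
    spline = model.get("spline") or {"kind": "none", "n_knots": 0}
    return ModelSpec(
        family=model["family"],
        link=model.get("link"),
        power=model.get("power"),
        covariate_set=model.get("covariate_set", "total"),
        spline=SplineSpec(spline["kind"], spline["n_knots"]),
        n_components=model.get("n_components"),
    )


# ---------------------------------------------------------------------------
# application

def table_to_model(table: Mapping) -> FittedModel:
    """Rebuild a predictor from a coefficient table (exact round trip)."""
    spec = _spec_from_dict(table["model"])
    floor = table["outcome_scale"]["floor"]
    knots = {c: np.asarray(k, dtype=float)
             for c, k in table.get("knots", {}).items()}
    expected = _expected_columns(spec)
    if spec.family == "mean":
        return MeanFit(spec, floor, table["coefficients"]["const"])
    if spec.family in ("ols",) + GLM_FAMILIES:
        params = pd.Series({c: table["coefficients"][c] for c in expected})
        return LinearFit(spec, floor, knots, params)
    if spec.family in FRACTIONAL_FAMILIES:
        params = pd.Series({c: table["coefficients"][c] for c in expected})
        return FractionalFit(spec, floor, knots, params)
    if spec.family in ("fmm_point_mass", "aldvmm"):
        mix = table["mixture"]
        betas = np.array([[comp["coefficients"][c] for c in expected]
                          for comp in mix["components"]])
        sigmas = np.array([comp["sigma"] for comp in mix["components"]])
        weights = np.array(mix["weights"])
        if spec.family == "aldvmm":
            return mixtures.ALDVMMFit(spec, floor, knots, betas, sigmas,
                                      weights, float("nan"), expected,
                                      floor_mass=mix.get("floor_mass", True))
        ceiling = mix["ceiling"]
        if "probability" in ceiling:
            cpar = float(ceiling["probability"])
        else:
            cpar = pd.Series({c: ceiling["coefficients"][c] for c in expected})
        return mixtures.FMMPointMassFit(spec, floor, knots, cpar, weights,
                                        betas, sigmas, float("nan"), expected)
    raise ValueError(f"cannot rebuild family {table['model']['family']!r}")


def apply_mapping(table: Mapping | str, scores: pd.DataFrame) -> np.ndarray:
    """Predicted EQ-5D-5L index for each row of CLDQ-NASH scores.

    ``scores`` must carry the table's covariate set (``cldq_total`` or the
    six domain columns), each on [1, 7]. The saved knots are reused, the
    linear predictor is formed, and the link inverted exactly as in the
    original fit.
    """
    if isinstance(table, str):
        table = load_table(table)
    report = validate_table(table)
    if report["errors"]:
        raise ValueError("invalid mapping table: " + "; ".join(report["errors"]))
    fit = table_to_model(table)
    for cov in fit.spec.covariates:
        if cov not in scores.columns:
            raise ValueError(f"scores frame missing covariate {cov!r}")
        vals = scores[cov].to_numpy(dtype=float)
        if np.any(vals < 1.0) or np.any(vals > 7.0):
            raise ValueError(f"{cov}: CLDQ-NASH scores must lie in [1, 7]")
    return np.asarray(fit.predict(scores), dtype=float)
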
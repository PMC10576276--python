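"""Tenfold cross-validation, the RMSE panel, and model-space ranking.

Every candidate is scored by out-of-sample RMSE from a k-fold (default
ten) cross-validation: the cohort is randomly partitioned into k folds,
each fold is predicted by a model trained on the other k-1, and accuracy
statistics are computed on the combined held-out predictions. RMSE is
reported overall, within three equal-width thirds of the feasible index
range, and within the obesity and type-2-diabetes subgroups — the same
single set of out-of-sample predictions stratified, never refitted per
stratum. The candidate with the lowest overall CV RMSE wins; ties go to
the model with fewer estimated parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .estimators import (GLM_FAMILIES, NOMINAL_POWER_COUNT, FittedModel,
                         FlaggedModel, ModelSpec, fit_model, power_grid)
from .features import SplineSpec

DEFAULT_FOLDS = 10

#: spline options in the default grid: none, linear 2-4 knots, cubic 3-5 knots
SPLINE_OPTIONS = (
    SplineSpec("none"),
    SplineSpec("linear", 2), SplineSpec("linear", 3), SplineSpec("linear", 4),
    SplineSpec("restricted_cubic", 3), SplineSpec("restricted_cubic", 4),
    SplineSpec("restricted_cubic", 5),
)


def kfold_partition(n: int, k: int = DEFAULT_FOLDS, seed: int = 0) -> np.ndarray:
    """Balanced random fold labels (sizes differ by at most one)."""
    if n < 2 * k:
        raise ValueError(f"n={n} too small for {k}-fold cross-validation "
                         f"(need at least {2 * k})")
    labels = np.empty(n, dtype=int)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.arange(n))):
        labels[test_idx] = fold
    return labels


def rmse(predicted, observed) -> float:
    """Root-mean squared error; undefined (NaN) on empty input."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("prediction/observation length mismatch")
    if p.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def segment_bounds(floor: float) -> tuple[float, float]:
    """Cut points splitting [floor, 1] into three equal-width segments."""
    width = (1.0 - floor) / 3.0
    return floor + width, floor + 2.0 * width


def segment_labels(index, floor: float) -> np.ndarray:
    """lower / middle / upper membership of each observed index value.

    Half-open segments, upper closed at 1: [floor, b1), [b1, b2), [b2, 1].
    """
    b1, b2 = segment_bounds(floor)
    arr = np.asarray(index, dtype=float)
    out = np.where(arr < b1, "lower", np.where(arr < b2, "middle", "upper"))
    return out


@dataclass
class CVResult:
    """Out-of-sample predictions and the Table-3-style RMSE panel."""

    spec: ModelSpec
    predictions: np.ndarray          # one out-of-sample prediction per row
    observed: np.ndarray
    fold_labels: np.ndarray
    rmse_panel: dict[str, float]     # overall / lower / middle / upper / subgroups
    flagged: bool = False
    flag_reasons: list[str] = field(default_factory=list)
    clip_count: int = 0              # unbounded-family predictions clipped
    n_params: float = float("nan")

    @property
    def rmse_overall(self) -> float:
        return self.rmse_panel["overall"]


PANEL_KEYS = ("overall", "lower", "middle", "upper",
              "obese", "non_obese", "t2d", "non_t2d")


def rmse_panel(predicted, df: pd.DataFrame, floor: float) -> dict[str, float]:
    """Stratified RMSE panel from one prediction vector.

    Segment membership uses the observed index; subgroup membership the
    obese / t2d flags (NaN where a stratum is empty or a flag is absent).
    """
    observed = df["eq5d_index"].to_numpy(dtype=float)
    panel = {"overall": rmse(predicted, observed)}
    seg = segment_labels(observed, floor)
    for name in ("lower", "middle", "upper"):
        m = seg == name
        panel[name] = rmse(predicted[m], observed[m]) if m.any() else float("nan")
    for key, col, positive in (("obese", "obese", True), ("non_obese", "obese", False),
                               ("t2d", "t2d", True), ("non_t2d", "t2d", False)):
        if col not in df.columns:
            panel[key] = float("nan")
            continue
        flags = df[col].astype(bool).to_numpy()
        m = flags if positive else ~flags
        panel[key] = rmse(predicted[m], observed[m]) if m.any() else float("nan")
    return panel


def cross_validate(spec: ModelSpec, df: pd.DataFrame, floor: float,
                   k: int = DEFAULT_FOLDS, seed: int = 0,
                   fold_labels: np.ndarray | None = None,
                   **fit_options) -> CVResult:
    """k-fold CV of one candidate: every observation predicted exactly once
    by a model that never saw it (knots included: placed on training folds)."""
    data = df.reset_index(drop=True)
    n = len(data)
    if fold_labels is None:
        fold_labels = kfold_partition(n, k, seed)
    predictions = np.full(n, np.nan)
    reasons: list[str] = []
    clip_count = 0
    n_params: float = float("nan")
    for fold in np.unique(fold_labels):
        test = fold_labels == fold
        train_df = data.loc[~test]
        fit = fit_model(spec, train_df, floor, **fit_options)
        if isinstance(fit, FlaggedModel) or not fit.converged:
            reasons.append(f"fold {fold}: {fit.message}")
            continue
        n_params = fit.n_params
        pred = np.asarray(fit.predict(data.loc[test]), dtype=float)
        if not fit.bounded:
            out_of_range = (pred < floor) | (pred > 1.0)
            clip_count += int(out_of_range.sum())
            pred = np.clip(pred, floor, 1.0)
        predictions[test] = pred
    flagged = len(reasons) > 0
    if flagged:
        panel = {key: float("nan") for key in PANEL_KEYS}
    else:
        panel = rmse_panel(predictions, data, floor)
    return CVResult(spec=spec, predictions=predictions,
                    observed=data["eq5d_index"].to_numpy(dtype=float),
                    fold_labels=fold_labels, rmse_panel=panel,
                    flagged=flagged, flag_reasons=reasons,
                    clip_count=clip_count, n_params=n_params)


# ---------------------------------------------------------------------------
# model-space enumeration

def enumerate_model_space(grid: str = "full", seed: int = 0,
                          n_components: int = 2) -> list[ModelSpec]:
    """The candidate grid.

    ``grid='full'`` is the exhaustive Cartesian enumeration: GLM families x
    (identity + log + 100 power links) x 2 covariate sets x 7 spline
    options, plus OLS, fractional logit/probit and the two mixture families
    over covariate sets x splines, the three nonparametric learners over
    covariate sets (basis expansion is inert for trees), and the constant
    benchmark. ``grid='reduced'`` is a small representative sweep with
    every family present, sized for interactive runs and testing.
    """
    if grid == "reduced":
        return _reduced_grid(seed, n_components)
    if grid != "full":
        raise ValueError(f"unknown grid {grid!r}")
    specs: list[ModelSpec] = [ModelSpec("mean", seed=seed)]
    covsets = ("total", "domains")
    for covset in covsets:
        for spline in SPLINE_OPTIONS:
            specs.append(ModelSpec("ols", covariate_set=covset, spline=spline,
                                   seed=seed))
            for fam in ("fractional_logit", "fractional_probit"):
                specs.append(ModelSpec(fam, covariate_set=covset, spline=spline,
                                       seed=seed))
            for fam in ("fmm_point_mass", "aldvmm"):
                specs.append(ModelSpec(fam, covariate_set=covset, spline=spline,
                                       n_components=n_components, seed=seed))
            for fam in GLM_FAMILIES:
                specs.append(ModelSpec(fam, link="identity", covariate_set=covset,
                                       spline=spline, seed=seed))
                specs.append(ModelSpec(fam, link="log", covariate_set=covset,
                                       spline=spline, seed=seed))
                for p in power_grid():
                    specs.append(ModelSpec(fam, link="power", power=float(p),
                                           covariate_set=covset, spline=spline,
                                           seed=seed))
        for fam in ("local_linear", "cart", "random_forest"):
            specs.append(ModelSpec(fam, covariate_set=covset, seed=seed))
    return specs


def _reduced_grid(seed: int, n_components: int) -> list[ModelSpec]:
    rcs3 = SplineSpec("restricted_cubic", 3)
    lin3 = SplineSpec("linear", 3)
    none = SplineSpec()
    nc = n_components
    return [
        ModelSpec("mean", seed=seed),
        ModelSpec("ols", covariate_set="total", seed=seed),
        ModelSpec("ols", covariate_set="domains", seed=seed),
        ModelSpec("ols", covariate_set="total", spline=lin3, seed=seed),
        ModelSpec("glm_gaussian", link="identity", covariate_set="total", seed=seed),
        ModelSpec("glm_gaussian", link="power", power=-0.3,
                  covariate_set="total", spline=rcs3, seed=seed),
        ModelSpec("glm_gaussian", link="log", covariate_set="total", seed=seed),
        ModelSpec("glm_gamma", link="log", covariate_set="total", seed=seed),
        ModelSpec("glm_inverse_gaussian", link="power", power=-2.0,
                  covariate_set="total", seed=seed),
        ModelSpec("fractional_logit", covariate_set="domains", spline=rcs3, seed=seed),
        ModelSpec("fractional_logit", covariate_set="total", spline=none, seed=seed),
        ModelSpec("fractional_probit", covariate_set="total", spline=none, seed=seed),
        ModelSpec("local_linear", covariate_set="total", seed=seed),
        ModelSpec("cart", covariate_set="total", seed=seed),
        ModelSpec("random_forest", covariate_set="total", seed=seed),
        ModelSpec("fmm_point_mass", covariate_set="total", n_components=nc, seed=seed),
        ModelSpec("aldvmm", covariate_set="total", n_components=nc, seed=seed),
    ]


def describe_grid(specs: Sequence[ModelSpec]) -> str:
    """Count and factorisation of a grid, for the run log."""
    by_family: dict[str, int] = {}
    for s in specs:
        by_family[s.family] = by_family.get(s.family, 0) + 1
    parts = ", ".join(f"{fam}: {cnt}" for fam, cnt in sorted(by_family.items()))
    n_powers = len(power_grid())
    return (f"{len(specs)} candidate models ({parts}); power-link grid: "
            f"{NOMINAL_POWER_COUNT} nominal exponents, {n_powers} after "
            f"excluding p=0 (log link covers it)")


# ---------------------------------------------------------------------------
# search and ranking

def run_search(df: pd.DataFrame, specs: Iterable[ModelSpec], floor: float,
               k: int = DEFAULT_FOLDS, seed: int = 0,
               **fit_options) -> list[CVResult]:
    """Cross-validate every spec on the same fold assignment."""
    data = df.reset_index(drop=True)
    fold_labels = kfold_partition(len(data), k, seed)
    return [cross_validate(spec, data, floor, k=k, seed=seed,
                           fold_labels=fold_labels, **fit_options)
            for spec in specs]


def rank_models(results: Sequence[CVResult]) -> pd.DataFrame:
    """Ascending by overall CV RMSE; ties broken by fewer parameters, then
    by the model spec's lexicographic key. Flagged fits are listed separately at
    the bottom with their reasons; all-flagged input is an error."""
    ok = [r for r in results if not r.flagged]
    flagged = [r for r in results if r.flagged]
    if not ok:
        raise ValueError("every candidate fit was flagged; nothing to rank")
    ok_sorted = sorted(ok, key=lambda r: (r.rmse_overall,
                                          r.n_params if math.isfinite(r.n_params) else np.inf,
                                          r.spec.sort_key()))
    rows = []
    for rank, r in enumerate(ok_sorted, start=1):
        row = {"rank": rank, "model": r.spec.family,
               "description": r.spec.label(),
               "covariate_set": r.spec.covariate_set,
               "flagged": False, "clip_count": r.clip_count,
               "n_params": r.n_params}
        for key in PANEL_KEYS:
            row[f"rmse_{key}"] = r.rmse_panel[key]
        rows.append(row)
    for r in flagged:
        row = {"rank": np.nan, "model": r.spec.family,
               "description": r.spec.label(),
               "covariate_set": r.spec.covariate_set,
               "flagged": True, "clip_count": r.clip_count,
               "n_params": r.n_params,
               "flag_reason": "; ".join(r.flag_reasons[:2])}
        for key in PANEL_KEYS:
            row[f"rmse_{key}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
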
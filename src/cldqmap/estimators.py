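"""Candidate model families for the CLDQ-NASH -> EQ-5D-5L mapping.

Every family implements one contract: ``fit_model(spec, train_df)`` returns
a :class:`FittedModel` whose ``predict(df)`` yields predictions on the
natural EQ-5D index scale. Families that model a bounded outcome
(fractional logit/probit, the ceiling point-mass mixture) fit on the
[0, 1] rescaled index and inverse-rescale their predictions; the ALDVMM
works on the natural scale with explicit bounds. Unbounded families (OLS,
GLMs, trees, local-linear) may predict outside [floor, 1]; they are never
clipped here — clipping, with counts, happens at evaluation time.

The GLM grid pairs gaussian, inverse-gaussian and gamma errors with
identity, log and power links g(mu) = mu^p, p on a grid from -5 to 5 in
steps of 0.1 with p = 0 excluded (the log link covers that limit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor
from statsmodels.genmod.families import links as sm_links
from statsmodels.nonparametric.kernel_regression import KernelReg
from statsmodels.tools.sm_exceptions import DomainWarning, PerfectSeparationError

from .features import SplineSpec, build_design, inverse_rescale, rescale
from .instruments import CLDQ_DOMAINS

GLM_FAMILIES = ("glm_gaussian", "glm_inverse_gaussian", "glm_gamma")
FRACTIONAL_FAMILIES = ("fractional_logit", "fractional_probit")
MIXTURE_FAMILIES = ("fmm_point_mass", "aldvmm")
ALL_FAMILIES = (("mean", "ols") + GLM_FAMILIES + FRACTIONAL_FAMILIES
                + ("local_linear", "cart", "random_forest") + MIXTURE_FAMILIES)

#: nominal power-link grid: -5 to 5 in steps of 0.1 (101 values)
NOMINAL_POWER_COUNT = 101


def power_grid() -> np.ndarray:
    """Usable power-link exponents: the 101-value nominal grid minus p = 0."""
    grid = np.round(np.arange(-50, 51) / 10.0, 1)
    assert len(grid) == NOMINAL_POWER_COUNT
    return grid[grid != 0.0]


class FitError(RuntimeError):
    """A fit that cannot proceed or did not converge; flagged, not fatal."""


@dataclass(frozen=True)
class ModelSpec:
    """One point of the candidate-model grid."""

    family: str
    link: str | None = None          # GLMs only: identity | log | power
    power: float | None = None       # exponent for the power link
    covariate_set: str = "total"     # total | domains
    spline: SplineSpec = field(default_factory=SplineSpec)
    n_components: int | None = None  # mixture families only
    seed: int = 0

    def __post_init__(self):
        if self.family not in ALL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        is_glm = self.family in GLM_FAMILIES
        if is_glm:
            if self.link not in ("identity", "log", "power"):
                raise ValueError("GLM families need link in identity/log/power")
            if (self.link == "power") != (self.power is not None):
                raise ValueError("power exponent given iff link is 'power'")
            if self.power == 0:
                raise ValueError("power 0 is the log link; use link='log'")
        elif self.link is not None or self.power is not None:
            raise ValueError(f"family {self.family!r} takes no link")
        if self.family in MIXTURE_FAMILIES:
            if self.n_components is not None and self.n_components < 1:
                raise ValueError("n_components must be >= 1")
        elif self.n_components is not None:
            raise ValueError(f"family {self.family!r} takes no n_components")
        if self.covariate_set not in ("total", "domains"):
            raise ValueError("covariate_set must be 'total' or 'domains'")

    @property
    def covariates(self) -> list[str]:
        if self.family == "mean":
            return []
        if self.covariate_set == "total":
            return ["cldq_total"]
        return list(CLDQ_DOMAINS)

    def label(self) -> str:
        names = {
            "mean": "Constant model",
            "ols": "OLS linear regression",
            "glm_gaussian": "GLM with gaussian family",
            "glm_inverse_gaussian": "GLM with inverse gaussian family",
            "glm_gamma": "GLM with gamma family",
            "fractional_logit": "Fractional logistic",
            "fractional_probit": "Fractional probit",
            "local_linear": "Local-linear regression",
            "cart": "Regression tree",
            "random_forest": "Random forest",
            "fmm_point_mass": "Finite mixture with point mass at 1",
            "aldvmm": "Adjusted limited dependent variable mixture model",
        }
        parts = [names[self.family]]
        if self.family in GLM_FAMILIES:
            if self.link == "power":
                parts[0] += f" and power link (power {self.power:g})"
            else:
                parts[0] += f" and {self.link} link"
        if self.family in MIXTURE_FAMILIES and self.n_components:
            parts[0] += f" ({self.n_components} components)"
        if self.spline.kind != "none":
            parts.append(self.spline.label())
        return ", ".join(parts)

    def sort_key(self) -> tuple:
        """Deterministic lexicographic key used for tie-breaking."""
        return (self.family, self.link or "", self.power if self.power is not None else 0.0,
                self.covariate_set, self.spline.kind, self.spline.n_knots,
                self.n_components or 0)


# ---------------------------------------------------------------------------
# links

class ClippedPower(sm_links.Power):
    """Power link with the working mean clipped to stay positive.

    For non-integer or negative exponents mu^p is undefined at mu <= 0, so
    IRLS working means and linear predictors are floored at a small
    positive epsilon. p = 1 bypasses the clip (it is the identity link and
    must reproduce OLS exactly).
    """

    EPS = 1e-10

    def _pos(self, x):
        return np.clip(x, self.EPS, None)

    def __call__(self, p):
        return super().__call__(self._pos(p))

    def deriv(self, p):
        return super().deriv(self._pos(p))

    def deriv2(self, p):
        return super().deriv2(self._pos(p))

    def inverse(self, z):
        return super().inverse(self._pos(z))

    def inverse_deriv(self, z):
        return super().inverse_deriv(self._pos(z))


def _make_link(link: str, power: float | None):
    if link == "identity":
        return sm_links.Identity()
    if link == "log":
        return sm_links.Log()
    if power == 1.0:
        return sm_links.Power(power=1.0)
    return ClippedPower(power=power)


def _glm_family(family: str, link, power=None):
    # check_link off: the power-link grid pairs every family with
    # exponents statsmodels does not whitelist; validity is our contract
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DomainWarning)
        if family == "glm_gaussian":
            return sm.families.Gaussian(link=link, check_link=False)
        if family == "glm_gamma":
            return sm.families.Gamma(link=link, check_link=False)
        if family == "glm_inverse_gaussian":
            return sm.families.InverseGaussian(link=link, check_link=False)
    raise ValueError(family)


# ---------------------------------------------------------------------------
# fitted-model containers

class FittedModel:
    """Uniform prediction contract: covariate frame -> EQ-5D index scale."""

    #: bounded families guarantee predictions in [floor, 1]
    bounded = False

    def __init__(self, spec: ModelSpec, floor: float,
                 knots: Mapping[str, np.ndarray] | None = None,
                 n_params: float = 0, converged: bool = True, message: str = ""):
        self.spec = spec
        self.floor = floor
        self.knots = dict(knots or {})
        self.n_params = n_params
        self.converged = converged
        self.message = message

    def design(self, df: pd.DataFrame) -> pd.DataFrame:
        X, _ = build_design(df, self.spec.covariates, self.spec.spline, self.knots)
        return X

    def predict(self, df: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class FlaggedModel(FittedModel):
    """Placeholder for a fit that failed; excluded from ranking."""

    def __init__(self, spec, floor, message):
        super().__init__(spec, floor, converged=False, message=message)

    def predict(self, df):
        raise FitError(f"model {self.spec.label()!r} was flagged: {self.message}")


class MeanFit(FittedModel):
    def __init__(self, spec, floor, mean: float):
        super().__init__(spec, floor, n_params=1)
        self.mean = float(mean)

    def predict(self, df):
        return np.full(len(df), self.mean)


class LinearFit(FittedModel):
    """OLS and GLM fits: named coefficients plus an inverse link."""

    def __init__(self, spec, floor, knots, params: pd.Series, sm_result=None):
        super().__init__(spec, floor, knots, n_params=len(params))
        self.params = params
        self.sm_result = sm_result  # kept for diagnostics; not serialised

    def linear_predictor(self, df):
        X = self.design(df)
        if list(X.columns) != list(self.params.index):
            raise FitError("design columns do not match fitted coefficients")
        return X.to_numpy() @ self.params.to_numpy()

    def predict(self, df):
        eta = self.linear_predictor(df)
        spec = self.spec
        if spec.family == "ols" or (spec.family in GLM_FAMILIES and spec.link == "identity"):
            return eta
        if spec.link == "log":
            return np.exp(eta)
        # power link: mu = eta^(1/p); eta floored at the same epsilon as fitting
        p = spec.power
        if p == 1.0:
            return eta
        return np.clip(eta, ClippedPower.EPS, None) ** (1.0 / p)


class FractionalFit(FittedModel):
    bounded = True

    def __init__(self, spec, floor, knots, params: pd.Series, sm_result=None):
        super().__init__(spec, floor, knots, n_params=len(params))
        self.params = params
        self.sm_result = sm_result

    def predict_rescaled(self, df):
        X = self.design(df)
        if list(X.columns) != list(self.params.index):
            raise FitError("design columns do not match fitted coefficients")
        eta = X.to_numpy() @ self.params.to_numpy()
        if self.spec.family == "fractional_logit":
            return expit(eta)
        return norm.cdf(eta)

    def predict(self, df):
        return inverse_rescale(self.predict_rescaled(df), self.floor)


class KernelFit(FittedModel):
    def __init__(self, spec, floor, reg: KernelReg, covariates):
        # effective parameter count of a kernel smoother is data-dependent;
        # use the training size so ties never favour it over parametric fits
        super().__init__(spec, floor, n_params=reg.nobs)
        self.reg = reg
        self.covariates = covariates

    def predict(self, df):
        exog = df[self.covariates].to_numpy(dtype=float)
        mean, _ = self.reg.fit(data_predict=exog)
        return np.asarray(mean)


class SklearnFit(FittedModel):
    def __init__(self, spec, floor, model, covariates, n_params):
        super().__init__(spec, floor, n_params=n_params)
        self.model = model
        self.covariates = covariates

    def predict(self, df):
        return self.model.predict(df[self.covariates].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# fitting

def _prepare(spec: ModelSpec, df: pd.DataFrame):
    X, knots = build_design(df, spec.covariates, spec.spline, None)
    y = df["eq5d_index"].to_numpy(dtype=float)
    return X, y, knots


def fit_mean(spec: ModelSpec, df: pd.DataFrame, floor: float) -> MeanFit:
    y = df["eq5d_index"].to_numpy(dtype=float)
    if len(y) == 0:
        raise FitError("empty training data")
    return MeanFit(spec, floor, np.mean(y))


def fit_ols(spec, df, floor):
    X, y, knots = _prepare(spec, df)
    res = sm.OLS(y, X).fit()
    return LinearFit(spec, floor, knots, pd.Series(res.params, index=X.columns), res)


def fit_glm(spec, df, floor):
    X, y, knots = _prepare(spec, df)
    if spec.family in ("glm_gamma", "glm_inverse_gaussian") and np.any(y <= 0):
        raise FitError(f"{spec.family} requires strictly positive outcomes; "
                       f"training fold contains index values <= 0")
    link = _make_link(spec.link, spec.power)
    fam = _glm_family(spec.family, link)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=fam).fit(maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as exc:
            raise FitError(f"GLM fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError("GLM produced non-finite coefficients")
    if not getattr(res, "converged", True):
        raise FitError("IRLS did not converge within 200 iterations")
    return LinearFit(spec, floor, knots, pd.Series(res.params, index=X.columns), res)


def fit_fractional(spec, df, floor, cov_type: str = "HC0"):
    """Papke-Wooldridge fractional regression: Bernoulli quasi-likelihood on
    the [0, 1]-rescaled index; boundary values are legitimate observations."""
    X, y, knots = _prepare(spec, df)
    y01 = rescale(y, floor)
    link = sm_links.Logit() if spec.family == "fractional_logit" else sm_links.Probit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y01, X, family=sm.families.Binomial(link=link)).fit(
                maxiter=200, cov_type=cov_type)
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as exc:
            raise FitError(f"fractional fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or not getattr(res, "converged", True):
        raise FitError("fractional regression did not converge")
    return FractionalFit(spec, floor, knots, pd.Series(res.params, index=X.columns), res)


def rule_of_thumb_bandwidth(X: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Silverman-style per-dimension bandwidth for the local-linear smoother."""
    n, d = X.shape
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return scale * 1.06 * sd * n ** (-1.0 / (4 + d))


def fit_local_linear(spec, df, floor, bw_scale: float = 1.0):
    cov = spec.covariates
    X = df[cov].to_numpy(dtype=float)
    y = df["eq5d_index"].to_numpy(dtype=float)
    if np.allclose(X.std(axis=0), 0):
        raise FitError("degenerate covariates for local-linear regression")
    bw = rule_of_thumb_bandwidth(X, bw_scale)
    reg = KernelReg(endog=y, exog=X, var_type="c" * X.shape[1],
                    reg_type="ll", bw=bw)
    return KernelFit(spec, floor, reg, cov)


def fit_cart(spec, df, floor, max_depth: int | None = None,
             min_samples_leaf: int = 10):
    if max_depth == 0:  # a single-leaf tree is the constant model
        return fit_mean(replace(spec, family="mean", covariate_set="total",
                                spline=SplineSpec()), df, floor)
    cov = spec.covariates
    X = df[cov].to_numpy(dtype=float)
    y = df["eq5d_index"].to_numpy(dtype=float)
    tree = DecisionTreeRegressor(max_depth=max_depth,
                                 min_samples_leaf=min_samples_leaf,
                                 random_state=spec.seed)
    tree.fit(X, y)
    return SklearnFit(spec, floor, tree, cov, n_params=tree.get_n_leaves())


def fit_random_forest(spec, df, floor, n_estimators: int = 200,
                      min_samples_leaf: int = 5):
    cov = spec.covariates
    X = df[cov].to_numpy(dtype=float)
    y = df["eq5d_index"].to_numpy(dtype=float)
    rf = RandomForestRegressor(n_estimators=n_estimators,
                               min_samples_leaf=min_samples_leaf,
                               random_state=spec.seed, n_jobs=1)
    rf.fit(X, y)
    n_leaves = sum(est.get_n_leaves() for est in rf.estimators_)
    return SklearnFit(spec, floor, rf, cov, n_params=n_leaves)


def fit_model(spec: ModelSpec, df: pd.DataFrame, floor: float,
              **options) -> FittedModel:
    """Fit one candidate model; failures come back as a FlaggedModel.

    ``df`` must carry the scored columns (``cldq_total``, the six domain
    scores, ``eq5d_index``). Mixture families live in
    :mod:`cldqmap.mixtures` and are dispatched from here.
    """
    from . import mixtures  # deferred: mixtures imports this module's types

    dispatch = {
        "mean": fit_mean,
        "ols": fit_ols,
        "glm_gaussian": fit_glm,
        "glm_inverse_gaussian": fit_glm,
        "glm_gamma": fit_glm,
        "fractional_logit": fit_fractional,
        "fractional_probit": fit_fractional,
        "local_linear": fit_local_linear,
        "cart": fit_cart,
        "random_forest": fit_random_forest,
        "fmm_point_mass": mixtures.fit_fmm_point_mass,
        "aldvmm": mixtures.fit_aldvmm,
    }
    try:
        return dispatch[spec.family](spec, df, floor, **options)
    except FitError as exc:
        return FlaggedModel(spec, floor, str(exc))
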
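"""Mixture models for the ceiling-inflated EQ-5D index.

Roughly 40% of respondents in NASH cohorts sit at full health (index
1.00), which a single smooth regression cannot represent. Two families
address this directly:

* ``fmm_point_mass`` — a two-part model: a logistic model for the
  probability of being exactly at the ceiling, combined with a finite
  mixture of Gaussian linear regressions for the interior (y < 1), fitted
  by EM on the [0, 1]-rescaled index. Predictions are the two-part
  expected value.

* ``aldvmm`` — the adjusted limited dependent variable mixture model: a
  C-component mixture of Gaussian linear regressions on the natural index
  scale in which each component is censored at the bounds, so mass
  accumulates at 1 (and optionally at the floor). Maximum likelihood by
  multi-start quasi-Newton; expected values integrate the censored
  components and therefore respect the bounds by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax
from scipy.stats import norm
from statsmodels.tools import numdiff

from .estimators import FitError, FittedModel, ModelSpec
from .features import build_design, inverse_rescale, rescale

CEILING_TOL = 1e-9
DEFAULT_COMPONENTS = 2


# ---------------------------------------------------------------------------
# helpers

def observed_information_se(negloglike, params, **kwargs) -> np.ndarray:
    """Standard errors from the observed information (numerical Hessian)."""
    hess = numdiff.approx_hess(np.asarray(params, float), negloglike, **kwargs)
    cov = np.linalg.inv(hess)
    return np.sqrt(np.clip(np.diag(cov), 0, None))


def _pack_mixture(betas, sigmas, weights):
    """[beta_1..beta_C, log sigma_1..C, mixing logits delta_1..C-1]."""
    C = len(sigmas)
    delta = np.log(weights[:-1]) - np.log(weights[-1])
    return np.concatenate([np.ravel(betas), np.log(sigmas), delta])


def _unpack_mixture(theta, C, k):
    betas = theta[:C * k].reshape(C, k)
    sigmas = np.exp(theta[C * k:C * k + C])
    delta = np.concatenate([theta[C * k + C:], [0.0]])
    weights = softmax(delta)
    return betas, sigmas, weights


# ---------------------------------------------------------------------------
# two-part point-mass mixture

class FMMPointMassFit(FittedModel):
    """Two-part fit: ceiling logistic + interior Gaussian-regression mixture.

    All parameters live on the rescaled [0, 1] outcome scale; ``predict``
    returns natural-index expected values.
    """

    bounded = True

    def __init__(self, spec, floor, knots, ceiling_params, weights, betas,
                 sigmas, interior_loglik, design_columns, reduction=None):
        n_ceiling = 1 if np.isscalar(ceiling_params) else len(ceiling_params)
        n_params = (n_ceiling + np.asarray(betas).size + len(sigmas)
                    + (len(weights) - 1))
        super().__init__(spec, floor, knots, n_params=n_params)
        self.ceiling_params = ceiling_params  # pd.Series or float prob
        self.weights = np.asarray(weights)
        self.betas = np.asarray(betas)
        self.sigmas = np.asarray(sigmas)
        self.interior_loglik = interior_loglik
        self.design_columns = list(design_columns)
        self.reduction = reduction  # logged when a part was empty

    def ceiling_probability(self, df):
        if np.isscalar(self.ceiling_params):
            return np.full(len(df), float(self.ceiling_params))
        X = self.design(df)
        eta = X.to_numpy() @ self.ceiling_params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_rescaled(self, df):
        p1 = self.ceiling_probability(df)
        X = self.design(df).to_numpy()
        interior_mean = (self.weights[None, :] * (X @ self.betas.T)).sum(axis=1)
        # a linear interior mean can stray outside the unit interval; the
        # bounded-contract expectation clips it to the feasible interior
        interior_mean = np.clip(interior_mean, 0.0, 1.0)
        return p1 * 1.0 + (1.0 - p1) * interior_mean

    def predict(self, df):
        return inverse_rescale(self.predict_rescaled(df), self.floor)

    # packed-parameter interior log-likelihood (for observed-information SEs)
    def interior_negloglike(self, X, y):
        C, k = self.betas.shape

        def nll(theta):
            betas, sigmas, weights = _unpack_mixture(theta, C, k)
            comp = (np.log(weights)[None, :]
                    + norm.logpdf(y[:, None], loc=X @ betas.T, scale=sigmas[None, :]))
            return -float(logsumexp(comp, axis=1).sum())

        return nll

    @property
    def packed_interior(self):
        return _pack_mixture(self.betas, self.sigmas, self.weights)


def _em_mixture_regressions(X, y, C, rng, n_restarts=5, max_iter=500, tol=1e-8):
    """EM for a C-component mixture of Gaussian linear regressions."""
    n, k = X.shape
    base = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ base
    sd = max(resid.std(), 1e-3)
    best = None
    for _ in range(max(1, n_restarts)):
        # init: spread component intercepts across residual quantiles, jittered
        offsets = np.quantile(resid, np.linspace(0.2, 0.8, C))
        betas = np.tile(base, (C, 1)) + 0.0
        betas[:, 0] += offsets + rng.normal(0, 0.3 * sd, size=C)
        sigmas = np.full(C, sd)
        weights = np.full(C, 1.0 / C)
        last_ll = -np.inf
        for _it in range(max_iter):
            logcomp = (np.log(weights)[None, :]
                       + norm.logpdf(y[:, None], loc=X @ betas.T,
                                     scale=sigmas[None, :]))
            ll = float(logsumexp(logcomp, axis=1).sum())
            r = np.exp(logcomp - logsumexp(logcomp, axis=1, keepdims=True))
            nk = r.sum(axis=0)
            if np.any(nk < 1e-8):
                break  # degenerate restart
            weights = nk / n
            for c in range(C):
                w = r[:, c]
                WX = X * w[:, None]
                try:
                    betas[c] = np.linalg.solve(WX.T @ X, WX.T @ y)
                except np.linalg.LinAlgError:
                    betas[c] = np.linalg.lstsq(WX.T @ X, WX.T @ y, rcond=None)[0]
                res_c = y - X @ betas[c]
                sigmas[c] = max(np.sqrt((w * res_c ** 2).sum() / nk[c]), 1e-6)
            if ll - last_ll < tol and _it > 2:
                last_ll = ll
                break
            last_ll = ll
        if np.isfinite(last_ll) and (best is None or last_ll > best[0]):
            best = (last_ll, betas.copy(), sigmas.copy(), weights.copy())
    if best is None:
        raise FitError("interior mixture EM failed in every restart")
    ll, betas, sigmas, weights = best
    order = np.argsort(betas[:, 0])  # label switching: order by intercept/mean
    return ll, betas[order], sigmas[order], weights[order]


def fit_fmm_point_mass(spec: ModelSpec, df: pd.DataFrame, floor: float,
                       n_restarts: int = 5,
                       intercept_only_ceiling: bool = False) -> FMMPointMassFit:
    C = spec.n_components or DEFAULT_COMPONENTS
    X_df, knots = build_design(df, spec.covariates, spec.spline, None)
    X = X_df.to_numpy()
    y01 = rescale(df["eq5d_index"].to_numpy(dtype=float), floor)
    at_ceiling = y01 >= 1.0 - CEILING_TOL
    rng = np.random.default_rng(spec.seed)
    reduction = None

    # part 1: ceiling probability
    if intercept_only_ceiling or at_ceiling.all() or not at_ceiling.any():
        ceiling_params = float(at_ceiling.mean())  # Bernoulli ML
        if at_ceiling.all() or not at_ceiling.any():
            reduction = ("ceiling set empty" if not at_ceiling.any()
                         else "interior set empty") + "; part reduced to a constant"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(at_ceiling.astype(float), X_df,
                             family=sm.families.Binomial()).fit(maxiter=200)
            except Exception as exc:  # noqa: BLE001 - flagged upstream
                raise FitError(f"ceiling logistic failed: {exc}") from exc
        if not np.all(np.isfinite(res.params)):
            raise FitError("ceiling logistic produced non-finite coefficients")
        ceiling_params = pd.Series(res.params, index=X_df.columns)

    # part 2: interior mixture
    interior = ~at_ceiling
    if interior.sum() < (C + 1) * X.shape[1]:
        raise FitError("too few interior observations for the mixture part")
    if C == 1:
        beta = np.linalg.lstsq(X[interior], y01[interior], rcond=None)[0]
        resid = y01[interior] - X[interior] @ beta
        sigma = max(np.sqrt(np.mean(resid ** 2)), 1e-8)  # ML variance
        ll = float(norm.logpdf(resid, scale=sigma).sum())
        betas, sigmas, weights = beta[None, :], np.array([sigma]), np.array([1.0])
    else:
        ll, betas, sigmas, weights = _em_mixture_regressions(
            X[interior], y01[interior], C, rng, n_restarts=n_restarts)
    return FMMPointMassFit(spec, floor, knots, ceiling_params, weights, betas,
                           sigmas, ll, X_df.columns, reduction)


# ---------------------------------------------------------------------------
# ALDVMM

class ALDVMMFit(FittedModel):
    """Censored mixture of Gaussian regressions on the natural index scale."""

    bounded = True

    def __init__(self, spec, floor, knots, betas, sigmas, weights, loglik,
                 design_columns, floor_mass=True, n_iter=None):
        C, k = betas.shape
        super().__init__(spec, floor, knots,
                         n_params=C * k + C + (C - 1))
        self.betas = betas
        self.sigmas = sigmas
        self.weights = weights
        self.loglik = loglik
        self.design_columns = list(design_columns)
        self.floor_mass = floor_mass
        self.n_iter = n_iter

    @property
    def packed(self):
        return _pack_mixture(self.betas, self.sigmas, self.weights)

    def component_means(self, df):
        X = self.design(df).to_numpy()
        return X @ self.betas.T  # (n, C) latent means

    def predict(self, df):
        mu = self.component_means(df)
        out = np.zeros(len(df))
        for c in range(len(self.weights)):
            out += self.weights[c] * _censored_expectation(
                mu[:, c], self.sigmas[c], self.floor, self.floor_mass)
        return np.clip(out, self.floor, 1.0)


def _censored_expectation(mu, sigma, floor, floor_mass):
    b = (1.0 - mu) / sigma
    a = (floor - mu) / sigma if floor_mass else np.full_like(mu, -np.inf)
    Fb, Fa = norm.cdf(b), norm.cdf(a)
    interior_p = np.clip(Fb - Fa, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_a = norm.pdf(a) if floor_mass else np.zeros_like(mu)
        trunc = mu + sigma * (phi_a - norm.pdf(b)) / np.where(interior_p > 1e-12,
                                                              interior_p, np.nan)
    exp_val = (1.0 - Fb) * 1.0 + np.where(np.isnan(trunc), 0.0, interior_p * trunc)
    if floor_mass:
        exp_val = exp_val + Fa * floor
    return exp_val


def _aldvmm_parts(theta, X, y, C, floor, floor_mass):
    n, k = X.shape
    betas, sigmas, weights = _unpack_mixture(theta, C, k)
    sigmas = np.clip(sigmas, 1e-6, None)
    mu = X @ betas.T
    at_top = y >= 1.0 - CEILING_TOL
    at_bottom = (y <= floor + CEILING_TOL) & floor_mass
    interior = ~(at_top | at_bottom)
    logf = np.empty((n, C))
    dmu = np.empty((n, C))      # d logf / d mu
    dls = np.empty((n, C))      # d logf / d log sigma
    with np.errstate(divide="ignore", over="ignore"):
        for c in range(C):
            s = sigmas[c]
            b = (1.0 - mu[at_top, c]) / s
            logf[at_top, c] = norm.logsf(b)
            haz = np.exp(norm.logpdf(b) - norm.logsf(b))  # Mills-ratio hazard
            dmu[at_top, c] = haz / s
            dls[at_top, c] = haz * b
            if floor_mass:
                a = (floor - mu[at_bottom, c]) / s
                logf[at_bottom, c] = norm.logcdf(a)
                m = np.exp(norm.logpdf(a) - norm.logcdf(a))
                dmu[at_bottom, c] = -m / s
                dls[at_bottom, c] = -m * a
            z = (y[interior] - mu[interior, c]) / s
            logf[interior, c] = norm.logpdf(y[interior], loc=mu[interior, c], scale=s)
            dmu[interior, c] = z / s
            dls[interior, c] = z ** 2 - 1.0
    logjoint = np.log(weights)[None, :] + logf
    ll_i = logsumexp(logjoint, axis=1)
    resp = np.exp(logjoint - ll_i[:, None])
    return ll_i, resp, dmu, dls, weights


def aldvmm_negloglike(theta, X, y, C, floor, floor_mass=True):
    """Negative log-likelihood of the packed ALDVMM parameter vector."""
    ll_i, *_ = _aldvmm_parts(theta, X, y, C, floor, floor_mass)
    return -float(ll_i.sum())


def aldvmm_negloglike_grad(theta, X, y, C, floor, floor_mass=True):
    """Negative log-likelihood and its analytic gradient."""
    n, k = X.shape
    ll_i, resp, dmu, dls, weights = _aldvmm_parts(theta, X, y, C, floor, floor_mass)
    grad = np.empty_like(theta)
    wmu = resp * dmu
    for c in range(C):
        grad[c * k:(c + 1) * k] = -(wmu[:, c] @ X)
    grad[C * k:C * k + C] = -(resp * dls).sum(axis=0)
    grad[C * k + C:] = -(resp[:, :-1] - weights[None, :-1]).sum(axis=0)
    return -float(ll_i.sum()), grad


def fit_aldvmm(spec: ModelSpec, df: pd.DataFrame, floor: float,
               n_restarts: int = 20, floor_mass: bool = True,
               maxiter: int = 500) -> ALDVMMFit:
    C = spec.n_components or DEFAULT_COMPONENTS
    X_df, knots = build_design(df, spec.covariates, spec.spline, None)
    X = X_df.to_numpy()
    y = df["eq5d_index"].to_numpy(dtype=float)
    n, k = X.shape
    if n < (C + 1) * k + 2:
        raise FitError("too few observations for the requested ALDVMM")
    rng = np.random.default_rng(spec.seed)
    base = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ base
    sd = max(resid.std(), 1e-3)

    best = None
    for r in range(max(1, n_restarts)):
        betas0 = np.tile(base, (C, 1))
        offsets = np.quantile(resid, np.linspace(0.25, 0.75, C))
        betas0[:, 0] += offsets + rng.normal(0, 0.5 * sd, size=C)
        sigmas0 = np.abs(sd * np.exp(rng.normal(0, 0.3, size=C)))
        weights0 = softmax(rng.normal(0, 0.2, size=C))
        theta0 = _pack_mixture(betas0, sigmas0, weights0)
        try:
            res = minimize(aldvmm_negloglike_grad, theta0,
                           args=(X, y, C, floor, floor_mass), jac=True,
                           method="L-BFGS-B",
                           options={"maxiter": maxiter, "maxfun": 20000})
        except (np.linalg.LinAlgError, ValueError):
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        ll = -res.fun
        if np.isfinite(ll) and (best is None or ll > best[0]):
            best = (ll, res.x, res.nit)
    if best is None:
        raise FitError("every ALDVMM restart failed to produce a finite optimum")
    ll, theta, nit = best
    betas, sigmas, weights = _unpack_mixture(theta, C, k)
    # label switching: order components by their mean fitted latent mean
    order = np.argsort((X @ betas.T).mean(axis=0))
    return ALDVMMFit(spec, floor, knots, betas[order], sigmas[order],
                     weights[order], ll, X_df.columns,
                     floor_mass=floor_mass, n_iter=nit)
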
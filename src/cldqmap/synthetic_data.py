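"""Synthetic NASH cohorts with the joint structure the mapping assumes.

The source cohort (a proprietary cross-sectional survey, n = 347) cannot
be redistributed, so every stage of the pipeline is exercised on
generated data that emulates its published structure:

* a single latent health factor drives both instruments, giving the
  positive monotone association between CLDQ-NASH and EQ-5D-5L;
* obese and type-2-diabetes subgroups (prevalences ~0.72 and ~0.56)
  receive a negative latent shift, reproducing the direction of the
  published subgroup contrasts, plus an EQ-5D-specific noise inflation
  emulating comorbidity-driven variability (which makes mapping harder in
  those subgroups);
* ordinal thresholds are calibrated so ~39% of patients land exactly at
  index 1.00 (the ceiling) and the CLDQ-NASH total has mean ~5.4 and
  SD ~1.2.

Calibration is semi-analytic: item-level moments conditional on latent
health are exact normal-CDF expressions, integrated over the
four-subgroup latent mixture by Gauss-Hermite quadrature, so the
calibrated thresholds are deterministic (no Monte Carlo inside the
root-finder). The latent health column is retained for diagnostics only
and must never enter a fitting path.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root
from scipy.stats import norm

from .instruments import (CLDQ_COLUMNS, CLDQ_DOMAINS, EQ5D_COLUMNS, DomainMap,
                          ValueSet, filter_complete_cases, score_cohort)

_GH_NODES = 48


@dataclass(frozen=True)
class CohortParams:
    """Generator configuration; defaults are the emulated study conditions."""

    ceiling_target: float = 0.39       # share of patients at index 1.00
    cldq_mean_target: float = 5.4
    cldq_sd_target: float = 1.2
    p_obese: float = 0.72
    p_t2d: float = 0.56
    shift_obese: float = -0.35         # latent-health shift (SD units)
    shift_t2d: float = -0.35
    loading_cldq: float = 0.75         # item loading on latent health
    loading_eq: float = 0.70           # EQ-5D dimension loading
    eq_noise_mult_obese: float = 1.25  # comorbidity-driven extra EQ-5D noise
    eq_noise_mult_t2d: float = 1.25
    #: spacing of EQ-5D severity thresholds above the calibrated top cut
    eq_threshold_offsets: tuple[float, ...] = (0.9, 1.7, 2.4)

    def __post_init__(self):
        for name in ("ceiling_target", "p_obese", "p_t2d"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not 0 < self.loading_cldq < 1 or not 0 < self.loading_eq < 1:
            raise ValueError("loadings must be in (0, 1)")
        if any(np.diff((0.0,) + self.eq_threshold_offsets) <= 0):
            raise ValueError("threshold offsets must be strictly increasing")


@dataclass(frozen=True)
class CalibratedThresholds:
    cldq: tuple[float, ...]  # 6 cuts for the 7-level items
    eq5d: tuple[float, ...]  # 4 cuts for the 5-level dimensions


def _subgroup_mixture(params: CohortParams):
    """Weights and latent-health means of the 4 obesity x T2D cells."""
    po, pt = params.p_obese, params.p_t2d
    cells = []
    for obese in (0, 1):
        for t2d in (0, 1):
            w = (po if obese else 1 - po) * (pt if t2d else 1 - pt)
            mu = obese * params.shift_obese + t2d * params.shift_t2d
            mult = ((params.eq_noise_mult_obese if obese else 1.0)
                    * (params.eq_noise_mult_t2d if t2d else 1.0))
            cells.append((w, mu, mult))
    return cells


def _gh():
    x, w = np.polynomial.hermite.hermgauss(_GH_NODES)
    return np.sqrt(2.0) * x, w / np.sqrt(np.pi)  # E[f(Z)] = sum w f(node)


#: share of the total-score variance contributed by item-level noise:
#: Var(total | h) = Var(item | h) * (1/36) * sum_d 1/n_d
def _item_variance_weight(domain_map: DomainMap) -> float:
    sizes = [len(domain_map.domains[d]) for d in CLDQ_DOMAINS]
    return sum(1.0 / s for s in sizes) / 36.0


def _cldq_moments(tau: np.ndarray, params: CohortParams,
                  domain_map: DomainMap) -> tuple[float, float]:
    """Exact mean and SD of the CLDQ total under thresholds ``tau``."""
    lam = params.loading_cldq
    s = np.sqrt(1.0 - lam ** 2)
    nodes, wts = _gh()
    vw = _item_variance_weight(domain_map)
    mean_acc = var_between = var_within = 0.0
    total_w = 0.0
    for w_g, mu_g, _ in _subgroup_mixture(params):
        h = mu_g + nodes                                    # (G,)
        z = (tau[None, :] - lam * h[:, None]) / s           # (G, 6)
        upper = norm.cdf(z)
        pmf = np.diff(np.concatenate(
            [np.zeros((len(h), 1)), upper, np.ones((len(h), 1))], axis=1), axis=1)
        levels = np.arange(1, 8)
        e_item = pmf @ levels
        v_item = pmf @ (levels ** 2) - e_item ** 2
        mean_acc += w_g * (wts @ e_item)
        var_between += w_g * (wts @ e_item ** 2)
        var_within += w_g * (wts @ v_item)
        total_w += w_g
    mean = mean_acc / total_w
    var = (var_between / total_w - mean ** 2) + vw * (var_within / total_w)
    return mean, np.sqrt(var)


def _ceiling_probability(t1: float, params: CohortParams) -> float:
    """P(all five EQ-5D dimensions at level 1) given the top threshold."""
    gam = params.loading_eq
    s0 = np.sqrt(1.0 - gam ** 2)
    nodes, wts = _gh()
    acc = 0.0
    for w_g, mu_g, mult in _subgroup_mixture(params):
        h = mu_g + nodes
        p1 = norm.cdf((t1 + gam * h) / (s0 * mult))
        acc += w_g * (wts @ p1 ** 5)
    return acc


def calibrate_thresholds(params: CohortParams,
                         domain_map: DomainMap | None = None,
                         ) -> CalibratedThresholds:
    """Solve for the ordinal thresholds hitting the calibration targets.

    CLDQ cuts are an affine transform ``a + b * tau0`` of equal-probability
    base cuts, with (a, b) solved so the total score matches its
    mean/SD targets; the EQ-5D top cut is solved by monotone root-finding
    on the ceiling share. Unreachable targets raise with the binding
    constraint named.
    """
    if domain_map is None:
        return _calibrate_default(params)
    return _calibrate(params, domain_map)


@lru_cache(maxsize=32)
def _calibrate_default(params: CohortParams) -> CalibratedThresholds:
    return _calibrate(params, DomainMap.default())


def _calibrate(params: CohortParams, domain_map: DomainMap) -> CalibratedThresholds:
    dm = domain_map
    tau0 = norm.ppf(np.arange(1, 7) / 7.0)

    def objective(ab):
        a, b = ab
        mean, sd = _cldq_moments(a + abs(b) * tau0, params, dm)
        return [mean - params.cldq_mean_target, sd - params.cldq_sd_target]

    sol = root(objective, x0=[-1.0, 0.8], method="hybr")
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise ValueError(
            "CLDQ threshold calibration failed: the mean/SD targets "
            f"({params.cldq_mean_target}, {params.cldq_sd_target}) are not "
            "reachable with the configured item loading — the item-level "
            "noise floor bounds the attainable total-score SD")
    a, b = sol.x
    tau = tuple(a + abs(b) * tau0)

    if params.ceiling_target == 0.0:
        t1 = -np.inf
    else:
        lo, hi = -8.0, 8.0
        f = lambda t: _ceiling_probability(t, params) - params.ceiling_target
        if f(lo) > 0 or f(hi) < 0:
            raise ValueError("ceiling_target outside the reachable range for "
                             "the configured EQ-5D loading/noise")
        t1 = brentq(f, lo, hi, xtol=1e-10)
    eq = tuple(t1 + np.asarray((0.0,) + params.eq_threshold_offsets))
    return CalibratedThresholds(cldq=tau, eq5d=eq)


def generate_cohort(n: int, seed: int = 0,
                    params: CohortParams | None = None,
                    domain_map: DomainMap | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort in the patient-CSV schema.

    Deterministic given (n, seed, params). The returned frame carries a
    ``latent_health`` diagnostic column which downstream fitting must
    ignore (the search only ever reads the scored instrument columns).
    """
    params = params or CohortParams()
    thr = calibrate_thresholds(params, domain_map)
    rng = np.random.default_rng(seed)
    obese = rng.random(n) < params.p_obese
    t2d = rng.random(n) < params.p_t2d
    h = (rng.standard_normal(n)
         + params.shift_obese * obese + params.shift_t2d * t2d)

    lam = params.loading_cldq
    s_item = np.sqrt(1.0 - lam ** 2)
    u = lam * h[:, None] + s_item * rng.standard_normal((n, 36))
    cldq_levels = np.digitize(u, thr.cldq) + 1

    gam = params.loading_eq
    mult = np.where(obese, params.eq_noise_mult_obese, 1.0) \
        * np.where(t2d, params.eq_noise_mult_t2d, 1.0)
    s_dim = np.sqrt(1.0 - gam ** 2) * mult
    v = -gam * h[:, None] + s_dim[:, None] * rng.standard_normal((n, 5))
    eq_levels = np.digitize(v, thr.eq5d) + 1

    # BMI drawn to be consistent with the obesity flag (>= 30 kg/m^2)
    bmi = np.where(
        obese,
        np.clip(rng.normal(35.7, 4.8, n), 30.0, 60.0),
        np.clip(rng.normal(26.8, 2.7, n), 16.0, 29.9))

    data = {"patient_id": [f"S{i + 1:05d}" for i in range(n)]}
    for j, col in enumerate(CLDQ_COLUMNS):
        data[col] = cldq_levels[:, j]
    for j, col in enumerate(EQ5D_COLUMNS):
        data[col] = eq_levels[:, j]
    data["bmi"] = np.round(bmi, 1)
    data["obese"] = data["bmi"] >= 30.0
    data["t2d"] = t2d
    data["latent_health"] = h
    return pd.DataFrame(data)


def summarize_cohort(df: pd.DataFrame,
                     value_set: ValueSet | None = None,
                     domain_map: DomainMap | None = None) -> pd.DataFrame:
    """Descriptive table: mean/SD/median/IQR of the CLDQ total, each domain
    and the EQ-5D index — overall and by obesity / T2D status."""
    if len(df) == 0:
        raise ValueError("empty cohort")
    complete, _ = filter_complete_cases(df)
    scored = score_cohort(complete, value_set, domain_map)
    measures = ["cldq_total", *CLDQ_DOMAINS, "eq5d_index"]
    groups = {"overall": np.ones(len(scored), dtype=bool)}
    if "obese" in scored.columns:
        ob = scored["obese"].astype(bool).to_numpy()
        groups["obese"], groups["non_obese"] = ob, ~ob
    if "t2d" in scored.columns:
        td = scored["t2d"].astype(bool).to_numpy()
        groups["t2d"], groups["non_t2d"] = td, ~td
    rows = []
    for m in measures:
        vals = scored[m].to_numpy(dtype=float)
        for stat in ("mean", "sd", "median", "q1", "q3"):
            row = {"measure": m, "stat": stat}
            for gname, mask in groups.items():
                v = vals[mask]
                if len(v) == 0:
                    row[gname] = np.nan
                    continue
                row[gname] = {
                    "mean": np.mean(v),
                    "sd": np.std(v, ddof=1) if len(v) > 1 else 0.0,
                    "median": np.median(v),
                    "q1": np.quantile(v, 0.25),
                    "q3": np.quantile(v, 0.75),
                }[stat]
            rows.append(row)
    return pd.DataFrame(rows).set_index(["measure", "stat"])
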
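"""Outcome rescaling and spline basis construction for the mapping models.

Bounded model families (fractional regression, the ceiling point-mass
mixture) work on the unit interval, so the EQ-5D index is mapped
affinely from [floor, 1] to [0, 1] and predictions are mapped back.

Candidate models may expand the CLDQ-NASH covariates with linear splines
(2-4 equally spaced knots) or restricted cubic splines (3-5 knots at
Harrell's default quantiles). The restricted cubic basis is linear beyond
the boundary knots and has k-1 columns including the identity term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

#: Harrell's default knot quantiles by number of knots.
HARRELL_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}

SplineKind = Literal["none", "linear", "restricted_cubic"]


def rescale(index, floor: float):
    """Map the EQ-5D index affinely from [floor, 1] onto [0, 1]."""
    arr = np.asarray(index, dtype=float)
    if np.any(arr < floor - 1e-9) or np.any(arr > 1 + 1e-9):
        raise ValueError(f"index outside [{floor}, 1]")
    out = (arr - floor) / (1.0 - floor)
    return float(out) if np.isscalar(index) else out


def inverse_rescale(r, floor: float):
    """Inverse of :func:`rescale`; exact affine round trip."""
    arr = np.asarray(r, dtype=float)
    out = arr * (1.0 - floor) + floor
    return float(out) if np.isscalar(r) else out


@dataclass(frozen=True)
class SplineSpec:
    """Covariate expansion: none, or a spline family with its knot count.

    The same spec applies to every covariate of a model (total score, or
    each of the six domain scores).
    """

    kind: SplineKind = "none"
    n_knots: int = 0

    def __post_init__(self):
        if self.kind == "none":
            if self.n_knots:
                raise ValueError("kind='none' takes no knots")
        elif self.kind == "linear":
            if not 2 <= self.n_knots <= 4:
                raise ValueError("linear splines use 2-4 knots")
        elif self.kind == "restricted_cubic":
            if not 3 <= self.n_knots <= 5:
                raise ValueError("restricted cubic splines use 3-5 knots")
        else:
            raise ValueError(f"unknown spline kind {self.kind!r}")

    @property
    def n_basis_columns(self) -> int:
        """Columns per covariate, including the identity term."""
        if self.kind == "none":
            return 1
        if self.kind == "linear":
            return self.n_knots + 1
        return self.n_knots - 1

    def label(self) -> str:
        if self.kind == "none":
            return "no splines"
        if self.kind == "linear":
            return f"linear splines with {self.n_knots} knots"
        return f"cubic splines with {self.n_knots} knots"


def equal_spaced_knots(lo: float, hi: float, n_knots: int) -> np.ndarray:
    """Interior knots splitting [lo, hi] into n_knots + 1 equal intervals."""
    if not 2 <= n_knots <= 4:
        raise ValueError("linear-spline knot count must be 2-4")
    if not hi > lo:
        raise ValueError("degenerate covariate range; cannot place knots")
    step = (hi - lo) / (n_knots + 1)
    return lo + step * np.arange(1, n_knots + 1)


def harrell_knots(x, n_knots: int) -> np.ndarray:
    """Knots at Harrell's default quantiles of the observed covariate."""
    if n_knots not in HARRELL_QUANTILES:
        raise ValueError("restricted-cubic knot count must be 3-5")
    arr = np.asarray(x, dtype=float)
    knots = np.quantile(arr, HARRELL_QUANTILES[n_knots])
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            "tied quantiles collapse the knot sequence; reduce n_knots or "
            "supply knots explicitly")
    return knots


def linear_spline_basis(x, knots) -> np.ndarray:
    """Identity column plus one hinge (x - k)+ per knot."""
    arr = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    cols = [arr] + [np.clip(arr - k, 0.0, None) for k in knots]
    return np.column_stack(cols)


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (identity plus k-2 nonlinear terms).

    Natural-spline construction: truncated cubics combined so the curve is
    linear beyond the boundary knots, normalised by the squared knot span
    so coefficients stay on a comparable scale.
    """
    arr = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    if t.ndim != 1 or len(t) < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")
    k = len(t)
    norm = (t[-1] - t[0]) ** 2

    def cube(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [arr]
    for j in range(k - 2):
        term = (cube(arr - t[j])
                - cube(arr - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + cube(arr - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2]))
        cols.append(term / norm)
    return np.column_stack(cols)


def place_knots(x, spline: SplineSpec) -> np.ndarray | None:
    """Knot locations for one covariate under a SplineSpec.

    Linear-spline knots are equally spaced over the observed range;
    restricted-cubic knots sit at Harrell's quantiles. Placement uses the
    data passed in (during cross-validation: the training folds).
    """
    if spline.kind == "none":
        return None
    arr = np.asarray(x, dtype=float)
    if spline.kind == "linear":
        return equal_spaced_knots(arr.min(), arr.max(), spline.n_knots)
    return harrell_knots(arr, spline.n_knots)


def basis_column_names(cov: str, spline: SplineSpec) -> list[str]:
    if spline.kind == "none":
        return [cov]
    if spline.kind == "linear":
        return [cov] + [f"{cov}_ls{j}" for j in range(1, spline.n_knots + 1)]
    return [cov] + [f"{cov}_rcs{j}" for j in range(1, spline.n_knots - 1)]


def build_design(df: pd.DataFrame, covariates: list[str], spline: SplineSpec,
                 knots: Mapping[str, np.ndarray] | None = None,
                 ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Basis-expanded design matrix with an intercept column ``const``.

    If ``knots`` is None they are placed from ``df`` (training data) and
    returned so validation/application can reuse them bit-identically.
    """
    if knots is None:
        knots = {}
        for cov in covariates:
            kn = place_knots(df[cov].to_numpy(), spline)
            if kn is not None:
                knots[cov] = kn
    blocks = {"const": np.ones(len(df))}
    for cov in covariates:
        x = df[cov].to_numpy(dtype=float)
        if spline.kind == "none":
            mat = x[:, None]
        elif spline.kind == "linear":
            mat = linear_spline_basis(x, knots[cov])
        else:
            mat = rcs_basis(x, knots[cov])
        for name, col in zip(basis_column_names(cov, spline), mat.T):
            blocks[name] = col
    X = pd.DataFrame(blocks, index=df.index)
    return X, {c: np.asarray(k) for c, k in knots.items()}
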
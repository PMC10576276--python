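"""Scoring of the CLDQ-NASH and the EQ-5D-5L from raw item responses.

The CLDQ-NASH has 36 items on a 1-7 Likert scale (higher = better health)
grouped into six domains (abdominal, activity/energy, emotional, fatigue,
systemic, worry). Each domain score is the mean of its items and the total
score is the mean of the six domain scores, so every score lives on [1, 7].

The EQ-5D-5L describes a health state by five dimensions (mobility,
self-care, usual activities, pain/discomfort, anxiety/depression), each on
five severity levels. A country-specific value set converts the state into
a single utility index: the respondent starts at 1.00 (full health) and
each dimension/level pair subtracts a tariff decrement. The bundled US
societal value set has floor -0.573 (the all-5s state).

Scoring is strict complete-case per instrument: a record missing any item
of an instrument gets no score for that instrument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EQ5D_DIMENSIONS = ("mobility", "self_care", "usual_activities",
                   "pain_discomfort", "anxiety_depression")
#: CSV column names, in instrument order.
EQ5D_COLUMNS = ("eq5d_mo", "eq5d_sc", "eq5d_ua", "eq5d_pd", "eq5d_ad")
CLDQ_COLUMNS = tuple(f"cldq_{i:02d}" for i in range(1, 37))
CLDQ_DOMAINS = ("abdominal", "activity", "emotional", "fatigue",
                "systemic", "worry")

OBESITY_BMI_CUTOFF = 30.0


def _load_bundled(name: str) -> dict:
    with resources.files("cldqmap.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class ValueSet:
    """An EQ-5D-5L tariff: per-dimension, per-level decrements from 1.00.

    ``decrements[dim][level - 1]`` is the amount subtracted from the
    baseline score of 1 when ``dim`` is at ``level``. Level 1 must carry a
    zero decrement in every dimension; the floor (index of the all-5s
    state) is derived, never stored independently.
    """

    name: str
    decrements: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        for dim in EQ5D_DIMENSIONS:
            if dim not in self.decrements:
                raise ValueError(f"value set {self.name!r} missing dimension {dim!r}")
            decs = self.decrements[dim]
            if len(decs) != 5:
                raise ValueError(f"{dim}: expected 5 per-level decrements, got {len(decs)}")
            if decs[0] != 0.0:
                raise ValueError(f"{dim}: level-1 decrement must be 0, got {decs[0]}")

    @property
    def floor(self) -> float:
        """Index of the worst state (level 5 in every dimension)."""
        return 1.0 - sum(self.decrements[d][4] for d in EQ5D_DIMENSIONS)

    @classmethod
    def us5l(cls) -> "ValueSet":
        """The bundled US societal 5L set; self-validates its -0.573 floor."""
        raw = _load_bundled("us5l_pickard.json")
        vs = cls(name=raw["name"], decrements=raw["decrements"])
        expected = raw["expected_floor"]
        if abs(vs.floor - expected) > 1e-12:
            raise RuntimeError(
                f"bundled value set corrupt: derived floor {vs.floor}, expected {expected}")
        return vs

    @classmethod
    def from_json(cls, path: str) -> "ValueSet":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(name=raw["name"], decrements=raw["decrements"])


@dataclass(frozen=True)
class DomainMap:
    """Assignment of the 36 CLDQ-NASH items to the six domains (1-based)."""

    name: str
    domains: Mapping[str, Sequence[int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for dom in CLDQ_DOMAINS:
            items = self.domains.get(dom)
            if not items:
                raise ValueError(f"domain map {self.name!r} missing domain {dom!r}")
            for it in items:
                if not 1 <= it <= 36:
                    raise ValueError(f"item number {it} outside 1..36")
                if it in seen:
                    raise ValueError(f"item {it} assigned to more than one domain")
                seen.add(it)
        if len(seen) != 36:
            raise ValueError(f"domain map covers {len(seen)} items, expected 36")

    @classmethod
    def default(cls) -> "DomainMap":
        raw = _load_bundled("cldq_nash_domains.json")
        return cls(name=raw["name"], domains=raw["domains"])

    @classmethod
    def from_json(cls, path: str) -> "DomainMap":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(name=raw["name"], domains=raw["domains"])


@dataclass(frozen=True)
class CLDQScores:
    domain_scores: Mapping[str, float]
    total: float


def score_cldq(items: Sequence[float], domain_map: DomainMap | None = None) -> CLDQScores:
    """Score one respondent's 36 CLDQ-NASH items.

    Raises ``ValueError`` if any item is missing or outside {1..7}; the
    caller flags such records incomplete rather than imputing.
    """
    domain_map = domain_map or DomainMap.default()
    arr = np.asarray(items, dtype=float)
    if arr.shape != (36,):
        raise ValueError(f"expected 36 items, got shape {arr.shape}")
    if np.isnan(arr).any():
        raise ValueError("missing CLDQ-NASH item; record is incomplete")
    if ((arr < 1) | (arr > 7)).any() or (arr != np.round(arr)).any():
        raise ValueError("CLDQ-NASH responses must be integers in 1..7")
    domain_scores = {
        dom: float(np.mean([arr[i - 1] for i in domain_map.domains[dom]]))
        for dom in CLDQ_DOMAINS
    }
    total = float(np.mean(list(domain_scores.values())))
    return CLDQScores(domain_scores=domain_scores, total=total)


def score_eq5d(responses: Sequence[float], value_set: ValueSet | None = None) -> float:
    """EQ-5D-5L index of one health state: 1 minus the tariff decrements."""
    vs = value_set or ValueSet.us5l()
    arr = np.asarray(responses, dtype=float)
    if arr.shape != (5,):
        raise ValueError(f"expected 5 dimension responses, got shape {arr.shape}")
    if np.isnan(arr).any():
        raise ValueError("missing EQ-5D-5L dimension; index not calculated")
    if ((arr < 1) | (arr > 5)).any() or (arr != np.round(arr)).any():
        raise ValueError("EQ-5D-5L responses must be integers in 1..5")
    index = 1.0
    for dim, level in zip(EQ5D_DIMENSIONS, arr.astype(int)):
        index -= vs.decrements[dim][level - 1]
    return float(index)


# ---------------------------------------------------------------------------
# cohort-level (DataFrame) API

def load_patients(path_or_buf, validate: bool = True) -> pd.DataFrame:
    """Read the patient CSV (cldq_01..cldq_36, eq5d_*, bmi, t2d; blank = missing).

    Out-of-range responses are rejected at load; the obese flag is derived
    from BMI (>= 30 kg/m^2) when BMI is present.
    """
    df = pd.read_csv(path_or_buf)
    if validate:
        validate_responses(df)
    if "bmi" in df.columns and "obese" not in df.columns:
        df["obese"] = df["bmi"] >= OBESITY_BMI_CUTOFF
    return df


def validate_responses(df: pd.DataFrame) -> None:
    for col in CLDQ_COLUMNS:
        if col in df.columns:
            vals = df[col].dropna()
            bad = vals[(vals < 1) | (vals > 7) | (vals != np.round(vals))]
            if len(bad):
                raise ValueError(f"{col}: responses outside 1..7 at rows {list(bad.index[:5])}")
    for col in EQ5D_COLUMNS:
        if col in df.columns:
            vals = df[col].dropna()
            bad = vals[(vals < 1) | (vals > 5) | (vals != np.round(vals))]
            if len(bad):
                raise ValueError(f"{col}: responses outside 1..5 at rows {list(bad.index[:5])}")
    if "bmi" in df.columns and "obese" in df.columns:
        have = df["bmi"].notna() & df["obese"].notna()
        mismatch = have & (df["obese"].astype(bool) != (df["bmi"] >= OBESITY_BMI_CUTOFF))
        if mismatch.any():
            raise ValueError(
                f"obese flag inconsistent with BMI >= {OBESITY_BMI_CUTOFF} "
                f"at rows {list(df.index[mismatch][:5])}")


def filter_complete_cases(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep records with all 36 CLDQ items and all 5 EQ-5D responses present.

    Returns the retained frame and per-instrument exclusion counts.
    """
    cldq_ok = df[list(CLDQ_COLUMNS)].notna().all(axis=1)
    eq_ok = df[list(EQ5D_COLUMNS)].notna().all(axis=1)
    counts = {
        "n_input": int(len(df)),
        "excluded_cldq_incomplete": int((~cldq_ok).sum()),
        "excluded_eq5d_incomplete": int((~eq_ok).sum()),
        "n_retained": int((cldq_ok & eq_ok).sum()),
    }
    return df.loc[cldq_ok & eq_ok].copy(), counts


def score_cohort(df: pd.DataFrame,
                 value_set: ValueSet | None = None,
                 domain_map: DomainMap | None = None) -> pd.DataFrame:
    """Append domain scores, the CLDQ total, and the EQ-5D index to a
    complete-case frame (vectorised; same arithmetic as the per-record API)."""
    vs = value_set or ValueSet.us5l()
    dm = domain_map or DomainMap.default()
    out = df.copy()
    items = out[list(CLDQ_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(items).any():
        raise ValueError("cohort contains incomplete CLDQ records; filter first")
    for dom in CLDQ_DOMAINS:
        idx = [i - 1 for i in dm.domains[dom]]
        out[dom] = items[:, idx].mean(axis=1)
    out["cldq_total"] = out[list(CLDQ_DOMAINS)].mean(axis=1)
    levels = out[list(EQ5D_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(levels).any():
        raise ValueError("cohort contains incomplete EQ-5D records; filter first")
    index = np.full(len(out), 1.0)
    for j, dim in enumerate(EQ5D_DIMENSIONS):
        decs = np.asarray(vs.decrements[dim], dtype=float)
        index -= decs[levels[:, j].astype(int) - 1]
    out["eq5d_index"] = index
    return out
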
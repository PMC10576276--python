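"""Instrument scoring: tariff arithmetic, domain means, complete-case rule."""

import io
import json
from importlib import resources

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cldqmap as cm
from cldqmap.instruments import (CLDQ_DOMAINS, EQ5D_DIMENSIONS, DomainMap,
                                 load_patients, validate_responses)


def _raw_decrements():
    """Independent lookup of the bundled tariff, bypassing ValueSet."""
    with resources.files("cldqmap.data").joinpath("us5l_pickard.json").open() as fh:
        return json.load(fh)["decrements"]


def oracle_index(levels):
    """Brute-force lookup-and-sum oracle for the EQ-5D-5L index."""
    decs = _raw_decrements()
    return 1.0 - sum(decs[dim][lvl - 1]
                     for dim, lvl in zip(EQ5D_DIMENSIONS, levels))


class TestEQ5DScoring:
    def test_full_health_scores_one(self, us5l):
        assert cm.score_eq5d([1, 1, 1, 1, 1], us5l) == pytest.approx(1.0, abs=1e-12)

    def test_worst_state_scores_floor(self, us5l):
        assert cm.score_eq5d([5, 5, 5, 5, 5], us5l) == pytest.approx(-0.573, abs=1e-9)
        assert us5l.floor == pytest.approx(-0.573, abs=1e-12)

    def test_mid_state_matches_lookup_oracle(self, us5l):
        state = (2, 1, 3, 2, 1)
        assert cm.score_eq5d(state, us5l) == pytest.approx(oracle_index(state),
                                                          abs=1e-12)

    def test_random_states_match_oracle(self, us5l, rng):
        for _ in range(200):
            state = rng.integers(1, 6, size=5)
            assert cm.score_eq5d(state, us5l) == pytest.approx(
                oracle_index(state), abs=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(state=st.lists(st.integers(1, 5), min_size=5, max_size=5),
           dim=st.integers(0, 4))
    def test_worsening_one_dimension_never_raises_index(self, us5l, state, dim):
        if state[dim] == 5:
            return
        worse = list(state)
        worse[dim] += 1
        assert cm.score_eq5d(worse, us5l) <= cm.score_eq5d(state, us5l) + 1e-12

    def test_missing_dimension_refused(self, us5l):
        with pytest.raises(ValueError, match="missing"):
            cm.score_eq5d([1, 2, np.nan, 1, 1], us5l)

    def test_out_of_range_refused(self, us5l):
        with pytest.raises(ValueError):
            cm.score_eq5d([0, 1, 1, 1, 1], us5l)
        with pytest.raises(ValueError):
            cm.score_eq5d([1, 1, 6, 1, 1], us5l)


class TestCLDQScoring:
    def test_extreme_responses(self):
        top = cm.score_cldq([7] * 36)
        assert top.total == pytest.approx(7.0)
        assert all(v == pytest.approx(7.0) for v in top.domain_scores.values())
        assert cm.score_cldq([1] * 36).total == pytest.approx(1.0)

    def test_hand_computed_fixture_with_custom_map(self):
        # two-item abdominal domain responding (4, 6) -> domain mean 5.0
        custom = DomainMap(name="fixture", domains={
            "abdominal": [1, 2],
            "activity": list(range(3, 10)),
            "emotional": list(range(10, 18)),
            "fatigue": list(range(18, 25)),
            "systemic": list(range(25, 32)),
            "worry": list(range(32, 37)),
        })
        items = np.full(36, 3)
        items[0], items[1] = 4, 6
        scores = cm.score_cldq(items, custom)
        assert scores.domain_scores["abdominal"] == pytest.approx(5.0)
        # total recomputed by hand: mean of (5, 3, 3, 3, 3, 3)
        assert scores.total == pytest.approx((5 + 3 * 5) / 6)

    def test_item_order_invariant_within_domain(self, rng):
        dm = DomainMap.default()
        items = rng.integers(1, 8, size=36)
        base = cm.score_cldq(items, dm)
        shuffled = items.copy()
        dom_idx = [i - 1 for i in dm.domains["fatigue"]]
        shuffled[dom_idx] = shuffled[list(reversed(dom_idx))]
        again = cm.score_cldq(shuffled, dm)
        assert again.total == pytest.approx(base.total, abs=1e-12)

    def test_total_bracketed_by_domain_scores(self, rng):
        for _ in range(50):
            scores = cm.score_cldq(rng.integers(1, 8, size=36))
            vals = list(scores.domain_scores.values())
            assert min(vals) - 1e-12 <= scores.total <= max(vals) + 1e-12

    def test_missing_item_refused(self):
        items = [4.0] * 36
        items[10] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            cm.score_cldq(items)

    def test_bad_domain_map_rejected(self):
        with pytest.raises(ValueError):
            DomainMap(name="broken", domains={d: [1] for d in CLDQ_DOMAINS})


class TestCompleteCases:
    def _frame(self, n=3):
        data = {c: [4] * n for c in cm.CLDQ_COLUMNS}
        data.update({c: [2] * n for c in cm.EQ5D_COLUMNS})
        return pd.DataFrame(data)

    def test_one_missing_cldq_item_drops_record(self):
        df = self._frame(3)
        df.loc[1, "cldq_05"] = np.nan
        kept, counts = cm.filter_complete_cases(df)
        assert len(kept) == 2
        assert counts["excluded_cldq_incomplete"] == 1
        assert counts["n_retained"] == 2

    def test_all_complete_is_identity(self):
        df = self._frame(4)
        kept, counts = cm.filter_complete_cases(df)
        assert len(kept) == 4 and counts["excluded_eq5d_incomplete"] == 0

    def test_missing_eq5d_dimension_excludes(self):
        df = self._frame(2)
        df.loc[0, "eq5d_pd"] = np.nan
        kept, counts = cm.filter_complete_cases(df)
        assert list(kept.index) == [1]
        assert counts["excluded_eq5d_incomplete"] == 1


class TestLoading:
    def test_out_of_range_rejected_at_load(self):
        df = pd.DataFrame({c: [4] for c in cm.CLDQ_COLUMNS}
                          | {c: [2] for c in cm.EQ5D_COLUMNS})
        df["cldq_01"] = 9
        buf = io.StringIO(df.to_csv(index=False))
        with pytest.raises(ValueError, match="cldq_01"):
            load_patients(buf)

    def test_obese_flag_derived_from_bmi(self):
        df = pd.DataFrame({c: [4, 4] for c in cm.CLDQ_COLUMNS}
                          | {c: [2, 2] for c in cm.EQ5D_COLUMNS})
        df["bmi"] = [31.0, 25.0]
        buf = io.StringIO(df.to_csv(index=False))
        out = load_patients(buf)
        assert list(out["obese"]) == [True, False]

    def test_inconsistent_obese_flag_rejected(self):
        df = pd.DataFrame({"bmi": [25.0], "obese": [True]})
        with pytest.raises(ValueError, match="obese"):
            validate_responses(df)


def test_scored_cohort_within_instrument_ranges(scored_cohort_500):
    idx = scored_cohort_500["eq5d_index"]
    assert idx.between(-0.573 - 1e-9, 1 + 1e-9).all()
    assert scored_cohort_500["cldq_total"].between(1, 7).all()


def test_vectorised_scoring_matches_per_record(scored_cohort_500, us5l):
    row = scored_cohort_500.iloc[17]
    items = row[list(cm.CLDQ_COLUMNS)].to_numpy(dtype=float)
    levels = row[list(cm.EQ5D_COLUMNS)].to_numpy(dtype=float)
    assert cm.score_cldq(items).total == pytest.approx(row["cldq_total"])
    assert cm.score_eq5d(levels, us5l) == pytest.approx(row["eq5d_index"])
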
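"""Cross-validation machinery: folds, RMSE panel, enumeration, ranking."""

import numpy as np
import pandas as pd
import pytest

import cldqmap as cm
from cldqmap.estimators import ALL_FAMILIES, ModelSpec
from cldqmap.evaluation import (SPLINE_OPTIONS, CVResult, PANEL_KEYS,
                                cross_validate, describe_grid,
                                enumerate_model_space, kfold_partition,
                                rank_models, rmse, segment_bounds,
                                segment_labels)


class TestKFold:
    def test_study_sized_cohort_partition(self):
        labels = kfold_partition(347, 10, seed=1)
        sizes = sorted(np.bincount(labels), reverse=True)
        assert sizes == [35] * 7 + [34] * 3

    def test_exact_division(self):
        sizes = np.bincount(kfold_partition(100, 10, seed=0))
        assert list(sizes) == [10] * 10

    def test_seeded_determinism(self):
        np.testing.assert_array_equal(kfold_partition(101, 10, 5),
                                      kfold_partition(101, 10, 5))
        assert not np.array_equal(kfold_partition(101, 10, 5),
                                  kfold_partition(101, 10, 6))

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            kfold_partition(19, 10, 0)


class TestRMSE:
    def test_perfect_predictions(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        assert rmse([0.5, 0.5], [0.0, 1.0]) == pytest.approx(0.5)

    def test_brute_force_oracle(self, rng):
        p, o = rng.normal(size=1000), rng.normal(size=1000)
        brute = np.sqrt(sum((a - b) ** 2 for a, b in zip(p, o)) / 1000)
        assert rmse(p, o) == pytest.approx(brute, abs=1e-12)

    def test_empty_is_undefined(self):
        assert np.isnan(rmse([], []))


class TestSegments:
    def test_bounds_are_equal_thirds_matching_published_rounding(self, floor):
        b1, b2 = segment_bounds(floor)
        width = (1 - floor) / 3
        assert b1 - floor == pytest.approx(width, abs=1e-12)
        assert 1 - b2 == pytest.approx(width, abs=1e-12)
        assert round(b1, 3) == -0.049
        assert round(b2, 3) == 0.476

    def test_membership_covers_range_without_overlap(self, floor):
        xs = np.linspace(floor, 1, 1001)
        labels = segment_labels(xs, floor)
        assert set(labels) == {"lower", "middle", "upper"}
        # ordered: lower block, then middle, then upper
        changes = np.nonzero(labels[:-1] != labels[1:])[0]
        assert len(changes) == 2


class TestCrossValidate:
    def test_every_observation_predicted_exactly_once(self, scored_cohort_500,
                                                      floor):
        res = cross_validate(ModelSpec("ols"), scored_cohort_500, floor, seed=4)
        assert not np.isnan(res.predictions).any()
        assert len(np.unique(res.fold_labels)) == 10
        assert np.bincount(res.fold_labels).sum() == len(scored_cohort_500)

    def test_mean_model_cv_rmse_near_cohort_sd(self, us5l):
        cohort = cm.generate_cohort(1000, seed=8)
        scored = cm.score_cohort(cm.filter_complete_cases(cohort)[0], us5l)
        res = cross_validate(ModelSpec("mean"), scored, us5l.floor, seed=8)
        sd = scored["eq5d_index"].std(ddof=0)
        assert res.rmse_overall == pytest.approx(sd, rel=0.05)

    def test_flagged_fold_propagates(self, scored_cohort_500, floor):
        df = scored_cohort_500.copy()
        df.loc[df.index[0], "eq5d_index"] = -0.1  # breaks the gamma family
        res = cross_validate(ModelSpec("glm_gamma", link="log"), df, floor,
                             seed=0)
        assert res.flagged and res.flag_reasons

    def test_panel_undefined_without_subgroup_flags(self, floor, rng):
        df = pd.DataFrame({"cldq_total": rng.uniform(1, 7, 100),
                           "eq5d_index": rng.uniform(0, 1, 100)})
        res = cross_validate(ModelSpec("ols"), df, floor, seed=1)
        assert np.isnan(res.rmse_panel["obese"])
        assert not np.isnan(res.rmse_overall)


class TestEnumeration:
    def test_seven_spline_options(self):
        assert len(SPLINE_OPTIONS) == 7
        kinds = [(s.kind, s.n_knots) for s in SPLINE_OPTIONS]
        assert ("none", 0) in kinds
        assert all(("linear", k) in kinds for k in (2, 3, 4))
        assert all(("restricted_cubic", k) in kinds for k in (3, 4, 5))

    def test_full_grid_composition_reported(self):
        specs = enumerate_model_space("full")
        text = describe_grid(specs)
        assert f"{len(specs)} candidate models" in text
        assert "101 nominal exponents, 100 after excluding p=0" in text
        per_family = {f: sum(s.family == f for s in specs) for f in ALL_FAMILIES}
        # each GLM family: 102 links x 2 covariate sets x 7 spline options
        assert per_family["glm_gaussian"] == 102 * 2 * 7
        assert per_family["mean"] == 1
        assert len(specs) == len(set(specs))  # no duplicate spec

    def test_reduced_grid_covers_every_family(self):
        specs = enumerate_model_space("reduced")
        assert len(specs) <= 50
        assert {s.family for s in specs} == set(ALL_FAMILIES)


def _fake_result(spec, overall, n_params=2, flagged=False):
    panel = {k: overall for k in PANEL_KEYS}
    return CVResult(spec=spec, predictions=np.zeros(1), observed=np.zeros(1),
                    fold_labels=np.zeros(1, dtype=int), rmse_panel=panel,
                    flagged=flagged, flag_reasons=["x"] if flagged else [],
                    n_params=n_params)


class TestRanking:
    def test_lowest_rmse_first(self):
        r = rank_models([_fake_result(ModelSpec("ols"), 0.20),
                         _fake_result(ModelSpec("mean"), 0.15, 1)])
        assert r.iloc[0]["model"] == "mean"

    def test_tie_broken_by_fewer_parameters(self):
        complex_spec = ModelSpec("ols", spline=cm.SplineSpec("linear", 4))
        r = rank_models([_fake_result(complex_spec, 0.15, n_params=6),
                         _fake_result(ModelSpec("mean"), 0.15, n_params=1)])
        assert r.iloc[0]["model"] == "mean"

    def test_invariant_to_evaluation_order(self):
        results = [_fake_result(ModelSpec("ols"), 0.3, 2),
                   _fake_result(ModelSpec("mean"), 0.2, 1),
                   _fake_result(ModelSpec("fractional_logit"), 0.25, 3)]
        a = rank_models(results)
        b = rank_models(list(reversed(results)))
        pd.testing.assert_frame_equal(a, b)

    def test_flagged_listed_separately(self):
        r = rank_models([_fake_result(ModelSpec("ols"), 0.2),
                         _fake_result(ModelSpec("glm_gamma", link="log"), np.nan,
                                      flagged=True)])
        assert r["flagged"].tolist() == [False, True]
        assert np.isnan(r.iloc[1]["rank"])

    def test_all_flagged_is_an_error(self):
        with pytest.raises(ValueError, match="flagged"):
            rank_models([_fake_result(ModelSpec("ols"), np.nan, flagged=True)])
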
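"""Coefficient-table export, validation, and application to new scores."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import cldqmap as cm
from cldqmap.estimators import ModelSpec, fit_model
from cldqmap.mapping_apply import (apply_mapping, export_table, load_table,
                                   save_table, table_to_model, validate_table)

PARAMETRIC_SPECS = [
    ModelSpec("mean"),
    ModelSpec("ols", covariate_set="total",
              spline=cm.SplineSpec("linear", 2)),
    ModelSpec("glm_gaussian", link="power", power=-0.3, covariate_set="total",
              spline=cm.SplineSpec("restricted_cubic", 3)),
    ModelSpec("fractional_logit", covariate_set="domains",
              spline=cm.SplineSpec("restricted_cubic", 3)),
    ModelSpec("fmm_point_mass", covariate_set="total", n_components=2, seed=4),
    ModelSpec("aldvmm", covariate_set="total", n_components=2, seed=4),
]


class TestRoundTrip:
    @pytest.mark.parametrize("spec", PARAMETRIC_SPECS,
                             ids=lambda s: s.family)
    def test_export_apply_reproduces_fit_predictions(self, spec,
                                                     scored_cohort_500, floor):
        fit = fit_model(spec, scored_cohort_500, floor)
        assert fit.converged
        table = export_table(fit, provenance="fitted on synthetic cohort")
        direct = fit.predict(scored_cohort_500)
        via_table = apply_mapping(table, scored_cohort_500)
        np.testing.assert_allclose(via_table, direct, atol=1e-12)

    def test_json_file_round_trip(self, scored_cohort_500, floor, tmp_path):
        fit = fit_model(PARAMETRIC_SPECS[2], scored_cohort_500, floor)
        path = tmp_path / "table.json"
        save_table(export_table(fit), str(path))
        reloaded = load_table(str(path))
        np.testing.assert_allclose(apply_mapping(reloaded, scored_cohort_500),
                                   fit.predict(scored_cohort_500), atol=1e-12)

    def test_nonparametric_fits_refuse_export(self, scored_cohort_500, floor):
        fit = fit_model(ModelSpec("random_forest"), scored_cohort_500, floor)
        with pytest.raises(ValueError, match="coefficient-table"):
            export_table(fit)


class TestHandBuiltTables:
    def test_intercept_only_identity_table(self, floor):
        table = {
            "schema_version": 1,
            "model": {"family": "glm_gaussian", "link": "identity",
                      "covariate_set": "total",
                      "spline": {"kind": "none", "n_knots": 0}},
            "outcome_scale": {"scale": "natural", "floor": floor},
            "coefficients": {"const": 0.854, "cldq_total": 0.0},
        }
        scores = pd.DataFrame({"cldq_total": [1.0, 4.0, 7.0]})
        np.testing.assert_allclose(apply_mapping(table, scores), 0.854)

    def test_fractional_logit_expit_by_hand(self, floor):
        b0, b1 = -2.0, 0.5
        table = {
            "schema_version": 1,
            "model": {"family": "fractional_logit", "covariate_set": "total",
                      "spline": {"kind": "none", "n_knots": 0}},
            "outcome_scale": {"scale": "rescaled", "floor": floor},
            "coefficients": {"const": b0, "cldq_total": b1},
        }
        scores = pd.DataFrame({"cldq_total": [2.0, 4.0, 6.0]})
        expected = expit(b0 + b1 * scores["cldq_total"]) * (1 - floor) + floor
        np.testing.assert_allclose(apply_mapping(table, scores), expected,
                                   atol=1e-12)


class TestValidation:
    def _glm_table(self, floor):
        return {
            "schema_version": 1,
            "model": {"family": "glm_gaussian", "link": "power", "power": -0.3,
                      "covariate_set": "total",
                      "spline": {"kind": "restricted_cubic", "n_knots": 3}},
            "knots": {"cldq_total": [2.5, 5.0, 6.5]},
            "outcome_scale": {"scale": "natural", "floor": floor},
            "coefficients": {"const": 1.2, "cldq_total": -0.05,
                             "cldq_total_rcs1": -0.01},
        }

    def test_valid_table_reports_clean(self, floor):
        report = validate_table(self._glm_table(floor))
        assert report["errors"] == []

    def test_missing_basis_coefficient_named(self, floor):
        table = self._glm_table(floor)
        del table["coefficients"]["cldq_total_rcs1"]
        report = validate_table(table)
        assert any("cldq_total_rcs1" in e for e in report["errors"])

    def test_reversed_knots_rejected(self, floor):
        table = self._glm_table(floor)
        table["knots"]["cldq_total"] = [6.5, 5.0, 2.5]
        report = validate_table(table)
        assert any("increasing" in e for e in report["errors"])
        with pytest.raises(ValueError, match="invalid mapping table"):
            apply_mapping(table, pd.DataFrame({"cldq_total": [4.0]}))

    def test_covariate_outside_instrument_range_rejected(self, floor):
        table = self._glm_table(floor)
        with pytest.raises(ValueError, match=r"\[1, 7\]"):
            apply_mapping(table, pd.DataFrame({"cldq_total": [8.0]}))

    def test_monotonicity_violation_warns_not_errors(self, floor):
        table = self._glm_table(floor)
        table["coefficients"] = {"const": 0.2, "cldq_total": 0.9,
                                 "cldq_total_rcs1": -9.0}
        report = validate_table(table)
        assert report["errors"] == []
        assert any("monotone" in w for w in report["warnings"])


class TestPartialCurves:
    def test_domain_table_partial_dependence_is_well_behaved(
            self, scored_cohort_500, floor):
        # hold five domains at their means, vary one: the published
        # supplementary display (explicitly artificial) — shape check only
        spec = ModelSpec("fractional_logit", covariate_set="domains",
                         spline=cm.SplineSpec("restricted_cubic", 3))
        fit = fit_model(spec, scored_cohort_500, floor)
        table = export_table(fit)
        model = table_to_model(table)
        means = {d: scored_cohort_500[d].mean() for d in cm.CLDQ_DOMAINS}
        grid = np.linspace(1, 7, 40)
        for vary in cm.CLDQ_DOMAINS:
            probe = pd.DataFrame({d: (grid if d == vary
                                      else np.full(40, means[d]))
                                  for d in cm.CLDQ_DOMAINS})
            curve = model.predict(probe)
            assert np.all(np.isfinite(curve))
            assert np.all((curve >= floor - 1e-9) & (curve <= 1 + 1e-9))
            assert np.ptp(curve) > 0  # the varied domain moves the prediction
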
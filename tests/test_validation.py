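"""Prediction-error records, cohort summaries and exceedance reporting."""

import math

import numpy as np
import pandas as pd
import pytest

from cochleaplan import (
    CochlearGeometry,
    ObservedInsertion,
    cohort_angle_summary,
    eca_cdl,
    exceedance_report,
    flex28_spec,
    invert_eca,
    predict_insertion,
    prediction_error,
    summarize_errors,
)


class TestPredictionError:
    def test_signed_subtraction(self, geom):
        pred = predict_insertion(geom, flex28_spec(), "eca")
        obs = ObservedInsertion("s1", 1, angular_actual=pred.angular_c1 - 40.0)
        rec = prediction_error(pred, obs, geom, flex28_spec())
        assert rec.angular_error == pytest.approx(-40.0)
        assert rec.linear_error < 0  # shallower actual => overestimation

    def test_perfect_prediction_gives_zero_error(self, geom):
        pred = predict_insertion(geom, flex28_spec(), "eca")
        obs = ObservedInsertion("s1", 1, angular_actual=pred.angular_c1)
        rec = prediction_error(pred, obs, geom, flex28_spec())
        assert rec.angular_error == pytest.approx(0.0, abs=1e-9)
        assert rec.linear_error == pytest.approx(0.0, abs=1e-6)

    def test_three_subject_toy_set_matches_hand_subtraction(self):
        # errors written out by hand against the cubic/BTL expressions
        spec = flex28_spec()
        cases = [(9.2, 6.8, 560.0), (8.8, 6.5, 540.0), (9.6, 7.1, 520.0)]
        for a, b, actual in cases:
            geom = CochlearGeometry(a, b)
            pred = predict_insertion(geom, spec, "eca")
            rec = prediction_error(
                pred, ObservedInsertion("s", 1, angular_actual=actual), geom, spec
            )
            btl = (1.18 * (a - 0.7) + 2.69 * (b - 0.7)
                   - math.sqrt(0.72 * (a - 0.7) * (b - 0.7)))
            pct = 8.3e-8 * actual**3 - 2.4e-4 * actual**2 + 0.34 * actual + 3.7
            assert rec.angular_error == pytest.approx(actual - pred.angular_c1)
            assert rec.linear_error == pytest.approx(pct / 100 * btl - 26.8, abs=1e-9)

    def test_tip_reading_converted_to_c1(self, geom):
        # a tip reading and its C1 equivalent give the same error record
        spec = flex28_spec()
        pred = predict_insertion(geom, spec, "eca")
        c1_deg = pred.angular_c1 - 25.0
        tip_mm = eca_cdl(geom, c1_deg) + spec.tip_to_c1
        tip_deg = invert_eca(geom, tip_mm)
        rec_tip = prediction_error(
            pred, ObservedInsertion("s", 1, tip_deg, reference="tip"), geom, spec
        )
        rec_c1 = prediction_error(
            pred, ObservedInsertion("s", 1, c1_deg, reference="c1"), geom, spec
        )
        assert rec_tip.angular_error == pytest.approx(rec_c1.angular_error, abs=1e-6)
        assert rec_tip.linear_error == pytest.approx(rec_c1.linear_error, abs=1e-6)

    def test_observation_domain_checked(self):
        with pytest.raises(ValueError):
            ObservedInsertion("s", 1, angular_actual=0.0)
        with pytest.raises(ValueError):
            ObservedInsertion("s", 1, angular_actual=901.0)
        with pytest.raises(ValueError, match="reference"):
            ObservedInsertion("s", 1, 400.0, reference="middle")


def _error_frame(angular, linear=None, model="eca", observer=1):
    angular = list(angular)
    linear = list(linear) if linear is not None else [a / 40 for a in angular]
    return pd.DataFrame(
        {
            "model": model,
            "observer": observer,
            "angular_error_deg": angular,
            "linear_error_mm": linear,
        }
    )


class TestSummarizeErrors:
    def test_symmetric_errors(self):
        out = summarize_errors(_error_frame([-10.0, 10.0]))
        row = out.iloc[0]
        assert row["mean_abs_angular_deg"] == 10.0
        assert row["mean_signed_angular_deg"] == 0.0
        assert row["n"] == 2

    def test_single_record_has_undefined_sample_sd(self):
        out = summarize_errors(_error_frame([-5.0]))
        assert np.isnan(out.iloc[0]["sd_abs_angular_deg"])

    def test_five_error_toy_matches_hand_computation(self):
        # |errors| = 2,1,0,1,3: mean 1.4; sample SD sqrt(5.2/4); signed mean 0.2
        out = summarize_errors(_error_frame([-2.0, -1.0, 0.0, 1.0, 3.0]))
        row = out.iloc[0]
        assert row["mean_abs_angular_deg"] == pytest.approx(1.4)
        assert row["sd_abs_angular_deg"] == pytest.approx(math.sqrt(5.2 / 4))
        assert row["mean_signed_angular_deg"] == pytest.approx(0.2)
        assert row["mean_abs_angular_deg"] >= abs(row["mean_signed_angular_deg"])

    def test_grouping_by_model_and_observer(self):
        df = pd.concat(
            [
                _error_frame([-10, 10], model="eca", observer=1),
                _error_frame([-30, 30], model="escude", observer=2),
            ]
        )
        out = summarize_errors(df)
        assert len(out) == 2
        assert set(out["model"]) == {"eca", "escude"}

    def test_empty_or_malformed_input_rejected(self):
        with pytest.raises(ValueError, match="no error records"):
            summarize_errors(_error_frame([]))
        with pytest.raises(ValueError, match="missing columns"):
            summarize_errors(pd.DataFrame({"model": ["eca"]}))


class TestCohortAngleSummary:
    def test_single_turn(self):
        out = cohort_angle_summary([360.0, 360.0])
        assert out["mean_deg"] == 360.0
        assert out["mean_turns"] == 1.0

    def test_mean_of_two(self):
        assert cohort_angle_summary([540.0, 580.0])["mean_deg"] == 560.0

    def test_pooled_mean_equals_mean_of_balanced_observer_means(self, rng):
        o1 = rng.normal(560, 30, 46)
        o2 = rng.normal(570, 30, 46)
        pooled = cohort_angle_summary(np.concatenate([o1, o2]))["mean_deg"]
        per_obs = (cohort_angle_summary(o1)["mean_deg"]
                   + cohort_angle_summary(o2)["mean_deg"]) / 2
        assert pooled == pytest.approx(per_obs, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_angle_summary([])


class TestExceedance:
    def test_all_negative_errors_never_exceed(self):
        out = exceedance_report([-0.5, -1.0, -2.0, -0.1])
        assert out["empirical_frac_above_0"] == 0.0
        assert out["empirical_frac_above_bound"] == 0.0

    def test_normal_model_tails_match_cdf_oracle(self):
        # closed-form oracle via erf, independent of scipy
        rng = np.random.default_rng(5)
        e = rng.normal(-0.58, 1.19, 100_000)
        out = exceedance_report(e, bound_mm=2.38)
        mu, sd = e.mean(), e.std(ddof=1)
        oracle0 = 0.5 * (1 - math.erf((0 - mu) / (sd * math.sqrt(2))))
        oracleb = 0.5 * (1 - math.erf((2.38 - mu) / (sd * math.sqrt(2))))
        assert out["normal_frac_above_0"] == pytest.approx(oracle0, abs=1e-12)
        assert out["normal_frac_above_bound"] == pytest.approx(oracleb, abs=1e-12)
        # for this error distribution roughly a third of insertions go deeper
        assert out["empirical_frac_above_0"] == pytest.approx(oracle0, abs=0.01)
        # the generic one/two-SD one-sided tails (the 16 % / 2.5 % reading)
        assert out["normal_one_sd_tail"] == pytest.approx(0.1587, abs=5e-4)
        assert out["normal_two_sd_tail"] == pytest.approx(0.0228, abs=5e-4)

    def test_empirical_fraction_is_a_hand_count(self):
        e = [-1, -2, 0.5, 3.0, -0.2, 2.5, -4, 0.1, -0.3, -0.6]
        out = exceedance_report(e, bound_mm=2.38)
        assert out["empirical_frac_above_0"] == 4 / 10
        assert out["empirical_frac_above_bound"] == 2 / 10
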
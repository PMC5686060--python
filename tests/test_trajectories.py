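"""Eligibility filtering and per-patient progression-slope estimation."""

import math

import numpy as np
import pytest

from msdss.cohort import TreatmentEpoch, ValidationError
from msdss.scales import combiwise_from_components
from msdss.therapy import EfficacyModel, epoch_efficacy
from msdss.trajectories import (
    adjust_trajectory,
    eligible,
    fit_slope,
    paired_r2_summary,
    retained_visits,
)

from conftest import make_patient, make_visit

FLAT = EfficacyModel(
    class_coefficients={"none_or_unknown": (0.0, 0.0), "low": (0.0, 20.0), "high": (0.0, 60.0)}
)


def patient_on_line(pid, ages, slope, intercept=20.0, scale="CombiWISE", treatments=()):
    """Patient whose chosen scale follows an exact line against age."""
    p = make_patient(pid, [], treatments=treatments)
    for age in ages:
        value = intercept + slope * (age - ages[0])
        if scale == "CombiWISE":
            # vary only the walk time so CombiWISE hits the target exactly
            v = make_visit(age, edss=3.0, snrs=70)
            residual = value - combiwise_from_components(3.0, 70, 1.0, 0, v.ndh_9hpt_seconds, 0)
            v.t25fw_seconds = 2.0 ** (residual / 2.409)
        else:
            v = make_visit(age, edss=value)
        p.visits.append(v)
    return p


class TestEligibility:
    def test_boundary_fixture(self, eligibility_fixture):
        patients, expected = eligibility_fixture
        assert [eligible(p) for p in patients] == expected

    def test_exclusion_set_is_exactly_the_flagged_visits(self):
        p = make_patient("P1", [50.0, 50.5, 51.0, 51.5])
        p.visits[2].exacerbation = 1
        kept = retained_visits(p)
        assert [v.visit_age for v in kept] == [50.0, 50.5, 51.5]


class TestFitSlope:
    def test_exact_line(self):
        p = patient_on_line("P1", [50, 51, 52], slope=2.0, intercept=10.0)
        t = fit_slope(p, "CombiWISE")
        assert t.slope == pytest.approx(2.0, abs=1e-9)
        assert t.r_squared == pytest.approx(1.0, abs=1e-9)
        assert t.intercept == pytest.approx(10.0, abs=1e-9)
        assert t.n_visits == 3 and t.span_years == pytest.approx(2.0)

    def test_constant_edss_gives_zero_slope_undefined_r2(self):
        p = make_patient("P1", [50, 51, 52])
        t = fit_slope(p, "EDSS")
        assert t.slope == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(t.r_squared)

    def test_three_point_closed_form(self):
        # values 10, 13, 14 at ages 50, 51, 52: slope 2, R^2 = 12/13
        p = patient_on_line("P1", [50, 51, 52], slope=0.0)
        for v, value in zip(p.visits, [10.0, 13.0, 14.0]):
            residual = value - combiwise_from_components(3.0, 70, 1.0, 0, 20.0, 0)
            v.t25fw_seconds = 2.0 ** (residual / 2.409)
        t = fit_slope(p, "CombiWISE")
        assert t.slope == pytest.approx(2.0, abs=1e-9)
        assert t.r_squared == pytest.approx(12.0 / 13.0, abs=1e-9)

    def test_exacerbation_visits_excluded_from_fit(self):
        p = patient_on_line("P1", [50, 51, 52, 53], slope=1.0)
        bump = make_visit(52.5, edss=6.0, snrs=40)
        bump.exacerbation = 1
        p.visits.insert(3, bump)
        t = fit_slope(p, "CombiWISE")
        assert t.slope == pytest.approx(1.0, abs=1e-9)
        assert t.n_visits == 4

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_slope(make_patient("P1", [50.0]))

    def test_slope_invariant_to_age_shift(self):
        a = patient_on_line("P1", [50, 51.3, 52, 54], slope=1.7)
        b = patient_on_line("P1", [30, 31.3, 32, 34], slope=1.7)
        assert fit_slope(a).slope == pytest.approx(fit_slope(b).slope, abs=1e-9)

    def test_unbiased_on_noisy_lines(self):
        rng = np.random.default_rng(7)
        true = 1.5
        estimates = []
        for i in range(500):
            ages = 40 + np.sort(rng.uniform(0, 4, size=5))
            values = 25 + true * (ages - ages[0]) + rng.normal(0, 2, size=5)
            p = patient_on_line(f"P{i}", list(ages), slope=0.0)
            for v, val in zip(p.visits, values):
                residual = val - combiwise_from_components(3.0, 70, 1.0, 0, 20.0, 0)
                v.t25fw_seconds = 2.0 ** (residual / 2.409)
            estimates.append(fit_slope(p).slope)
        se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(np.mean(estimates) - true) < 2 * se


class TestAdjustTrajectory:
    def test_untreated_identity(self):
        p = patient_on_line("P1", [50, 51, 52], slope=1.0)
        t = adjust_trajectory(fit_slope(p), p)
        assert t.adjusted_slope == pytest.approx(t.slope)

    def test_constant_efficacy_recovers_true_slope_exactly(self):
        # window fully treated at a flat 20%: observed slope = true * 0.8
        true = 1.25
        epoch = TreatmentEpoch(50, 54, "low")
        p = patient_on_line(
            "P1", [50, 51, 52, 54], slope=true * 0.8, treatments=[epoch]
        )
        t = adjust_trajectory(fit_slope(p), p, FLAT)
        assert t.adjusted_slope == pytest.approx(true, abs=1e-12)

    def test_improving_branch(self):
        epoch = TreatmentEpoch(50, 54, "high")  # flat 60%
        true = -0.5
        p = patient_on_line("P1", [50, 52, 54], slope=true / 0.4, treatments=[epoch])
        t = adjust_trajectory(fit_slope(p), p, FLAT)
        assert t.adjusted_slope == pytest.approx(true, abs=1e-12)

    def test_age_dependent_example(self):
        # slope 1.0, efficacy 0.25 over the window -> adjusted 4/3
        p = patient_on_line("P1", [50, 52, 54], slope=1.0)
        eff_value = 0.25
        model = EfficacyModel(
            class_coefficients={"none_or_unknown": (0.0, 0.0), "low": (0.0, 100 * eff_value),
                                "high": (0.0, 0.0)}
        )
        p.treatments = [TreatmentEpoch(50, 54, "low")]
        t = adjust_trajectory(fit_slope(p), p, model)
        assert t.adjusted_slope == pytest.approx(4.0 / 3.0, abs=1e-9)

    def test_edss_slopes_cannot_be_adjusted(self):
        p = make_patient("P1", [50, 51, 52])
        with pytest.raises(ValidationError):
            adjust_trajectory(fit_slope(p, "EDSS"), p)


class TestPairedR2:
    def test_identical_vectors_give_zero_difference(self):
        fits = [fit_slope(patient_on_line(f"P{i}", [50, 51, 52, 53], slope=1.0))
                for i in range(4)]
        out = paired_r2_summary(fits, fits)
        assert out.mean_difference == pytest.approx(0.0)
        assert out.ci_low <= 0.0 <= out.ci_high

    def test_constant_shift_gives_degenerate_interval(self):
        cw, edss = [], []
        for i in range(5):
            a = fit_slope(patient_on_line(f"P{i}", [50, 51, 52, 53], slope=1.0))
            b = fit_slope(patient_on_line(f"P{i}", [50, 51, 52, 53], slope=1.0))
            a.r_squared, b.r_squared = 0.9, 0.8
            cw.append(a)
            edss.append(b)
        out = paired_r2_summary(cw, edss)
        assert out.mean_difference == pytest.approx(0.1)
        assert out.ci_low == out.ci_high == pytest.approx(0.1)

    def test_undefined_r2_patients_are_excluded(self):
        good = fit_slope(patient_on_line("P0", [50, 51, 52, 53], slope=1.0))
        flat = fit_slope(make_patient("P1", [50, 51, 52]), "EDSS")  # constant -> NaN
        flat2 = fit_slope(make_patient("P0", [50, 51, 52]), "EDSS")
        flat2.r_squared = 0.5
        out = paired_r2_summary([good, flat], [flat2, flat])
        assert out.n == 1

    def test_no_overlap_rejected(self):
        a = fit_slope(patient_on_line("A", [50, 51, 52], slope=1.0))
        b = fit_slope(patient_on_line("B", [50, 51, 52], slope=1.0))
        with pytest.raises(ValidationError):
            paired_r2_summary([a], [b])

    def test_noisier_edss_yields_positive_mean_difference(self, seed1_cohort):
        patients, _ = seed1_cohort
        cw = [fit_slope(p, "CombiWISE") for p in patients if eligible(p)]
        edss = [fit_slope(p, "EDSS") for p in patients if eligible(p)]
        out = paired_r2_summary(cw, edss)
        assert out.mean_difference > 0
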
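"""Unit, oracle and property tests for the measurement-properties pipeline."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import remotefit as rf
from remotefit.exceptions import (
    DegenerateDesignError,
    InfeasibleDesignError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedStatisticError,
)


class TestPearson:
    def test_identity_is_one(self):
        r, _, _ = rf.pearson_with_normality([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        r, _, _ = rf.pearson_with_normality([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, p, shapiro_p = rf.pearson_with_normality([1, 2, 3, 4], [2, 4, 5, 9])
        assert r == pytest.approx(11 / math.sqrt(130), abs=1e-12)
        assert 0 <= shapiro_p <= 1

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            rf.pearson_with_normality([1, 1, 1], [1, 2, 3])


class TestCCC:
    def test_identity_is_one(self):
        ccc, _ = rf.lins_ccc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ccc == pytest.approx(1.0)

    def test_hand_computed_offset_example(self):
        ccc, ci = rf.lins_ccc([1, 2, 3], [2, 3, 4])
        assert ccc == pytest.approx(4 / 7, abs=1e-12)
        assert ci[0] <= ccc <= ci[1]

    def test_constant_margins_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            rf.lins_ccc([1, 1, 1], [2, 2, 2])

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 10_000))
    def test_ccc_never_exceeds_pearson(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        x = rng.normal(0, rng.uniform(0.5, 5), n)
        y = rng.uniform(-2, 2) + rng.uniform(-2, 2) * x + rng.normal(0, 1, n)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        ccc, _ = rf.lins_ccc(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(ccc) <= abs(r) + 1e-12


class TestRelativeError:
    def test_definition(self):
        assert rf.relative_measurement_error([104.4], [100.0]) == pytest.approx(4.40)

    def test_perfect_agreement(self):
        assert rf.relative_measurement_error([5, 6], [5, 6]) == 0.0

    def test_mean_over_records(self):
        assert rf.relative_measurement_error([95, 105], [100, 100]) == pytest.approx(5.0)

    def test_zero_gold_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            rf.relative_measurement_error([1.0], [0.0])


class TestBlandAltman:
    def test_identical_vectors(self):
        assert rf.bland_altman([1, 2, 3], [1, 2, 3]) == (0, 0, 0, 0)

    def test_constant_offset(self):
        m, s, lo, hi = rf.bland_altman([4, 5, 6], [1, 2, 3])
        assert (m, s, lo, hi) == (3.0, 0.0, 3.0, 3.0)

    def test_hand_computed_example(self):
        m, s, lo, hi = rf.bland_altman([10, 12, 14], [9, 12, 16])
        assert m == pytest.approx(-1 / 3, abs=1e-9)
        assert s == pytest.approx(1.5275, abs=1e-4)
        assert lo == pytest.approx(-3.327, abs=1e-3)
        assert hi == pytest.approx(2.661, abs=1e-3)

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            rf.bland_altman([1.0], [2.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_limits_symmetric_about_mean(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(100, 10, 20)
        y = x + rng.normal(0, 5, 20)
        m, s, lo, hi = rf.bland_altman(x, y)
        assert hi - m == pytest.approx(m - lo, abs=1e-10)
        assert hi - m == pytest.approx(1.96 * s, abs=1e-10)


class TestIcc:
    def test_worked_three_by_two_table(self, small_rm):
        res = rf.icc_2_1(small_rm)
        assert res.icc == pytest.approx(8 / 9, abs=1e-12)
        assert (res.msr, res.msc, res.mse) == (8.0, 1.5, 0.0)

    def test_perfectly_stable_subjects(self):
        rm = pd.DataFrame(
            {
                "subject": ["a", "a", "b", "b", "c", "c"],
                "session": [1, 2] * 3,
                "score": [1.0, 1.0, 5.0, 5.0, 9.0, 9.0],
            }
        )
        assert rf.icc_2_1(rm).icc == pytest.approx(1.0)

    def test_pure_noise_icc_near_zero(self):
        rng = np.random.default_rng(0)
        n, k = 500, 3
        rm = pd.DataFrame(
            {
                "subject": np.repeat(range(n), k),
                "session": np.tile(range(k), n),
                "score": rng.normal(0, 1, n * k),
            }
        )
        assert abs(rf.icc_2_1(rm).icc) < 0.1

    def test_single_session_degenerate(self):
        rm = pd.DataFrame({"subject": ["a", "b"], "session": [1, 1], "score": [1.0, 2.0]})
        with pytest.raises(DegenerateDesignError):
            rf.icc_2_1(rm)

    def test_matches_independent_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        for _ in range(50):
            n, k = int(rng.integers(4, 15)), int(rng.integers(2, 5))
            x = rng.normal(50, 10, (n, k)) + rng.normal(0, 5, (n, 1))
            rm = pd.DataFrame(
                {
                    "subject": np.repeat(range(n), k),
                    "session": np.tile(range(k), n),
                    "score": x.ravel(),
                }
            )
            mine = rf.icc_2_1(rm)
            ref = (
                pg.intraclass_corr(rm, targets="subject", raters="session", ratings="score")
                .set_index("Type")
                .loc["ICC(A,1)"]
            )
            assert mine.icc == pytest.approx(ref.ICC, abs=1e-10)


class TestMixedModelIcc:
    def test_matches_anova_when_covariates_are_null(self):
        rm, _, _ = rf.simulate_validation_study(
            rf.StudySimSpec(n_subjects=200, sigma_between=50, sigma_error=35, seed=5)
        )
        icc_adj, vb, ve = rf.icc_mixed_adjusted(rm)
        anova = rf.icc_2_1(rm)
        assert icc_adj == pytest.approx(anova.icc, abs=0.03)

    def test_recovers_generating_variances(self):
        rm, _, truth = rf.simulate_validation_study(
            rf.StudySimSpec(n_subjects=200, sigma_between=50, sigma_error=35, seed=9)
        )
        icc_adj, vb, ve = rf.icc_mixed_adjusted(rm)
        assert icc_adj == pytest.approx(truth["icc"], abs=0.05)

    def test_single_session_degenerate(self):
        rm = pd.DataFrame(
            {
                "subject": ["a", "b", "c"],
                "session": [1, 1, 1],
                "score": [1.0, 2.0, 3.0],
                "age": [30, 40, 50],
                "bmi": [22, 23, 24],
                "phone_brand": ["x", "y", "z"],
            }
        )
        with pytest.raises(DegenerateDesignError):
            rf.icc_mixed_adjusted(rm)


class TestSemMdc:
    def test_walk_test_values(self):
        sem, mdc, mdc_pct = rf.sem_mdc(35.20**2, 704.55)
        assert sem == pytest.approx(35.20)
        assert mdc == pytest.approx(97.57, abs=0.01)
        assert mdc_pct == pytest.approx(13.85, abs=0.01)

    def test_sts_values(self):
        _, mdc, _ = rf.sem_mdc(2.66**2)
        assert round(mdc, 2) == 7.37

    def test_zero_error(self):
        assert rf.sem_mdc(0.0) == (0.0, 0.0, None)

    def test_negative_variance_invalid(self):
        with pytest.raises(InvalidInputError):
            rf.sem_mdc(-1.0)


class TestCv:
    def test_constant_subject_zero(self):
        rm = pd.DataFrame(
            {"subject": ["a"] * 3, "session": [1, 2, 3], "score": [100.0] * 3}
        )
        assert rf.within_subject_cv(rm) == 0.0

    def test_single_subject_value(self):
        rm = pd.DataFrame({"subject": ["a", "a"], "session": [1, 2], "score": [90.0, 110.0]})
        assert rf.within_subject_cv(rm) == pytest.approx(14.14, abs=0.01)

    def test_rms_aggregation(self):
        # two subjects engineered to CVs of exactly 3% and 4%
        rm = pd.DataFrame(
            {
                "subject": ["a", "a", "b", "b"],
                "session": [1, 2, 1, 2],
                "score": [
                    100 - 3 / math.sqrt(2), 100 + 3 / math.sqrt(2),
                    100 - 4 / math.sqrt(2), 100 + 4 / math.sqrt(2),
                ],
            }
        )
        assert rf.within_subject_cv(rm) == pytest.approx(math.sqrt((9 + 16) / 2), abs=1e-3)


class TestSampleSize:
    def test_reference_design_needs_53(self):
        assert rf.icc_sample_size(0.70, 0.85, 0.05, 0.80, 2) == 53

    def test_larger_expected_icc_needs_fewer(self):
        assert rf.icc_sample_size(0.70, 0.90, 0.05, 0.80, 2) == 23

    def test_equal_rhos_infeasible(self):
        with pytest.raises(InfeasibleDesignError):
            rf.icc_sample_size(0.70, 0.70)

    def test_monte_carlo_power_near_nominal(self):
        power = rf.icc_power_simulation(0.70, 0.85, n=53, k=2, n_sims=2000, seed=3)
        assert 0.74 <= power <= 0.86


class TestGrading:
    @pytest.mark.parametrize(
        "value, scheme, label",
        [
            (0.84, "mccall_r", "high"),
            (0.95, "mccall_r", "very high"),
            (0.90, "mccall_r", "very high"),  # boundary -> upper band
            (0.30, "mccall_r", "low"),
            (0.84, "ccc", "poor"),
            (0.99, "ccc", "good"),
            (0.90, "ccc", "moderate"),
            (0.50, "ccc", "very poor"),
        ],
    )
    def test_bands(self, value, scheme, label):
        assert rf.grade_coefficient(value, scheme) == label

    def test_out_of_range_invalid(self):
        with pytest.raises(InvalidInputError):
            rf.grade_coefficient(1.2, "ccc")


class TestReports:
    def test_validity_report_consistency(self):
        _, pairs, _ = rf.simulate_validation_study(rf.StudySimSpec(seed=2))
        rep = rf.validity_report(pairs)
        assert abs(rep.ccc) <= abs(rep.pearson_r) + 1e-12
        assert rep.loa_high - rep.mean_diff == pytest.approx(1.96 * rep.sd_diff, abs=1e-9)
        assert rep.grade_r == rf.grade_coefficient(rep.pearson_r, "mccall_r")

    def test_reliability_report_invariants(self):
        rm, _, _ = rf.simulate_validation_study(rf.StudySimSpec(seed=2))
        rep = rf.reliability_report(rm)
        assert rep.sem == pytest.approx(math.sqrt(rep.var_error))
        assert rep.mdc == pytest.approx(1.96 * math.sqrt(2) * rep.sem)
        assert rep.mdc_percent == pytest.approx(100 * rep.mdc / rep.grand_mean)
        assert 0 <= rep.icc <= 1

    def test_perfect_device_gives_ccc_one(self):
        _, pairs, _ = rf.simulate_validation_study(
            rf.StudySimSpec(device_bias=0.0, device_error_sd=0.0, seed=4)
        )
        rep = rf.validity_report(pairs)
        assert rep.ccc == pytest.approx(1.0)
        assert rep.mean_abs_rme == pytest.approx(0.0, abs=1e-9)
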
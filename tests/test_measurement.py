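"""Measurement-process model: CV, calibration, quantification limits, censoring."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from censimpute import (
    CalibratorSet,
    CensoredDataset,
    MeasurementRange,
    PrecisionProfile,
    censor,
    compute_cv,
    derive_loqs,
    fit_calibration_curve,
    fit_precision_profile,
    measure,
    sd_rule_cutoff,
)
from censimpute.errors import (
    CensImputeError,
    ConfigurationError,
    DomainError,
    InsufficientDataError,
    NoOperationalRangeError,
)


class TestComputeCV:
    @pytest.mark.parametrize(
        "signals, expected",
        [
            ([90.0, 110.0], np.sqrt(200.0) / 100.0),  # SD/mean directly
            ([7.0, 7.0, 7.0], 0.0),  # zero variance
            ([95.0, 100.0, 105.0], 0.05),  # sample SD 5 over mean 100
        ],
    )
    def test_known_values(self, signals, expected):
        assert compute_cv(signals) == pytest.approx(expected, abs=1e-12)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            compute_cv([5.0])
        with pytest.raises(DomainError):
            compute_cv([-1.0, 1.0])  # zero mean

    @given(
        st.lists(st.floats(1.0, 1e4), min_size=2, max_size=20),
        st.floats(0.1, 100.0),
    )
    def test_scale_invariance(self, signals, c):
        """Multiplying all replicate signals by c > 0 leaves the CV unchanged."""
        base = compute_cv(signals)
        scaled = compute_cv([c * s for s in signals])
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestCalibration:
    def test_exact_line_recovered(self):
        cal = CalibratorSet(
            [10.0, 20.0, 40.0],
            [[21.0, 21.0], [41.0, 41.0], [81.0, 81.0]],  # signal = 2c + 1
        )
        curve = fit_calibration_curve(cal)
        assert curve.intercept == pytest.approx(1.0, abs=1e-9)
        assert curve.slope == pytest.approx(2.0, abs=1e-9)
        assert curve.to_concentration(41.0) == pytest.approx(20.0)

    def test_two_point_through_origin(self):
        cal = CalibratorSet([10.0, 20.0], [[20.0, 20.0], [40.0, 40.0]])
        curve = fit_calibration_curve(cal)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.slope == pytest.approx(2.0, abs=1e-9)

    def test_noisy_fit_matches_normal_equations(self, rng):
        conc = np.array([5.0, 10.0, 25.0, 50.0, 100.0])
        reps = [list(3.0 * c + 2.0 + rng.normal(0, 0.5, size=4)) for c in conc]
        cal = CalibratorSet(conc, reps)
        curve = fit_calibration_curve(cal)
        # independent closed-form least squares on the replicate means
        y = np.array([np.mean(r) for r in reps])
        x = np.column_stack([conc, np.ones_like(conc)])
        slope, intercept = np.linalg.solve(x.T @ x, x.T @ y)
        assert curve.slope == pytest.approx(slope, rel=1e-10)
        assert curve.intercept == pytest.approx(intercept, rel=1e-10)

    def test_negative_slope_rejected(self):
        cal = CalibratorSet([10.0, 20.0], [[40.0, 40.0], [20.0, 20.0]])
        with pytest.raises(CensImputeError):
            fit_calibration_curve(cal)

    def test_precision_profile_recovers_constant_cv(self):
        # all calibrators at 5% CV -> cv_base ~ 0.05 and no inflation terms
        conc = [10.0, 50.0, 100.0, 200.0]
        reps = [[95.0 * c / 100, 100.0 * c / 100, 105.0 * c / 100] for c in conc]
        profile = fit_precision_profile(CalibratorSet(conc, reps))
        assert profile.cv(50.0) == pytest.approx(0.05, abs=1e-6)


class TestDeriveLoqs:
    def test_whole_range_acceptable_is_flagged(self):
        profile = PrecisionProfile(cv_base=0.05, cv_cutoff=0.10)
        limits = derive_loqs(profile, MeasurementRange(1.0, 500.0))
        assert limits.no_finite_limits
        assert (limits.lloq, limits.uloq) == (1.0, 500.0)

    def test_crossings_match_bisection_oracle(self):
        profile = PrecisionProfile(cv_base=0.02, k_low=1.5, k_high=0.0004, cv_cutoff=0.10)
        rng = MeasurementRange(1.0, 500.0)
        limits = derive_loqs(profile, rng)
        # oracle: naive bisection on a fine grid bracketing of CV(x) = cutoff
        xs = np.linspace(1.0, 500.0, 2_000_001)
        ok = profile.cv(xs) <= profile.cv_cutoff
        lloq_oracle = xs[np.argmax(ok)]
        uloq_oracle = xs[len(ok) - 1 - np.argmax(ok[::-1])]
        assert limits.lloq == pytest.approx(lloq_oracle, abs=5e-4)
        assert limits.uloq == pytest.approx(uloq_oracle, abs=5e-4)
        # at finite limits the CV sits exactly on the cutoff
        assert profile.cv(limits.lloq) == pytest.approx(0.10, abs=1e-8)
        assert profile.cv(limits.uloq) == pytest.approx(0.10, abs=1e-8)

    def test_raising_cutoff_widens_range(self):
        rng = MeasurementRange(1.0, 500.0)
        tight = derive_loqs(
            PrecisionProfile(0.02, 1.5, 0.0004, cv_cutoff=0.10), rng
        )
        loose = derive_loqs(
            PrecisionProfile(0.02, 1.5, 0.0004, cv_cutoff=0.20), rng
        )
        assert loose.lloq < tight.lloq
        assert loose.uloq > tight.uloq

    def test_unreachable_cutoff_rejected(self):
        profile = PrecisionProfile(cv_base=0.15, cv_cutoff=0.10)
        with pytest.raises(NoOperationalRangeError):
            derive_loqs(profile, MeasurementRange(1.0, 100.0))


class TestSdRuleCutoff:
    @pytest.mark.parametrize(
        "values, k, expected",
        [
            ([-1.0, 1.0], 3.0, 3.0 * np.sqrt(2.0)),  # mean 0, sample SD sqrt(2)
            ([10.0, 20.0, 30.0], 0.0, 20.0),  # k = 0 is the mean
            ([10.0, 20.0, 30.0], 2.5, 45.0),  # 20 + 2.5 * 10
        ],
    )
    def test_known_values(self, values, k, expected):
        assert sd_rule_cutoff(values, k) == pytest.approx(expected)

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientDataError):
            sd_rule_cutoff([1.0], 3.0)


class TestMeasure:
    def test_zero_cv_is_identity(self):
        profile = PrecisionProfile(cv_base=0.0, cv_cutoff=0.1)
        truth = np.array([10.0, 50.0, 100.0])
        assert np.array_equal(measure(truth, profile, seed=7), truth)

    def test_empirical_cv_matches_profile(self):
        """10^5 repeat reads of y*=100 under an 8% CV show an 8% relative SD."""
        profile = PrecisionProfile(cv_base=0.08, cv_cutoff=0.2)
        reads = measure(np.full(100_000, 100.0), profile, seed=11)
        emp_cv = reads.std(ddof=1) / reads.mean()
        se = 0.08 / np.sqrt(2 * reads.size)
        assert abs(emp_cv - 0.08) < 3 * se

    def test_same_seed_same_output(self):
        profile = PrecisionProfile(cv_base=0.1, k_low=0.5, cv_cutoff=0.3)
        truth = np.linspace(5.0, 200.0, 50)
        assert np.array_equal(
            measure(truth, profile, seed=42), measure(truth, profile, seed=42)
        )

    def test_outputs_stay_positive_under_huge_cv(self):
        # CV > 1 at small concentrations forces the redraw path
        profile = PrecisionProfile(cv_base=0.1, k_low=5.0, cv_cutoff=0.9)
        reads = measure(np.full(5000, 2.0), profile, seed=3)
        assert np.all(reads > 0)

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(DomainError):
            measure([1.0, 0.0], PrecisionProfile(cv_base=0.1), seed=0)


class TestCensor:
    def test_no_censoring_inside_cutoffs(self):
        data = censor([10.0, 20.0, 30.0], lc=5.0, uc=50.0)
        assert (data.n_bc, data.n_ac) == (0, 0)
        assert np.array_equal(data.observed, [10.0, 20.0, 30.0])

    def test_boundary_values_stay_observed(self):
        data = censor([50.0, 60.0, 250.0], lc=50.0, uc=250.0)
        assert (data.n_bc, data.n_ac) == (0, 0)

    def test_strict_inequalities_classify(self):
        data = censor([49.9, 100.0, 250.1], lc=50.0, uc=250.0)
        assert (data.n_bc, data.n_ac) == (1, 1)
        assert data.observed.tolist() == [100.0]

    def test_observed_order_preserved(self):
        data = censor([200.0, 10.0, 100.0, 60.0], lc=50.0, uc=250.0)
        assert data.observed.tolist() == [200.0, 100.0, 60.0]

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ConfigurationError):
            censor([1.0], lc=10.0, uc=10.0)

    @given(
        st.lists(st.floats(0.01, 1000.0), min_size=0, max_size=100),
        st.floats(1.0, 400.0),
        st.floats(10.0, 500.0),
    )
    def test_record_count_conserved(self, values, lc, gap):
        """n_obs + n_bc + n_ac equals the input length for any cutoffs."""
        data = censor(values, lc=lc, uc=lc + gap)
        assert data.n == len(values)

    def test_dataset_invariants_enforced(self):
        with pytest.raises(DomainError):
            CensoredDataset(observed=np.array([5.0]), n_bc=0, n_ac=0, lc=10.0, uc=20.0)
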
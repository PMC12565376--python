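"""Core MMS engine: peak detection, Gamma MLE, Eq.-style normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import make_series
from spiba.core import (
    GammaSignature,
    UniformSeries,
    detect_peaks,
    deviation_series,
    empirical_gamma_fit,
    fit_power_law,
    mms_normalize,
    mms_pipeline,
)
from spiba.errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidInputError,
)
from spiba.synthetic import mms_spike_train


class TestDetectPeaks:
    def test_monotone_ramp_has_no_peaks(self):
        pk = detect_peaks(make_series(np.arange(10.0)))
        assert len(pk) == 0

    def test_two_spikes_with_flanking_minima(self):
        pk = detect_peaks(make_series([0, 1, 0, 2, 0]))
        assert pk.peak_indices.tolist() == [1, 3]
        assert pk.left_min_indices.tolist() == [0, 2]
        assert pk.right_min_indices.tolist() == [2, 4]

    def test_sinusoid_boundary_rule(self):
        # 1 Hz sine over 10 s at 100 Hz has maxima at t = 0.25 + k, all ten
        # retained: the series endpoint at t=0 counts as the left flanking
        # minimum of the first cycle (endpoints are minima, never maxima).
        t = np.arange(1000) / 100.0
        series = UniformSeries(t, np.sin(2 * np.pi * t), 100.0)
        pk = detect_peaks(series, min_separation=0.5)
        assert len(pk) == 10
        np.testing.assert_allclose(t[pk.peak_indices], 0.25 + np.arange(10), atol=1e-9)

    def test_plateau_maximum_takes_first_sample(self):
        pk = detect_peaks(make_series([0, 1, 2, 2, 2, 1, 0, 1, 0]))
        assert 2 in pk.peak_indices

    def test_min_separation_keeps_larger(self):
        # two peaks 2 samples apart at 10 Hz: 0.2 s < 0.5 s separation
        pk = detect_peaks(make_series([0, 1, 0.5, 3, 0, 1]), min_separation=0.5)
        assert pk.peak_indices.tolist() == [3]

    def test_prominence_filter(self):
        v = [1, 0, 5, 0, 0.2, 0.1, 0.3, 0, 5, 0, 1]
        pk = detect_peaks(make_series(v), min_prominence=1.0)
        assert pk.peak_indices.tolist() == [2, 8]

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidInputError):
            detect_peaks(make_series([1, 2]))


class TestGammaFit:
    def test_exponential_regime_shape_one(self):
        # the memoryless exponential limit of the Gamma family has shape 1
        x = np.random.default_rng(2024).exponential(1.0, 100_000)
        sig = empirical_gamma_fit(x)
        assert abs(sig.shape - 1.0) < 0.02

    def test_parameter_recovery_gamma_4_05(self):
        x = np.random.default_rng(7).gamma(4.0, 0.5, 100_000)
        sig = empirical_gamma_fit(x)
        assert abs(sig.shape - 4.0) / 4.0 < 0.03
        assert abs(sig.scale - 0.5) / 0.5 < 0.03

    def test_matches_scipy_mle(self, rng):
        # independent route: scipy's constrained-location Gamma MLE
        x = rng.gamma(3.0, 2.0, 2000)
        sig = empirical_gamma_fit(x)
        a_sp, _, scale_sp = stats.gamma.fit(x, floc=0)
        assert abs(sig.shape - a_sp) / a_sp < 1e-4
        assert abs(sig.scale - scale_sp) / scale_sp < 1e-4

    def test_fitted_mean_equals_sample_mean(self, rng):
        x = rng.gamma(5.0, 0.1, 500)
        sig = empirical_gamma_fit(x)
        assert sig.mean == pytest.approx(np.mean(x), rel=1e-12)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateFitError):
            empirical_gamma_fit(np.full(50, 3.0))

    def test_nonpositive_samples_rejected(self, rng):
        x = rng.gamma(2.0, 1.0, 50)
        x[3] = -1.0
        with pytest.raises(InvalidInputError):
            empirical_gamma_fit(x)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            empirical_gamma_fit([1.0, 2.0, 3.0])

    def test_closed_form_moments(self):
        sig = GammaSignature(4.0, 0.5, (3.0, 5.0), (0.4, 0.6), 100)
        assert sig.mean == pytest.approx(2.0, rel=1e-12)
        assert sig.variance == pytest.approx(1.0, rel=1e-12)
        assert sig.nsr == pytest.approx(sig.variance / sig.mean, rel=1e-12)
        assert sig.skewness == pytest.approx(1.0, rel=1e-12)
        assert sig.kurtosis == pytest.approx(4.5, rel=1e-12)

    def test_ci_brackets_point_estimate(self, rng):
        sig = empirical_gamma_fit(rng.gamma(4.0, 0.5, 1000))
        assert sig.shape_ci[0] < sig.shape < sig.shape_ci[1]
        assert sig.scale_ci[0] < sig.scale < sig.scale_ci[1]


class TestDeviationSeries:
    def test_constant_at_mean_is_zero(self):
        dev = deviation_series(make_series([2.0] * 5), 2.0)
        assert np.all(dev.values == 0)

    def test_absolute_deviation_values(self):
        dev = deviation_series(make_series([1.0, 3.0]), 2.0)
        assert dev.values.tolist() == [1.0, 1.0]

    def test_timestamps_preserved_bitwise(self):
        s = make_series([1.0, 2.0, 5.0], fs=3.0)
        dev = deviation_series(s, 2.5)
        assert dev.timestamps is s.timestamps or np.array_equal(
            dev.timestamps, s.timestamps
        )
        assert dev.sampling_rate == s.sampling_rate


class TestMMSNormalize:
    def test_simple_window_arithmetic(self):
        # window [0, 3, 0]: Peak 3, Avrg 1 -> 3/(3+1)
        s = make_series([0, 3, 0])
        pk = detect_peaks(s)
        mms = mms_normalize(s, pk)
        assert mms.amplitudes.tolist() == [0.75]
        assert mms.event_times.tolist() == [s.timestamps[1]]

    def test_peak_to_one_as_window_average_vanishes(self):
        # tall spike over a near-zero window drives MMS towards 1
        v = np.zeros(41)
        v[20] = 1000.0
        mms = mms_normalize(make_series(v), detect_peaks(make_series(v)))
        assert mms.amplitudes[0] > 0.9

    def test_amplitudes_in_unit_interval(self, rng):
        v = np.abs(rng.normal(1.0, 0.5, 200))
        s = make_series(v)
        mms = mms_normalize(s, detect_peaks(s))
        assert np.all(mms.amplitudes > 0) and np.all(mms.amplitudes <= 1)

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_uniform_rescaling_invariance(self, k):
        v = np.abs(np.sin(np.arange(50) * 0.7)) + 0.1
        s1, s2 = make_series(v), make_series(k * v)
        m1 = mms_normalize(s1, detect_peaks(s1))
        m2 = mms_normalize(s2, detect_peaks(s2))
        np.testing.assert_allclose(m1.amplitudes, m2.amplitudes, rtol=1e-12)


class TestPipeline:
    def test_constant_input_fails_at_stage_one(self):
        with pytest.raises((DegenerateFitError, InsufficientDataError),
                           match="stage 1"):
            mms_pipeline(make_series(np.full(100, 1.0)))

    def test_scale_invariance_of_mms(self):
        values, truth = mms_spike_train(60, seed=11)
        s1 = make_series(values)
        s2 = make_series(3.0 * values)
        m1, _ = mms_pipeline(s1, min_prominence=truth["min_prominence"])
        m2, _ = mms_pipeline(s2, min_prominence=3.0 * truth["min_prominence"])
        np.testing.assert_allclose(m1.amplitudes, m2.amplitudes, rtol=1e-9)

    def test_recovers_prescribed_gamma_within_ci(self):
        values, truth = mms_spike_train(400, 400.0, 0.0017, seed=5)
        _, sig = mms_pipeline(make_series(values),
                              min_prominence=truth["min_prominence"])
        assert sig.shape_ci[0] <= truth["shape"] <= sig.shape_ci[1]
        assert sig.scale_ci[0] <= truth["scale"] <= sig.scale_ci[1]

    def test_event_times_subset_of_source_timestamps(self):
        values, truth = mms_spike_train(60, seed=3)
        s = make_series(values)
        mms, _ = mms_pipeline(s, min_prominence=truth["min_prominence"])
        assert np.all(np.isin(mms.event_times, s.timestamps))


class TestPowerLaw:
    def test_exact_inverse_relation(self):
        sigs = [GammaSignature(1.0 / b, b, (0.1, 99), (0.01, 99), 10)
                for b in (0.1, 0.2, 0.5, 1.0)]
        fit = fit_power_law(sigs)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_slope_recovery(self, rng):
        log_b = rng.uniform(-3, -1, 50)
        log_a = -0.8 * log_b + 0.3 + rng.normal(0, 0.05, 50)
        sigs = [GammaSignature(np.exp(la), np.exp(lb), (1, 2), (1, 2), 10)
                for la, lb in zip(log_a, log_b)]
        fit = fit_power_law(sigs)
        assert abs(fit.slope - (-0.8)) / 0.8 < 0.05

    def test_single_point_rejected(self):
        sig = GammaSignature(2.0, 0.5, (1, 3), (0.3, 0.7), 10)
        with pytest.raises(InvalidInputError):
            fit_power_law([sig])
        with pytest.raises(InvalidInputError):
            fit_power_law([sig, sig])


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_random_walk_mms_amplitudes_stay_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    v = np.abs(np.cumsum(rng.normal(0, 1, 300))) + 1.0
    s = make_series(v)
    try:
        mms, _ = mms_pipeline(s)
    except (DegenerateFitError, InsufficientDataError):
        return
    assert np.all(mms.amplitudes > 0) and np.all(mms.amplitudes <= 1)
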
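import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repcount import (
    CounterConfig,
    DegenerateSignalError,
    ParameterError,
    count_fourier,
    count_threshold,
    count_threshold_lowpass,
    lowpass_filter,
    run_counter,
    threshold_level,
)


def oracle_threshold_count(s, fs, frac=2.0 / 3.0, refractory=0.1):
    """Literal per-sample reference: scan all samples, apply the rules."""
    lo, hi = min(s), max(s)
    if hi - lo < 1e-9:
        return 0
    tau = lo + frac * (hi - lo)
    count, last_t = 0, None
    for k in range(1, len(s)):
        if s[k - 1] < tau <= s[k]:
            t = k / fs
            if last_t is None or t - last_t >= refractory:
                count += 1
                last_t = t
    return count


class TestThresholdLevel:
    def test_two_thirds_of_range(self, make_series):
        assert threshold_level(make_series([0, 3]), 2 / 3) == pytest.approx(2.0)

    def test_symmetric_range(self, make_series):
        assert threshold_level(make_series([-1, 1]), 2 / 3) == pytest.approx(1 / 3)

    def test_flat_signal_is_degenerate(self, make_series):
        with pytest.raises(DegenerateSignalError):
            threshold_level(make_series([5.0] * 10))

    def test_invalid_fraction(self, make_series):
        with pytest.raises(ParameterError):
            threshold_level(make_series([0, 1]), 1.5)


class TestCountThreshold:
    def test_one_crossing_per_sinusoid_period(self, sinusoid_series):
        series = sinusoid_series(f=1.0, duration_s=10.0, fs=100.0)
        assert count_threshold(series).count == 10

    def test_flat_signal_counts_zero(self, make_series):
        res = count_threshold(make_series([2.0] * 100))
        assert res.count == 0
        assert res.threshold_used is None

    def test_refractory_suppresses_second_peak(self, make_series):
        # peak pairs 0.05 s apart, one pair every 2 s over 10 s
        fs, n = 100.0, 1001
        s = np.zeros(n)
        for k in range(5):
            first = int((0.5 + 2 * k) * fs)
            s[first] = 1.0
            s[first + 5] = 1.0  # 0.05 s later
        res = count_threshold(make_series(s, fs=fs))
        assert res.count == 5

    def test_matches_bruteforce_oracle_on_random_signals(self, make_series):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(10, 400))
            fs = float(rng.choice([20.0, 50.0, 100.0]))
            if rng.random() < 0.5:
                s = np.cumsum(rng.normal(size=n))  # random walk
            else:
                t = np.arange(n) / fs
                s = (np.sin(2 * np.pi * rng.uniform(0.2, 3.0) * t)
                     + 0.3 * rng.normal(size=n))
            series = make_series(s, fs=fs)
            assert count_threshold(series).count == oracle_threshold_count(s, fs)

    @pytest.mark.parametrize("c", [0.1, 1.0, 7.3, 1e4])
    def test_amplitude_equivariance(self, make_series, c):
        rng = np.random.default_rng(5)
        t = np.arange(600) / 50.0
        s = np.sin(2 * np.pi * 0.8 * t) + 0.2 * rng.normal(size=600)
        base = make_series(s)
        scaled = make_series(c * s)
        assert count_threshold(base).count == count_threshold(scaled).count
        assert (count_threshold_lowpass(base).count
                == count_threshold_lowpass(scaled).count)
        assert count_fourier(base).count == count_fourier(scaled).count

    def test_refractory_monotonicity(self, make_series):
        rng = np.random.default_rng(9)
        t = np.arange(1500) / 50.0
        s = np.sin(2 * np.pi * 1.5 * t) + 0.5 * rng.normal(size=1500)
        series = make_series(s)
        counts = [count_threshold(series, CounterConfig(refractory_s=r)).count
                  for r in (0.0, 0.05, 0.1, 0.2, 0.5)]
        assert counts == sorted(counts, reverse=True)


class TestLowpassFilter:
    def test_impulse_response_with_printed_coefficients(self, make_series):
        series = make_series([1.0, 0.0, 0.0, 0.0])
        out = lowpass_filter(series, alpha=0.1, initial=0.0)
        assert np.allclose(out.s, [0.0, 0.1, 0.09, 0.081], rtol=1e-12)

    def test_constant_is_fixed_point(self, make_series):
        out = lowpass_filter(make_series([3.5] * 20), alpha=0.1)
        assert np.allclose(out.s, 3.5)

    def test_one_step_recursion_from_first_sample(self, make_series):
        # A_0 = X_0 = 10; A_1 = 0.9·A_0 + 0.1·X_0 = 10 (the input sample
        # drives the following output sample)
        out = lowpass_filter(make_series([10.0, 0.0]), alpha=0.1)
        assert np.allclose(out.s, [10.0, 10.0])

    def test_invalid_alpha(self, make_series):
        with pytest.raises(ParameterError):
            lowpass_filter(make_series([0, 1]), alpha=1.0)

    def test_output_stays_within_input_range(self, make_series):
        rng = np.random.default_rng(13)
        for _ in range(20):
            s = rng.normal(size=300)
            out = lowpass_filter(make_series(s), alpha=float(rng.uniform(0.05, 0.9)))
            assert out.s.min() >= s.min() - 1e-12
            assert out.s.max() <= s.max() + 1e-12

    def test_preserves_length(self, make_series):
        out = lowpass_filter(make_series(np.arange(57.0)))
        assert len(out.s) == 57

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 2 ** 20), alpha=st.floats(0.01, 0.99),
           n=st.integers(2, 300))
    def test_contraction_property(self, seed, alpha, n):
        # the recursion is a convex combination of past inputs, so the
        # output can never leave the input's range
        s = np.random.default_rng(seed).normal(size=n)
        from repcount import SignedMagnitudeSeries
        out = lowpass_filter(SignedMagnitudeSeries(fs=50.0, s=s), alpha=alpha)
        assert out.s.min() >= s.min() - 1e-12
        assert out.s.max() <= s.max() + 1e-12


class TestCountThresholdLowpass:
    def test_noiseless_sinusoid_counts_once_per_period(self, sinusoid_series):
        series = sinusoid_series(f=1.0, duration_s=30.0, fs=50.0)
        assert count_threshold_lowpass(series).count == 30

    def test_equals_composition(self, make_series):
        rng = np.random.default_rng(21)
        t = np.arange(1000) / 50.0
        s = np.sin(2 * np.pi * 0.7 * t) + 0.4 * rng.normal(size=1000)
        series = make_series(s)
        cfg = CounterConfig()
        composed = count_threshold(lowpass_filter(series, cfg.alpha), cfg)
        assert count_threshold_lowpass(series, cfg).count == composed.count

    def test_filters_out_spike_overcount(self, sinusoid_series):
        # single-sample spikes at 3x amplitude inflate the raw count;
        # the filtered count stays at one per period
        series = sinusoid_series(f=1.0, duration_s=30.0, fs=50.0)
        s = series.s.copy()
        # two spikes per period, 0.4 s apart: both cross the raised threshold
        s[(np.arange(30) * 50 + 15).astype(int)] = 3.0
        s[(np.arange(30) * 50 + 35).astype(int)] = 3.0
        from repcount import SignedMagnitudeSeries
        spiky = SignedMagnitudeSeries(fs=50.0, s=s)
        assert count_threshold(spiky).count > 30
        assert count_threshold_lowpass(spiky).count == 30

    def test_flat_signal_counts_zero(self, make_series):
        assert count_threshold_lowpass(make_series([1.0] * 50)).count == 0


class TestCountFourier:
    def test_pure_half_hertz_over_thirty_seconds(self, sinusoid_series):
        res = count_fourier(sinusoid_series(f=0.5, duration_s=30.0, fs=50.0))
        assert res.count == 15
        assert res.dominant_freq_hz == pytest.approx(0.5, abs=0.02)

    def test_dominant_component_wins(self, make_series):
        t = np.arange(int(20 * 50) + 1) / 50.0
        s = 2.0 * np.sin(2 * np.pi * 0.5 * t) + 0.5 * np.sin(2 * np.pi * 3.0 * t)
        res = count_fourier(make_series(s))
        assert res.count == 10

    def test_flat_signal_counts_zero(self, make_series):
        assert count_fourier(make_series([4.2] * 100)).count == 0

    def test_count_is_rounded_product(self, sinusoid_series):
        for f in (0.3, 0.7, 1.3):
            res = count_fourier(sinusoid_series(f=f, duration_s=30.0, fs=50.0))
            assert res.count == math.floor(res.dominant_freq_hz * res.duration_s + 0.5)

    def test_band_excludes_out_of_band_peak(self, make_series):
        # 0.05 Hz drift dominates raw spectrum but sits below the band
        t = np.arange(1501) / 50.0
        s = 5.0 * np.sin(2 * np.pi * 0.05 * t) + 1.0 * np.sin(2 * np.pi * 1.0 * t)
        res = count_fourier(make_series(s))
        assert res.dominant_freq_hz == pytest.approx(1.0, abs=0.05)
        assert res.count == 30

    def test_empty_band_counts_zero(self, make_series):
        rng = np.random.default_rng(1)
        cfg = CounterConfig(band_hz=(30.0, 40.0))  # beyond Nyquist of 50 Hz
        res = count_fourier(make_series(rng.normal(size=100)), cfg)
        assert res.count == 0


class TestDispatch:
    def test_unknown_method_rejected(self, make_series):
        with pytest.raises(ParameterError, match="unknown method"):
            run_counter("wavelet", make_series([0, 1, 0, 1]))

    def test_dispatch_labels_match(self, sinusoid_series):
        series = sinusoid_series(f=1.0, duration_s=10.0, fs=50.0)
        for m in ("threshold", "threshold_lowpass", "fourier"):
            assert run_counter(m, series).method == m
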
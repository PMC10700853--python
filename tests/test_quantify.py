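import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldclock import (
    DetrendedTrace,
    OscillatorParams,
    PeakSet,
    ReporterParams,
    baseline_level,
    build_protocol,
    compute_dff,
    detect_peaks,
    detrend_running_average,
    estimate_amplitude,
    estimate_period,
    is_rhythmic,
    normalize_amplitude,
    phase_randomized_cohort,
    restart_phase,
    running_mean,
)

from conftest import cosine_series


# --- independent oracle: per-index running-mean loop -------------------------

def brute_force_running_mean(values, window_h, step_h):
    """Trapezoidal centered mean over +/- window/2, truncated symmetrically at
    the edges; written as an explicit per-index loop."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    H = int(round(window_h / step_h)) // 2
    out = np.empty(n)
    for i in range(n):
        h = min(i, n - 1 - i, H)
        if h == 0:
            out[i] = v[i]
            continue
        total = 0.5 * v[i - h] + 0.5 * v[i + h]
        for j in range(i - h + 1, i + h):
            total += v[j]
        out[i] = total / (2 * h)
    return out


class TestComputeDff:
    def test_minimum_maps_to_zero(self):
        assert np.allclose(compute_dff([100.0, 150.0, 100.0]), [0.0, 50.0, 0.0])

    def test_constant_series_is_all_zero(self):
        assert np.allclose(compute_dff(np.full(10, 7.0)), 0.0)

    @pytest.mark.parametrize("bad", [[0.0, 1.0], [-1.0, 2.0], [np.nan, 1.0]])
    def test_nonpositive_fluorescence_rejected(self, bad):
        with pytest.raises(ValueError):
            compute_dff(bad)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e6))
    def test_invariant_to_multiplicative_rescaling(self, k):
        v = np.array([100.0, 130.0, 95.0, 160.0])
        assert np.allclose(compute_dff(k * v), compute_dff(v), atol=1e-8)


class TestDetrend:
    def test_cosine_passes_through_on_interior(self):
        t, v = cosine_series(24.0, 96.0)
        det = detrend_running_average(v, t, 24.0)
        assert np.allclose(det.values[12:-12], v[12:-12], atol=1e-9)

    def test_linear_ramp_vanishes_on_interior(self):
        t = np.arange(0.0, 97.0)
        det = detrend_running_average(3.0 * t + 2.0, t, 24.0)
        assert np.allclose(det.values[12:-12], 0.0, atol=1e-10)

    def test_cosine_plus_ramp_matches_brute_force_oracle(self):
        t, v = cosine_series(24.0, 120.0)
        y = v + 0.5 * t
        det = detrend_running_average(y, t, 24.0)
        oracle = y - brute_force_running_mean(y, 24.0, 1.0)
        assert np.max(np.abs(det.values - oracle)) < 1e-9
        assert np.allclose(det.values[12:-12], v[12:-12], atol=1e-9)

    def test_idempotent_on_interior(self):
        t, v = cosine_series(24.0, 120.0)
        y = v + 0.5 * t
        once = detrend_running_average(y, t, 24.0)
        twice = detrend_running_average(once.values, t, 24.0)
        # interior excludes one full window: the first pass distorts the edge
        # samples, which sit inside the second pass's windows up to 2 half-
        # widths in
        assert np.allclose(twice.values[24:-24], once.values[24:-24], atol=1e-9)

    def test_window_validation(self):
        t = np.arange(0.0, 20.0)
        with pytest.raises(ValueError):
            running_mean(np.ones(20), t, 24.0)  # window longer than series
        t2 = np.arange(0.0, 97.0)
        with pytest.raises(ValueError):
            running_mean(np.ones(97), t2, 23.5)  # not a multiple of the step

    def test_breaks_stop_trend_bleed_across_level_step(self):
        t = np.arange(0.0, 96.0)
        y = np.where(t < 48, 1.0, 3.0)
        det = detrend_running_average(y, t, 24.0, breaks=(48.0,))
        assert np.allclose(det.values, 0.0, atol=1e-12)


class TestDetectPeaks:
    def test_cosine_peaks_including_boundaries(self):
        t, v = cosine_series(24.0, 96.0)
        peaks = detect_peaks(DetrendedTrace(t, v))
        assert len(peaks) == 5
        assert np.allclose(peaks.peak_times_h, [0, 24, 48, 72, 96], atol=0.1)
        assert np.allclose(peaks.peak_values, 1.0, atol=1e-2)

    def test_flat_series_has_no_peaks(self):
        t = np.arange(0.0, 50.0)
        assert len(detect_peaks(DetrendedTrace(t, np.zeros(50)))) == 0

    def test_simulated_trace_against_exhaustive_local_maxima(self):
        osc, rep = OscillatorParams.default(), ReporterParams.default()
        p = build_protocol(288, 35, 0, 0)
        tr = phase_randomized_cohort(osc, rep, p, 1, seed=9)[0]
        dff = compute_dff(tr.channel("Ca"))
        det = detrend_running_average(dff, tr.time_h)
        peaks = detect_peaks(det)
        assert 11 <= len(peaks) <= 13
        assert np.all(np.abs(np.diff(peaks.peak_times_h) - 23.2) < 1.0)
        # oracle: every detected peak sits within one sample of some local
        # maximum of the raw detrended series
        v = det.values
        locmax = np.flatnonzero(
            (v[1:-1] >= v[:-2]) & (v[1:-1] > v[2:])
        ) + 1
        cand = set(locmax) | {0, len(v) - 1}
        for pt in peaks.peak_times_h:
            assert min(abs(pt - det.time_h[i]) for i in cand) <= 1.0

    def test_min_separation_enforced(self):
        t, v = cosine_series(24.0, 240.0)
        peaks = detect_peaks(DetrendedTrace(t, v), min_separation_h=30.0)
        assert np.all(np.diff(peaks.peak_times_h) >= 30.0)


class TestPeriodAndAmplitude:
    def test_period_from_peak_times(self):
        pk = PeakSet(np.array([2.0, 26.0, 50.0]), np.ones(3))
        assert estimate_period(pk) == pytest.approx(24.0)

    def test_single_peak_period_undefined(self):
        pk = PeakSet(np.array([5.0]), np.ones(1))
        assert estimate_period(pk) is None

    def test_window_restricts_peaks(self):
        pk = PeakSet(np.array([2.0, 26.0, 50.0, 80.0]), np.ones(4))
        assert estimate_period(pk, (0.0, 51.0)) == pytest.approx(24.0)

    def test_cosine_amplitude_recovered(self):
        t, v = cosine_series(24.0, 120.0, amplitude=17.0, peak_at_h=3.0)
        amp = estimate_amplitude(DetrendedTrace(t, v))
        assert amp == pytest.approx(17.0, rel=0.01)

    def test_amplitude_is_linear_in_signal_scale(self):
        t, v = cosine_series(24.0, 120.0, peak_at_h=5.0)
        a1 = estimate_amplitude(DetrendedTrace(t, v))
        a3 = estimate_amplitude(DetrendedTrace(t, 3.0 * v))
        assert a3 == pytest.approx(3.0 * a1, rel=1e-9)

    def test_no_cycles_gives_none(self):
        t = np.arange(0.0, 60.0)
        assert estimate_amplitude(DetrendedTrace(t, np.zeros(60))) is None

    def test_normalization(self):
        assert normalize_amplitude(15.0, 30.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            normalize_amplitude(15.0, 0.0)


class TestBaseline:
    def test_constant_dff_baseline(self):
        t = np.arange(0.0, 96.0)
        assert baseline_level(np.full(96, 50.0), t, (10, 80)) == pytest.approx(50.0)

    def test_zero_mean_cosine_baseline_near_zero(self):
        t, v = cosine_series(24.0, 96.0, amplitude=30.0)
        assert abs(baseline_level(v, t, (12, 84))) < 0.5


class TestRhythmicity:
    def test_noiseless_cosine_is_rhythmic(self):
        t, v = cosine_series(24.0, 96.0)
        verdict, score = is_rhythmic(DetrendedTrace(t, v))
        assert verdict and score > 0.9

    def test_white_noise_false_positive_rate_below_5pct(self):
        t = np.arange(0.0, 96.0)
        hits = 0
        for seed in range(100):
            v = np.random.default_rng(seed).normal(size=96)
            verdict, _ = is_rhythmic(DetrendedTrace(t, v))
            hits += verdict
        assert hits < 5

    def test_window_shorter_than_two_days_rejected(self):
        t, v = cosine_series(24.0, 96.0)
        with pytest.raises(ValueError):
            is_rhythmic(DetrendedTrace(t, v), (0.0, 40.0))


class TestRestartPhase:
    def test_first_peak_phase(self):
        pk = PeakSet(np.array([192 + 14.0, 192 + 37.0]), np.ones(2))
        assert restart_phase(pk, 192.0, skip_first=False) == pytest.approx(14.0)

    def test_second_peak_phase_wraps(self):
        pk = PeakSet(np.array([192 + 5.0, 192 + 28.8]), np.ones(2))
        assert restart_phase(pk, 192.0, skip_first=True) == pytest.approx(4.8)

    def test_insufficient_peaks(self):
        pk = PeakSet(np.array([200.0]), np.ones(1))
        with pytest.raises(ValueError):
            restart_phase(pk, 192.0, skip_first=True)
        with pytest.raises(ValueError):
            restart_phase(PeakSet(np.array([10.0]), np.ones(1)), 192.0)
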
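"""Per-trace rhythm quantification.

The measurement chain mirrors standard fluorescence-rhythm practice:
dF/F0 normalization against the recording minimum, 24-h running-average
detrending, peak detection with a minimum circadian separation, and summary
statistics (period as the mean successive peak interval, amplitude as mean
half peak-to-trough, baseline as the retained trend component, and a
rhythmicity verdict from the circadian-lag autocorrelation).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_prominences


@dataclass
class DetrendedTrace:
    """A detrended series.

    ``edge_margin_h`` flags how far from the series ends (and from each
    interior ``breaks`` time) the trend estimate used truncated windows;
    peak *times* inside those margins are biased and are skipped by
    :func:`detect_peaks`.  Directly constructed traces default to margin 0.
    """

    time_h: np.ndarray
    values: np.ndarray
    source_channel: str = ""
    window_h: float = 24.0
    breaks: tuple = ()
    edge_margin_h: float = 0.0

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.time_h) != len(self.values):
            raise ValueError("time/value length mismatch")

    @property
    def step_h(self) -> float:
        return float(self.time_h[1] - self.time_h[0])

    def window(self, start_h: float, end_h: float) -> "DetrendedTrace":
        m = (self.time_h >= start_h) & (self.time_h <= end_h)
        inner = tuple(b for b in self.breaks if start_h < b < end_h)
        return DetrendedTrace(self.time_h[m], self.values[m],
                              self.source_channel, self.window_h,
                              inner, self.edge_margin_h)

    def unreliable(self, times) -> np.ndarray:
        """Boolean mask: which of ``times`` fall in an edge-distorted zone."""
        t = np.asarray(times, dtype=float)
        if self.edge_margin_h <= 0 or len(self.time_h) == 0:
            return np.zeros(t.shape, dtype=bool)
        edges = [self.time_h[0], self.time_h[-1], *self.breaks]
        bad = np.zeros(t.shape, dtype=bool)
        for e in edges:
            bad |= np.abs(t - e) < self.edge_margin_h
        return bad


@dataclass
class PeakSet:
    peak_times_h: np.ndarray
    peak_values: np.ndarray
    channel: str = ""
    detection_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peak_times_h = np.asarray(self.peak_times_h, dtype=float)
        self.peak_values = np.asarray(self.peak_values, dtype=float)
        if np.any(np.diff(self.peak_times_h) <= 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_times_h)

    def in_window(self, start_h: float, end_h: float) -> "PeakSet":
        m = (self.peak_times_h >= start_h) & (self.peak_times_h <= end_h)
        return PeakSet(self.peak_times_h[m], self.peak_values[m],
                       self.channel, self.detection_params)


@dataclass
class RhythmSummary:
    channel: str
    window: tuple[float, float]
    period_h: float | None
    amplitude: float | None
    amplitude_norm: float | None
    baseline_pct: float
    rhythmic: bool
    rhythm_score: float


def compute_dff(trace_values) -> np.ndarray:
    """dF/F0 in percent, with F0 the minimum fluorescence of the recording.

    The minimum of the output is exactly 0 %.
    """
    v = np.asarray(trace_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty trace")
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("fluorescence must be finite and positive (F0 > 0)")
    f0 = v.min()
    return 100.0 * (v - f0) / f0


def _check_uniform(time_h: np.ndarray) -> float:
    dt = np.diff(time_h)
    if len(dt) == 0:
        raise ValueError("series too short")
    step = float(dt[0])
    if step <= 0 or np.any(np.abs(dt - step) > 1e-6):
        raise ValueError("sampling grid must be uniform")
    return step


def running_mean(values, time_h, window_h: float = 24.0,
                 breaks=()) -> np.ndarray:
    """Centered running mean over ``window_h`` with half-sample end weights.

    The full-window mean is a trapezoidal average over [t - W/2, t + W/2]
    (half weight on the two end samples), which annihilates both a linear
    trend and any oscillation whose period equals the window exactly.  Edges
    use shrinking symmetric windows so the output has the input's length; at
    the first/last sample the "mean" is the sample itself.

    ``breaks`` lists interior times (h) at which the trend is discontinuous
    (e.g. temperature steps): the mean is then computed independently per
    segment, so a level jump does not bleed into neighbouring samples.  A
    segment shorter than the window is reduced to its own mean.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(time_h, dtype=float)
    if len(breaks):
        out = np.empty_like(v)
        edges = [t[0]] + sorted(float(b) for b in breaks) + [np.inf]
        for a, b in zip(edges, edges[1:]):
            m = (t >= a) & (t < b)
            if not m.any():
                continue
            seg_v, seg_t = v[m], t[m]
            step = seg_t[1] - seg_t[0] if len(seg_t) > 1 else 1.0
            if len(seg_v) <= int(round(window_h / step)):
                out[m] = seg_v.mean()
            else:
                out[m] = running_mean(seg_v, seg_t, window_h)
        return out
    step = _check_uniform(t)
    m = window_h / step
    if abs(m - round(m)) > 1e-9 or round(m) < 2 or round(m) % 2 != 0:
        raise ValueError("window_h must be a positive even multiple of the step")
    m = int(round(m))
    H = m // 2
    n = len(v)
    if m + 1 > n:
        raise ValueError("window longer than series")
    w = np.ones(m + 1)
    w[0] = w[-1] = 0.5
    w /= m
    out = np.empty(n)
    out[H:n - H] = np.convolve(v, w, mode="valid")
    for i in range(H):
        for j in (i, n - 1 - i):
            h = i
            if h == 0:
                out[j] = v[j]
            else:
                seg = v[j - h:j + h + 1].copy()
                seg[0] *= 0.5
                seg[-1] *= 0.5
                out[j] = seg.sum() / (2 * h)
    return out


def detrend_running_average(values, time_h, window_h: float = 24.0,
                            source_channel: str = "",
                            breaks=()) -> DetrendedTrace:
    """Subtract the centered ``window_h`` running average from the series.

    Pass the temperature-step times as ``breaks`` to detrend each protocol
    segment independently (a level step otherwise contaminates the trend for
    half a window on either side of the boundary).
    """
    trend = running_mean(values, time_h, window_h, breaks)
    return DetrendedTrace(np.asarray(time_h, dtype=float),
                          np.asarray(values, dtype=float) - trend,
                          source_channel, window_h,
                          tuple(float(b) for b in breaks), window_h / 2.0)


def _smooth(values: np.ndarray, time_h: np.ndarray, smooth_h: float) -> np.ndarray:
    """Centered boxcar smoother with shrinking edge windows."""
    step = _check_uniform(time_h)
    k = max(int(round(smooth_h / step)) // 2, 0)
    if k == 0:
        return values.copy()
    n = len(values)
    out = np.empty(n)
    csum = np.concatenate(([0.0], np.cumsum(values)))
    for i in range(n):
        a, b = max(0, i - k), min(n - 1, i + k)
        out[i] = (csum[b + 1] - csum[a]) / (b - a + 1)
    return out


def _refine_quadratic(y: np.ndarray, i: int, t: np.ndarray):
    """Sub-sample vertex of the parabola through points (i-1, i, i+1)."""
    if i == 0 or i == len(y) - 1:
        return float(t[i]), float(y[i])
    d2 = y[i - 1] - 2 * y[i] + y[i + 1]
    if d2 >= 0:
        return float(t[i]), float(y[i])
    dt = 0.5 * (y[i - 1] - y[i + 1]) / d2
    dt = float(np.clip(dt, -1.0, 1.0))
    step = t[1] - t[0]
    val = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * dt
    return float(t[i] + dt * step), float(val)


def detect_peaks(detrended: DetrendedTrace, min_separation_h: float = 16.0,
                 smooth_h: float = 3.0, rel_prominence: float = 0.2) -> PeakSet:
    """Local maxima of the lightly smoothed series, kept greedily in order of
    decreasing prominence subject to a minimum separation, with quadratic
    sub-sample refinement.  Boundary maxima are eligible (a peak exactly at
    the start of a recording is still a peak).  Candidates whose prominence
    falls below ``rel_prominence`` times the largest prominence are discarded
    (suppresses shoulder artifacts near the detrending edges).  May be empty.
    """
    t, raw = detrended.time_h, detrended.values
    n = len(raw)
    params = {"min_separation_h": min_separation_h, "smooth_h": smooth_h,
              "rel_prominence": rel_prominence}
    if n < 3 or np.ptp(raw) == 0:
        return PeakSet(np.array([]), np.array([]), detrended.source_channel, params)
    y = _smooth(raw, t, smooth_h)

    # Candidate maxima and their prominences are computed on a
    # reflection-padded copy: without padding, a genuine peak close to either
    # end has its prominence truncated by the series cut and would be lost to
    # the relative floor.
    step = detrended.step_h
    pad = min(max(int(round(min_separation_h / step)), 1), n - 1)
    yp = np.concatenate([y[1:pad + 1][::-1], y, y[-pad - 1:-1][::-1]])
    locs, _ = find_peaks(yp)
    proms = peak_prominences(yp, locs)[0] if len(locs) else np.array([])
    cand_idx, cand_prom = [], []
    guard = max(int(round(0.5 * min_separation_h / step)), 1)
    max_slope = np.abs(np.diff(raw)).max()
    bad_zone = detrended.unreliable(t)
    for loc, prom in zip(locs, proms):
        i = int(loc) - pad
        if not 0 <= i <= n - 1:
            continue
        if bad_zone[i]:
            continue  # peak time would be biased by a truncated-window trend
        if i in (0, n - 1):
            # A boundary maximum counts only as a *truncated vertex*: it must
            # dominate the adjacent half-separation span and the series must
            # have nearly levelled off (a steep cut-off tail is a rising
            # flank, not a peak).
            inc = raw[0] - raw[1] if i == 0 else raw[-1] - raw[-2]
            span = y[:guard + 1] if i == 0 else y[n - 1 - guard:]
            if y[i] < span.max() or inc >= 0.5 * max_slope:
                continue
        cand_idx.append(i)
        cand_prom.append(float(prom))

    floor = rel_prominence * max(cand_prom, default=0.0)
    order = np.argsort(cand_prom)[::-1]
    kept: list[int] = []
    for o in order:
        if cand_prom[o] < floor:
            break
        i = cand_idx[o]
        if all(abs(i - j) * step >= min_separation_h for j in kept):
            kept.append(i)
    kept.sort()

    times, vals = [], []
    for i in kept:
        ti, _ = _refine_quadratic(y, i, t)       # timing from smoothed series
        _, vi = _refine_quadratic(raw, i, t)     # height from raw series
        times.append(ti)
        vals.append(vi)
    order2 = np.argsort(times)
    return PeakSet(np.array(times)[order2], np.array(vals)[order2],
                   detrended.source_channel, params)


def estimate_period(peaks: PeakSet, window: tuple[float, float] | None = None):
    """Mean successive peak interval within ``window``; None if fewer than
    two peaks (undefined, as distinct from zero)."""
    ps = peaks if window is None else peaks.in_window(*window)
    if len(ps) < 2:
        return None
    return float(np.mean(np.diff(ps.peak_times_h)))


def estimate_amplitude(detrended: DetrendedTrace,
                       window: tuple[float, float] | None = None,
                       min_separation_h: float = 16.0,
                       smooth_h: float = 3.0):
    """Mean half peak-to-trough excursion of the detrended series within
    ``window``; None when no full cycle (no peak or no trough) is present."""
    seg = detrended if window is None else detrended.window(*window)
    if len(seg.values) < 3:
        return None
    peaks = detect_peaks(seg, min_separation_h, smooth_h)
    neg = DetrendedTrace(seg.time_h, -seg.values, seg.source_channel, seg.window_h)
    troughs = detect_peaks(neg, min_separation_h, smooth_h)
    if len(peaks) == 0 or len(troughs) == 0:
        return None
    return float((peaks.peak_values.mean() + troughs.peak_values.mean()) / 2.0)


def normalize_amplitude(amp: float, amp_pre: float) -> float:
    """Amplitude as a fraction of the pre-condition amplitude."""
    if amp_pre is None or amp_pre <= 0:
        raise ValueError("pre-condition amplitude must be positive")
    return float(amp / amp_pre)


def baseline_level(dff_values, time_h, window: tuple[float, float],
                   window_h: float = 24.0, breaks=()) -> float:
    """Mean of the running-average trend of dF/F0 over ``window`` (percent):
    the slow component with the oscillation removed."""
    t = np.asarray(time_h, dtype=float)
    trend = running_mean(dff_values, t, window_h, breaks)
    m = (t >= window[0]) & (t <= window[1])
    if not m.any():
        raise ValueError("empty window")
    return float(trend[m].mean())


def is_rhythmic(detrended: DetrendedTrace,
                window: tuple[float, float] | None = None,
                score_threshold: float = 0.3,
                lag_range_h: tuple[float, float] = (20.0, 28.0),
                min_peaks: int = 2):
    """Rhythmicity verdict from the circadian-lag autocorrelation.

    ``rhythm_score`` is the maximum Pearson autocorrelation of the detrended
    series at lags between 20 and 28 h; the series is called rhythmic when the
    score reaches ``score_threshold`` (calibrated to <5 % false positives on
    white noise) and at least ``min_peaks`` peaks are detected in the window.
    Requires a window of at least 48 h.
    """
    seg = detrended if window is None else detrended.window(*window)
    t, v = seg.time_h, seg.values
    if len(t) < 2 or (t[-1] - t[0]) < 48.0:
        raise ValueError("rhythmicity needs a window of at least 48 h")
    step = _check_uniform(t)
    lags = np.arange(int(np.ceil(lag_range_h[0] / step)),
                     int(np.floor(lag_range_h[1] / step)) + 1)
    score = 0.0
    for L in lags:
        if L >= len(v) - 2:
            continue
        a, b = v[:-L], v[L:]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        score = max(score, r)
    npeaks = len(detect_peaks(seg))
    return (score >= score_threshold and npeaks >= min_peaks), score


def restart_phase(peaks: PeakSet, rewarm_time_h: float,
                  skip_first: bool = False) -> float:
    """Phase (h in [0, 24)) of the first post-rewarm peak relative to the
    rewarm time.  With ``skip_first`` the second peak is used instead: the
    first transcription-reporter peak after rewarming can reflect an acute
    reporter response rather than the restarted rhythm.
    """
    after = peaks.peak_times_h[peaks.peak_times_h > rewarm_time_h]
    need = 2 if skip_first else 1
    if len(after) < need:
        raise ValueError(
            f"need at least {need} peak(s) after rewarming, found {len(after)}"
        )
    sel = after[1] if skip_first else after[0]
    return float((sel - rewarm_time_h) % 24.0)
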
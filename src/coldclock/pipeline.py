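"""End-to-end orchestration: simulate -> quantify -> phase analysis -> report.

``run_experiment`` takes a validated :class:`ExperimentConfig`, simulates (or
loads) a cohort of slices, quantifies every (slice, channel, window) cell into
one summary row, computes cohort circular summaries of the post-rewarm restart
phases, and writes traces, tables and provenance to the output directory.
Everything is deterministic given the config seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circular import PhaseSample, circular_mean, export_rayleigh_plot, phase_difference
from .protocol import TemperatureProtocol, build_protocol
from .quantify import (
    RhythmSummary,
    baseline_level,
    compute_dff,
    detect_peaks,
    detrend_running_average,
    estimate_amplitude,
    estimate_period,
    is_rhythmic,
    normalize_amplitude,
    restart_phase,
)
from .simulate import (
    MultiChannelTrace,
    OscillatorParams,
    ReporterParams,
    params_hash,
    phase_randomized_cohort,
)
from .traceio import write_trace_csv

#: window length used for condition comparisons (4-day blocks)
BLOCK_H = 96.0
#: minimum window length for a rhythmicity verdict
MIN_WINDOW_H = 48.0

#: channels whose first post-rewarm peak is treated as an acute reporter
#: response (restart phase read from the second peak)
SKIP_FIRST_PEAK = {"Per2": True, "Bmal1": True, "Ca": False}


class ConfigError(ValueError):
    """The experiment configuration failed validation."""


_PROTOCOL_KEYS = {"pre_h", "cold_temp_C", "cold_h", "post_h", "warm_temp_C"}


@dataclass
class ExperimentConfig:
    protocol: dict
    n_slices: int
    seed: int
    channels: tuple[str, ...] = ("Ca", "Per2", "Bmal1")
    windows: object = "segments"  # "segments" or list of [start_h, end_h]
    oscillator_overrides: dict = field(default_factory=dict)
    reporter_overrides: dict = field(default_factory=dict)
    out_dir: str | None = None
    step_h: float = 0.1
    make_figures: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {unknown}")
        required = {"protocol", "n_slices", "seed"}
        missing = sorted(required - set(d))
        if missing:
            raise ConfigError(f"missing required config key(s): {missing}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.protocol, dict):
            raise ConfigError("protocol must be a mapping")
        bad = sorted(set(self.protocol) - _PROTOCOL_KEYS)
        if bad:
            raise ConfigError(f"unknown protocol key(s): {bad}")
        if int(self.n_slices) < 1:
            raise ConfigError("n_slices must be >= 1")
        defaults = OscillatorParams.default().channels
        for name in self.channels:
            if name not in defaults:
                raise ConfigError(f"unknown channel {name!r}")
        for ov, pool in (
            (self.oscillator_overrides, defaults),
            (self.reporter_overrides, ReporterParams.default().channels),
        ):
            for ch, fields_ in ov.items():
                if ch not in pool:
                    raise ConfigError(f"override for unknown channel {ch!r}")
                valid = {f.name for f in dataclasses.fields(type(pool[ch]))}
                bad = sorted(set(fields_) - valid)
                if bad:
                    raise ConfigError(f"unknown field(s) for {ch!r}: {bad}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(self.channels)
        return d


@dataclass
class RunReport:
    summary: pd.DataFrame
    circular: pd.DataFrame
    traces: list[MultiChannelTrace]
    provenance: dict


def _tuplify(value):
    if isinstance(value, (list, tuple)):
        return tuple(_tuplify(v) for v in value)
    return value


def build_params(config: ExperimentConfig) -> tuple[OscillatorParams, ReporterParams]:
    osc = OscillatorParams.default()
    rep = ReporterParams.default()
    for ch, fields_ in config.oscillator_overrides.items():
        kw = {k: _tuplify(v) for k, v in fields_.items()}
        osc.channels[ch] = dataclasses.replace(osc.channels[ch], **kw)
    for ch, fields_ in config.reporter_overrides.items():
        kw = {k: _tuplify(v) for k, v in fields_.items()}
        rep.channels[ch] = dataclasses.replace(rep.channels[ch], **kw)
    return osc, rep


def segment_windows(protocol: TemperatureProtocol,
                    block_h: float = BLOCK_H) -> list[tuple[float, float]]:
    """Analysis windows: protocol segments split into 4-day blocks; a short
    remainder (< 48 h) is merged into the preceding block."""
    edges = list(protocol.start_times) + [protocol.total_h]
    windows: list[tuple[float, float]] = []
    for a, b in zip(edges, edges[1:]):
        t = a
        seg: list[tuple[float, float]] = []
        while b - t > 1e-9:
            e = min(t + block_h, b)
            seg.append((t, e))
            t = e
        if len(seg) > 1 and seg[-1][1] - seg[-1][0] < MIN_WINDOW_H:
            last = seg.pop()
            seg[-1] = (seg[-1][0], last[1])
        windows.extend(seg)
    return windows


def segments_from_trace(trace: MultiChannelTrace) -> list[tuple[float, float]]:
    """Segment boundaries inferred from the temp_C column of a loaded trace."""
    t, T = trace.time_h, trace.temp_C
    change = np.flatnonzero(np.diff(T) != 0) + 1
    edges = [t[0], *t[change], t[-1] + (t[1] - t[0])]
    return list(zip(edges, edges[1:]))


def trace_breaks(trace: MultiChannelTrace) -> tuple[float, ...]:
    """Interior temperature-step times of a trace, used to detrend each
    protocol segment independently."""
    t, T = trace.time_h, trace.temp_C
    change = np.flatnonzero(np.diff(T) != 0) + 1
    return tuple(float(x) for x in t[change])


def quantify_trace(trace: MultiChannelTrace,
                   windows: list[tuple[float, float]] | None = None,
                   detrend_window_h: float = 24.0) -> pd.DataFrame:
    """One summary row per (channel, window) for a single slice."""
    if windows is None:
        windows = []
        for a, b in segments_from_trace(trace):
            t0 = a
            while b - t0 > 1e-9:
                e = min(t0 + BLOCK_H, b)
                windows.append((t0, e))
                t0 = e
    rows = []
    slice_id = trace.meta.get("slice_id", "")
    breaks = trace_breaks(trace)
    for name, raw in trace.channels.items():
        dff = compute_dff(raw)
        det = detrend_running_average(dff, trace.time_h, detrend_window_h,
                                      name, breaks)
        peaks = detect_peaks(det)
        amp_pre = estimate_amplitude(det, windows[0]) if windows else None
        for (a, b) in windows:
            period = estimate_period(peaks, (a, b))
            amp = estimate_amplitude(det, (a, b))
            try:
                rhythmic, score = is_rhythmic(det, (a, b))
            except ValueError:  # window too short for a verdict
                rhythmic, score = False, float("nan")
            summary = RhythmSummary(
                channel=name,
                window=(a, b),
                period_h=period,
                amplitude=amp,
                amplitude_norm=(
                    None if (amp is None or not amp_pre)
                    else normalize_amplitude(amp, amp_pre)
                ),
                baseline_pct=baseline_level(
                    dff, trace.time_h, (a, b), detrend_window_h, breaks
                ),
                rhythmic=bool(rhythmic),
                rhythm_score=score,
            )
            rows.append(
                {
                    "slice": slice_id,
                    "channel": summary.channel,
                    "window_start_h": summary.window[0],
                    "window_end_h": summary.window[1],
                    "period_h": np.nan if summary.period_h is None else summary.period_h,
                    "amplitude_pct": np.nan if summary.amplitude is None else summary.amplitude,
                    "amplitude_norm": (
                        np.nan if summary.amplitude_norm is None
                        else summary.amplitude_norm
                    ),
                    "baseline_pct": summary.baseline_pct,
                    "rhythmic": summary.rhythmic,
                    "rhythm_score": summary.rhythm_score,
                }
            )
    return pd.DataFrame(rows)


def restart_phases(traces: list[MultiChannelTrace], rewarm_time_h: float,
                   channel: str,
                   skip_first: bool | None = None) -> PhaseSample:
    """Post-rewarm restart phase of ``channel`` for each slice in a cohort."""
    if skip_first is None:
        skip_first = SKIP_FIRST_PEAK.get(channel, False)
    phases, labels = [], []
    for tr in traces:
        dff = compute_dff(tr.channel(channel))
        det = detrend_running_average(dff, tr.time_h, source_channel=channel,
                                      breaks=trace_breaks(tr))
        peaks = detect_peaks(det)
        phases.append(restart_phase(peaks, rewarm_time_h, skip_first))
        labels.append(tr.meta.get("slice_id", f"slice-{len(labels):03d}"))
    return PhaseSample(np.array(phases), tuple(labels), reference="cold_end")


def _rewarm_time(protocol: TemperatureProtocol) -> float | None:
    """Start of the final warm segment after a cold segment, if any."""
    temps = protocol.temperatures
    starts = protocol.start_times
    if len(temps) >= 2 and temps[-1] > temps[-2]:
        return float(starts[-1])
    return None


def run_experiment(config: ExperimentConfig) -> RunReport:
    config.validate()
    protocol = build_protocol(**config.protocol)
    osc, rep = build_params(config)
    traces = phase_randomized_cohort(
        osc, rep, protocol, int(config.n_slices), int(config.seed),
        step_h=config.step_h,
    )
    if config.channels != tuple(osc.channels):
        for tr in traces:
            tr.channels = {k: v for k, v in tr.channels.items()
                           if k in config.channels}

    windows = (
        segment_windows(protocol) if config.windows == "segments"
        else [tuple(map(float, w)) for w in config.windows]
    )
    summary = pd.concat(
        [quantify_trace(tr, windows) for tr in traces], ignore_index=True
    )

    circ_rows = []
    phase_samples: dict[str, PhaseSample] = {}
    rewarm = _rewarm_time(protocol)
    if rewarm is not None:
        for name in config.channels:
            try:
                sample = restart_phases(traces, rewarm, name)
            except ValueError:
                continue
            phase_samples[name] = sample
            cs = circular_mean(sample)
            circ_rows.append(
                {
                    "channel": name,
                    "condition": "post_rewarm",
                    "n": cs.n,
                    "mean_phase_h": cs.mean_phase_h,
                    "resultant_length": cs.resultant_length,
                    "circ_sd_h": cs.circ_sd_h,
                    "rayleigh_z": cs.rayleigh_z,
                    "rayleigh_p": cs.rayleigh_p,
                }
            )
    circular = pd.DataFrame(circ_rows)

    provenance = {
        "config": config.to_dict(),
        "seed": int(config.seed),
        "params_hash": params_hash(osc, rep, protocol),
        "version": __version__,
        "n_traces": len(traces),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        (out / "traces").mkdir(parents=True, exist_ok=True)
        for tr in traces:
            write_trace_csv(tr, out / "traces" / f"{tr.meta['slice_id']}.csv")
        summary.to_csv(out / "summary.csv", index=False)
        circular.to_csv(out / "circular.csv", index=False)
        (out / "config_echo.json").write_text(json.dumps(provenance, indent=2))
        if config.make_figures:
            for name, sample in phase_samples.items():
                export_rayleigh_plot(
                    circular_mean(sample), sample,
                    out / f"rayleigh_{name}.png",
                )
    return RunReport(summary, circular, traces, provenance)


def duration_sweep(
    durations_h=(6.0, 12.0, 24.0, 48.0, 96.0),
    n_slices: int = 9,
    seed: int = 0,
    cold_temp_C: float = 15.0,
    pre_h: float = 96.0,
    post_h: float = 96.0,
    channels: tuple[str, ...] = ("Ca", "Bmal1"),
) -> pd.DataFrame:
    """Cold-exposure-duration sweep: first-peak restart phase per duration.

    Returns one row per (duration, channel) with the cohort circular mean
    phase, resultant length and circular SD -- the summary behind the
    "how long must the cold last to reset the clock" question.
    """
    osc, rep = OscillatorParams.default(), ReporterParams.default()
    rows = []
    rng = np.random.default_rng(seed)
    for dur in durations_h:
        protocol = build_protocol(pre_h, cold_temp_C, float(dur), post_h)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        traces = phase_randomized_cohort(osc, rep, protocol, n_slices, sub_seed)
        for name in channels:
            sample = restart_phases(traces, pre_h + float(dur), name)
            cs = circular_mean(sample)
            rows.append(
                {
                    "cold_h": float(dur),
                    "channel": name,
                    "n": cs.n,
                    "mean_phase_h": cs.mean_phase_h,
                    "resultant_length": cs.resultant_length,
                    "circ_sd_h": cs.circ_sd_h,
                    "rayleigh_p": cs.rayleigh_p,
                }
            )
    return pd.DataFrame(rows)


def cohort_phase_difference(traces: list[MultiChannelTrace], channel_a: str,
                            channel_b: str,
                            window: tuple[float, float] | None = None) -> list[float]:
    """Per-slice mean circular peak-time difference b - a (hours)."""
    diffs = []
    for tr in traces:
        sets = {}
        for name in (channel_a, channel_b):
            dff = compute_dff(tr.channel(name))
            det = detrend_running_average(dff, tr.time_h, source_channel=name,
                                          breaks=trace_breaks(tr))
            peaks = detect_peaks(det)
            sets[name] = peaks if window is None else peaks.in_window(*window)
        diffs.append(phase_difference(sets[channel_a], sets[channel_b]))
    return diffs
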
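"""Piecewise-constant temperature schedules for chill/rewarm recordings."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: allowed temperature range for a protocol segment (deg C)
TEMP_MIN_C = 5.0
TEMP_MAX_C = 40.0


@dataclass(frozen=True)
class TemperatureProtocol:
    """A temperature schedule over a recording.

    ``segments`` is an ordered tuple of ``(start_h, temp_C)`` pairs; each
    segment holds from its start until the next segment's start (the last one
    until ``total_h``).  The schedule is right-continuous: a sample taken
    exactly at a boundary belongs to the new segment.
    """

    segments: tuple[tuple[float, float], ...]
    total_h: float

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if not np.isfinite(self.total_h) or self.total_h <= 0:
            raise ValueError("total_h must be positive and finite")
        starts = [s for s, _ in self.segments]
        temps = [t for _, t in self.segments]
        if starts[0] != 0:
            raise ValueError("first segment must start at 0 h")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment starts must be strictly increasing")
        if any(s >= self.total_h for s in starts):
            raise ValueError("all segment starts must lie before total_h")
        for t in temps:
            if not (TEMP_MIN_C <= t <= TEMP_MAX_C):
                raise ValueError(
                    f"temperature {t} degC outside [{TEMP_MIN_C}, {TEMP_MAX_C}]"
                )

    @property
    def start_times(self) -> np.ndarray:
        return np.array([s for s, _ in self.segments], dtype=float)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([t for _, t in self.segments], dtype=float)

    def temp_at(self, time_h):
        """Temperature at ``time_h`` (scalar or array), right-continuous."""
        t = np.asarray(time_h, dtype=float)
        if np.any(t < 0) or np.any(t > self.total_h):
            raise ValueError("time outside protocol range")
        idx = np.searchsorted(self.start_times, t, side="right") - 1
        out = self.temperatures[idx]
        return float(out) if np.isscalar(time_h) else out

    def boundaries(self) -> list[float]:
        """Interior segment-change times (h)."""
        return [float(s) for s, _ in self.segments[1:]]


def build_protocol(
    pre_h: float,
    cold_temp_C: float,
    cold_h: float,
    post_h: float,
    warm_temp_C: float = 35.0,
) -> TemperatureProtocol:
    """Three-segment chill protocol: warm / cold / rewarm.

    ``build_protocol(96, 15, 96, 96)`` reproduces the reference schedule of
    4 days at 35 degC, 4 days cold, 4 days rewarmed.  Zero-length phases are
    dropped, so degenerate constant protocols are allowed.
    """
    for name, d in (("pre_h", pre_h), ("cold_h", cold_h), ("post_h", post_h)):
        if not np.isfinite(d) or d < 0:
            raise ValueError(f"{name} must be a non-negative finite duration")
    total = pre_h + cold_h + post_h
    if total <= 0:
        raise ValueError("at least one phase must have positive duration")
    raw = [
        (0.0, warm_temp_C, pre_h),
        (pre_h, cold_temp_C, cold_h),
        (pre_h + cold_h, warm_temp_C, post_h),
    ]
    segments: list[tuple[float, float]] = []
    for start, temp, dur in raw:
        if dur <= 0:
            continue
        if segments and segments[-1][1] == temp:
            continue  # merge with running segment at the same temperature
        segments.append((float(start), float(temp)))
    # re-anchor in case the first phase had zero length
    if segments[0][0] != 0.0:
        segments[0] = (0.0, segments[0][1])
    return TemperatureProtocol(tuple(segments), float(total))
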
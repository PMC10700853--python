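"""Circular statistics on a 24-h phase circle.

Phases are hours in [0, 24) mapped to angles by 2*pi*phase/24.  The summary
statistics are the circular mean direction, the mean resultant length R, the
circular standard deviation sqrt(-2 ln R) (in hours), and the Rayleigh test
of uniformity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .quantify import PeakSet

HOURS_PER_CYCLE = 24.0


@dataclass
class PhaseSample:
    phases_h: np.ndarray
    labels: tuple[str, ...] | None = None
    reference: str = "absolute"  # one of: cold_start, cold_end, absolute

    def __post_init__(self) -> None:
        self.phases_h = np.asarray(self.phases_h, dtype=float) % HOURS_PER_CYCLE
        if self.labels is not None:
            self.labels = tuple(self.labels)
            if len(self.labels) != len(self.phases_h):
                raise ValueError("labels length mismatch")
            if len(set(self.labels)) != len(self.labels):
                raise ValueError("labels must be unique")
        if self.reference not in ("cold_start", "cold_end", "absolute"):
            raise ValueError(f"unknown reference {self.reference!r}")

    def __len__(self) -> int:
        return len(self.phases_h)


@dataclass
class CircularSummary:
    mean_phase_h: float  # NaN when the mean is undefined (R == 0)
    resultant_length: float
    circ_sd_h: float     # inf when R == 0
    rayleigh_z: float
    rayleigh_p: float
    n: int

    @property
    def mean_defined(self) -> bool:
        return not math.isnan(self.mean_phase_h)


def _as_phases(phases) -> np.ndarray:
    if isinstance(phases, PhaseSample):
        return phases.phases_h
    return np.asarray(phases, dtype=float) % HOURS_PER_CYCLE


_R_EPS = 1e-12


def _mean_resultant(phases) -> tuple[float, float, int]:
    ph = _as_phases(phases)
    n = len(ph)
    if n == 0:
        raise ValueError("need at least one phase")
    ang = 2.0 * np.pi * ph / HOURS_PER_CYCLE
    c, s = np.cos(ang).mean(), np.sin(ang).mean()
    R = float(np.hypot(c, s))
    mean_h = float((math.atan2(s, c) * HOURS_PER_CYCLE / (2.0 * np.pi)) % HOURS_PER_CYCLE)
    if HOURS_PER_CYCLE - mean_h < 1e-9:  # rounding just below a full turn
        mean_h = 0.0
    return mean_h, R, n


def circular_mean(phases) -> CircularSummary:
    """Full circular summary of a set of 24-h phases."""
    mean_h, R, n = _mean_resultant(phases)
    if R < _R_EPS:
        mean_h, sd = float("nan"), float("inf")
    else:
        sd = math.sqrt(-2.0 * math.log(R)) * HOURS_PER_CYCLE / (2.0 * np.pi)
    z, p = rayleigh_test(phases)
    return CircularSummary(mean_h, R, sd, z, p, n)


def circular_sd(phases) -> float:
    """Circular standard deviation sqrt(-2 ln R) in hours; inf when R = 0
    (infinite dispersion)."""
    _, R, n = _mean_resultant(phases)
    if n < 2:
        raise ValueError("need at least two phases")
    if R < _R_EPS:
        return float("inf")
    return math.sqrt(-2.0 * math.log(R)) * HOURS_PER_CYCLE / (2.0 * np.pi)


def rayleigh_test(phases) -> tuple[float, float]:
    """Rayleigh uniformity test: ``z = n R**2`` and the standard series
    approximation for p (clamped to (0, 1])."""
    _, R, n = _mean_resultant(phases)
    z = n * R * R
    Rn = n * R
    arg = 1.0 + 4.0 * n + 4.0 * (n * n - Rn * Rn)
    p = math.exp(math.sqrt(max(arg, 0.0)) - (1.0 + 2.0 * n))
    return float(z), float(min(max(p, np.nextafter(0, 1)), 1.0))


def phase_difference(peaks_a: PeakSet, peaks_b: PeakSet,
                     cycle_h: float | None = None) -> float:
    """Mean circular peak-time difference b - a, in hours in [0, 24).

    Each peak of ``a`` is paired with the nearest-in-time peak of ``b`` and
    the differences are averaged circularly.  Differences are wrapped at the
    rhythm's own cycle length (estimated from ``b``'s successive peak
    intervals when at least two are available, else 24 h), which makes the
    result independent of which cycle's peak happens to be nearest.
    """
    ta, tb = peaks_a.peak_times_h, peaks_b.peak_times_h
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both peak sets must be non-empty")
    if cycle_h is None:
        cycle_h = float(np.mean(np.diff(tb))) if len(tb) >= 3 else HOURS_PER_CYCLE
    diffs = []
    for t in ta:
        j = int(np.argmin(np.abs(tb - t)))
        diffs.append((tb[j] - t) % cycle_h)
    ang = 2.0 * np.pi * np.array(diffs) / cycle_h
    mean_ang = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float((mean_ang * cycle_h / (2.0 * np.pi)) % cycle_h % HOURS_PER_CYCLE)


def export_rayleigh_plot(summary: CircularSummary, phases, path) -> None:
    """Polar phase plot: 24-h dial, 0 h at top, clockwise; individual phases
    as dots on the rim and the mean phase as an arrow of length R."""
    ph = _as_phases(phases)
    if len(ph) == 0:
        raise ValueError("cannot plot an empty phase sample")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ang = 2.0 * np.pi * ph / HOURS_PER_CYCLE
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_xticks(np.arange(0, 2 * np.pi, np.pi / 4))
    ax.set_xticklabels([f"{int(h)}" for h in np.arange(0, 24, 3)])
    ax.set_yticks([])
    ax.set_ylim(0, 1.15)
    ax.plot(ang, np.full_like(ang, 1.05), "o", color="0.2", ms=6, clip_on=False)
    if summary.mean_defined:
        th = 2.0 * np.pi * summary.mean_phase_h / HOURS_PER_CYCLE
        ax.annotate(
            "", xy=(th, summary.resultant_length), xytext=(0, 0),
            arrowprops=dict(arrowstyle="-|>", lw=2, color="crimson"),
        )
    ax.set_title(f"n={summary.n}, R={summary.resultant_length:.2f}", fontsize=9)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
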
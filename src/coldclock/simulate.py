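"""Synthetic multi-channel fluorescence recordings from coupled limit-cycle
oscillators.

Each reporter channel (cytosolic Ca2+, *Per2*, *Bmal1*) is modelled as a
Stuart-Landau oscillator -- the normal form of a supercritical Hopf
bifurcation -- whose bifurcation parameter ``mu`` depends on temperature.
Above the critical temperature (``mu > 0``) the channel settles onto a limit
cycle of radius ``sqrt(mu)``; below it (``mu <= 0``) the oscillation damps
toward a fixed point and the phase is held frozen (the angular frequency is
set to zero), so a rewarmed slice resumes from wherever it stopped.

The three channels form the regulatory ring Ca -> Per2 -> Bmal1 -> Ca via
weak, phase-lagged additive coupling.  Cold exposure shifts the fixed point
of a channel along the observation axis (elevated cold Ca2+ level); for
channels with ``state_coupling_frac = 1`` this displacement erases the phase
memory over sufficiently long cold exposures, which is what makes rewarming
reset the rhythm.  The oscillator state is passed through a reporter model:
temperature-dependent fluorescent-protein brightness, slow multiplicative
expression drift, and additive Gaussian noise.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .protocol import TemperatureProtocol

#: canonical channel order
CHANNELS = ("Ca", "Per2", "Bmal1")


def _interp_anchors(anchors: tuple[tuple[float, float], ...], temp_c) -> np.ndarray | float:
    """Piecewise-linear interpolation through (temp_C, value) anchors,
    clamped at the end anchors."""
    pts = sorted(anchors)
    ts = np.array([p[0] for p in pts], dtype=float)
    vs = np.array([p[1] for p in pts], dtype=float)
    out = np.interp(np.asarray(temp_c, dtype=float), ts, vs)
    return float(out) if np.isscalar(temp_c) else out


@dataclass(frozen=True)
class Coupling:
    """Additive forcing from ``source``, delayed by ``phase_lag_h`` hours."""

    source: str
    gain: float
    phase_lag_h: float


@dataclass(frozen=True)
class ChannelOscillator:
    """Temperature-dependent Stuart-Landau parameters for one channel.

    ``period_anchors``, ``mu_anchors`` and ``baseline_anchors`` are
    ``(temp_C, value)`` pairs interpolated linearly and clamped outside their
    range.  ``osc_scale`` converts oscillator units to normalized fluorescence
    (the observed oscillation amplitude is ``osc_scale * sqrt(mu)``).
    ``state_coupling_frac`` is the fraction of a temperature-step baseline
    change that displaces the oscillator state (1 = the cold level shift is a
    true state displacement that resets phase; 0 = purely observational).
    ``displacement_phase_h`` orients that displacement in state space: a
    fully reset channel restarts this many hours before its first peak, so
    the post-rewarm peak time is a model property rather than an accident of
    the step geometry.
    """

    period_anchors: tuple[tuple[float, float], ...]
    mu_anchors: tuple[tuple[float, float], ...]
    baseline_anchors: tuple[tuple[float, float], ...]
    relaxation_rate: float = 0.3  # 1/h
    osc_scale: float = 0.2
    initial_phase_h: float = 0.0
    critical_temp_C: float = 18.5
    coupling: tuple[Coupling, ...] = ()
    state_coupling_frac: float = 1.0
    displacement_phase_h: float = 0.0

    def __post_init__(self) -> None:
        flat = [v for pair in self.period_anchors for v in pair]
        flat += [v for pair in self.mu_anchors for v in pair]
        flat += [v for pair in self.baseline_anchors for v in pair]
        flat += [self.relaxation_rate, self.osc_scale, self.initial_phase_h]
        flat += [c.gain for c in self.coupling]
        if not np.all(np.isfinite(flat)):
            raise ValueError("non-finite oscillator parameter")
        if self.relaxation_rate <= 0:
            raise ValueError("relaxation_rate must be positive")
        if self.osc_scale <= 0:
            raise ValueError("osc_scale must be positive")
        if not 0.0 <= self.state_coupling_frac <= 1.0:
            raise ValueError("state_coupling_frac must lie in [0, 1]")

    def period_h(self, temp_c):
        return _interp_anchors(self.period_anchors, temp_c)

    def mu(self, temp_c):
        return _interp_anchors(self.mu_anchors, temp_c)

    def baseline_level(self, temp_c):
        return _interp_anchors(self.baseline_anchors, temp_c)

    def omega(self, temp_c) -> float:
        """Angular frequency (rad/h); frozen (0) below the bifurcation."""
        if self.mu(temp_c) <= 0.0:
            return 0.0
        return 2.0 * np.pi / self.period_h(temp_c)


@dataclass(frozen=True)
class ChannelReporter:
    """Observation model for one channel.

    ``fp_gain_anchors``: multiplicative brightness vs temperature (1 at 35 degC,
    rising in cold as fluorescent proteins brighten).  ``drift_rate`` is the
    slow expression increase (fraction/day, capped at ``drift_cap`` fold).
    ``noise_sd`` is the additive noise sd as a fraction of the channel's
    35 degC peak-to-trough dynamic range.
    """

    fp_gain_anchors: tuple[tuple[float, float], ...]
    drift_rate: float = 0.05  # per day
    noise_sd: float = 0.02
    drift_cap: float = 2.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.drift_rate < 0:
            raise ValueError("noise_sd and drift_rate must be >= 0")
        pts = sorted(self.fp_gain_anchors)
        gains = [g for _, g in pts]
        if any(b > a for a, b in zip(gains, gains[1:])):
            raise ValueError("fp_gain must be non-increasing in temperature")

    def fp_gain(self, temp_c):
        return _interp_anchors(self.fp_gain_anchors, temp_c)

    def drift_factor(self, time_h):
        f = 1.0 + self.drift_rate * np.asarray(time_h, dtype=float) / 24.0
        return np.minimum(f, self.drift_cap)


@dataclass
class OscillatorParams:
    """Per-channel oscillator parameters for the coupled network."""

    channels: dict[str, ChannelOscillator]

    def __post_init__(self) -> None:
        for name, ch in self.channels.items():
            for c in ch.coupling:
                if c.source not in self.channels:
                    raise ValueError(
                        f"channel {name!r} couples to unknown source {c.source!r}"
                    )

    @classmethod
    def default(cls) -> "OscillatorParams":
        return cls(channels=dict(default_oscillators()))

    def with_phase_offset(self, offset_h: float) -> "OscillatorParams":
        """Shift every channel's initial phase by the same amount (mod 24),
        preserving the programmed inter-channel offsets."""
        shifted = {
            name: replace(ch, initial_phase_h=(ch.initial_phase_h + offset_h) % 24.0)
            for name, ch in self.channels.items()
        }
        return OscillatorParams(channels=shifted)


@dataclass
class ReporterParams:
    channels: dict[str, ChannelReporter]

    @classmethod
    def default(cls) -> "ReporterParams":
        return cls(channels=dict(default_reporters()))


# --- default parameterization -------------------------------------------------
#
# Period anchors follow the reported Ca2+ periods (23.2 h at 35 degC, 23.9 h at
# 28 degC, 25.3 h at 22 degC); all channels share them so the weakly coupled
# ring locks to a single collective period.  mu anchors place the Hopf point at
# 18.5 degC, inside the observed 15-22 degC critical window; Bmal1 damps more
# slowly in the cold (smaller |mu| below the bifurcation, smaller relaxation
# rate) and its cold baseline change is treated as observational
# (state_coupling_frac = 0), so its stop phase is variable and its restart
# phase disperses.  Phase lags around the ring (7.9 + 5.3 + 10.0 = 23.2 h) make
# the programmed offsets (Per2 7.9 h and Bmal1 13.2 h after Ca) an exact
# rotating solution.
#
# osc_scale and the 15 degC baseline anchors are calibration constants: they
# were solved once so that the quantification pipeline applied to default
# simulations reproduces the reference measurements (35 degC Ca amplitude
# ~30 % dF/F0; Day-1 cold baselines ~196.7 % / 55.7 % / 25.4 % for
# Ca / Per2 / Bmal1).  See docs/methods.md.

_PERIOD_ANCHORS = ((22.0, 25.3), (28.0, 23.9), (35.0, 23.2))
_MU_ANCHORS = ((15.0, -0.3), (18.5, 0.0), (22.0, 0.15), (35.0, 1.0))
_MU_ANCHORS_SLOW = ((15.0, -0.1), (18.5, 0.0), (22.0, 0.15), (35.0, 1.0))

CA_BASELINE_15C = 1.190  # calibrated; see docs/methods.md
PER2_BASELINE_15C = 0.954
BMAL1_BASELINE_15C = 0.798
CA_OSC_SCALE = 0.183


def default_oscillators() -> dict[str, ChannelOscillator]:
    return {
        "Ca": ChannelOscillator(
            period_anchors=_PERIOD_ANCHORS,
            mu_anchors=_MU_ANCHORS,
            baseline_anchors=(
                (15.0, CA_BASELINE_15C),
                (22.0, 1.10),
                (28.0, 1.05),
                (35.0, 1.0),
            ),
            relaxation_rate=0.2,
            osc_scale=CA_OSC_SCALE,
            initial_phase_h=6.0,
            coupling=(Coupling("Bmal1", 0.01, 10.0),),
            state_coupling_frac=0.3,
            displacement_phase_h=14.0,  # observed Ca restart peak ~14 h
        ),
        "Per2": ChannelOscillator(
            period_anchors=_PERIOD_ANCHORS,
            mu_anchors=_MU_ANCHORS,
            baseline_anchors=(
                (15.0, PER2_BASELINE_15C),
                (22.0, 1.03),
                (28.0, 1.02),
                (35.0, 1.0),
            ),
            relaxation_rate=0.2,
            osc_scale=0.05,
            initial_phase_h=13.9,  # 7.9 h after Ca
            coupling=(Coupling("Ca", 0.05, 7.9),),
            state_coupling_frac=1.0,
            displacement_phase_h=5.6,  # second Per2 peak ~4.8 h (mod 24)
        ),
        "Bmal1": ChannelOscillator(
            period_anchors=_PERIOD_ANCHORS,
            mu_anchors=_MU_ANCHORS_SLOW,
            baseline_anchors=(
                (15.0, BMAL1_BASELINE_15C),
                (22.0, 1.05),
                (28.0, 1.03),
                (35.0, 1.0),
            ),
            relaxation_rate=0.1,  # slow damping
            osc_scale=0.015,
            initial_phase_h=19.2,  # 13.2 h after Ca
            coupling=(Coupling("Per2", 0.02, 5.3),),
            state_coupling_frac=0.0,
        ),
    }


#: measured fluorescent-protein brightness gains at 15 degC
#: (Venus +27.7 %, mApple +67.1 %)
VENUS_GAIN_15C = 1.277
MAPPLE_GAIN_15C = 1.671


def default_reporters() -> dict[str, ChannelReporter]:
    mapple = ((15.0, MAPPLE_GAIN_15C), (35.0, 1.0))
    venus = ((15.0, VENUS_GAIN_15C), (35.0, 1.0))
    return {
        "Ca": ChannelReporter(fp_gain_anchors=mapple),
        "Per2": ChannelReporter(fp_gain_anchors=venus),
        "Bmal1": ChannelReporter(fp_gain_anchors=venus),
    }


@dataclass
class MultiChannelTrace:
    """A sampled multi-channel recording from one slice."""

    time_h: np.ndarray
    temp_C: np.ndarray
    channels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.temp_C = np.asarray(self.temp_C, dtype=float)
        n = len(self.time_h)
        if len(self.temp_C) != n:
            raise ValueError("temp_C length mismatch")
        for name, vals in self.channels.items():
            vals = np.asarray(vals, dtype=float)
            self.channels[name] = vals
            if len(vals) != n:
                raise ValueError(f"channel {name!r} length mismatch")
            if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
                raise ValueError(f"channel {name!r} must be finite and positive")

    @property
    def step_h(self) -> float:
        return float(self.time_h[1] - self.time_h[0])

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


def params_hash(osc: OscillatorParams, rep: ReporterParams,
                protocol: TemperatureProtocol) -> str:
    blob = json.dumps(
        {
            "osc": {k: asdict(v) for k, v in sorted(osc.channels.items())},
            "rep": {k: asdict(v) for k, v in sorted(rep.channels.items())},
            "protocol": {"segments": protocol.segments, "total_h": protocol.total_h},
        },
        sort_keys=True,
        default=list,
    )
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def simulate_network(
    osc: OscillatorParams,
    rep: ReporterParams,
    protocol: TemperatureProtocol,
    step_h: float = 0.1,
    seed: int = 0,
    sample_step_h: float = 1.0,
    slice_id: str = "slice-000",
) -> MultiChannelTrace:
    """Integrate the coupled network over a temperature protocol.

    Fixed-step RK4 at ``step_h`` (must divide the sampling step), decimated to
    the sampling grid.  Deterministic given identical parameters and seed.
    """
    if step_h <= 0 or step_h > sample_step_h:
        raise ValueError("need 0 < step_h <= sample_step_h")
    dec = round(sample_step_h / step_h)
    if abs(dec * step_h - sample_step_h) > 1e-9:
        raise ValueError("step_h must divide sample_step_h")
    if set(osc.channels) != set(rep.channels):
        raise ValueError("oscillator and reporter channel sets differ")

    names = list(osc.channels)
    chans = [osc.channels[n] for n in names]
    idx = {n: i for i, n in enumerate(names)}
    C = len(names)

    n_samples = int(round(protocol.total_h / sample_step_h))
    times = np.arange(n_samples) * sample_step_h
    n_sub = (n_samples - 1) * dec
    sub_times = np.arange(n_sub + 1) * step_h
    sub_temps = protocol.temp_at(sub_times)

    kappa = np.array([c.relaxation_rate for c in chans])
    scale = np.array([c.osc_scale for c in chans])
    state_frac = np.array([c.state_coupling_frac for c in chans])
    # direction of the cold fixed-point displacement, referenced to the warm
    # angular frequency so a reset channel peaks displacement_phase_h after
    # rewarming
    disp_dir = np.array(
        [
            np.exp(-1j * (2.0 * np.pi / c.period_h(35.0)) * c.displacement_phase_h)
            for c in chans
        ]
    )

    def seg_constants(T: float):
        mu = np.array([c.mu(T) for c in chans])
        om = np.array([c.omega(T) for c in chans])
        M = np.zeros((C, C), dtype=complex)
        for i, c in enumerate(chans):
            for cp in c.coupling:
                # rotate the source back by the lag so the programmed offset
                # is reinforced, not pulled
                M[i, idx[cp.source]] += cp.gain * np.exp(-1j * om[i] * cp.phase_lag_h)
        return mu, om, M

    T_cur = float(sub_temps[0])
    mu, om, M = seg_constants(T_cur)

    # slices come out of warm culture: start from the 35 degC attractor, and
    # if the recording opens cold, apply the entry displacement immediately
    w = np.empty(C, dtype=complex)
    for i, c in enumerate(chans):
        r0 = np.sqrt(max(c.mu(35.0), 0.0))
        w[i] = r0 * np.exp(-1j * c.omega(35.0) * c.initial_phase_h)
        if T_cur != 35.0:
            w[i] += (
                c.state_coupling_frac
                * (c.baseline_level(35.0) - c.baseline_level(T_cur))
                / c.osc_scale
            ) * disp_dir[i]

    def deriv(w):
        return kappa * (mu - np.abs(w) ** 2) * w + 1j * om * w + M @ w

    W = np.empty((n_samples, C), dtype=complex)
    W[0] = w
    h = step_h
    for j in range(n_sub):
        Tj = float(sub_temps[j])
        if Tj != T_cur:
            # temperature step: displace the state by the fixed-point shift
            shift = np.array(
                [c.baseline_level(T_cur) - c.baseline_level(Tj) for c in chans]
            )
            w = w + state_frac * (shift / scale) * disp_dir
            T_cur = Tj
            mu, om, M = seg_constants(T_cur)
        k1 = deriv(w)
        k2 = deriv(w + 0.5 * h * k1)
        k3 = deriv(w + 0.5 * h * k2)
        k4 = deriv(w + h * k3)
        w = w + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if (j + 1) % dec == 0:
            W[(j + 1) // dec] = w

    temp_samples = sub_temps[::dec][:n_samples]
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for i, name in enumerate(names):
        c, r = chans[i], rep.channels[name]
        base = _interp_anchors(c.baseline_anchors, temp_samples)
        gain = _interp_anchors(r.fp_gain_anchors, temp_samples)
        y = base + c.osc_scale * W[:, i].real
        F = gain * r.drift_factor(times) * y
        if r.noise_sd > 0:
            dyn = 2.0 * c.osc_scale * np.sqrt(max(c.mu(35.0), 0.0))
            F = F + rng.normal(0.0, r.noise_sd * dyn, n_samples)
        out[name] = F

    meta = {
        "slice_id": slice_id,
        "seed": int(seed),
        "params_hash": params_hash(osc, rep, protocol),
    }
    return MultiChannelTrace(times, temp_samples, out, meta)


def phase_randomized_cohort(
    osc: OscillatorParams,
    rep: ReporterParams,
    protocol: TemperatureProtocol,
    n: int,
    seed: int = 0,
    step_h: float = 0.1,
) -> list[MultiChannelTrace]:
    """``n`` slices differing only in a shared random phase offset (uniform on
    [0, 24), applied to every channel so inter-channel offsets are preserved)
    and in the noise stream.

    Offsets are stratified (one uniform draw per 24/n-h bin, in shuffled
    order): each offset is marginally uniform, but a small cohort is
    guaranteed to cover the whole cycle rather than clustering by chance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    offsets = rng.permutation((np.arange(n) + rng.uniform(0.0, 1.0, n)) * 24.0 / n)
    seeds = rng.integers(0, 2**31 - 1, n)
    traces = []
    for i in range(n):
        osc_i = osc.with_phase_offset(float(offsets[i]))
        tr = simulate_network(
            osc_i, rep, protocol, step_h=step_h, seed=int(seeds[i]),
            slice_id=f"slice-{i:03d}",
        )
        tr.meta["phase_offset_h"] = float(offsets[i])
        traces.append(tr)
    return traces
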
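import numpy as np
import pytest

from coldclock import (
    ChannelOscillator,
    ChannelReporter,
    OscillatorParams,
    ReporterParams,
)


@pytest.fixture
def default_osc() -> OscillatorParams:
    return OscillatorParams.default()


@pytest.fixture
def default_rep() -> ReporterParams:
    return ReporterParams.default()


def single_channel(
    mu_anchors=((5.0, 1.0), (40.0, 1.0)),
    period_h: float = 24.0,
    kappa: float = 0.5,
    scale: float = 0.2,
    baseline_anchors=((5.0, 1.0), (40.0, 1.0)),
    phase_h: float = 0.0,
    noise_sd: float = 0.0,
    drift_rate: float = 0.0,
    fp_gain_anchors=((5.0, 1.0), (40.0, 1.0)),
    **osc_kw,
):
    """A single uncoupled channel with flat temperature maps by default."""
    osc = OscillatorParams(
        channels={
            "Ca": ChannelOscillator(
                period_anchors=((5.0, period_h), (40.0, period_h)),
                mu_anchors=tuple(mu_anchors),
                baseline_anchors=tuple(baseline_anchors),
                relaxation_rate=kappa,
                osc_scale=scale,
                initial_phase_h=phase_h,
                **osc_kw,
            )
        }
    )
    rep = ReporterParams(
        channels={
            "Ca": ChannelReporter(
                fp_gain_anchors=tuple(fp_gain_anchors),
                drift_rate=drift_rate,
                noise_sd=noise_sd,
            )
        }
    )
    return osc, rep


def cosine_series(period_h=24.0, total_h=96.0, step_h=1.0, amplitude=1.0,
                  peak_at_h=0.0):
    t = np.arange(0.0, total_h + step_h / 2, step_h)
    return t, amplitude * np.cos(2 * np.pi * (t - peak_at_h) / period_h)
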
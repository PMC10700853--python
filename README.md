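# coldclock

Does the circadian clock keep ticking when a brain cools down? `coldclock` is
a Python library for studying that question computationally in the mouse
suprachiasmatic nucleus (SCN): it simulates long-term multi-channel
fluorescence recordings of intracellular Ca²⁺ and clock-gene reporter
(*Per2*, *Bmal1*) rhythms under controlled temperature protocols, and it
implements the full quantification chain used on such recordings — ΔF/F₀
normalization, running-average detrending, peak detection, period/amplitude/
baseline estimation, rhythmicity calls, circular phase statistics, and the
Ca²⁺-probe calibration arithmetic needed to turn reporter fluorescence into
absolute concentrations.

It is written for chronobiologists and modellers who want a reproducible,
testable stand-in for slice-imaging experiments: every downstream estimator
can be exercised on synthetic data whose ground truth is known.

## The model

Each reporter channel is a Stuart–Landau oscillator — the normal form of a
supercritical Hopf bifurcation:

```
dw/dt = κ (μ(T) − |w|²) w + i ω(T) w + Σ_src g e^{−iω·lag} w_src
```

* `μ(T)` is the temperature-dependent bifurcation parameter: positive at
  culture temperature (limit cycle of radius √μ), crossing zero near 18.5 °C,
  negative in deep cold (oscillation damps to a fixed point; the phase is
  frozen, `ω = 0`, below the bifurcation).
* `ω(T) = 2π / period(T)`; the period lengthens as temperature falls
  (23.2 h at 35 °C → 25.3 h at 22 °C).
* The channels form the regulatory ring **Ca²⁺ → Per2 → Bmal1 → Ca²⁺** via
  weak phase-lagged coupling; the programmed peak lags (Per2 7.9 h, Bmal1
  13.2 h after Ca²⁺ — near anti-phase) are an exact rotating solution.
* Cold displaces the Ca²⁺ (and Per2) fixed point in state space — the
  elevated cold Ca²⁺ level. After long cold the damped state has forgotten
  its phase, so rewarming restarts all slices at the same phase; after a few
  hours of cold the surviving oscillation dominates and the phase is only
  delayed. Bmal1's cold level shift is treated as observational and its
  oscillation damps slowly, so its restart phase is dispersed.
* Observation model: fluorescent-protein brightness gain in the cold
  (Venus +27.7 %, mApple +67.1 % at 15 °C), slow multiplicative expression
  drift, additive Gaussian noise.

The quantification side follows standard practice for fluorescence rhythm
traces: `ΔF/F₀ = (F − F₀)/F₀` with `F₀` the recording minimum; detrending by
subtraction of a centered 24-h running average (restarted at temperature
steps); peaks by prominence-ranked local maxima with a 16-h minimum
separation and quadratic sub-sample refinement; circular statistics (mean
direction, resultant length R, circular SD √(−2 ln R), Rayleigh test) on the
24-h circle.

## A worked example

`examples/quantify_rhythms.py` simulates six slices for 12 days at 35 °C and
reads the programmed rhythm parameters back through the measurement chain:

```
Ca period:     23.19 +/- 0.03 h (programmed 23.2 h)
Ca amplitude:   29.1 +/- 0.2 % dF/F0
Ca->Per2  peak lag:  7.89 h (programmed 7.9 h)
Ca->Bmal1 peak lag: 13.15 h (programmed 13.2 h)
```

`examples/reset_by_cold_duration.py` asks how long deep cold (15 °C) must
last to reset the Ca²⁺ clock, summarizing first post-rewarm peak phases over
a phase-randomized cohort:

```
cold_h  mean_phase_h      R  circ_sd_h  rayleigh_p
     6          14.9   0.22       6.61       0.649
    12          14.8   0.81       2.51      0.0012
    24          14.4   0.98       0.84     7.8e-06
    48          14.3   1.00       0.20    2.63e-06
    96          14.2   1.00       0.16    2.58e-06
```

Six hours of cold merely delays the rhythm (phases stay spread around the
clock, Rayleigh p ≈ 0.65); two days of cold resets it (every slice restarts
≈ 14 h after rewarming, R ≈ 1).

`examples/probe_calibration.py` runs the calibration arithmetic: EGTA-buffer
free-Ca²⁺ with pH/temperature corrections, a Hill fit of a synthetic
titration, and the fluorescent-protein correction that turns the raw
~197 % cold ΔF/F₀ increase into ≈ 4.3× the circadian rhythm amplitude —
about 370 nM on published basal/peak anchors (172/218 nM):

```
Reporter-corrected cold Ca2+ increase: 4.32 x rhythm amplitude
Estimated Ca2+ in deep cold: 371 nM (basal 172, rhythm peak 218)
```

`examples/simulate_cold_protocol.py` writes a full chill/rewarm trace CSV and
prints per-phase rhythmicity verdicts and baselines.

There is also a thin CLI for batch runs:

```bash
coldclock simulate --config cfg.json --out-dir out/   # traces + summary tables
coldclock quantify --in-dir out/traces --out-dir out/
coldclock phases   --in-dir out/traces --rewarm-h 192 --channel Ca --out-dir out/
coldclock calibrate --dff-cold 196.7 --fp-gain 67.1 --amplitude 30
```

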
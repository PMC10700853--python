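# Methods

This note documents the model, the measurement chain, the defaults and the
design choices behind `coldclock`, in the order a reader would meet them.

## Oscillator model

Each reporter channel c ∈ {Ca, Per2, Bmal1} carries a complex state `w_c`
obeying the Stuart–Landau equation, the normal form of a supercritical Hopf
bifurcation:

    dw_c/dt = κ_c (μ_c(T) − |w_c|²) w_c + i ω_c(T) w_c + Σ_s g_{cs} e^{−i ω_c λ_{cs}} w_s

* **Bifurcation parameter** `μ_c(T)`: piecewise-linear in temperature through
  anchors (35 °C, 1.0), (22 °C, 0.15), (18.5 °C, 0), (15 °C, −0.3); the
  Bmal1 channel uses −0.1 at 15 °C so it damps more slowly. Above the
  bifurcation the channel settles on a limit cycle of radius √μ; below it
  the oscillation decays to a fixed point at rate ≈ κ|μ|. The Hopf point at
  18.5 °C sits inside the experimentally bracketed 15–22 °C critical window;
  the anchor values are calibration choices, not measured quantities.
* **Angular frequency** `ω_c(T) = 2π/period_c(T)` with period anchors
  23.2 h (35 °C), 23.9 h (28 °C), 25.3 h (22 °C), linearly interpolated and
  clamped. Where μ ≤ 0 the frequency is set to zero: a sub-critical channel
  holds its phase frozen while its amplitude decays, so a rewarmed slice
  resumes from the state where it stopped. All three channels share the
  period anchors; the weak ring coupling locks them to a single collective
  period anyway, and detuning the Bmal1 channel by the few tenths of an hour
  seen in measured periods would bias the programmed phase lags by a
  comparable amount.
* **Coupling**: the regulatory ring Ca → Per2 → Bmal1 → Ca, realized as
  additive linear forcing with the source state rotated back by the phase
  lag. Default gains are weak (Per2 ← Ca 0.05; Bmal1 ← Per2 0.02;
  Ca ← Bmal1 0.01) so intrinsic dynamics dominate; the lags
  (7.9 + 5.3 + 10.0 h) sum to the 23.2-h period, which makes the programmed
  offsets (Per2 7.9 h, Bmal1 13.2 h after Ca) an exact uniformly rotating
  solution rather than an initial condition that drifts. The gains into
  Bmal1 and Ca are deliberately smaller than the Ca → Per2 drive: after
  rewarming from deep cold, Bmal1 restarts at a history-dependent phase and
  re-locks to the ring over ~2 days (1/gain), reproducing the slow
  re-establishment of the anti-phase relation, without dragging the freshly
  reset Ca phase around.
* **Cold displacement**: a temperature step from T₁ to T₂ displaces the
  state by `state_coupling_frac × (baseline(T₁) − baseline(T₂))/osc_scale`
  along a fixed direction in state space. This is the mechanism of phase
  resetting: after long cold the decayed state is dominated by the
  displacement, which is identical for every slice, so rewarming restarts
  all slices in phase; after short cold the surviving oscillation dominates
  and the restart phase retains each slice's history. The direction is set
  by `displacement_phase_h` (Ca 14.0 h, Per2 5.6 h), so a fully reset Ca
  rhythm peaks ≈ 14 h after rewarming and the second Per2 peak falls at
  ≈ 4.8 h (mod 24) — the restart phases reported experimentally.
  `state_coupling_frac` is 0.3 for Ca and 1.0 for Per2; with the full Ca
  displacement even a 6-h exposure would cluster restart phases, whereas the
  observed behaviour is that short (6–24 h) exposures delay but do not reset.
  Bmal1 uses 0.0: its cold baseline change is treated as a reporter/
  expression effect, so its phase is carried frozen through the cold and its
  restart phase is dispersed (circular SD of several hours on Day 1).
* **Integration**: fixed-step RK4 at 0.1 h decimated to the 1-h sampling
  grid. The system is smooth and non-stiff; a fixed step makes runs
  bit-reproducible across platforms, which an adaptive stepper would not
  guarantee. Temperature is piecewise constant per sub-step; displacement is
  applied exactly at segment changes. Recordings start from the 35 °C
  attractor (slices come out of warm culture); a protocol that opens cold
  applies the entry displacement at t = 0.

## Observation model

Observed fluorescence per channel:

    F(t) = fp_gain(T) × drift(t) × (baseline(T) + osc_scale × Re w) + ε

* `fp_gain(T)`: fluorescent proteins brighten in the cold; anchors are the
  measured gains at 15 °C (Venus-based reporters ×1.277, the mApple-based
  Ca²⁺ probe ×1.671), 1.0 at 35 °C, linear between, clamped outside.
* `drift(t) = min(1 + 0.05 t/24 h, 2)`: slow viral-expression increase,
  5 %/day capped at two-fold.
* `ε`: additive Gaussian noise, sd = 2 % of the channel's 35 °C
  peak-to-trough dynamic range, drawn from a seeded generator on the 1-h
  grid only — with `noise_sd = 0` the output is exactly deterministic and
  smooth between temperature steps.
* Cohorts (`phase_randomized_cohort`) share one random phase offset per
  slice, applied to all channels so inter-channel lags are preserved (slices
  differ in clock phase, not in their internal phase relations). Offsets are
  stratified — one uniform draw per 24/n-h bin, shuffled — so each offset is
  marginally uniform but a small cohort always covers the cycle; with
  independent draws, roughly 2 % of n = 9 cohorts would start with a
  circular SD under 4 h by chance, which would confound any statement about
  dispersion after rewarming.

## Calibrated defaults

Four generator constants are calibrated rather than chosen: the Ca
oscillation scale (0.183) and the 15 °C baseline anchors (Ca 1.190,
Per2 0.954, Bmal1 0.798). They were solved once, by secant iteration on
cohort-averaged measurements taken through the real quantification pipeline,
so that default simulations reproduce the reference measurements this kind
of experiment reports: a 35 °C Ca²⁺ rhythm amplitude of ≈ 30 % ΔF/F₀ and
Day-1 cold (15 °C) baselines of ≈ 196.7 % (Ca), ≈ 55.7 % (Per2) and
≈ 25.4 % (Bmal1) — the raw Ca figure intentionally includes the mApple
brightness gain, which the calibration module later removes. The solved
values are frozen as the package defaults.

## Quantification chain

* **ΔF/F₀**: `100 (F − min F)/min F`, per channel over the full recording;
  the minimum of the output is exactly 0 %. Ties in the minimum are
  irrelevant to the value; non-positive fluorescence is rejected.
* **Detrending**: subtraction of a centered 24-h running mean. The full
  window is a trapezoid (half weight on the two end samples), which
  annihilates exactly both a linear trend and any oscillation with period
  equal to the window. Edges use shrinking symmetric windows so the output
  keeps the input length. The pipeline passes the protocol's temperature
  steps as `breaks` so the mean restarts at each segment: a ~25 % level step
  otherwise contaminates the trend for half a window on either side,
  manufacturing spurious peaks at the boundaries and burying the ~1 %
  Bmal1 oscillation. Segments shorter than the window are reduced to their
  own mean.
* **Edge margins**: within half a window of a series end or break the trend
  uses truncated windows and peak *times* there are biased (a final rising
  cycle, for instance, acquires a false vertex a few hours early).
  `DetrendedTrace` records these margins and `detect_peaks` skips candidates
  inside them; traces constructed directly (not via the detrender) carry no
  margin, so a peak at t = 0 of a clean signal still counts.
* **Peak detection**: 3-h boxcar smoothing; local maxima ranked by
  prominence (computed on a reflection-padded copy so near-edge peaks are
  not under-ranked), kept greedily subject to a 16-h minimum separation and
  a relative prominence floor of 0.2 × the largest prominence (suppresses
  shoulder artifacts); peak times refined by the vertex of a parabola
  through the three samples around each maximum (times from the smoothed
  series, heights from the raw one). Endpoints qualify only as truncated
  vertices: they must dominate the adjacent half-separation span and the
  series must have nearly levelled off there.
* **Period**: mean successive peak interval within the analysis window;
  undefined (`None`) with fewer than two peaks — deliberately distinct from
  zero.
* **Amplitude**: mean peak height minus mean trough height over the window,
  halved; normalized amplitude divides by the pre-condition (first-window)
  amplitude.
* **Baseline**: mean of the running-average trend of ΔF/F₀ over the window —
  the slow component with the oscillation removed, trend retained.
* **Rhythmicity**: maximum Pearson autocorrelation of the detrended window
  at lags 20–28 h; rhythmic iff score ≥ 0.3 and ≥ 2 peaks detected. The 0.3
  threshold was calibrated on white noise (< 5 % false positives over 100
  seeded draws at 96-h windows). Windows shorter than 48 h are refused.
* **Restart phase**: time of the first peak after rewarming, mod 24 h; for
  the transcription reporters the second peak is used (`skip_first`), since
  the first may reflect an acute reporter response rather than the restarted
  clock.
* **Phase difference**: each peak of channel a is paired with the
  nearest-in-time peak of channel b and the differences are averaged
  circularly. Differences are wrapped at the rhythm's own cycle length
  (estimated from b's successive peak intervals; 24 h fallback), which makes
  the result independent of which cycle's peak happens to be nearest — on a
  23.2-h rhythm, wrapping at a fixed 24 h would make an anti-phasic 13.2-h
  lag read alternately as 13.2 and 14.0 depending on the pairing.

## Circular statistics

Phases live on a 24-h circle. Reported are the mean direction, the mean
resultant length R, the circular SD √(−2 ln R)·24/2π (infinite at R = 0,
where the mean is flagged undefined), and the Rayleigh uniformity test with
z = nR² and the standard series approximation
p = exp(√(1 + 4n + 4(n² − (nR)²)) − (1 + 2n)), clamped to (0, 1]. Monte
Carlo under the uniform null puts the type-I error at or below 7 % at
nominal 5 % for n ∈ {6, 9, 20}. Rayleigh plots use a 24-h dial, 0 h at the
top, clockwise, individual phases on the rim and a mean arrow of length R.

## Probe calibration

* **Van't Hoff isochore**: `logK′ = logK + (ΔH/2.303R)(1/T_ref − 1/T)`,
  T in kelvin, T_ref = 293.15 K, R = 1.9872×10⁻³ kcal K⁻¹ mol⁻¹ — the
  standard form, under which an exothermic constant grows on cooling. A
  `literal_printed` flag evaluates a published typeset variant that carries
  an extra 1/T factor; it is dimensionally inconsistent and kept only for
  comparison.
* **EGTA Kd**: `(1 + 10^(logK₁−pH) + 10^(logK₁+logK₂−2pH))/K_Ca` with
  logK₁ = 9.58, logK₂ = 8.96, logK_Ca = 10.97 at 20 °C and enthalpies
  −5.8, −5.8, −8.0 kcal/mol. Note the direction: every association constant
  grows on cooling, but the double-protonation term grows with
  |ΔH₁+ΔH₂| = 11.6 kcal/mol against 8.0 for K_Ca, so the effective Kd at
  fixed pH *rises* as temperature falls (150 nM at 20 °C → 167 nM at 15 °C,
  pH 7.2), consistent with published EGTA tables.
* **Free Ca²⁺**: `Kd × [CaEGTA]/[EGTA_free]`; homogeneous of degree zero in
  the two concentrations.
* **Hill fit**: log–log linearization `log(Ca) vs log((F−F_min)/(F_max−F))`;
  slope = Hill n, x-intercept = log Kd. The line is fitted by weighted least
  squares with weights `(F−F_min)(F_max−F)` — the inverse of the first-order
  noise amplification of the log-ratio transform — because with uniform
  weights the near-saturated points dominate and 5 % measurement noise
  produces tens of percent of Kd error. F_min/F_max default to the endpoint
  measurements and are held fixed (kit protocol); co-fitting all four Hill
  parameters on the untransformed model is available via `fit_endpoints`.
  On noiseless data the fit inverts the model exactly.
* **Reporter correction**: `(ΔF/F₀ increase − brightness increase)/rhythm
  amplitude` converts the raw cold signal rise into a multiple of the
  circadian amplitude; with published basal/peak anchors b, p the absolute
  estimate is `b + fold × (p − b)`. With the reference inputs
  (196.7 %, 67.1 %, 30 %; 172/218 nM) this gives 4.3× and ≈ 370 nM.

## Pipeline, I/O, determinism

`run_experiment` validates a JSON-shaped config against its schema (unknown
keys rejected with their names), simulates a phase-randomized cohort, splits
the protocol into 4-day analysis windows aligned to the temperature
segments (a sub-48-h remainder merges into the preceding block), emits one
summary row per (slice, channel, window) and cohort circular summaries of
post-rewarm restart phases, and writes traces (CSV: `time_h, temp_C,` one
column per channel), tables, a provenance JSON with a parameter hash, and
optional Rayleigh figures. Identical config + seed gives byte-identical
CSVs. Trace reading enforces a uniform grid (10⁻⁶ h tolerance) and reports
the first offending row for gaps, duplicates, non-monotone times or NaNs.
The CLI (`coldclock simulate/quantify/phases/calibrate/run-all`) is a thin
wrapper over these functions.

## Problem sizes

Default analyses use the reference recording geometry: 1-h sampling, 4-day
condition blocks, 12-day recordings (288 h), cohorts of 6–9 slices; the
duration sweep uses 6–96 h cold exposures. The acceptance script simulates
27 slices in total and runs in a few seconds on one core.

## What the synthetic data does and does not capture

The generator reproduces the features the estimators are sensitive to:
circadian oscillations with realistic periods, amplitudes and phase lags;
amplitude attenuation and period lengthening in moderate cold; oscillation
death with an elevated Ca²⁺ level in deep cold; brightness gain, expression
drift and shot-like noise; phase resetting that depends on cold duration.
It does not attempt: mechanistic transcription–translation kinetics, spatial
SCN network structure or cell-to-cell heterogeneity (traces are ROI means),
temperature equilibration transients (steps are instantaneous), the slow
decline of the cold Ca²⁺ baseline between Day 1 and Day 4, or probe
photophysics beyond a static brightness factor. Passing tests therefore
demonstrate that the estimators recover known ground truth under realistic
signal structure — not that the biological model is correct in detail.

## Known limitations

* The restart phase of a fully reset channel is imposed through
  `displacement_phase_h` rather than emerging from a mechanistic rewarming
  trajectory; only its cohort statistics (clustering vs dispersion) are
  emergent.
* The rhythmicity score is a single autocorrelation statistic; it is
  calibrated for 4-day windows at 1-h sampling and has no formal p-value.
* Sub-sample peak refinement assumes a locally quadratic vertex; strongly
  skewed waveforms would bias it by a fraction of the sampling step.
* The Van't Hoff correction extrapolates printed 20 °C constants with
  constant enthalpies; far from the reference temperature this is a
  first-order estimate.
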
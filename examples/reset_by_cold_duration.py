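"""How long must deep cold last to reset the Ca2+ clock?

Sweeps the 15-degC exposure duration over a phase-randomized cohort and
summarizes the first post-rewarm Ca2+ peak phases on the 24-h circle.  A
short exposure leaves the restart phase dependent on each slice's history
(small resultant length R, large circular SD); once the exposure is long
enough for the damped oscillation to forget its phase, every slice restarts
together (R near 1, SD well under an hour).  Also writes a Rayleigh plot for
the two extreme durations.
"""
from coldclock import (
    OscillatorParams,
    ReporterParams,
    build_protocol,
    circular_mean,
    export_rayleigh_plot,
    phase_randomized_cohort,
)
from coldclock.pipeline import duration_sweep, restart_phases

table = duration_sweep(durations_h=(6, 12, 24, 48, 96), n_slices=9, seed=2,
                       channels=("Ca",))
print("cold_h  mean_phase_h      R  circ_sd_h  rayleigh_p")
for _, r in table.iterrows():
    print(f"{r.cold_h:6.0f}  {r.mean_phase_h:12.1f}  {r.resultant_length:5.2f}"
          f"  {r.circ_sd_h:9.2f}  {r.rayleigh_p:10.3g}")
print("\nSD shrinks and R -> 1 once the cold lasts ~2 days: the rewarmed "
      "rhythm no longer remembers its pre-cooling phase.")

osc, rep = OscillatorParams.default(), ReporterParams.default()
for cold_h in (6.0, 96.0):
    protocol = build_protocol(96, 15, cold_h, 96)
    cohort = phase_randomized_cohort(osc, rep, protocol, 9, seed=2)
    sample = restart_phases(cohort, 96 + cold_h, "Ca")
    name = f"rayleigh_ca_{int(cold_h)}h.png"
    export_rayleigh_plot(circular_mean(sample), sample, name)
    print(f"wrote {name}")
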
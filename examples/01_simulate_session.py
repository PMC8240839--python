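"""Simulate a passive VNS-tone pairing recording and look at its pieces.

A session has three blocks (pre / during / post VNS) of 20 best-frequency tone
presentations at a 12-s intertrial interval, a 30 Hz pupil trace with drift,
VNS-evoked dilations and blink artifacts, and Poisson spiking units whose gain
follows the (lagged) pupil.
"""

from vnspupil import GeneratorConfig, simulate_session

cfg = GeneratorConfig(seed=0, n_units=3)
trials, units, pupil, licks, truth = simulate_session(cfg)

print(f"trials: {len(trials)} "
      f"({dict(trials.groupby('session_phase').size())})")
print(f"pupil: {pupil.n_samples} samples over {pupil.span[1]:.0f} s, "
      f"{truth.blink_times.size} injected blinks")
for uid, u in units.items():
    ut = truth.units[uid]
    print(f"  unit {uid}: {u.spike_times.size} spikes, plastic={ut.plastic} "
          f"(injected suppression d={ut.d:.2f})")

# The ground truth records every injected quantity, so any analysis result can
# be checked against what the generator actually put in.
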
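"""Clean a pupil trace and measure the VNS-evoked dilation.

Blinks appear as rapid V-shaped drops in the fitted pupil diameter. They are
detected on the derivative (> 6 SD from the mean, robustly estimated), a 6-s
window around each event is excised, and the gap is bridged by linear
interpolation. The dilation curve aligns each trial to VNS onset and expresses
diameter as fraction change relative to the pre-VNS second.
"""

from vnspupil import GeneratorConfig, remove_blinks, vns_evoked_dilation
from vnspupil.simulate import simulate_vns_pupil_validation

cfg = GeneratorConfig(seed=3, dilation_peak_s=6.0, dilation_amp_frac=0.1)
observed, vns_onsets, _ = simulate_vns_pupil_validation(cfg, n_vns=60, inter_vns_s=40.0)

clean, report = remove_blinks(observed)
print(f"blink removal: {len(report.blink_intervals)} interval(s), "
      f"{report.n_samples_replaced} samples replaced "
      f"(threshold {report.threshold_used:.2f} px/sample)")

curve = vns_evoked_dilation(clean, vns_onsets, grid_hz=2.0, smooth_bins=5)
print(f"evoked dilation: peak {100 * curve.peak_amplitude:.1f}% at "
      f"{curve.peak_time:.2f} s after VNS onset (n = {curve.n_trials} trials)")
# The generator injected a 10% dilation peaking 6 s post-VNS; the recovered
# peak latency and amplitude should sit close to those values.
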
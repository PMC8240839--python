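"""Arousal gating: does pupil dilation during VNS predict later plasticity?

Each record pairs one unit's mean VNS-evoked pupil dilation (fraction change
during pairing trials) with the magnitude of its persistent post-VNS response
change (|Δ sustained r_persist|). A positive Pearson correlation indicates that
stimulation which evoked stronger arousal also produced larger lasting changes.
"""

from vnspupil import gating_correlation, simulate_gating_records

records = simulate_gating_records(n=71, rho=0.5, seed=2)
r, p, n = gating_correlation(records)
print(f"gating correlation: Pearson r = {r:.2f}, p = {p:.4f}, n = {n}")
print("(generator coupling rho = 0.5; the estimate should fall in its sampling range)")
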
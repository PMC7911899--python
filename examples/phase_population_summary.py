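"""Polar-histogram summary of phase-difference populations.

Measures the phase difference of a synchronous and an alternating cohort
of synthetic recordings and prints the axial circular summary (mean
direction, resultant length R, histogram bins) that a polar plot of
tremor patterns would display.
"""

import numpy as np

from tremoremg import (
    SynthParams,
    analyze,
    circular_summary,
    generate_burst_envelope,
)

rng = np.random.default_rng(7)
cohorts = {
    "synchronous cohort (true phase ~ 38 deg)": rng.normal(38.0, 14.0, 7),
    "alternating cohort (true phase ~ 154 deg)": rng.normal(154.0, 15.0, 14),
}

for name, truths in cohorts.items():
    phases = []
    for i, phi in enumerate(np.clip(truths, 0, 180)):
        p = SynthParams(f_tremor=4.7, delta_phi_deg=float(phi), seed=300 + i)
        phases.append(analyze(generate_burst_envelope(p)).phase_diff_deg)
    s = circular_summary(phases, bin_width_deg=20.0)
    print(name)
    print(f"  n = {s.n}, axial circular mean = {s.mean_deg:.1f} deg, R = {s.R:.3f}")
    print(f"  bins (20 deg): {[int(b) for b in s.bins]}")

print("\nR near 1 shows each cohort's phases cluster tightly on its side of")
print("the 90 deg boundary; the bin counts are what a polar histogram shows.")
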
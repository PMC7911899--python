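"""Simulate two clinical tremor regimes and analyze them end to end.

Generates a 30 s two-channel envelope recording for an alternating
(parkinsonian-like) and a synchronous (essential-tremor-like) regime,
runs the full pipeline, and prints the recovered tremor frequency,
inter-muscle phase difference and pattern label next to the ground truth.
"""

from tremoremg import SynthParams, analyze, generate_burst_envelope

REGIMES = {
    "alternating (parkinsonian-like)": SynthParams(
        f_tremor=4.63, delta_phi_deg=154.4, duration_s=30.0, seed=1
    ),
    "synchronous (essential-tremor-like)": SynthParams(
        f_tremor=4.82, delta_phi_deg=38.4, duration_s=30.0, seed=1
    ),
}

for name, params in REGIMES.items():
    rec = generate_burst_envelope(params)
    m = analyze(rec)
    print(f"{name}")
    print(f"  ground truth : {params.f_tremor:.2f} Hz, {params.delta_phi_deg:.1f} deg")
    print(
        f"  measured     : {m.f_tremor:.2f} Hz, {m.phase_diff_deg:.1f} deg "
        f"-> pattern: {m.pattern.value}"
    )
    print(f"  grid step {m.resolution_hz * 1000:.1f} mHz, "
          f"peak quality {m.meta['peak_quality']:.0f}")

print(
    "\nA phase difference below 90 deg means the flexor and extensor burst"
    "\ntogether (synchronous pattern); at or above 90 deg they alternate."
)
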
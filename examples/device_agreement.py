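"""Method-agreement statistics between two measurement systems.

Simulates a 21-subject validation study: each subject's tremor is
measured by a reference system (the generator's ground truth analyzed
from one synthetic recording) and by a second system (an independent
noisy rendering of the same tremor).  The paired phase measurements are
then compared with Bland-Altman, ICC(2,1), paired t, Pearson r, RMSE and
maximum absolute error — the standard validation report for a new
tremor-measurement device.
"""

import numpy as np

from tremoremg import (
    PairedMeasurements,
    SynthParams,
    agreement_report,
    analyze,
    generate_burst_envelope,
)

rng = np.random.default_rng(2024)

# 14 alternating-pattern and 7 synchronous-pattern subjects
true_phases = np.concatenate(
    [rng.normal(154.0, 15.0, 14), rng.normal(38.0, 14.0, 7)]
).clip(0, 180)
true_freqs = rng.normal(4.7, 0.6, 21).clip(3.0, 7.0)

system_a, system_b = [], []
for i, (f, phi) in enumerate(zip(true_freqs, true_phases)):
    base = SynthParams(f_tremor=f, delta_phi_deg=phi, duration_s=30.0)
    # two independent recordings of the same underlying tremor; the second
    # system sees the tremor through differently placed electrodes, which
    # shifts its effective phase by a few degrees and costs some SNR
    phi_b = float(np.clip(phi + rng.normal(0.0, 6.0), 0, 180))
    m_a = analyze(generate_burst_envelope(base.replace(seed=1000 + i)))
    m_b = analyze(
        generate_burst_envelope(
            base.replace(delta_phi_deg=phi_b, seed=2000 + i, snr_db=10.0)
        )
    )
    system_a.append(m_a.phase_diff_deg)
    system_b.append(m_b.phase_diff_deg)

rep = agreement_report(
    PairedMeasurements(system_a, system_b, quantity="phase_deg")
)
print(f"n = {rep.n} subjects, quantity: {rep.quantity}")
print(f"bias (a - b)        : {rep.bias:6.2f} deg")
print(f"95% limits of agr.  : [{rep.loa[0]:6.2f}, {rep.loa[1]:6.2f}] deg")
print(f"paired t            : t = {rep.paired_t_stat:.2f}, p = {rep.paired_t_p:.3f}")
print(f"Pearson r           : {rep.pearson_r:.3f} (p = {rep.pearson_p:.2g})")
print(f"ICC(2,1)            : {rep.icc:.3f} "
      f"(95% CI {rep.icc_ci[0]:.3f}-{rep.icc_ci[1]:.3f})")
print(f"RMSE / max abs err  : {rep.rmse:.1f} / {rep.max_abs_err:.1f} deg")
print(f"variance F test     : F = {rep.f_ratio:.2f}, p = {rep.f_p:.3f}")
print("\nA non-significant paired t (no systematic offset), r and ICC near 1,")
print("and limits of agreement narrower than the 90 deg class separation mean")
print("the two systems classify every subject's pattern identically.")
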
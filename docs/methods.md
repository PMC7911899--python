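# Methods

## Measurement model

A resting tremor drives the antagonist muscle pair of the forearm with a
common rhythmic central command at frequency `f_t` (typically 3–7 Hz).
On the surface EMG this appears as trains of activity bursts; the
rectified-integrated EMG (the *envelope*) of each muscle is therefore an
approximately periodic non-negative burst train at `f_t`. The clinically
discriminating quantity is the phase of the flexor train relative to the
extensor train **at the tremor fundamental**: synchronous firing
(|Δφ| < 90°) is characteristic of essential tremor with resting tremor,
alternating firing (|Δφ| ≥ 90°) of tremor-dominant Parkinson's disease.

The pipeline estimates, per recording:

* `f_t` — argmax over the 1–10 Hz band of the summed per-channel
  power spectra of the band-passed envelopes. Each channel's in-band
  power is normalized to unit total before summing so a high-gain
  channel cannot single-handedly move the peak.
* per-channel amplitude — `|S_ch(f_t)|` of the mean-removed, Hann-
  tapered *unfiltered* envelope (arbitrary units; no unit conversion is
  attempted, units ride along as metadata).
* `Δφ = |wrap(arg S_ext(f_t) − arg S_flex(f_t))| ∈ [0°, 180°]` — the
  per-channel DFT-phase difference. A cross-spectral estimate would
  coincide on stationary signals; the per-channel form is used because
  it is the direct reading of the two transforms. The signed value
  (which muscle leads) is preserved in the measurement metadata.
* pattern — half-open split at the boundary: [0°, 90°) synchronous,
  [90°, 180°] alternating. The boundary value itself is assigned to the
  alternating class; the switch point is exactly 90.000°.

## Processing chain and parameters

| parameter | default | why |
|---|---|---|
| envelope window | 50 ms centered moving average | passes ≤ 10 Hz tremor modulation, smooths the > 50 Hz EMG carrier; "integration" realized as a moving average (a leaky integrator would be an alternative; the moving average is linear-phase and parameter-free besides its width) |
| analysis rate | 200 Hz | native rate of the wearable class of recorders; high-rate clinical exports are decimated to it |
| band-pass | Butterworth order 4, 1–10 Hz, zero-phase | the filter family and band of the device chain; zero-phase (forward–backward, effective order 8) because the measurand is a phase difference — a causal filter would add frequency-dependent phase and channel-asymmetric edge transients |
| spectral grid | Hann taper, single segment, zero-padded to ≤ 0.05 Hz spacing | a single segment preserves phase fidelity (Welch averaging would discard it); 30 s of data gives ≤ 0.036 Hz intrinsic resolution |
| edge trim | 1 s per end, when the recording is ≥ 10 s | discards filtfilt edge transients before spectral estimation |
| peak-quality floor | 3 | peak height over median in-band level of the summed normalized spectrum, below which "no tremor detected" is raised |
| decision boundary | 90° | the synchronous/alternating split |
| minimum duration | 5 s | below this the spectral estimate is refused |

Order of operations for high-rate input: rectify + integrate at the
native rate, then decimate (polyphase, anti-aliased) to 200 Hz, then
filter. Rectifying before decimation matters: decimation first would
alias the raw carrier, and rectification is nonlinear so the two orders
are not equivalent.

**Detection-floor limitation.** With the peak-over-median quality
definition, 30 s of pure white noise scores ≈ 4–7 (the maximum of a few
hundred roughly exponential periodogram ordinates), while genuine burst
trains at 20 dB SNR score in the thousands. The default floor of 3
therefore rejects essentially nothing; it is a guard against degenerate
(near-empty) spectra, not a noise gate. Callers who need a hard
noise/tremor decision should raise `peak_quality_floor` (a floor of
~20–50 separates the regimes studied here by orders of magnitude) or
inspect `meta["peak_quality"]`.

## Synthetic generator

`generate_burst_envelope` emulates the rectified-integrated signal the
recorder digitizes: each cycle contributes a raised-cosine (Hann) burst
of width `duty/f_t` (default duty 0.3 — bursts in real recordings are
smooth and occupy a minority of the cycle); cycle-to-cycle periods get
multiplicative log-normal jitter with CV `jitter_cv` (default 0.02),
**identical on both channels**, reflecting the shared central drive and
keeping the inter-channel phase well-defined; the flexor train is the
extensor train delayed by `Δφ/(360·f_t)` seconds, evaluated analytically
at each sample time so the ground-truth phase at the fundamental is
exact rather than rounded to the sample grid. White Gaussian noise is
added at `snr_db` (default 20 dB, defined as clean-envelope power over
noise power) and clipped at zero, since a physical envelope is
non-negative; optional uniform quantization emulates a 10-bit ADC.

`generate_raw_emg` amplitude-modulates an independent band-limited
Gaussian carrier per channel (default 20–90 Hz at 200 Hz sampling,
20–500 Hz is a sensible choice at 6 kHz) by the noise-free burst train:
the interference-pattern EMG has no inter-muscle phase relation at the
carrier scale — the tremor phase lives entirely in the envelope, which
is what the rectify-integrate stage recovers.

What the generator does **not** model: motor-unit action-potential
shapes and recruitment, amplitude drift and electrode movement, ECG or
mains contamination, asymmetric per-muscle duty cycles, tremor
intermittency, or harmonically rich non-sinusoidal phase relations.
Passing tests therefore demonstrate that the estimator chain is correct
and internally consistent under the stated signal model, not that it is
robust to every artifact of clinical recordings. Burst duty, SNR and
jitter of real tremor EMG are not characterized in the validation
literature this package accompanies; the defaults are plausible
physiological choices, not calibrated fits.

## Agreement statistics

Validation of a new measurement system against a reference uses paired
per-subject measurements: Bland–Altman bias and 95% limits of agreement
(`bias ± 1.96·sd`, n−1 denominator), the paired t-test (two-sided;
identical samples give p = 1 by convention, a constant non-zero
difference gives the p → 0 limit), Pearson r, RMSE, maximum absolute
error (note: the *maximum*, not mean, absolute paired difference — the
convention of this validation literature), and a two-sided variance
F test (`p = 2·min(P(F≤f), P(F≥f))`).

Reliability uses the intraclass correlation. The form is **ICC(2,1)** —
two-way random effects, absolute agreement, single measurement — the
conservative standard choice for test–retest of a single device, since
it penalizes systematic offsets that a consistency ICC would forgive.
Point estimate from the two-way ANOVA decomposition; 95% CI from the
standard Shrout–Fleiss / McGraw–Wong F-distribution interval with
Satterthwaite degrees of freedom. ICC(3,1) (consistency) is available
behind a flag. The implementation is in-package (the pingouin
implementation, against which it is tested to agree to ~1e-15, rounds
its confidence interval to two decimals, too coarse for reporting
intervals like 0.976–0.997).

Phase differences are treated as linear quantities on [0°, 180°] in all
agreement statistics, which is how such device comparisons are
conventionally analyzed; `circular_agreement_bias` provides a circular
sensitivity check for data near the axial wrap.

Circular summaries of phase populations are **axial**: phases live on a
half circle, so mean direction and resultant length R are computed on
doubled angles and the mean is folded back to [0°, 180°).

## Numerical choices and degenerate inputs

* Spectral grid index of `f_t`: nearest grid point (`round(f/Δf)`).
* Phase wrap maps to (−180°, 180°], with the −180° tie sent to +180° so
  the absolute value stays in [0°, 180°].
* A channel whose spectral magnitude at `f_t` is below 1e-12 of its own
  maximum has undefined phase → `UndefinedPhaseError`.
* Recordings shorter than 5 s, non-finite samples, fs ≤ 0, unequal
  channel lengths and unknown stages are rejected with typed errors.
* CSV round-trips are exact to ~1e-12 relative (12 significant digits
  written); EDF round-trips are exact to half a 16-bit quantization step
  of each channel's physical range. EDF reading is delegated to mne,
  whose SI-unit rescaling is undone so samples return in stored units.
* Resampling requires a rational rate ratio (tolerance 1e-9, denominator
  ≤ 1000); upsampling works but warns.
* All generator outputs are pure functions of their parameter set
  including the seed.

## Problem sizes

The verification suite and the reproduction script simulate 30 s
recordings at 200 Hz (6 kHz for the dual-rate checks). Regime-level
checks use 50 seeded recordings per operating point; the ground-truth
recovery grid spans f ∈ {3,4,5,6} Hz × Δφ ∈ {0°,30°,…,180°} with 20
seeds per point (560 runs). With these sizes the recovered group means
sit well inside 0.1 Hz and 5° of the generator's ground truth.

## Known limitations

* The 90° rule is applied to a point estimate of Δφ; no uncertainty on
  Δφ is propagated into the classification (a subject with true phase
  near 90° can land on either side under noise).
* Single-segment DFT phase is noise-sensitive at low SNR; at high SNR it
  agrees with cross-spectral estimates, at low SNR they diverge and no
  claim is made about which is better.
* The default peak-quality floor does not reject structureless noise
  (see above).
* No artifact handling (mains notch, ECG, movement) — out of scope.
* Tremor amplitude is reported in arbitrary spectral-magnitude units;
  comparisons are meaningful only within a fixed acquisition setup.
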
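# tremoremg

Resting-tremor analysis of two-channel antagonist-muscle surface EMG.

Resting tremor occurs both in Parkinson's disease (PD) and in essential
tremor with resting tremor (rET), and the two are misdiagnosed in a
substantial fraction of cases. One electrophysiological parameter
separates them well at the individual level: the **activation pattern**
of the antagonist muscle pair (forearm extensor and flexor). In
tremor-dominant PD the two muscles fire **alternately** — their EMG
bursts are phase-shifted by more than 90° at the tremor frequency —
while in rET they fire **synchronously** (phase difference below 90°).
This package turns that qualitative visual judgement into a number.

## What it computes

Given a two-channel recording (raw EMG or its rectified-integrated
envelope) from the extensor and flexor:

1. **Envelope** — full-wave rectification and moving-average integration
   (50 ms window) of the raw signal, at the native sampling rate.
2. **Resampling** — anti-aliased polyphase decimation to the 200 Hz
   analysis rate (so 6 kHz clinical-EMG exports follow the same flow as
   a 200 Hz wearable stream).
3. **Band-pass** — zero-phase Butterworth filter (order 4, 1–10 Hz)
   isolating the tremor rhythm on each channel.
4. **Tremor frequency** `f_t` — location of the largest peak of the
   Hann-tapered, zero-padded power spectrum of the filtered envelopes
   (channels power-normalized and summed) in the 1–10 Hz band.
5. **Amplitude and phase** — read off the DFTs `S_ext(f)`, `S_flex(f)`
   of the *unfiltered* mean-removed envelopes at `f_t`; the phase
   difference is

   ```
   Δφ = | wrap( arg S_ext(f_t) − arg S_flex(f_t) ) |  ∈ [0°, 180°]
   ```

6. **Pattern** — `synchronous` if Δφ < 90°, `alternating` if Δφ ≥ 90°.

Around this core the package provides a synthetic burst-train generator
with exact ground truth (tremor frequency, inter-channel phase, period
jitter, SNR, ADC quantization), the method-agreement statistics used to
validate one measurement system against another (Bland–Altman limits of
agreement, ICC(2,1) with exact F-based CI, paired t, Pearson r, RMSE,
maximum absolute error, two-sided variance F test), axial circular
summaries for polar histograms, and CSV/EDF/JSON I/O.

## Worked example

```bash
python examples/simulate_and_analyze.py
```

prints

```
alternating (parkinsonian-like)
  ground truth : 4.63 Hz, 154.4 deg
  measured     : 4.64 Hz, 154.7 deg -> pattern: alternating
  grid step 35.7 mHz, peak quality 17290
synchronous (essential-tremor-like)
  ground truth : 4.82 Hz, 38.4 deg
  measured     : 4.82 Hz, 38.4 deg -> pattern: synchronous
  grid step 35.7 mHz, peak quality 18753
```

Each block simulates a 30 s two-channel envelope recording at a clinical
group-mean operating point and runs the full pipeline: the measured
frequency and phase match the generator's ground truth to within the
spectral grid step and a fraction of a degree, and the pattern label
falls on the correct side of the 90° boundary. "Peak quality" is the
tremor peak's height over the median in-band spectral level — values in
the thousands indicate an unambiguous rhythm.

Other examples: `dual_rate_consistency.py` (6 kHz clinical path vs
200 Hz wearable path), `device_agreement.py` (full validation-study
statistics on 21 simulated subjects), `phase_population_summary.py`
(axial circular statistics for polar histograms).

### From Python

```python
from tremoremg import SynthParams, analyze, generate_burst_envelope

rec = generate_burst_envelope(SynthParams(f_tremor=5.0, delta_phi_deg=120.0, seed=1))
m = analyze(rec)
print(m.f_tremor, m.phase_diff_deg, m.pattern.value)
```

### Command line

```bash
tremoremg simulate --out rec.csv --f-tremor 4.8 --phase-deg 150 --seed 7
tremoremg analyze rec.csv
tremoremg compare pairs.csv --quantity phase_deg
tremoremg recover --out grid.csv --seeds 5
```

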
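"""Synthetic two-channel tremor EMG with known ground truth.

The generator emulates the rectified-integrated ("envelope") signal a
wearable tremor recorder digitizes: each muscle channel is a periodic
train of raised-cosine bursts at the tremor frequency, the flexor train
delayed relative to the extensor by the inter-channel phase shift, with
common cycle-to-cycle period jitter (tremor has a shared central drive),
additive white measurement noise and optional ADC quantization.  A raw-EMG
variant amplitude-modulates band-limited carrier noise by the same burst
train, providing the stage upstream of rectification/integration.

Burst placement is evaluated analytically at each sample time, so the
flexor delay — and hence the ground-truth phase at the tremor fundamental
— is exact, not rounded to the sample grid.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .signal_model import Recording

__all__ = ["SynthParams", "generate_burst_envelope", "generate_raw_emg", "quantize"]


@dataclass(frozen=True)
class SynthParams:
    """Ground-truth parameters of a simulated tremor recording.

    Attributes
    ----------
    f_tremor
        Tremor frequency in Hz (resting tremor is typically 3–7 Hz).
    delta_phi_deg
        Flexor lag relative to the extensor at the tremor fundamental,
        in degrees, in [0, 180].
    duration_s, fs
        Recording length (s) and sampling rate (Hz).
    duty
        Burst width as a fraction of the tremor period, in (0, 1).
    carrier_band
        Pass band (Hz) of the raw-EMG carrier noise; only used by
        :func:`generate_raw_emg`.
    snr_db
        Envelope-power to additive-white-noise-power ratio in dB
        (``math.inf`` disables noise).
    jitter_cv
        Coefficient of variation of the cycle-to-cycle period
        (multiplicative log-normal, identical on both channels).
    adc_bits
        If set, quantize the output to this many uniform levels spanning
        the signal range, emulating the recorder's ADC.
    seed
        Seed of the pseudo-random generator; output is a pure function of
        the parameter set.
    """

    f_tremor: float = 5.0
    delta_phi_deg: float = 0.0
    duration_s: float = 30.0
    fs: float = 200.0
    duty: float = 0.3
    carrier_band: tuple[float, float] = (20.0, 90.0)
    snr_db: float = 20.0
    jitter_cv: float = 0.02
    adc_bits: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.f_tremor < self.fs / 2):
            raise ParameterError(
                f"f_tremor must be in (0, fs/2); got {self.f_tremor} at fs={self.fs}"
            )
        if not (0 <= self.delta_phi_deg <= 180):
            raise ParameterError(f"delta_phi_deg must be in [0, 180]; got {self.delta_phi_deg}")
        if self.duration_s * self.f_tremor < 10:
            raise ParameterError(
                "recording must contain at least 10 tremor cycles; got "
                f"{self.duration_s * self.f_tremor:.2f}"
            )
        if not (0 < self.duty < 1):
            raise ParameterError(f"duty must be in (0, 1); got {self.duty}")
        if self.jitter_cv < 0:
            raise ParameterError("jitter_cv must be >= 0")
        if math.isnan(self.snr_db):
            raise ParameterError("snr_db must not be NaN")
        if self.adc_bits is not None and self.adc_bits < 2:
            raise ParameterError("adc_bits must be >= 2")

    def replace(self, **kw) -> "SynthParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["carrier_band"] = list(self.carrier_band)
        return d


def _burst_onsets(p: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Cycle onset times covering [ -2T, duration + 2T ] with period jitter."""
    period = 1.0 / p.f_tremor
    n_cycles = int(math.ceil(p.duration_s * p.f_tremor)) + 5
    if p.jitter_cv > 0:
        sigma = math.sqrt(math.log1p(p.jitter_cv**2))
        factors = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n_cycles)
    else:
        factors = np.ones(n_cycles)
    periods = period * factors
    onsets = -2.0 * period + np.concatenate(([0.0], np.cumsum(periods[:-1])))
    return onsets


def _burst_train(t: np.ndarray, onsets: np.ndarray, width: float) -> np.ndarray:
    """Sum of unit-peak raised-cosine (Hann) bursts starting at each onset."""
    out = np.zeros_like(t)
    t0, t1 = t[0], t[-1]
    for on in onsets:
        if on + width < t0 or on > t1:
            continue
        i0 = int(np.searchsorted(t, on, side="left"))
        i1 = int(np.searchsorted(t, on + width, side="right"))
        seg = t[i0:i1] - on
        out[i0:i1] += 0.5 * (1.0 - np.cos(2.0 * np.pi * seg / width))
    return out


def generate_burst_envelope(p: SynthParams) -> Recording:
    """Simulate the rectified-integrated (envelope) tremor signal.

    Returns a ``stage="envelope"`` Recording whose extensor channel is the
    jittered burst train and whose flexor channel is the same train
    delayed by ``delta_phi_deg/(360·f_tremor)`` seconds, plus white noise
    at ``snr_db`` (clipped at zero: a physical envelope is non-negative)
    and optional ADC quantization.  Ground truth is stored in
    ``meta["ground_truth"]``.
    """
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.fs))
    t = np.arange(n) / p.fs
    onsets = _burst_onsets(p, rng)
    width = p.duty / p.f_tremor
    tau = p.delta_phi_deg / (360.0 * p.f_tremor)

    ext = _burst_train(t, onsets, width)
    flex = _burst_train(t, onsets + tau, width)
    clean = np.stack([ext, flex])

    if np.isfinite(p.snr_db):
        sig_power = float(np.mean(clean[0] ** 2))
        noise_sd = math.sqrt(sig_power * 10.0 ** (-p.snr_db / 10.0))
        clean = clean + rng.normal(0.0, noise_sd, size=clean.shape)
        np.clip(clean, 0.0, None, out=clean)

    rec = Recording(
        clean,
        p.fs,
        stage="envelope",
        meta={"ground_truth": p.to_dict(), "units": "au"},
    )
    if p.adc_bits is not None:
        full_scale = float(np.max(rec.samples)) or 1.0
        rec = quantize(rec, p.adc_bits, full_scale)
        rec.meta.setdefault("ground_truth", p.to_dict())
    return rec


def generate_raw_emg(p: SynthParams) -> Recording:
    """Simulate raw surface EMG: band-limited carrier noise modulated by
    the tremor burst train.

    Each channel gets an independent zero-mean Gaussian carrier filtered
    to ``carrier_band`` (the interference-pattern EMG has no phase
    relation between muscles at the carrier scale; the tremor phase lives
    in the modulating envelope).  White measurement noise is added at
    ``snr_db`` relative to the modulated-signal power.  The noise-free
    envelope is reproducible from ``meta["ground_truth"]`` by calling
    :func:`generate_burst_envelope` with ``snr_db=inf`` and
    ``adc_bits=None``.
    """
    lo, hi = p.carrier_band
    if not (0 < lo < hi):
        raise ParameterError(f"invalid carrier band {p.carrier_band}")
    if p.fs <= 2 * hi:
        raise ParameterError(
            f"fs={p.fs} Hz cannot carry a {hi} Hz carrier (need fs > 2·high)"
        )
    clean_env = generate_burst_envelope(
        p.replace(snr_db=math.inf, adc_bits=None)
    ).samples

    rng = np.random.default_rng(p.seed + 1)  # independent of the jitter stream
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=p.fs, output="sos")
    carriers = sps.sosfiltfilt(sos, rng.standard_normal(clean_env.shape), axis=1)
    carriers /= np.std(carriers, axis=1, keepdims=True)
    raw = carriers * clean_env

    if np.isfinite(p.snr_db):
        sig_power = float(np.mean(raw**2))
        noise_sd = math.sqrt(sig_power * 10.0 ** (-p.snr_db / 10.0))
        raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)

    rec = Recording(
        raw,
        p.fs,
        stage="raw",
        meta={"ground_truth": p.to_dict(), "units": "au"},
    )
    if p.adc_bits is not None:
        full_scale = float(np.max(np.abs(rec.samples))) or 1.0
        rec = quantize(rec, p.adc_bits, full_scale)
        rec.meta.setdefault("ground_truth", p.to_dict())
    return rec


def quantize(rec: Recording, bits: int, full_scale: float) -> Recording:
    """Map samples to the nearest of ``2**bits`` uniform levels.

    Raw-stage recordings are quantized over [-full_scale, +full_scale];
    envelope/filtered (non-negative) stages over [0, full_scale].  Values
    outside the range clip to the end levels.
    """
    if bits < 2:
        raise ParameterError(f"bits must be >= 2; got {bits}")
    if not (full_scale > 0):
        raise ParameterError(f"full_scale must be > 0; got {full_scale}")
    lo = -full_scale if rec.stage == "raw" else 0.0
    n_levels = 2**bits
    step = (full_scale - lo) / (n_levels - 1)
    q = np.rint((rec.samples - lo) / step)
    q = np.clip(q, 0, n_levels - 1) * step + lo
    meta = dict(rec.meta)
    meta["quantization"] = {"bits": bits, "full_scale": full_scale}
    return rec.replace(samples=q, meta=meta)
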
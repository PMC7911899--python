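"""Envelope extraction, resampling and tremor-band filtering.

Replicates the device's processing chain for both the 200 Hz wearable
path and the 6 kHz clinical-EMG export path: full-wave rectification with
moving-average integration, anti-aliased resampling to the analysis rate,
and a zero-phase Butterworth band-pass (1–10 Hz by default) isolating the
tremor rhythm.  Zero-phase filtering matters because the measurand is an
inter-channel phase difference: a causal filter would superimpose its own
frequency-dependent phase and its edge transients differ between channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import ContractError, ParameterError
from .signal_model import Recording

__all__ = ["FilterSpec", "envelope", "resample", "bandpass"]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification.

    ``zero_phase=True`` applies the filter forward and backward
    (``sosfiltfilt``), doubling the effective order and cancelling the
    filter's phase response.
    """

    low: float = 1.0
    high: float = 10.0
    order: int = 4
    zero_phase: bool = True
    kind: str = "butterworth band-pass"

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ParameterError(f"require 0 < low < high; got ({self.low}, {self.high})")
        if self.order < 1:
            raise ParameterError("order must be a positive integer")

    def sos(self, fs: float) -> np.ndarray:
        if self.high >= fs / 2:
            raise ParameterError(
                f"band edge {self.high} Hz at or above Nyquist ({fs / 2} Hz)"
            )
        return sps.butter(self.order, [self.low, self.high], btype="bandpass",
                          fs=fs, output="sos")


def envelope(rec: Recording, window_s: float = 0.05) -> Recording:
    """Full-wave rectification followed by moving-average integration.

    The window is centered and shrinks at the edges, so the output has the
    same length and rate as the input and is non-negative everywhere.
    Default 50 ms: short enough to pass tremor-band (≤ 10 Hz) amplitude
    modulation, long enough to smooth the > 50 Hz EMG carrier.
    """
    if rec.stage != "raw":
        raise ContractError(f"envelope() expects stage='raw'; got {rec.stage!r}")
    if not (0 < window_s < rec.duration_s / 4):
        raise ParameterError(
            f"window_s must be in (0, duration/4); got {window_s} for a "
            f"{rec.duration_s:.3g} s recording"
        )
    n = rec.n_samples
    half = max(int(round(window_s * rec.fs / 2)), 0)
    rect = np.abs(rec.samples)
    csum = np.concatenate(
        [np.zeros((2, 1)), np.cumsum(rect, axis=1)], axis=1
    )
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    out = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return rec.replace(samples=out, stage="envelope")


def resample(rec: Recording, target_fs: float) -> Recording:
    """Anti-alias filtered polyphase resampling to ``target_fs``.

    The decimation path (e.g. a 6 kHz clinical export down to the 200 Hz
    analysis rate) is the intended use; upsampling works but is flagged
    with a warning because it adds no information.
    """
    if not (target_fs > 0):
        raise ParameterError(f"target_fs must be > 0; got {target_fs}")
    if target_fs == rec.fs:
        return rec.replace(samples=rec.samples.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    if abs(float(frac) - target_fs / rec.fs) > 1e-9:
        raise ParameterError(
            f"resampling ratio {target_fs}/{rec.fs} is not rational within tolerance"
        )
    if target_fs > rec.fs:
        warnings.warn(
            f"upsampling {rec.fs} Hz -> {target_fs} Hz interpolates; no new information",
            stacklevel=2,
        )
    out = sps.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    if rec.stage == "envelope":
        # the anti-alias filter can ring slightly below zero; an envelope is
        # non-negative by construction
        out = np.clip(out, 0.0, None)
    return rec.replace(samples=out, fs=float(target_fs))


def bandpass(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Band-pass the envelope into the tremor band (stage -> 'filtered').

    The per-channel mean is removed before filtering so the pass-band
    transient at the lower edge is not excited by the envelope's large DC
    offset.
    """
    if rec.stage != "envelope":
        raise ContractError(f"bandpass() expects stage='envelope'; got {rec.stage!r}")
    spec = spec or FilterSpec()
    sos = spec.sos(rec.fs)
    x = rec.samples - rec.samples.mean(axis=1, keepdims=True)
    if spec.zero_phase:
        y = sps.sosfiltfilt(sos, x, axis=1)
    else:
        y = sps.sosfilt(sos, x, axis=1)
    meta = dict(rec.meta)
    meta["filter"] = {
        "kind": spec.kind,
        "low_hz": spec.low,
        "high_hz": spec.high,
        "order": spec.order,
        "zero_phase": spec.zero_phase,
    }
    return rec.replace(samples=y, stage="filtered", meta=meta)
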
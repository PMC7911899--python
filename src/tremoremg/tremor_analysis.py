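"""Tremor frequency, amplitude and inter-muscle phase estimation.

The tremor frequency is the location of the largest spectral peak of the
band-passed envelope in the analysis band, found on a zero-padded Hann
periodogram summed over the two (individually power-normalized) channels.
Amplitude and phase are then read off the discrete Fourier transforms of
the *unfiltered* (mean-removed) envelopes at that frequency, and the
phase difference — the absolute wrapped difference of the two channel
phases, in [0°, 180°] — drives the synchronous/alternating pattern call
at the 90° boundary: below 90° the antagonist muscles fire together
(typical of essential tremor with resting tremor), at or above 90° they
alternate (typical of tremor-dominant Parkinson's disease).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .errors import (
    ContractError,
    InsufficientDataError,
    NoTremorDetectedError,
    ParameterError,
    UndefinedPhaseError,
)
from .preprocess import FilterSpec, bandpass, envelope, resample
from .signal_model import (
    ROLES,
    AnalysisConfig,
    PatternLabel,
    Recording,
    TremorMeasurement,
)

__all__ = [
    "SpectralEstimate",
    "CircularSummary",
    "estimate_spectrum",
    "detect_tremor_frequency",
    "phase_difference",
    "classify_pattern",
    "analyze",
    "circular_summary",
]


@dataclass
class SpectralEstimate:
    """One-sided spectra of a two-channel recording.

    ``power`` comes from the band-passed channels (peak detection);
    ``complex_spectrum`` from the mean-removed unfiltered envelopes (phase
    and amplitude).  Both use the same Hann taper and zero-padded grid.
    Power is normalized so that ``power.sum(axis=1)`` equals the energy of
    the windowed signal (Parseval).  Channel row order is (extensor,
    flexor).
    """

    freqs: np.ndarray
    power: np.ndarray
    complex_spectrum: np.ndarray
    resolution_hz: float
    fs: float
    meta: dict = field(default_factory=dict)

    def index_of(self, f: float) -> int:
        """Nearest grid index to frequency ``f`` (uniform grid)."""
        return int(np.clip(round(f / self.resolution_hz), 0, len(self.freqs) - 1))


def _trim_edges(x: np.ndarray, fs: float, cfg: AnalysisConfig) -> np.ndarray:
    n = x.shape[1]
    if n / fs >= cfg.min_duration_for_trim_s:
        k = int(round(cfg.edge_trim_s * fs))
        if n - 2 * k >= 2:
            return x[:, k : n - k]
    return x


def estimate_spectrum(
    filtered: Recording,
    unfiltered: Recording,
    min_resolution_hz: float = 0.05,
    cfg: AnalysisConfig | None = None,
) -> SpectralEstimate:
    """Hann-tapered, zero-padded one-sided spectra of both recordings.

    ``filtered`` supplies the power spectrum for peak detection and
    ``unfiltered`` (the envelope before band-passing) the complex spectrum
    for amplitude/phase.  Both must cover the same samples at the same
    rate.  For recordings of at least 10 s, 1 s is trimmed from each end
    to discard filter edge transients.
    """
    if filtered.fs != unfiltered.fs:
        raise ContractError("filtered and unfiltered recordings differ in fs")
    if filtered.n_samples != unfiltered.n_samples:
        raise ContractError("filtered and unfiltered recordings differ in length")
    if filtered.channel_roles != unfiltered.channel_roles:
        raise ContractError("filtered and unfiltered recordings differ in channel order")
    fs = filtered.fs
    if filtered.duration_s < 5.0:
        raise InsufficientDataError(
            f"need at least 5 s for spectral estimation; got {filtered.duration_s:.3g} s"
        )
    if min_resolution_hz <= 0:
        raise ParameterError("min_resolution_hz must be > 0")
    cfg = cfg or AnalysisConfig()

    xf = _trim_edges(filtered.in_role_order(), fs, cfg)
    xu = _trim_edges(unfiltered.in_role_order(), fs, cfg)
    n = xf.shape[1]
    win = np.hanning(n)
    nfft = sfft.next_fast_len(max(n, int(math.ceil(fs / min_resolution_hz))))
    freqs = sfft.rfftfreq(nfft, 1.0 / fs)
    resolution = fs / nfft

    xf = (xf - xf.mean(axis=1, keepdims=True)) * win
    xu = (xu - xu.mean(axis=1, keepdims=True)) * win
    F = sfft.rfft(xf, nfft, axis=1)
    U = sfft.rfft(xu, nfft, axis=1)

    # one-sided Parseval weights: double every bin except DC (and Nyquist
    # when nfft is even) so sum(power) == sum(windowed signal ** 2)
    w = np.full(len(freqs), 2.0)
    w[0] = 1.0
    if nfft % 2 == 0:
        w[-1] = 1.0
    power = (np.abs(F) ** 2) * w / nfft

    return SpectralEstimate(
        freqs=freqs,
        power=power,
        complex_spectrum=U,
        resolution_hz=resolution,
        fs=fs,
        meta={"n_samples": n, "nfft": nfft},
    )


def detect_tremor_frequency(
    spec: SpectralEstimate,
    band: tuple[float, float] = (1.0, 10.0),
    quality_floor: float = 3.0,
) -> tuple[float, float]:
    """Locate the tremor peak in ``band`` on the summed normalized power.

    Each channel's in-band power is normalized to unit total before
    summing so that neither muscle dominates by sheer amplitude.  Returns
    ``(f_tremor, peak_quality)`` where quality is the peak's height over
    the median in-band level of the summed spectrum; below
    ``quality_floor`` no rhythmic component is credible and
    :class:`NoTremorDetectedError` is raised.
    """
    lo, hi = band
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not np.any(mask):
        raise ParameterError(f"band {band} is outside the frequency grid")
    p = spec.power[:, mask]
    totals = p.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise NoTremorDetectedError(0.0, quality_floor)
    s = (p / totals).sum(axis=0)
    i = int(np.argmax(s))
    med = float(np.median(s))
    quality = float(s[i] / med) if med > 0 else math.inf
    if quality < quality_floor:
        raise NoTremorDetectedError(quality, quality_floor)
    f = float(spec.freqs[mask][i])
    return f, quality


def _wrap_deg(d: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    w = (d + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def phase_difference(spec: SpectralEstimate, f_tremor: float) -> float:
    """Absolute wrapped extensor-minus-flexor phase at ``f_tremor``, in degrees.

    Phases are taken from the complex spectra of the unfiltered envelopes
    at the grid point nearest ``f_tremor``.  Raises
    :class:`UndefinedPhaseError` when either channel has numerically zero
    magnitude there.
    """
    i = spec.index_of(f_tremor)
    C = spec.complex_spectrum
    mags = np.abs(C[:, i])
    maxima = np.abs(C).max(axis=1)
    if np.any(mags < 1e-12 * np.maximum(maxima, np.finfo(float).tiny)):
        raise UndefinedPhaseError(
            f"channel magnitude at {spec.freqs[i]:.4g} Hz is numerically zero"
        )
    d = math.degrees(float(np.angle(C[0, i]) - np.angle(C[1, i])))
    return abs(_wrap_deg(d))


def classify_pattern(
    phase_diff_deg: float, boundary_deg: float = 90.0
) -> PatternLabel:
    """Synchronous below the boundary, alternating at or above it.

    The half-open split assigns the exact boundary value to the
    alternating class: [0, 90) synchronous, [90, 180] alternating.
    """
    if not (0.0 <= phase_diff_deg <= 180.0):
        raise ContractError(
            f"phase_diff_deg must be in [0, 180]; got {phase_diff_deg}"
        )
    if not (0.0 < boundary_deg < 180.0):
        raise ParameterError(f"boundary_deg must be in (0, 180); got {boundary_deg}")
    return (
        PatternLabel.SYNCHRONOUS
        if phase_diff_deg < boundary_deg
        else PatternLabel.ALTERNATING
    )


def analyze(rec: Recording, cfg: AnalysisConfig | None = None) -> TremorMeasurement:
    """Run the full pipeline on a raw or envelope recording.

    raw -> rectify+integrate -> resample to the analysis rate ->
    band-pass -> spectra -> peak detection -> phase at the peak ->
    pattern label.  Rectification happens at the native rate (so the
    high-frequency carrier is not aliased by decimation first), mirroring
    how a high-rate clinical export is pushed through the same flow as
    the wearable's 200 Hz stream.
    """
    cfg = cfg or AnalysisConfig()
    if rec.stage == "filtered":
        raise ContractError("analyze() expects a raw or envelope recording")
    env = envelope(rec, cfg.envelope_window_s) if rec.stage == "raw" else rec
    if env.fs != cfg.analysis_fs:
        env = resample(env, cfg.analysis_fs)
    filt = bandpass(
        env,
        FilterSpec(cfg.band_low, cfg.band_high, cfg.filter_order, cfg.zero_phase),
    )
    spec = estimate_spectrum(filt, env, cfg.min_freq_resolution_hz, cfg)
    f, quality = detect_tremor_frequency(
        spec, (cfg.band_low, cfg.band_high), cfg.peak_quality_floor
    )
    phase = phase_difference(spec, f)
    pattern = classify_pattern(phase, cfg.boundary_deg)
    i = spec.index_of(f)
    amp = tuple(float(a) for a in np.abs(spec.complex_spectrum[:, i]))
    signed = _wrap_deg(
        math.degrees(
            float(
                np.angle(spec.complex_spectrum[0, i])
                - np.angle(spec.complex_spectrum[1, i])
            )
        )
    )
    return TremorMeasurement(
        f_tremor=f,
        amplitude=amp,
        phase_diff_deg=phase,
        pattern=pattern,
        resolution_hz=spec.resolution_hz,
        band=(cfg.band_low, cfg.band_high),
        boundary_deg=cfg.boundary_deg,
        meta={
            "peak_quality": quality,
            "signed_phase_deg": signed,  # >0: extensor leads
            "amplitude_roles": list(ROLES),
        },
    )


@dataclass
class CircularSummary:
    """Axial circular summary of a set of phase differences in [0°, 180°].

    Phase differences are axial (they live on a half circle), so the mean
    direction and resultant length R are computed on doubled angles and
    the mean is folded back to [0°, 180°).  R = 1 means all phases equal;
    R = 0 maximal axial dispersion.
    """

    n: int
    mean_deg: float
    R: float
    bins: np.ndarray
    bin_edges: np.ndarray


def circular_summary(
    phases_deg, bin_width_deg: float = 20.0
) -> CircularSummary:
    """Summarize phase differences for a polar histogram."""
    phases = np.asarray(list(phases_deg), dtype=float)
    if phases.size == 0:
        raise ContractError("need at least one phase value")
    if np.any((phases < 0) | (phases > 180)) or not np.all(np.isfinite(phases)):
        raise ContractError("phase values must be finite and in [0, 180] degrees")
    if not (0 < bin_width_deg <= 180):
        raise ParameterError("bin_width_deg must be in (0, 180]")
    doubled = np.deg2rad(2.0 * phases)
    C = float(np.mean(np.cos(doubled)))
    S = float(np.mean(np.sin(doubled)))
    R = math.hypot(C, S)
    mean2 = math.degrees(math.atan2(S, C)) % 360.0
    mean_deg = mean2 / 2.0
    n_bins = int(math.ceil(180.0 / bin_width_deg))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width_deg, 180.0)
    counts, _ = np.histogram(phases, bins=edges)
    return CircularSummary(
        n=int(phases.size),
        mean_deg=mean_deg,
        R=R,
        bins=counts,
        bin_edges=edges,
    )
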
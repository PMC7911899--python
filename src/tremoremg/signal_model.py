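"""Data model and file I/O for two-channel antagonist-muscle EMG recordings.

A :class:`Recording` holds two synchronized channels (forearm extensor and
flexor), the sampling rate and the processing stage the samples are at:
``raw`` (the amplified EMG carrier), ``envelope`` (rectified + integrated)
or ``filtered`` (band-passed envelope).  Analysis results are carried by
:class:`TremorMeasurement`.  Recordings are exchanged as CSV (with a JSON
sidecar for metadata) or EDF; measurements as JSON.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ContractError,
    DataError,
    FormatError,
    ParameterError,
    RoleMappingError,
)

ROLES = ("extensor", "flexor")
STAGES = ("raw", "envelope", "filtered")

#: sidecar suffix appended to a CSV path to hold fs/stage/roles/meta
SIDECAR_SUFFIX = ".meta.json"


class PatternLabel(str, enum.Enum):
    """Resting-tremor activation pattern of the antagonist muscle pair."""

    SYNCHRONOUS = "synchronous"  # bursts in phase (< 90°): typical of rET
    ALTERNATING = "alternating"  # bursts phase-shifted (>= 90°): typical of tPD

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class Recording:
    """Two-channel sampled signal with rate, roles and processing stage.

    Parameters
    ----------
    samples
        Array of shape ``(2, n)``; row order matches ``channel_roles``.
        Amplitude units are arbitrary (mV or ADC counts) and are carried
        only as metadata.
    fs
        Sampling rate in Hz.
    channel_roles
        Ordered pair of labels drawn from ``{"extensor", "flexor"}``.
    stage
        One of ``raw``, ``envelope``, ``filtered``.
    meta
        Free-form metadata (subject id, device label, units, ground truth).
    """

    samples: np.ndarray
    fs: float
    channel_roles: tuple[str, str] = ROLES
    stage: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        try:
            self.samples = np.asarray(self.samples, dtype=float)
        except (ValueError, TypeError) as exc:  # ragged/non-numeric input
            raise DataError(f"samples not convertible to a (2, n) array: {exc}") from None
        if self.samples.ndim != 2 or self.samples.shape[0] != 2:
            raise DataError(
                f"expected samples of shape (2, n); got {self.samples.shape}"
            )
        if self.samples.shape[1] < 2:
            raise DataError("recording must contain at least 2 samples per channel")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("recording contains non-finite samples")
        if not (math.isfinite(self.fs) and self.fs > 0):
            raise DataError(f"sampling rate must be positive and finite; got {self.fs}")
        self.fs = float(self.fs)
        roles = tuple(self.channel_roles)
        if sorted(roles) != sorted(ROLES):
            raise RoleMappingError(
                f"channel_roles must be a permutation of {ROLES}; got {roles}"
            )
        self.channel_roles = roles
        if self.stage not in STAGES:
            raise ContractError(f"stage must be one of {STAGES}; got {self.stage!r}")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, role: str) -> np.ndarray:
        """Return the samples of one channel by role name."""
        try:
            idx = self.channel_roles.index(role)
        except ValueError:
            raise RoleMappingError(f"no channel with role {role!r}") from None
        return self.samples[idx]

    def in_role_order(self) -> np.ndarray:
        """Samples reordered to canonical (extensor, flexor) order."""
        return np.stack([self.channel(r) for r in ROLES])

    def replace(self, **kw) -> "Recording":
        return dataclasses.replace(self, **kw)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the tremor-analysis pipeline.

    Defaults replicate the device chain: a 1–10 Hz Butterworth band-pass
    on the 200 Hz rectified-integrated signal, spectral peak search in the
    same band, and the 90° synchronous/alternating decision boundary.
    """

    band_low: float = 1.0
    band_high: float = 10.0
    filter_order: int = 4
    zero_phase: bool = True
    analysis_fs: float = 200.0
    envelope_window_s: float = 0.05
    min_freq_resolution_hz: float = 0.05
    boundary_deg: float = 90.0
    peak_quality_floor: float = 3.0
    #: seconds trimmed from each end before spectral estimation (only when
    #: the recording is at least min_duration_for_trim_s long) to suppress
    #: filter edge transients
    edge_trim_s: float = 1.0
    min_duration_for_trim_s: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high < self.analysis_fs / 2):
            raise ParameterError(
                "require 0 < band_low < band_high < analysis_fs/2; got "
                f"({self.band_low}, {self.band_high}) at fs={self.analysis_fs}"
            )
        if not (0 < self.boundary_deg < 180):
            raise ParameterError(f"boundary_deg must be in (0, 180); got {self.boundary_deg}")
        if self.filter_order < 1:
            raise ParameterError("filter_order must be a positive integer")
        if self.envelope_window_s <= 0 or self.min_freq_resolution_hz <= 0:
            raise ParameterError("envelope window and frequency resolution must be > 0")


@dataclass
class TremorMeasurement:
    """Result of the full analysis of one recording.

    ``phase_diff_deg`` is the absolute wrapped difference of the two
    channels' spectral phases at the tremor frequency, in [0°, 180°];
    ``pattern`` follows the 90° rule (synchronous below the boundary,
    alternating at or above it).
    """

    f_tremor: float
    amplitude: tuple[float, float]  # (extensor, flexor), arbitrary units
    phase_diff_deg: float
    pattern: PatternLabel
    resolution_hz: float
    band: tuple[float, float] = (1.0, 10.0)
    boundary_deg: float = 90.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pattern = PatternLabel(self.pattern)
        lo, hi = self.band
        if not (lo <= self.f_tremor <= hi):
            raise ContractError(
                f"f_tremor {self.f_tremor} Hz outside analysis band [{lo}, {hi}] Hz"
            )
        if not (0.0 <= self.phase_diff_deg <= 180.0):
            raise ContractError(
                f"phase_diff_deg must be in [0, 180]; got {self.phase_diff_deg}"
            )
        if any(a < 0 for a in self.amplitude):
            raise ContractError("amplitudes must be non-negative")
        expected = (
            PatternLabel.SYNCHRONOUS
            if self.phase_diff_deg < self.boundary_deg
            else PatternLabel.ALTERNATING
        )
        if self.pattern is not expected:
            raise ContractError(
                f"pattern {self.pattern.value!r} inconsistent with phase "
                f"{self.phase_diff_deg}° under the {self.boundary_deg}° boundary"
            )

    def to_dict(self) -> dict:
        return {
            "f_tremor_hz": self.f_tremor,
            "amplitude": list(self.amplitude),
            "phase_diff_deg": self.phase_diff_deg,
            "pattern": self.pattern.value,
            "resolution_hz": self.resolution_hz,
            "band_hz": list(self.band),
            "boundary_deg": self.boundary_deg,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TremorMeasurement":
        return cls(
            f_tremor=d["f_tremor_hz"],
            amplitude=tuple(d["amplitude"]),
            phase_diff_deg=d["phase_diff_deg"],
            pattern=PatternLabel(d["pattern"]),
            resolution_hz=d["resolution_hz"],
            band=tuple(d.get("band_hz", (1.0, 10.0))),
            boundary_deg=d.get("boundary_deg", 90.0),
            meta=dict(d.get("meta", {})),
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + SIDECAR_SUFFIX)


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Write a recording to ``path`` as CSV (+ JSON sidecar) or EDF.

    CSV carries a ``time_s`` column plus one column per channel role; the
    sidecar preserves fs, stage, roles and metadata exactly.  EDF stores
    samples as 16-bit integers scaled per channel, so round-trips are
    exact only to the 16-bit quantization step.
    """
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "csv":
        t = np.arange(rec.n_samples) / rec.fs
        df = pd.DataFrame({"time_s": t})
        for role, row in zip(rec.channel_roles, rec.samples):
            df[role] = row
        df.to_csv(path, index=False, float_format="%.12g")
        sidecar = {
            "fs": rec.fs,
            "stage": rec.stage,
            "channel_roles": list(rec.channel_roles),
            "meta": _jsonable(rec.meta),
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    elif fmt == "edf":
        from ._edf import write_edf

        write_edf(path, rec)
    else:
        raise ParameterError(f"unknown format {fmt!r}")


def _jsonable(obj):
    """Coerce numpy scalars/arrays in metadata to plain Python types."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _looks_like_header(line: str) -> bool:
    for tok in line.strip().split(","):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    stage: str | None = None,
    channel_map: Mapping[str, str | int] | None = None,
) -> Recording:
    """Read a two-channel recording from CSV or EDF.

    For CSV, metadata comes from the JSON sidecar when present; otherwise
    ``fs`` (or a ``time_s`` column) and ``stage`` must be supplied.  When a
    time column exists its median step is cross-checked against fs to 1%.
    ``channel_map`` maps the roles to column names or indices when the
    file does not use the canonical ``extensor``/``flexor`` headers.
    """
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        return _read_edf(path, stage=stage, channel_map=channel_map)
    if fmt != "csv":
        raise ParameterError(f"unknown format {fmt!r}")

    sidecar = None
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())

    with open(path) as fh:
        first = fh.readline()
    has_header = _looks_like_header(first)
    try:
        df = pd.read_csv(path, header=0 if has_header else None)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"could not parse {path} as CSV: {exc}") from None
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows or missing values")
    if not has_header:
        ncol = df.shape[1]
        if ncol == 2:
            df.columns = list(ROLES)
        elif ncol == 3:
            df.columns = ["time_s", *ROLES]
        else:
            raise RoleMappingError(
                f"headerless CSV must have 2 or 3 columns; got {ncol}"
            )

    cols = {str(c).strip().lower(): c for c in df.columns}
    time_col = cols.get("time_s") or cols.get("time")

    def _resolve(role: str):
        if channel_map and role in channel_map:
            key = channel_map[role]
            if isinstance(key, int):
                return df.columns[key]
            if key in df.columns:
                return key
            raise RoleMappingError(f"column {key!r} for role {role!r} not found")
        if role in cols:
            return cols[role]
        raise RoleMappingError(
            f"cannot resolve a column for role {role!r}; columns: {list(df.columns)}"
        )

    roles = tuple(sidecar["channel_roles"]) if sidecar else ROLES
    data = []
    for role in roles:
        col = df[_resolve(role)].to_numpy(dtype=float)
        data.append(col)
    samples = np.stack(data)
    if not np.all(np.isfinite(samples)):
        raise DataError(f"{path}: non-finite sample values")

    if sidecar is not None:
        fs_val = float(sidecar["fs"]) if fs is None else float(fs)
        stage_val = stage or sidecar.get("stage", "raw")
        meta = dict(sidecar.get("meta", {}))
    else:
        fs_val = None if fs is None else float(fs)
        stage_val = stage or "raw"
        meta = {}

    if time_col is not None and len(df) > 1:
        steps = np.diff(df[time_col].to_numpy(dtype=float))
        med = float(np.median(steps))
        if med <= 0:
            raise FormatError(f"{path}: non-increasing time column")
        fs_time = 1.0 / med
        if fs_val is None:
            fs_val = fs_time
        elif abs(fs_time - fs_val) > 0.01 * fs_val:
            raise FormatError(
                f"{path}: declared fs {fs_val} Hz disagrees with time column "
                f"({fs_time:.6g} Hz) by more than 1%"
            )
    if fs_val is None:
        raise ParameterError(
            f"{path}: sampling rate unknown — no sidecar, no time column, no fs given"
        )
    return Recording(samples, fs_val, roles, stage_val, meta)


def _read_edf(path: Path, stage: str | None, channel_map) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"could not parse {path} as EDF: {exc}") from None
    names = {n.strip().lower(): i for i, n in enumerate(raw.ch_names)}

    def _resolve(role: str) -> int:
        if channel_map and role in channel_map:
            key = channel_map[role]
            if isinstance(key, int):
                return key
            k = str(key).strip().lower()
            if k in names:
                return names[k]
            raise RoleMappingError(f"EDF channel {key!r} for role {role!r} not found")
        if role in names:
            return names[role]
        raise RoleMappingError(
            f"cannot resolve EDF channel for role {role!r}; channels: {raw.ch_names}"
        )

    data = raw.get_data()
    idx = [_resolve(r) for r in ROLES]
    samples = np.asarray(data[idx], dtype=float)
    # mne rescales channels with a recognized physical dimension to SI
    # volts; undo that so samples come back in the units they were stored in
    si_per_unit = {"V": 1.0, "mV": 1e-3, "µV": 1e-6, "uV": 1e-6}
    orig_units = getattr(raw, "_orig_units", {}) or {}
    for row, ch_i in enumerate(idx):
        unit = orig_units.get(raw.ch_names[ch_i], "n/a")
        samples[row] /= si_per_unit.get(unit, 1.0)
    # recover the stage tag stashed in the EDF recording-id header field
    stage_val = stage or "raw"
    with open(path, "rb") as fh:
        rec_id = fh.read(168)[88:168].decode("ascii", errors="replace")
    for s in STAGES:
        if f"stage={s}" in rec_id:
            stage_val = stage or s
    return Recording(samples, float(raw.info["sfreq"]), ROLES, stage_val,
                     {"source": str(path)})


# ---------------------------------------------------------------------------
# Measurement I/O
# ---------------------------------------------------------------------------

def write_measurement(m: TremorMeasurement, path: str | Path) -> None:
    """Serialize a measurement as JSON (angles in degrees, lowercase labels)."""
    Path(path).write_text(json.dumps(_jsonable(m.to_dict()), indent=1, sort_keys=True))


def read_measurement(path: str | Path) -> TremorMeasurement:
    return TremorMeasurement.from_dict(json.loads(Path(path).read_text()))
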
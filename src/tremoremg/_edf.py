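"""Minimal EDF (European Data Format) writer.

Writes a plain EDF file: the fixed 256-byte header, one 256-byte signal
header per channel, and little-endian 16-bit integer samples.  The whole
recording is stored as a single data record so that no padding is needed
and the sample count round-trips exactly.  Samples are scaled per channel
to the full 16-bit digital range, so amplitudes round-trip to within one
quantization step of the channel's physical range.

Reading is delegated to ``mne.io.read_raw_edf``; this module only writes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ParameterError


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ParameterError(f"EDF header field {s!r} exceeds {width} ascii chars")
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, rec) -> None:
    """Write a two-channel Recording to ``path`` in EDF."""
    samples = np.asarray(rec.samples, dtype=float)
    n_ch, n = samples.shape
    duration = n / rec.fs
    dur_str = f"{duration:.6g}"
    if len(dur_str) > 8:
        raise ParameterError(f"record duration {duration} not representable in EDF")

    dig_min, dig_max = -32768, 32767
    phys_min = samples.min(axis=1)
    phys_max = samples.max(axis=1)
    # widen degenerate (constant) channels so the scale is well defined
    flat = phys_max - phys_min <= 0
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)

    header = bytearray()
    header += _field("0", 8)                                   # version
    header += _field("X X X X", 80)                            # patient id
    header += _field(f"Startdate X X X X stage={rec.stage}", 80)  # recording id
    header += _field("01.01.00", 8)                            # start date
    header += _field("00.00.00", 8)                            # start time
    header += _field(str(256 * (1 + n_ch)), 8)                 # header bytes
    header += _field("", 44)                                   # reserved
    header += _field("1", 8)                                   # n data records
    header += _field(dur_str, 8)                               # record duration s
    header += _field(str(n_ch), 4)                             # n signals

    units = str(rec.meta.get("units", ""))[:8]
    for i in range(n_ch):
        header += _field(rec.channel_roles[i], 16)             # label
    for _ in range(n_ch):
        header += _field("", 80)                               # transducer
    for _ in range(n_ch):
        header += _field(units, 8)                             # physical dim
    for i in range(n_ch):
        header += _field(f"{phys_min[i]:.7g}"[:8], 8)
    for i in range(n_ch):
        header += _field(f"{phys_max[i]:.7g}"[:8], 8)
    for _ in range(n_ch):
        header += _field(str(dig_min), 8)
    for _ in range(n_ch):
        header += _field(str(dig_max), 8)
    for _ in range(n_ch):
        header += _field("", 80)                               # prefiltering
    for _ in range(n_ch):
        header += _field(str(n), 8)                            # samples/record
    for _ in range(n_ch):
        header += _field("", 32)                               # reserved

    # header phys min/max were truncated to 8 chars; use the values as
    # written so writer and reader agree on the scale exactly
    pmin = np.array([float(f"{v:.7g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.7g}"[:8]) for v in phys_max])
    gain = (dig_max - dig_min) / (pmax - pmin)
    digital = np.rint((samples - pmin[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for i in range(n_ch):  # one record: signals stored back to back
            fh.write(digital[i].tobytes())
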
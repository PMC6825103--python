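"""Minimal EDF writer used only to fabricate read fixtures at test time.

Writes a plain EDF (16-bit) file with one-second data records.  This is
a synthetic fixture generator for exercising the package's EDF reader;
it is not a general-purpose exporter.
"""

from pathlib import Path

import numpy as np


def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: Path, data: np.ndarray, fs: int, channel_names: list[str]) -> Path:
    """Write channels x samples float data as a 16-bit EDF file.

    The number of samples must be a multiple of fs (whole one-second
    records).  Physical scaling maps each channel's [min, max] onto the
    full digital range, so the round trip is exact to ~16-bit precision.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samples = data.shape
    assert len(channel_names) == n_ch
    assert n_samples % fs == 0, "need whole one-second records"
    n_records = n_samples // fs

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    # guard constant channels against a zero physical span
    span = np.where(phys_max > phys_min, phys_max - phys_min, 1.0)
    dig_min, dig_max = -32768, 32767
    scaled = (data - phys_min[:, None]) / span[:, None]  # [0, 1]
    digital = np.round(scaled * (dig_max - dig_min) + dig_min).astype("<i2")

    header = b""
    header += _field("0", 8)                       # version
    header += _field("X X X X", 80)                # patient id
    header += _field("Startdate 01-JAN-2020", 80)  # recording id
    header += _field("01.01.20", 8)                # start date
    header += _field("00.00.00", 8)                # start time
    header += _field(256 * (1 + n_ch), 8)          # header byte count
    header += _field("", 44)                       # reserved
    header += _field(n_records, 8)
    header += _field(1, 8)                         # record duration (s)
    header += _field(n_ch, 4)

    header += b"".join(_field(name, 16) for name in channel_names)
    header += b"".join(_field("", 80) for _ in range(n_ch))        # transducer
    header += b"".join(_field("uV", 8) for _ in range(n_ch))       # dimension
    header += b"".join(_field(f"{v:.6g}", 8) for v in phys_min)
    header += b"".join(_field(f"{v:.6g}", 8) for v in (phys_min + span))
    header += b"".join(_field(dig_min, 8) for _ in range(n_ch))
    header += b"".join(_field(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_field("", 80) for _ in range(n_ch))        # prefiltering
    header += b"".join(_field(fs, 8) for _ in range(n_ch))         # samples/record
    header += b"".join(_field("", 32) for _ in range(n_ch))        # reserved

    body = bytearray()
    for rec in range(n_records):
        for ch in range(n_ch):
            body += digital[ch, rec * fs:(rec + 1) * fs].tobytes()

    path = Path(path)
    path.write_bytes(header + bytes(body))
    return path
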
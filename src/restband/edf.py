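"""Minimal writer for European Data Format (EDF, 16-bit) recordings.

Covers exactly what the fixture pipeline needs: continuous multichannel
signals in μV, one-second data records, per-channel physical scaling.
Reading goes through ``mne.io.read_raw_edf`` (see :mod:`restband.io`); this
writer exists because no EDF export library is part of the runtime stack.

Quantization: samples are mapped linearly onto the 16-bit digital range
[−32768, 32767], so the round-trip error per sample is at most half the
physical range divided by 65535.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .recording import Recording

__all__ = ["write_edf"]


def _field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {value!r} (max {width})")
    return b.ljust(width)


def _fmt_phys(value: float) -> str:
    """Shortest %G rendering of a physical range bound that fits 8 chars."""
    for prec in (6, 5, 4, 3, 2):
        s = f"{value:.{prec}G}"
        if len(s) <= 8:
            return s
    raise ValueError(f"physical range {value} not representable in 8 chars")


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF with 1 s data records.

    The recording length must be a whole number of seconds and the sampling
    rate an integer (both true for the fixture generator's outputs).
    """
    path = Path(path)
    fs = rec.sampling_rate
    if fs != int(fs):
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(fs)
    if rec.n_samples % fs != 0:
        raise ValueError(
            f"EDF writer requires a whole number of 1 s records: "
            f"{rec.n_samples} samples at {fs} Hz"
        )
    n_records = rec.n_samples // fs
    n_sig = rec.n_channels

    dig_min, dig_max = -32768, 32767
    phys_mins, phys_maxs, digital = [], [], []
    for x in rec.samples:
        span = float(np.abs(x).max())
        span = max(span * 1.01, 1.0)  # avoid zero range; headroom for rounding
        # format the range into the 8-char header field FIRST, then scale with
        # the value the reader will actually see
        span = abs(float(_fmt_phys(-span)))  # snap to the 8-char header rendering
        pmin, pmax = -span, span
        scale = (dig_max - dig_min) / (pmax - pmin)
        d = np.round((x - pmin) * scale + dig_min)
        d = np.clip(d, dig_min, dig_max).astype(np.int16)
        phys_mins.append(pmin)
        phys_maxs.append(pmax)
        digital.append(d)

    header_bytes = 256 * (1 + n_sig)
    with open(path, "wb") as f:
        f.write(_field("0", 8))
        f.write(_field(f"subject {rec.subject_id}", 80))
        f.write(_field(f"condition {rec.condition}", 80))
        f.write(_field("01.01.00", 8))
        f.write(_field("00.00.00", 8))
        f.write(_field(str(header_bytes), 8))
        f.write(_field("", 44))
        f.write(_field(str(n_records), 8))
        f.write(_field("1", 8))  # record duration, seconds
        f.write(_field(str(n_sig), 4))
        for ch in rec.channel_labels:
            f.write(_field(ch, 16))
        for _ in range(n_sig):
            f.write(_field("", 80))  # transducer
        for _ in range(n_sig):
            f.write(_field("uV", 8))
        for pmin in phys_mins:
            f.write(_field(_fmt_phys(pmin), 8))
        for pmax in phys_maxs:
            f.write(_field(_fmt_phys(pmax), 8))
        for _ in range(n_sig):
            f.write(_field(str(dig_min), 8))
        for _ in range(n_sig):
            f.write(_field(str(dig_max), 8))
        for _ in range(n_sig):
            f.write(_field("", 80))  # prefiltering
        for _ in range(n_sig):
            f.write(_field(str(fs), 8))
        for _ in range(n_sig):
            f.write(_field("", 32))
        for r in range(n_records):
            for d in digital:
                f.write(d[r * fs : (r + 1) * fs].astype("<i2").tobytes())
    return path
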
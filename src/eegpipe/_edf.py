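"""Minimal EDF/BDF writer for synthetic recordings.

Only what the fixture generator needs: continuous signals at one sampling
rate, 1-second data records, an optional integer trigger ("Status") channel.
Reading goes through :mod:`mne`; this module only writes.

BDF stores samples as little-endian 24-bit two's complement integers
(BioSemi), EDF as 16-bit. Physical scaling is chosen per channel from the
data range, so the quantization error is ~range/2^24 (BDF) or ~range/2^16
(EDF).
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

__all__ = ["write_edf"]


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _pack_int24(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype="<i4")
    return v.view("u1").reshape(-1, 4)[:, :3].tobytes()


def write_edf(
    path,
    signals_uv: np.ndarray,
    fs: float,
    labels,
    *,
    status: np.ndarray | None = None,
    fmt: str = "bdf",
    patient_id: str = "X",
    recording_id: str = "synthetic",
) -> None:
    """Write ``signals_uv`` (channels x samples, microvolts) to an EDF/BDF file.

    The signal is truncated to a whole number of 1-second records. ``status``,
    if given, is an integer trigger code per sample written as an extra
    "Status" channel with identity physical scaling.
    """
    signals_uv = np.atleast_2d(np.asarray(signals_uv, dtype=float))
    n_ch, n_samp = signals_uv.shape
    if len(labels) != n_ch:
        raise ValueError("labels length must match channel count")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("writer supports integer sampling rates only")
    fs = int(round(fs))
    n_records = n_samp // fs
    if n_records < 1:
        raise ValueError("recording shorter than one data record")
    n_keep = n_records * fs
    signals_uv = signals_uv[:, :n_keep]

    fmt = fmt.lower()
    if fmt == "bdf":
        dig_min, dig_max = -8388608, 8388607
        version_bytes = b"\xffBIOSEMI".ljust(8)
        reserved = "24BIT"
        bytes_per_samp = 3
    elif fmt == "edf":
        dig_min, dig_max = -32768, 32767
        version_bytes = _field("0", 8)
        reserved = ""
        bytes_per_samp = 2
    else:
        raise ValueError(f"unknown format {fmt!r}")

    all_labels = [str(lab) for lab in labels]
    columns = [signals_uv[i] for i in range(n_ch)]
    phys_min, phys_max, transducer, dim = [], [], [], []
    for col in columns:
        lo = float(np.floor(col.min())) - 1.0
        hi = float(np.ceil(col.max())) + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        transducer.append("AgAgCl electrode")
        dim.append("uV")
    if status is not None:
        status = np.asarray(status)[:n_keep].astype(np.int64)
        if status.min() < 0 or status.max() > dig_max:
            raise ValueError("status codes out of digital range")
        all_labels.append("Status")
        columns.append(status.astype(float))
        # identity mapping: physical value == digital value == trigger code
        phys_min.append(float(dig_min))
        phys_max.append(float(dig_max))
        transducer.append("Triggers and Status")
        dim.append("Boolean")
    n_total = len(all_labels)

    now = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header_bytes = 256 * (1 + n_total)
    head = [
        version_bytes,
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(header_bytes, 8),
        _field(reserved, 44),
        _field(n_records, 8),
        _field(1, 8),  # record duration, seconds
        _field(n_total, 4),
    ]
    for lab in all_labels:
        head.append(_field(lab[:16], 16))
    for t in transducer:
        head.append(_field(t, 80))
    for d in dim:
        head.append(_field(d, 8))
    for v in phys_min:
        head.append(_field(_num(v), 8))
    for v in phys_max:
        head.append(_field(_num(v), 8))
    for _ in all_labels:
        head.append(_field(dig_min, 8))
    for _ in all_labels:
        head.append(_field(dig_max, 8))
    for _ in all_labels:
        head.append(_field("HP:DC", 80))
    for _ in all_labels:
        head.append(_field(fs, 8))
    for _ in all_labels:
        head.append(_field("", 32))

    # digitize
    digital = np.empty((n_total, n_keep), dtype=np.int64)
    for i, col in enumerate(columns):
        gain = (phys_max[i] - phys_min[i]) / (dig_max - dig_min)
        d = np.rint((col - phys_min[i]) / gain) + dig_min
        digital[i] = np.clip(d, dig_min, dig_max)

    with open(path, "wb") as fh:
        fh.write(b"".join(head))
        buf = np.empty((n_total, fs), dtype=np.int64)
        for r in range(n_records):
            sl = slice(r * fs, (r + 1) * fs)
            buf[:] = digital[:, sl]
            if bytes_per_samp == 3:
                fh.write(_pack_int24(buf.reshape(-1)))
            else:
                fh.write(buf.astype("<i2").tobytes())


def _num(v: float) -> str:
    """Format a number into <=8 ascii chars the way EDF headers expect."""
    if v == int(v) and len(str(int(v))) <= 8:
        return str(int(v))
    for fmt in ("%.2f", "%.1f", "%.4g", "%.1e"):
        s = fmt % v
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot encode {v} in 8 bytes")
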
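"""Minimal EDF (European Data Format) writer/reader for single-trial records.

Writes one data record containing the whole trial as 16-bit integers with
per-channel physical scaling.  Only the subset of the format needed to
round-trip :class:`~eegdfc.synthetic.EEGRecord` objects is implemented.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

from .exceptions import DataError
from .synthetic import EEGRecord

_HDR = 256
_DIGITAL_MAX = 32767
_DIGITAL_MIN = -32768


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(record: EEGRecord, path) -> None:
    n_ch, n_samp = record.samples.shape
    phys_min = record.samples.min(axis=1)
    phys_max = record.samples.max(axis=1)
    # avoid zero physical range for flat channels
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    duration = n_samp / record.sampling_rate
    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field(f"S{record.subject_id:03d}", 80),
            _field(f"trial {record.trial_id} class {record.class_label}", 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(_HDR * (1 + n_ch)), 8),
            _field("", 44),
            _field("1", 8),  # one data record holding the whole trial
            _field(f"{duration:.6g}", 8),
            _field(str(n_ch), 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_field(lbl, 16) for lbl in record.channel_labels),
            b"".join(_field("EEG", 80) for _ in range(n_ch)),
            b"".join(_field("uV", 8) for _ in range(n_ch)),
            b"".join(_field(f"{v:.6g}", 8) for v in phys_min),
            b"".join(_field(f"{v:.6g}", 8) for v in phys_max),
            b"".join(_field(str(_DIGITAL_MIN), 8) for _ in range(n_ch)),
            b"".join(_field(str(_DIGITAL_MAX), 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(str(n_samp), 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )
    scale = (phys_max - phys_min) / (_DIGITAL_MAX - _DIGITAL_MIN)
    digital = np.rint(
        (record.samples - phys_min[:, None]) / scale[:, None] + _DIGITAL_MIN
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        fh.write(digital.tobytes())  # channel-major within the single record


def read_edf(path) -> tuple[np.ndarray, float, list[str], dict]:
    """Returns (samples, sampling_rate, channel_labels, header_info)."""
    with open(path, "rb") as fh:
        hdr = fh.read(_HDR)
        if len(hdr) < _HDR:
            raise DataError(f"{path}: truncated EDF header")
        n_records = int(hdr[236:244].decode("ascii").strip())
        duration = float(hdr[244:252].decode("ascii").strip())
        n_ch = int(hdr[252:256].decode("ascii").strip())
        sig = fh.read(_HDR * n_ch)
        payload = fh.read()

    def _col(block_off: int, width: int, i: int) -> str:
        start = block_off * n_ch + i * width
        return sig[start : start + width].decode("ascii").strip()

    labels = [_col(0, 16, i) for i in range(n_ch)]
    # per-signal blocks: label 16, transducer 80, unit 8, pmin 8, pmax 8,
    # dmin 8, dmax 8, prefilter 80, n_samples 8
    off_pmin = 16 * n_ch + 80 * n_ch + 8 * n_ch
    pmin = np.array([float(sig[off_pmin + 8 * i : off_pmin + 8 * (i + 1)]) for i in range(n_ch)])
    off_pmax = off_pmin + 8 * n_ch
    pmax = np.array([float(sig[off_pmax + 8 * i : off_pmax + 8 * (i + 1)]) for i in range(n_ch)])
    off_ns = off_pmax + 8 * n_ch + 8 * n_ch + 8 * n_ch + 80 * n_ch
    n_samp = int(sig[off_ns : off_ns + 8])
    if n_records != 1:
        raise DataError("only single-record EDF files are supported")
    digital = np.frombuffer(payload, dtype="<i2", count=n_ch * n_samp).reshape(n_ch, n_samp)
    scale = (pmax - pmin) / (_DIGITAL_MAX - _DIGITAL_MIN)
    samples = (digital.astype(float) - _DIGITAL_MIN) * scale[:, None] + pmin[:, None]
    info = {
        "patient": hdr[8:88].decode("ascii").strip(),
        "recording": hdr[88:168].decode("ascii").strip(),
    }
    return samples, n_samp / duration, labels, info
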
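"""Minimal EDF writer: 16-bit, one data record per second, physical unit uV.

Only what the pipeline needs — continuous multichannel signals with integer
sampling rates.  Reading goes through MNE (see :mod:`seegphrase.io`), which
also serves as an independent check of this writer.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .containers import Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    ns = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs))
    padded = np.zeros((ns, n_records * fs), dtype=np.float64)
    padded[:, : rec.n_samples] = rec.data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    phys_min = -phys_max
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.round((padded - phys_min[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),  # patient id (anonymous)
            _field("Startdate X X X X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (1 + ns)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),  # record duration (s)
            _field(str(ns), 4),
        ]
    )
    labels = [c.name for c in rec.channels]
    per_signal = b"".join(
        [
            b"".join(_field(lab, 16) for lab in labels),
            b"".join(_field("SEEG", 80) for _ in labels),
            b"".join(_field("uV", 8) for _ in labels),
            b"".join(_field(f"{phys_min[i]:.6g}"[:8], 8) for i in range(ns)),
            b"".join(_field(f"{phys_max[i]:.6g}"[:8], 8) for i in range(ns)),
            b"".join(_field(str(_DIG_MIN), 8) for _ in labels),
            b"".join(_field(str(_DIG_MAX), 8) for _ in labels),
            b"".join(_field("", 80) for _ in labels),
            b"".join(_field(str(fs), 8) for _ in labels),
            b"".join(_field("", 32) for _ in labels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + per_signal)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())
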
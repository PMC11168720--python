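"""Minimal EDF (16-bit European Data Format) writer.

Only what the fixture pipeline needs: continuous signals, one data record
per second, per-signal physical units and ranges.  Readers (mne) see a
standard EDF file.  No EDF+ annotations are written; seizure marks travel
in the plain-text sidecar instead.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np


def _field(text: str, width: int) -> bytes:
    b = str(text)[:width].encode("ascii")
    return b + b" " * (width - len(b))


def write_edf(path, signals, labels, fs, physical_dims,
              start=None, patient_id="X", recording_id="X") -> None:
    """Write ``signals`` (list of 1-D float arrays, equal length) to EDF.

    fs must be integral so one data record holds one second per signal.
    Values are scaled to the full 16-bit digital range per signal.
    """
    fs = int(fs)
    signals = [np.asarray(s, dtype=float).ravel() for s in signals]
    n = signals[0].size
    if any(s.size != n for s in signals):
        raise ValueError("all signals must share a sample count")
    if n % fs:
        # pad the tail so records are complete
        pad = fs - n % fs
        signals = [np.concatenate([s, np.full(pad, s[-1])]) for s in signals]
        n = signals[0].size
    n_records = n // fs
    ns = len(signals)
    start = start or _dt.datetime(2000, 1, 1, 0, 0, 0)

    phys_min, phys_max, dig_min, dig_max = [], [], [], []
    digital = []
    for s in signals:
        lo, hi = float(np.min(s)), float(np.max(s))
        if hi - lo < 1e-9:
            lo, hi = lo - 1.0, hi + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        dig_min.append(-32768)
        dig_max.append(32767)
        scaled = (s - lo) / (hi - lo) * 65535.0 - 32768.0
        digital.append(np.round(scaled).astype("<i2"))

    with open(path, "wb") as f:
        f.write(_field("0", 8))
        f.write(_field(patient_id, 80))
        f.write(_field(recording_id, 80))
        f.write(_field(start.strftime("%d.%m.%y"), 8))
        f.write(_field(start.strftime("%H.%M.%S"), 8))
        f.write(_field(str(256 * (ns + 1)), 8))
        f.write(_field("", 44))
        f.write(_field(str(n_records), 8))
        f.write(_field("1", 8))          # record duration, seconds
        f.write(_field(str(ns), 4))
        for lab in labels:
            f.write(_field(lab, 16))
        for _ in labels:
            f.write(_field("", 80))      # transducer
        for dim in physical_dims:
            f.write(_field(dim, 8))
        for v in phys_min:
            f.write(_field(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            f.write(_field(f"{v:.6g}"[:8], 8))
        for v in dig_min:
            f.write(_field(str(v), 8))
        for v in dig_max:
            f.write(_field(str(v), 8))
        for _ in labels:
            f.write(_field("", 80))      # prefiltering
        for _ in labels:
            f.write(_field(str(fs), 8))  # samples per record
        for _ in labels:
            f.write(_field("", 32))
        # data records: second r of every signal, interleaved
        block = np.empty((n_records, ns, fs), dtype="<i2")
        for j, d in enumerate(digital):
            block[:, j, :] = d.reshape(n_records, fs)
        f.write(block.tobytes())
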
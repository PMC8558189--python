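"""EDF (European Data Format) input and output.

Reading goes through :func:`mne.io.read_raw_edf`; raw channel labels are
mapped to canonical 10-20 names and non-EEG channels (annotations, ECG,
photic, ...) are dropped with a logged list.

Writing uses a small self-contained EDF writer (16-bit, one-second data
records) because no EDF-export library is bundled; the write→read round trip
against the mne reader is part of the test suite.  Physical units are
microvolts; quantisation error is bounded by the per-channel physical range
divided by 2^16.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .records import EEGRecord, canonical_channel_name

log = logging.getLogger(__name__)


def read_edf(path: str | Path, label: str = "control", device: str = "",
             subject_id: str | None = None) -> EEGRecord:
    """Read one subject's EDF/EDF+ file into an :class:`EEGRecord`.

    Channels whose label does not resolve to a canonical 10-20 electrode
    name are dropped (logged).  All retained channels must share one
    sampling rate (mne enforces this by resampling mismatched channels,
    which we reject by checking the header).
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    keep_idx: list[int] = []
    names: list[str] = []
    dropped: list[str] = []
    for i, ch in enumerate(raw.ch_names):
        canon = canonical_channel_name(ch)
        if canon is None or canon in names:
            dropped.append(ch)
        else:
            keep_idx.append(i)
            names.append(canon)
    if dropped:
        log.info("%s: dropped non-EEG/duplicate channels %s", path.name, dropped)
    if not names:
        raise ValueError(f"{path}: no recognizable EEG channels "
                         f"(labels were {raw.ch_names})")
    data_uv = raw.get_data(picks=keep_idx) * 1e6   # mne stores volts
    return EEGRecord(
        subject_id=subject_id or path.stem,
        signal=data_uv.T,
        fs=float(raw.info["sfreq"]),
        channel_names=names,
        label=label,
        device=device,
    )


def write_edf(path: str | Path, record: EEGRecord) -> None:
    """Write a record as a minimal 16-bit EDF file (1 s data records).

    Trailing samples that do not fill a whole data record are dropped.
    """
    path = Path(path)
    fs = record.fs
    if fs != int(fs) or fs <= 0:
        raise ValueError(f"EDF writer needs a positive integer sampling rate, got {fs}")
    spr = int(fs)                                  # samples per 1 s record
    n_rec = record.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    nch = record.n_channels
    data = record.signal[: n_rec * spr]

    def phys_str(v: float) -> str:
        # the scaling must use the value exactly as serialised in the
        # 8-char ASCII header field, or the round trip drifts
        for prec in range(7, 0, -1):
            s = f"{v:.{prec}g}"
            if len(s) <= 8:
                return s
        return f"{v:.0e}"

    raw_min = data.min(axis=0)
    raw_max = data.max(axis=0)
    raw_max = np.where(raw_max - raw_min == 0, raw_min + 1.0, raw_max)
    # widen slightly so 8-char ASCII rounding of the limits still brackets
    # the data (rounding is ~1e-6 relative, margin is 1e-4 of the span)
    margin = 1e-4 * (raw_max - raw_min)
    pmin_s = [phys_str(float(v)) for v in raw_min - margin]
    pmax_s = [phys_str(float(v)) for v in raw_max + margin]
    phys_min = np.array([float(s) for s in pmin_s])
    phys_max = np.array([float(s) for s in pmax_s])
    dig_min, dig_max = -32768, 32767

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * scale + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def f(x: object, width: int) -> bytes:
        s = f"{x}"
        if len(s) > width:
            s = s[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8),
        f(record.subject_id, 80),
        f(f"Startdate 01-JAN-2000 {record.device or 'X'}", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(256 * (1 + nch), 8),
        f("", 44),
        f(n_rec, 8),
        f(1, 8),                                   # record duration, s
        f(nch, 4),
    ])
    fields = [
        [f(ch, 16) for ch in record.channel_names],
        [f("AgAgCl electrode", 80)] * nch,
        [f("uV", 8) for _ in range(nch)],
        [f(pmin_s[j], 8) for j in range(nch)],
        [f(pmax_s[j], 8) for j in range(nch)],
        [f(dig_min, 8)] * nch,
        [f(dig_max, 8)] * nch,
        [f("", 80)] * nch,
        [f(spr, 8)] * nch,
        [f("", 32)] * nch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for col in fields:
            fh.write(b"".join(col))
        # data records: channel-sequential within each record
        for r in range(n_rec):
            block = digital[r * spr: (r + 1) * spr]    # (spr, nch)
            fh.write(block.T.tobytes())
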
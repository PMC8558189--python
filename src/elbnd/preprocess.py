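"""Preprocessing of raw resting-state EEG.

The pipeline applied to each record, in this fixed order:

1. drop technician-excluded spans (``apply_exclusions``),
2. downsample 256 Hz recordings to 128 Hz (``downsample_to_128``),
3. 50 Hz powerline notch (``notch_50hz``),
4. cut into non-overlapping 1000-sample segments — 7.8125 s at 128 Hz —
   with least-squares linear detrending per segment (``segment_1000``).

Segments never straddle an exclusion boundary: each segment is taken from one
contiguous retained span, so no fabricated discontinuity can enter a segment.
Amplitude normalisation (3-sigma z-scoring) happens later, in
:mod:`elbnd.adaptive`, per channel and per segment.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import signal as sps

from .records import EEGRecord, SegmentedRecord

TARGET_FS = 128.0
SEGMENT_LEN = 1000
NOTCH_HZ = 50.0
NOTCH_Q = 30.0


def downsample_to_128(record: EEGRecord) -> EEGRecord:
    """Bring a recording to the common 128 Hz rate.

    128 Hz input is returned unchanged; 256 Hz input is decimated by 2 using
    polyphase resampling with an anti-aliasing FIR low-pass (naive
    subsampling would alias 50-64 Hz content, including powerline residue).
    Any other rate is an error.
    """
    if record.fs == TARGET_FS:
        return record
    if record.fs != 2 * TARGET_FS:
        raise ValueError(
            f"unsupported sampling rate {record.fs} Hz for subject "
            f"{record.subject_id}; expected 128 or 256 Hz"
        )
    out = sps.resample_poly(record.signal, up=1, down=2, axis=0)
    out = out[: record.n_samples // 2]
    mask = None
    if record.exclusion_mask is not None:
        # a downsampled sample is excluded if either parent sample was
        m = record.exclusion_mask[: 2 * (record.n_samples // 2)]
        mask = m.reshape(-1, 2).any(axis=1)
    return replace(record, signal=out, fs=TARGET_FS, exclusion_mask=mask)


def linear_detrend(segment: np.ndarray) -> np.ndarray:
    """Subtract the least-squares best-fit line from each channel.

    The output has zero mean and zero least-squares slope per channel.
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim == 1:
        segment = segment[:, None]
        squeeze = True
    else:
        squeeze = False
    if segment.shape[0] < 2:
        raise ValueError("linear detrend needs at least 2 samples per channel")
    out = sps.detrend(segment, axis=0, type="linear")
    return out[:, 0] if squeeze else out


def notch_50hz(record: EEGRecord, notch_hz: float = NOTCH_HZ,
               q: float = NOTCH_Q) -> EEGRecord:
    """Suppress powerline interference with a second-order IIR notch.

    Requires fs > 2 * notch_hz (the notch frequency must be below Nyquist),
    so it is applied after downsampling to 128 Hz.
    """
    if record.fs <= 2 * notch_hz:
        raise ValueError(
            f"cannot notch {notch_hz} Hz at fs={record.fs} Hz "
            f"(need fs > {2 * notch_hz} Hz)"
        )
    b, a = sps.iirnotch(notch_hz, q, fs=record.fs)
    out = sps.filtfilt(b, a, record.signal, axis=0)
    return replace(record, signal=out)


def apply_exclusions(record: EEGRecord) -> tuple[EEGRecord, np.ndarray]:
    """Remove technician-excluded spans and concatenate the remainder.

    Returns the trimmed record (mask cleared) and an index map: element ``i``
    of the map is the original sample index of output sample ``i``.  Span
    boundaries are recorded so segmentation never crosses them (see
    ``retained_spans``).
    """
    if record.exclusion_mask is None:
        return record, np.arange(record.n_samples)
    keep = ~record.exclusion_mask
    index_map = np.flatnonzero(keep)
    out = replace(record, signal=record.signal[keep], exclusion_mask=None)
    return out, index_map


def retained_spans(mask: np.ndarray | None, n_samples: int) -> list[tuple[int, int]]:
    """Contiguous half-open [start, end) spans of retained samples."""
    if mask is None:
        return [(0, n_samples)] if n_samples else []
    keep = ~np.asarray(mask, dtype=bool)
    spans: list[tuple[int, int]] = []
    idx = np.flatnonzero(np.diff(np.concatenate(([False], keep, [False])).astype(int)))
    for start, end in idx.reshape(-1, 2):
        spans.append((int(start), int(end)))
    return spans


def segment_1000(record: EEGRecord, segment_len: int = SEGMENT_LEN,
                 detrend: bool = True) -> SegmentedRecord:
    """Cut a 128 Hz record into non-overlapping fixed-length segments.

    Each contiguous retained span contributes ``floor(len / segment_len)``
    segments; the trailing remainder of every span is discarded.  Each
    segment is linearly detrended per channel.
    """
    if record.fs != TARGET_FS:
        raise ValueError(f"segmentation expects fs={TARGET_FS} Hz, got {record.fs}")
    spans = retained_spans(record.exclusion_mask, record.n_samples)
    usable = sum(e - s for s, e in spans)
    if usable < segment_len:
        raise ValueError(
            f"subject {record.subject_id}: {usable} usable samples, "
            f"need at least {segment_len}"
        )
    segments: list[np.ndarray] = []
    starts: list[int] = []
    discarded = 0
    for s, e in spans:
        n_seg = (e - s) // segment_len
        discarded += (e - s) - n_seg * segment_len
        for j in range(n_seg):
            a = s + j * segment_len
            seg = record.signal[a: a + segment_len]
            segments.append(linear_detrend(seg) if detrend else seg.copy())
            starts.append(a)
    return SegmentedRecord(
        subject_id=record.subject_id,
        segments=segments,
        fs=record.fs,
        channel_names=list(record.channel_names),
        label=record.label,
        device=record.device,
        n_discarded_samples=discarded,
        segment_starts=starts,
    )


def preprocess_record(record: EEGRecord, segment_len: int = SEGMENT_LEN,
                      notch_hz: float = NOTCH_HZ, q: float = NOTCH_Q) -> SegmentedRecord:
    """Full preprocessing chain: exclusions handled span-wise, downsample,
    notch, segment + detrend."""
    rec = downsample_to_128(record)
    rec = notch_50hz(rec, notch_hz=notch_hz, q=q)
    return segment_1000(rec, segment_len=segment_len)
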
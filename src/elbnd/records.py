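"""Core in-memory containers for multichannel EEG recordings.

An :class:`EEGRecord` holds one subject's raw (or preprocessed) signal as a
``samples x channels`` float array in microvolts, together with the sampling
rate, 10-20 channel labels, diagnostic label and recording-device tag.  A
:class:`SegmentedRecord` holds the analysis-ready non-overlapping segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical 19-channel 10-20 montage order used throughout the package.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Recognised diagnostic labels. "control" is the negative class; AD and MCI
#: are the positive classes.
LABELS = ("control", "AD", "MCI")

# Case variants and common spelling aliases of 10-20 electrode names, mapped
# to the canonical capitalisation.  Modern equivalents of the legacy temporal
# names are included (T7->T3 etc. is NOT assumed; only spelling variants are).
_ALIAS = {name.upper(): name for name in CHANNELS_1020}
_ALIAS.update({
    "FPZ": "Fpz", "OZ": "Oz", "A1": "A1", "A2": "A2",
})


def canonical_channel_name(name: str) -> str | None:
    """Map a raw EDF channel label to its canonical 10-20 name.

    Strips common prefixes such as ``"EEG "`` and reference suffixes such as
    ``"-REF"`` or ``"-A1"`` before lookup.  Returns ``None`` when the label
    is not a recognised scalp electrode (e.g. ECG, annotations, photic).
    """
    s = name.strip()
    if s.upper().startswith("EEG"):
        s = s[3:].lstrip(" :")
    for sep in ("-", " "):
        if sep in s:
            s = s.split(sep, 1)[0]
    return _ALIAS.get(s.upper())


@dataclass
class EEGRecord:
    """One subject's multichannel EEG signal plus metadata."""

    subject_id: str
    signal: np.ndarray            # (n_samples, n_channels), microvolts
    fs: float                     # Hz
    channel_names: list[str]
    label: str = "control"
    device: str = ""
    exclusion_mask: np.ndarray | None = None   # bool, True = excluded sample

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (samples x channels) array")
        if len(self.channel_names) != self.signal.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[1]} signal columns"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if self.exclusion_mask is not None:
            self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
            if self.exclusion_mask.shape != (self.signal.shape[0],):
                raise ValueError(
                    f"exclusion mask length {self.exclusion_mask.shape[0]} "
                    f"!= sample count {self.signal.shape[0]}"
                )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    def is_positive(self) -> bool:
        return self.label in ("AD", "MCI")


@dataclass
class SegmentedRecord:
    """Non-overlapping fixed-length segments of one subject's recording.

    Each element of ``segments`` is a ``(segment_len, n_channels)`` array.
    Segments are in temporal order and never straddle an exclusion boundary.
    """

    subject_id: str
    segments: list[np.ndarray]
    fs: float
    channel_names: list[str]
    label: str = "control"
    device: str = ""
    n_discarded_samples: int = 0
    segment_starts: list[int] = field(default_factory=list)  # original sample index

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def segment_len(self) -> int:
        return self.segments[0].shape[0] if self.segments else 0

    def is_positive(self) -> bool:
        return self.label in ("AD", "MCI")
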
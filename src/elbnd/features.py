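"""Segment- and subject-level novelty descriptors.

Each 1000-sample segment is annotated with a single value per channel: the
standard deviation of the scalar ELBND novelty series over the segment's
valid samples (the 1000 - n samples with a full input history).  High
dispersion of the novelty coefficients means the adaptive predictor was
repeatedly surprised — the diagnostic signature of less predictable EEG
dynamics.  Subject-level features average the segment descriptors per
channel; cohort tables summarise subjects as mean +/- std per channel per
group.

Population standard deviations (divide by N) are used throughout, matching
the z-scoring convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adaptive import LNUConfig, NoveltySeries, novelty_by_segment
from .records import SegmentedRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentDescriptor:
    subject_id: str
    segment_index: int
    channel: str
    value: float


@dataclass
class SubjectFeatures:
    """One scalar novelty descriptor per channel for one subject."""

    subject_id: str
    label: str
    device: str
    per_channel: dict[str, float] = field(default_factory=dict)

    def is_positive(self) -> bool:
        return self.label in ("AD", "MCI")


def segment_descriptor(novelty: NoveltySeries) -> float:
    """Population std of the scalar novelty series over valid samples."""
    vals = novelty.valid
    if vals.size < 2:
        raise ValueError(
            f"segment has {vals.size} valid novelty samples; need at least 2"
        )
    return float(np.std(vals))


def subject_descriptors(seg_record: SegmentedRecord, cfg: LNUConfig | None = None
                        ) -> list[SegmentDescriptor]:
    """Segment descriptors for all channels and segments of one subject."""
    novelty = novelty_by_segment(seg_record, cfg)
    out = []
    for ch, series in novelty.items():
        for idx, nov in enumerate(series):
            out.append(SegmentDescriptor(
                subject_id=seg_record.subject_id, segment_index=idx,
                channel=ch, value=segment_descriptor(nov),
            ))
    return out


def aggregate_subject(descriptors: list[SegmentDescriptor], label: str,
                      device: str = "", reduction: str = "mean") -> SubjectFeatures:
    """Collapse a subject's segment descriptors to one value per channel.

    ``reduction``: ``"mean"`` (default) or ``"median"``.
    """
    if not descriptors:
        raise ValueError("no segment descriptors to aggregate")
    if reduction not in ("mean", "median"):
        raise ValueError(f"reduction must be 'mean' or 'median', got {reduction!r}")
    subject_ids = {d.subject_id for d in descriptors}
    if len(subject_ids) != 1:
        raise ValueError(f"descriptors span multiple subjects: {sorted(subject_ids)}")
    by_channel: dict[str, list[float]] = {}
    for d in descriptors:
        by_channel.setdefault(d.channel, []).append(d.value)
    reduce = np.mean if reduction == "mean" else np.median
    per_channel = {ch: float(reduce(vals)) for ch, vals in by_channel.items()}
    return SubjectFeatures(subject_id=subject_ids.pop(), label=label,
                           device=device, per_channel=per_channel)


def extract_features(seg_record: SegmentedRecord, cfg: LNUConfig | None = None,
                     reduction: str = "mean") -> SubjectFeatures:
    """Full novelty feature extraction for one preprocessed subject."""
    descs = subject_descriptors(seg_record, cfg)
    return aggregate_subject(descs, label=seg_record.label,
                             device=seg_record.device, reduction=reduction)


def features_frame(features: list[SubjectFeatures]) -> pd.DataFrame:
    """Subjects x channels feature table with label and device columns."""
    rows = []
    for f in features:
        row = {"subject_id": f.subject_id, "label": f.label, "device": f.device}
        row.update(f.per_channel)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def cohort_table(features: list[SubjectFeatures], group_by: str = "label"
                 ) -> pd.DataFrame:
    """Mean +/- population std per channel per group.

    ``group_by`` is ``"label"`` or ``"device"``.  Rows are channels, and each
    group contributes a ``(group, "mean")`` and a ``(group, "std")`` column.
    A group with fewer than 2 subjects gets NaN std and a warning.
    """
    if group_by not in ("label", "device"):
        raise ValueError(f"group_by must be 'label' or 'device', got {group_by!r}")
    df = features_frame(features)
    channels = [c for c in df.columns if c not in ("label", "device")]
    groups = sorted(df[group_by].unique())
    cols: dict[tuple[str, str], list[float]] = {}
    for g in groups:
        sub = df.loc[df[group_by] == g, channels].to_numpy(dtype=float)
        if sub.shape[0] < 2:
            warnings.warn(
                f"group {g!r} has {sub.shape[0]} subject(s); std not available",
                stacklevel=2,
            )
            sd = np.full(len(channels), np.nan)
        else:
            sd = sub.std(axis=0)  # population std
        cols[(g, "mean")] = sub.mean(axis=0)
        cols[(g, "std")] = sd
    out = pd.DataFrame(cols, index=pd.Index(channels, name="channel"))
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=[group_by, "stat"])
    return out
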
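"""Cohort manifests and the end-to-end pipeline.

A manifest is a JSON file listing, per subject: id, signal path (EDF or
CSV), diagnostic label, device tag, sampling rate and channel count.  The
pipeline reads every subject, preprocesses (exclusions, downsampling to
128 Hz, 50 Hz notch, 1000-sample segmentation with per-segment detrend),
extracts novelty descriptors, and writes feature and cross-validation CSVs.

All sample indices are 0-based; exclusion intervals are half-open
``[start, end)``.  Output is a pure function of the input files, the
configuration and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, features, preprocess
from .adaptive import LNUConfig
from .edf import read_edf
from .records import EEGRecord

log = logging.getLogger(__name__)

PIPELINE_VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Run-level knobs; defaults reproduce the standard analysis chain."""

    target_fs: float = 128.0
    segment_len: int = 1000
    notch_hz: float = 50.0
    notch_q: float = 30.0
    n: int = 6
    mu: float = 1.0
    eps: float = 1.0
    reduction: str = "max"            # novelty vector -> scalar
    reset_per_segment: bool = True
    subject_reduction: str = "mean"   # segments -> subject
    cv_p: int = 3
    contrast: str = "normal_vs_positives"

    def lnu(self) -> LNUConfig:
        return LNUConfig(n=self.n, mu=self.mu, eps=self.eps,
                         reduction=self.reduction,
                         reset_per_segment=self.reset_per_segment)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ManifestEntry:
    subject_id: str
    path: str
    label: str
    device: str = ""
    fs: float | None = None
    n_channels: int | None = None
    mask_path: str | None = None


@dataclass
class Manifest:
    entries: list[ManifestEntry] = field(default_factory=list)
    version: str = PIPELINE_VERSION

    def __post_init__(self) -> None:
        ids = [e.subject_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids in manifest")

    @classmethod
    def load(cls, path: str | Path) -> "Manifest":
        obj = json.loads(Path(path).read_text())
        entries = [ManifestEntry(**e) for e in obj["subjects"]]
        return cls(entries=entries, version=obj.get("version", PIPELINE_VERSION))

    def save(self, path: str | Path) -> None:
        obj = {"version": self.version, "subjects": [asdict(e) for e in self.entries]}
        Path(path).write_text(json.dumps(obj, indent=2))


def read_mask_csv(path: str | Path, n_samples: int) -> np.ndarray:
    """Exclusion intervals CSV (start_sample,end_sample; half-open, 0-based)
    to a boolean per-sample mask."""
    df = pd.read_csv(path)
    mask = np.zeros(n_samples, dtype=bool)
    for _, row in df.iterrows():
        s, e = int(row.iloc[0]), int(row.iloc[1])
        if not 0 <= s <= e <= n_samples:
            raise ValueError(f"exclusion interval [{s}, {e}) out of range "
                             f"for {n_samples} samples")
        mask[s:e] = True
    return mask


def read_csv_record(path: str | Path, fs: float, label: str = "control",
                    device: str = "", subject_id: str | None = None) -> EEGRecord:
    """CSV with a header row of channel names, one row per sample (uV)."""
    df = pd.read_csv(path)
    return EEGRecord(
        subject_id=subject_id or Path(path).stem,
        signal=df.to_numpy(dtype=float),
        fs=fs,
        channel_names=list(df.columns),
        label=label,
        device=device,
    )


def load_record(entry: ManifestEntry, base_dir: str | Path = ".") -> EEGRecord:
    base = Path(base_dir)
    p = base / entry.path
    if not p.exists():
        raise FileNotFoundError(f"subject {entry.subject_id}: {p} does not exist")
    if p.suffix.lower() == ".edf":
        rec = read_edf(p, label=entry.label, device=entry.device,
                       subject_id=entry.subject_id)
    elif p.suffix.lower() == ".csv":
        if entry.fs is None:
            raise ValueError(f"subject {entry.subject_id}: CSV input needs "
                             f"an explicit fs in the manifest")
        rec = read_csv_record(p, fs=entry.fs, label=entry.label,
                              device=entry.device, subject_id=entry.subject_id)
    else:
        raise ValueError(f"unsupported signal format {p.suffix!r}")
    if entry.mask_path:
        rec.exclusion_mask = read_mask_csv(base / entry.mask_path, rec.n_samples)
    return rec


def run_pipeline(manifest: Manifest, out_dir: str | Path,
                 config: PipelineConfig | None = None,
                 base_dir: str | Path = ".") -> dict:
    """Read → preprocess → extract → cross-validate; write all products.

    Writes ``features.csv`` (subjects x channels), ``cohort_table.csv``
    (mean ± std per channel per label group), ``cv_report.csv`` and a
    machine-readable ``run_summary.json`` under ``out_dir``.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lnu = config.lnu()

    feats = []
    counts = {"subjects": 0, "segments": 0, "discarded_samples": 0}
    for entry in manifest.entries:
        try:
            rec = load_record(entry, base_dir)
            seg = preprocess.preprocess_record(
                rec, segment_len=config.segment_len,
                notch_hz=config.notch_hz, q=config.notch_q)
            feats.append(features.extract_features(
                seg, lnu, reduction=config.subject_reduction))
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for subject {entry.subject_id}: {exc}"
            ) from exc
        counts["subjects"] += 1
        counts["segments"] += seg.n_segments
        counts["discarded_samples"] += seg.n_discarded_samples
        log.info("subject %s: %d segments (%d samples discarded)",
                 entry.subject_id, seg.n_segments, seg.n_discarded_samples)

    fdf = features.features_frame(feats)
    fdf.to_csv(out / "features.csv")
    features.cohort_table(feats, group_by="label").to_csv(out / "cohort_table.csv")

    reports = classify.evaluate_all_channels(feats, p=config.cv_p,
                                             contrast=config.contrast)
    rdf = classify.cv_report_frame(reports)
    rdf.to_csv(out / "cv_report.csv", index=False)

    summary = {
        "version": PIPELINE_VERSION,
        "config_hash": config.hash(),
        "config": asdict(config),
        "counts": counts,
        "n_folds": {r.channel: r.n_folds for r in reports},
        "skipped_folds": {r.channel: r.n_skipped for r in reports},
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return {"features": fdf, "cv": rdf, "summary": summary}
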
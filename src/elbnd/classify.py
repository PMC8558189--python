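"""Midpoint-threshold classification, exhaustive leave-p-out CV, and the
delta/theta band-power group comparison.

The classifier is deliberately minimal: the decision criterion for a channel
is placed exactly halfway between the training means of the negative
(control) and positive (AD/MCI) groups, and a subject is called positive iff
its novelty descriptor is strictly greater than the criterion.  Validation
is exhaustive leave-p-out (default p = 3): every one of the C(N, p) held-out
subject combinations is tested against a model fitted on the remaining
N - p subjects, and sensitivity / specificity / accuracy are computed over
the pooled test predictions.

The exhaustive CV is exact but cheap: per-fold class means are obtained from
cached class sums by subtracting the held-out subjects, so all C(168, 3) =
774,916 folds of a full-size cohort run in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import SubjectFeatures, features_frame
from .records import EEGRecord

log = logging.getLogger(__name__)

#: CV contrasts: which labels form the positive class (controls always negative).
CONTRASTS = {
    "normal_vs_AD": ("AD",),
    "normal_vs_MCI": ("MCI",),
    "normal_vs_positives": ("AD", "MCI"),
}

BANDS = {"delta": (2.0, 4.0), "theta": (4.0, 8.0)}


@dataclass(frozen=True)
class ThresholdModel:
    channel: str
    mean_negative: float
    mean_positive: float

    @property
    def criterion(self) -> float:
        return 0.5 * (self.mean_negative + self.mean_positive)


@dataclass(frozen=True)
class CVReport:
    channel: str
    sensitivity: float   # percent
    specificity: float   # percent
    accuracy: float      # percent
    n_folds: int
    n_skipped: int
    contrast: str


def fit_threshold(values: np.ndarray, is_positive: np.ndarray,
                  channel: str = "?") -> ThresholdModel:
    """Fit the midpoint criterion from training descriptors and labels."""
    values = np.asarray(values, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    if values.shape != is_positive.shape:
        raise ValueError("values and labels must have matching shapes")
    n_pos = int(is_positive.sum())
    if n_pos == 0 or n_pos == values.size:
        raise ValueError(
            f"channel {channel}: training set must contain both classes"
        )
    return ThresholdModel(
        channel=channel,
        mean_negative=float(values[~is_positive].mean()),
        mean_positive=float(values[is_positive].mean()),
    )


def predict(model: ThresholdModel, value: float) -> bool:
    """True (positive) iff the descriptor is strictly above the criterion."""
    if not np.isfinite(value):
        raise ValueError(f"non-finite descriptor value {value!r}")
    return value > model.criterion


def leave_p_out_cv(values: np.ndarray, is_positive: np.ndarray, p: int = 3,
                   channel: str = "?", contrast: str = "normal_vs_positives"
                   ) -> CVReport:
    """Exhaustive leave-p-out cross-validation of the midpoint classifier.

    For every combination of ``p`` held-out subjects, the criterion is
    fitted on the remainder and the held-out subjects are classified; the
    pooled predictions over all folds give the metrics (in percent).  Folds
    whose training set lacks a class are skipped and counted.
    """
    values = np.asarray(values, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    n = values.size
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    if p >= n:
        raise ValueError(f"p={p} must be smaller than cohort size N={n}")
    n_pos = int(is_positive.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("cohort must contain both classes")

    combos = np.fromiter(
        (i for c in combinations(range(n), p) for i in c), dtype=np.int64,
    ).reshape(-1, p)
    held_vals = values[combos]                       # (n_folds, p)
    held_pos = is_positive[combos]                   # (n_folds, p)

    sum_pos = float(values[is_positive].sum())
    sum_neg = float(values[~is_positive].sum())
    held_pos_sum = np.where(held_pos, held_vals, 0.0).sum(axis=1)
    held_pos_cnt = held_pos.sum(axis=1)
    train_pos_cnt = n_pos - held_pos_cnt
    train_neg_cnt = n_neg - (p - held_pos_cnt)
    valid = (train_pos_cnt > 0) & (train_neg_cnt > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_pos = (sum_pos - held_pos_sum) / train_pos_cnt
        mean_neg = (sum_neg - (held_vals.sum(axis=1) - held_pos_sum)) / train_neg_cnt
    criterion = 0.5 * (mean_pos + mean_neg)

    pred_pos = held_vals > criterion[:, None]
    v = valid[:, None] & np.ones_like(pred_pos, dtype=bool)
    tp = int(np.count_nonzero(pred_pos & held_pos & v))
    fn = int(np.count_nonzero(~pred_pos & held_pos & v))
    tn = int(np.count_nonzero(~pred_pos & ~held_pos & v))
    fp = int(np.count_nonzero(pred_pos & ~held_pos & v))

    n_folds = int(valid.sum())
    n_skipped = combos.shape[0] - n_folds
    if n_skipped:
        log.warning("channel %s: skipped %d/%d folds with a single-class "
                    "training set", channel, n_skipped, combos.shape[0])
    assert n_folds + n_skipped == comb(n, p)

    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    return CVReport(channel=channel, sensitivity=sens, specificity=spec,
                    accuracy=acc, n_folds=n_folds, n_skipped=n_skipped,
                    contrast=contrast)


def _contrast_subset(features: list[SubjectFeatures], contrast: str
                     ) -> list[SubjectFeatures]:
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of "
                         f"{sorted(CONTRASTS)}")
    keep = ("control",) + CONTRASTS[contrast]
    return [f for f in features if f.label in keep]


def evaluate_all_channels(features: list[SubjectFeatures], p: int = 3,
                          contrast: str = "normal_vs_positives",
                          channels: list[str] | None = None) -> list[CVReport]:
    """Leave-p-out CV independently for every channel."""
    subset = _contrast_subset(features, contrast)
    df = features_frame(subset)
    is_positive = df["label"].isin(CONTRASTS[contrast]).to_numpy()
    if channels is None:
        channels = [c for c in df.columns if c not in ("label", "device")]
    return [
        leave_p_out_cv(df[ch].to_numpy(dtype=float), is_positive, p=p,
                       channel=ch, contrast=contrast)
        for ch in channels
    ]


def cv_report_frame(reports: list[CVReport]) -> pd.DataFrame:
    """CV reports as a table with percent metrics rounded to 2 decimals."""
    return pd.DataFrame([
        {"Channel": r.channel,
         "Sensitivity": round(r.sensitivity, 2),
         "Specificity": round(r.specificity, 2),
         "Accuracy": round(r.accuracy, 2),
         "n_folds": r.n_folds}
        for r in reports
    ])


def band_power(record: EEGRecord, bands: dict[str, tuple[float, float]] = BANDS,
               nperseg: int = 512) -> dict[tuple[str, str], float]:
    """Mean Welch-PSD power per channel per band for one subject."""
    nperseg = min(nperseg, record.n_samples)
    freqs, psd = sps.welch(record.signal, fs=record.fs, nperseg=nperseg, axis=0)
    out = {}
    for band, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs < hi)
        for j, ch in enumerate(record.channel_names):
            out[(ch, band)] = float(psd[sel, j].mean())
    return out


def band_power_test(group_a: list[EEGRecord], group_b: list[EEGRecord],
                    bands: dict[str, tuple[float, float]] = BANDS,
                    q: float = 0.05, nperseg: int = 512) -> pd.DataFrame:
    """Two-sample t-test of Welch band power between two subject groups.

    Per channel and band, subject-level mean band powers are compared with a
    two-sample t-test; Benjamini-Hochberg FDR at ``q`` is applied jointly
    across all channel x band hypotheses.  Cells with degenerate (zero)
    variance in both groups are flagged and excluded from the FDR family.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    pa = [band_power(r, bands, nperseg) for r in group_a]
    pb = [band_power(r, bands, nperseg) for r in group_b]
    cells = sorted(pa[0].keys())
    rows = []
    for ch, band in cells:
        a = np.array([d[(ch, band)] for d in pa])
        b = np.array([d[(ch, band)] for d in pb])
        if a.std() == 0.0 and b.std() == 0.0:
            rows.append({"channel": ch, "band": band, "mean_a": a.mean(),
                         "mean_b": b.mean(), "p_value": np.nan,
                         "degenerate": True})
            continue
        t, pval = stats.ttest_ind(a, b)
        rows.append({"channel": ch, "band": band, "mean_a": a.mean(),
                     "mean_b": b.mean(), "p_value": float(pval),
                     "degenerate": False})
    df = pd.DataFrame(rows)
    df["reject"] = False
    ok = ~df["degenerate"]
    if ok.any():
        reject, _, _, _ = multipletests(df.loc[ok, "p_value"], alpha=q,
                                        method="fdr_bh")
        df.loc[ok, "reject"] = reject
    return df
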
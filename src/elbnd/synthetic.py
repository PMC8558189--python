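"""Synthetic resting-state EEG cohorts with controllable group structure.

No clinical recordings ship with this package, so every pipeline stage is
exercised on simulated cohorts that emulate the salient properties of
resting EEG:

* a band-limited rhythmic background per channel — a stationary AR(2)
  process resonant near 10 Hz (the posterior alpha rhythm), driven by
  unit-variance Gaussian innovations;
* an additional *white innovation component* whose standard deviation is the
  group's unpredictability knob: controls receive ``innovation_sd_negative``,
  positives ``innovation_sd_positive``.  Because each channel segment is
  3-sigma z-scored before adaptive filtering, uniformly scaling the whole
  process cannot change the novelty descriptor; what raises ELBND dispersion
  is the *fraction* of the signal that is unpredictable, which is exactly
  what this component controls (positives > negatives plants the clinical
  direction: less predictable dynamics in AD/MCI);
* optionally, slow random wandering of the AR coefficient vector
  (``ar_wander_sd``) as a second, non-stationarity-based mechanism;
* per-subject heterogeneity: each subject's white-innovation scale is
  jittered log-normally (``between_subject_sd``) so cohorts overlap the way
  real clinical groups do;
* measurement nuisances removed by preprocessing: linear drift, 50 Hz
  powerline contamination, and Poisson-timed transient amplitude events;
* two-machine emulation: a "256 Hz device" records the *same* 128 Hz latent
  process polyphase-upsampled by 2, so device tags never alter the process
  parameters — only the sampling chain.

Generation is a pure function of the spec and seed: per-subject RNG streams
are derived from the master seed and the subject index, so extending a
cohort never perturbs existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import CHANNELS_1020, EEGRecord

#: AR(2) resonant near 10 Hz at fs=128: complex roots at radius 0.9.
_THETA = 2.0 * np.pi * 10.0 / 128.0
DEFAULT_AR = (2 * 0.9 * np.cos(_THETA), -0.81)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort.

    Durations default to 120 s (15-16 analysis segments per subject), long
    enough for stable subject descriptors while keeping simulation studies
    desk-scale; clinical resting recordings are typically 15 min
    (``duration_s=900``).
    """

    n_negative: int = 10
    n_positive: int = 10
    n_mci: int = 0                      # subset of positives labelled MCI
    n_channels: int = 19
    fs: float = 128.0                   # 128 or 256 (256 = upsampled device)
    duration_s: float = 120.0
    ar_coeffs: tuple[float, ...] = DEFAULT_AR
    innovation_sd_negative: float = 0.3
    innovation_sd_positive: float = 0.6
    between_subject_sd: float = 0.2     # lognormal sd of per-subject scale
    ar_wander_sd: float = 0.0           # random-walk sd of AR coeffs per sample
    drift_slope: float = 2.0            # uV per second
    mains_amplitude: float = 2.0        # uV, 50 Hz
    event_rate: float = 0.0             # transient events per second
    event_amplitude: float = 5.0        # in units of the background sd
    amplitude_uv: float = 20.0          # overall scale of the neural signal
    device: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_negative < 1 or self.n_positive < 0:
            raise ValueError("need at least one negative subject and n_positive >= 0")
        if not 0 <= self.n_mci <= self.n_positive:
            raise ValueError("n_mci must lie within n_positive")
        if self.fs not in (128.0, 256.0):
            raise ValueError(f"fs must be 128 or 256 Hz, got {self.fs}")
        roots = np.roots(np.concatenate(([1.0], -np.asarray(self.ar_coeffs))))
        if np.any(np.abs(roots) >= 1.0):
            raise ValueError(
                f"unstable AR coefficients {self.ar_coeffs}: root magnitudes "
                f"{np.abs(roots)} must be < 1"
            )

    @property
    def n_subjects(self) -> int:
        return self.n_negative + self.n_positive

    @property
    def n_samples_128(self) -> int:
        return int(round(self.duration_s * 128.0))

    def label_of(self, i: int) -> str:
        if i < self.n_negative:
            return "control"
        if i < self.n_subjects - self.n_mci:
            return "AD"
        return "MCI"


def ar_theoretical_variance(ar_coeffs: tuple[float, ...], innovation_var: float = 1.0
                            ) -> float:
    """Closed-form stationary variance of an AR(1) or AR(2) process."""
    a = tuple(ar_coeffs)
    if len(a) == 1:
        return innovation_var / (1.0 - a[0] ** 2)
    if len(a) == 2:
        a1, a2 = a
        return innovation_var * (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1 ** 2))
    raise ValueError("closed form implemented for AR(1) and AR(2) only")


def ar_theoretical_acf1(ar_coeffs: tuple[float, ...]) -> float:
    """Closed-form lag-1 autocorrelation of an AR(1)/AR(2) process."""
    a = tuple(ar_coeffs)
    if len(a) == 1:
        return a[0]
    if len(a) == 2:
        return a[0] / (1.0 - a[1])
    raise ValueError("closed form implemented for AR(1) and AR(2) only")


def _event_rng(spec: CohortSpec, subject: int) -> np.random.Generator:
    # dedicated stream so ground_truth() can re-derive event times exactly
    return np.random.default_rng([spec.seed % (2 ** 31), subject, 17])


def _signal_rng(spec: CohortSpec, subject: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed % (2 ** 31), subject, 29])


def _draw_events(spec: CohortSpec, subject: int) -> dict[str, np.ndarray]:
    """Poisson-timed event sample indices (at 128 Hz) per channel."""
    rng = _event_rng(spec, subject)
    names = _channel_names(spec)
    n = spec.n_samples_128
    out = {}
    for ch in names:
        n_events = rng.poisson(spec.event_rate * spec.duration_s)
        # keep events away from segment-start warm-up regions is NOT done:
        # localisation tests must face realistic placement
        out[ch] = np.sort(rng.integers(10, max(11, n - 10), size=n_events))
    return out


def _channel_names(spec: CohortSpec) -> list[str]:
    if spec.n_channels <= len(CHANNELS_1020):
        return list(CHANNELS_1020[: spec.n_channels])
    extra = [f"X{i}" for i in range(spec.n_channels - len(CHANNELS_1020))]
    return list(CHANNELS_1020) + extra


def _ar_background(rng: np.random.Generator, a: np.ndarray, n: int,
                   wander_sd: float) -> np.ndarray:
    innov = rng.standard_normal(n + 500)          # 500-sample burn-in
    if wander_sd == 0.0:
        x = sps.lfilter([1.0], np.concatenate(([1.0], -a)), innov)
    else:
        # slow random walk on the coefficients, reflected into the stable
        # triangle for AR(2) by clipping the root radius
        p = len(a)
        x = np.zeros(n + 500)
        coeffs = a.copy()
        for k in range(n + 500):
            if k >= p:
                x[k] = float(coeffs @ x[k - p: k][::-1]) + innov[k]
            else:
                x[k] = innov[k]
            coeffs = coeffs + wander_sd * rng.standard_normal(p)
            coeffs = np.clip(coeffs, -1.9, 1.9)
            if p == 2:
                coeffs[1] = np.clip(coeffs[1], -0.98, 0.98)
    return x[500:]


def _subject_signal(spec: CohortSpec, subject: int) -> np.ndarray:
    """Latent 128 Hz multichannel signal (no drift/mains), in microvolts."""
    rng = _signal_rng(spec, subject)
    events = _draw_events(spec, subject)
    names = _channel_names(spec)
    n = spec.n_samples_128
    a = np.asarray(spec.ar_coeffs, dtype=float)
    positive = spec.label_of(subject) != "control"
    base_w = spec.innovation_sd_positive if positive else spec.innovation_sd_negative
    # per-subject heterogeneity of the unpredictability scale
    w = base_w * float(np.exp(spec.between_subject_sd * rng.standard_normal()))
    bg_sd = np.sqrt(ar_theoretical_variance(tuple(a)))
    sig = np.empty((n, len(names)))
    for j, ch in enumerate(names):
        colored = _ar_background(rng, a, n, spec.ar_wander_sd)
        white = w * rng.standard_normal(n)
        x = colored + white
        for k0 in events[ch]:
            x[k0] += spec.event_amplitude * bg_sd
        sig[:, j] = x / bg_sd * spec.amplitude_uv
    return sig


def generate_cohort(spec: CohortSpec) -> list[EEGRecord]:
    """Generate a full labelled cohort deterministically from the spec."""
    records = []
    names = _channel_names(spec)
    for i in range(spec.n_subjects):
        sig = _subject_signal(spec, i)
        if spec.fs == 256.0:
            sig = sps.resample_poly(sig, up=2, down=1, axis=0)
        n = sig.shape[0]
        t = np.arange(n) / spec.fs
        sig = sig + (spec.drift_slope * t
                     + spec.mains_amplitude * np.sin(2 * np.pi * 50.0 * t))[:, None]
        records.append(EEGRecord(
            subject_id=f"S{i:03d}", signal=sig, fs=spec.fs,
            channel_names=list(names), label=spec.label_of(i),
            device=spec.device,
        ))
    return records


def ground_truth(spec: CohortSpec) -> dict:
    """Planted event times and group parameters for recovery experiments.

    Event indices are given at the record's own sampling rate (doubled when
    the device records at 256 Hz).
    """
    scale = 2 if spec.fs == 256.0 else 1
    events = {
        f"S{i:03d}": {ch: idx * scale for ch, idx in _draw_events(spec, i).items()}
        for i in range(spec.n_subjects)
    }
    return {
        "events": events,
        "labels": {f"S{i:03d}": spec.label_of(i) for i in range(spec.n_subjects)},
        "innovation_sd": {
            "negative": spec.innovation_sd_negative,
            "positive": spec.innovation_sd_positive,
        },
        "ar_coeffs": tuple(spec.ar_coeffs),
    }
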
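# Methods

This note documents the model, the parameter choices that matter, what the
synthetic cohorts do and do not emulate, and the numerical decisions made
where the design was genuinely open.

## The predictor and the novelty statistic

The core object is a linear neural unit (LNU): a linear predictor
`y(k) = w(k)·x(k)` over a constant bias input (1) and the last n = 6
samples of one EEG channel. Adaptation is stochastic online gradient
descent on the squared prediction error with a per-sample normalized step —
the normalized least-mean-squares (NLMS) rule `η(k) = μ/(1 + x(k)ᵀx(k))`.
Six taps capture the short-range autocorrelation of resting EEG at 128 Hz
(≈47 ms of history); longer histories add computation without changing the
novelty feature appreciably.

The novelty coefficient vector `c(k) = |e(k)·Δw(k)|` multiplies the two
quantities an adaptive filter exposes about the unexpectedness of a sample:
the prediction error and the weight correction it forced. Algebraically
`c(k) = |e(k)²·x(k)·η(k)|`, so with the regularized normalization
`η = μ/(ε + xᵀx)` and ε = 1 the two published forms of the statistic are
the same expression; the implementation computes it from `e·Δw` and the
test suite verifies the expanded form agrees to 1e-12 relative. The vector
is reduced to a scalar by its maximum component (the weight increments are
strongly correlated across taps, so the maximum loses little information;
the mean is available as a config option). A segment is then described by
the **population standard deviation of the scalar novelty series** over its
valid samples — dispersion, not level, because a uniformly high but steady
novelty floor is indistinguishable from noise scale after normalization,
whereas bursty, irregular novelty is what distinguishes poorly predictable
dynamics.

Key defaults (all in `LNUConfig` / `PipelineConfig`):

| parameter | default | meaning / rationale |
|---|---|---|
| n | 6 | history taps; 47 ms at 128 Hz |
| μ | 1.0 | base learning rate; safe because inputs are 3σ-normalized and the step is NLMS-normalized (stable for μ ∈ (0, 2]) |
| ε | 1.0 | normalization regularizer; identical to the bias² term, so both published denominators coincide |
| bias | 1.0 | constant input element |
| reduction | max | c-vector → scalar |
| segment_len | 1000 | 7.8125 s at 128 Hz |
| notch | 50 Hz, Q = 30 | second-order IIR, zero-phase (filtfilt) |

## Normalization and processing order

Each channel of each 1000-sample segment is independently z-scored with a
3σ denominator: `(y − mean)/(3·std)`, population std. This confines nearly
all samples of an approximately Gaussian signal to [−1, 1], which together
with NLMS keeps the weight recursion stable at μ near 1. Per-segment (not
per-record) scoping matches per-segment detrending and makes segment
descriptors exchangeable. A constant segment (zero variance) is an error
naming the channel, not a silent NaN.

Fixed processing order: technician exclusions → downsample → notch →
segmentation → per-segment detrend → per-segment z-score. Exclusions are
honored by segmenting each contiguous retained span separately, so no
segment ever straddles an excision boundary and no fabricated discontinuity
enters the filter. Downsampling 256→128 Hz uses polyphase decimation with
an anti-aliasing FIR (naive subsampling would alias 50–64 Hz content,
including powerline residue). Weights start at zero — the first prediction
is 0 and the first error equals the signal, the convention of stochastic
online back-propagation — and the filter state is **reset at every segment
boundary** (`reset_per_segment`), keeping segment descriptors independent
and the cross-validation honest. The first n samples of each segment carry
no novelty value (no full history; nothing is padded).

## Classification and validation

Subject features are per-channel means of segment descriptors (median
available). The classifier per channel is deliberately minimal: the
criterion sits exactly halfway between the training means of controls and
positives, and a subject is positive iff its descriptor is *strictly*
greater (a tie classifies negative). Validation is exhaustive leave-p-out
(p = 3): all C(N, p) held-out combinations are evaluated and sensitivity,
specificity and accuracy are computed over the **pooled** test predictions
(every test occurrence counts; pooling rather than per-fold averaging is a
design choice and is what the fold-level oracle in the tests checks).
Folds whose training set loses a class entirely — possible only in tiny
cohorts — are skipped and counted. Per-fold class means are derived from
cached class sums by subtracting the held-out subjects, which is exact and
makes the full C(168,3) = 776,216-fold evaluation of a 168-subject cohort
run in seconds.

The band-power comparison computes each subject's mean Welch-PSD power in
the delta (2–4 Hz) and theta (4–8 Hz) bands per channel, applies a
two-sample t-test per channel × band, and controls the false discovery
rate with Benjamini–Hochberg at q = 0.05 jointly across all channel × band
hypotheses (one family). Cells with zero variance in both groups are
flagged and excluded from the family rather than tested.

## Synthetic cohorts

The generator emulates the signal properties the pipeline must cope with,
per subject and channel, at 128 Hz:

* a stationary AR(2) background resonant near 10 Hz (posterior alpha
  rhythm), unit-variance innovations, normalized to an overall scale of
  20 µV;
* a **white innovation component** whose standard deviation (relative to
  the unit-sd background) is the group's unpredictability knob — controls
  0.3, positives 0.6 by default. Because every segment is z-scored,
  uniformly rescaling a fixed-AR process cannot change the novelty
  descriptor; what raises ELBND dispersion is the *fraction* of signal
  variance that is unpredictable, which is exactly what this component
  controls. Positives > controls plants the clinically observed direction
  (higher novelty in AD/MCI). Slow random wandering of the AR coefficients
  is available as a second, non-stationarity-based mechanism
  (`ar_wander_sd`, off by default);
* log-normal between-subject jitter of the unpredictability scale
  (sd 0.2), matching the ~20% between-subject coefficient of variation
  seen in clinical descriptor tables, so synthetic groups overlap the way
  real ones do;
* nuisances removed by preprocessing: linear drift (2 µV/s), 50 Hz mains
  (2 µV), and Poisson-timed single-sample transients at 5× the background
  sd (`event_rate`, off by default) whose exact indices are exposed by
  `ground_truth()` for localization experiments;
* two-machine emulation: the "256 Hz device" records the *same* 128 Hz
  latent process polyphase-upsampled by two, so device tags never alter
  process parameters and a descriptor difference between devices can only
  come from the sampling/processing chain — the device-invariance check
  isolates exactly that effect.

Default recordings are 120 s (15 analysis segments), long enough for
stable subject descriptors while keeping simulation studies desk-scale;
clinical resting recordings are typically 15 min (`duration_s=900`, or
`--clinical-scale` on the CLI). Generation is a pure function of (spec, seed)
with one RNG stream per subject, so extending a cohort never perturbs
existing subjects.

What the generator does **not** emulate: biophysical volume conduction and
inter-channel correlation (channels are independent), realistic ocular or
myogenic artifacts, age or medication covariates, and any MCI-specific
generative structure beyond a second effect-size level. Passing tests
therefore demonstrate that the pipeline recovers planted unpredictability
differences under realistic noise, drift, mains and sampling conditions —
not that it diagnoses clinical dementia; clinical performance can only be
established on clinical data.

## Numerical choices and edge cases

* Population standard deviation (divide by N) everywhere — z-scoring,
  segment descriptors, cohort tables — for internal consistency.
* The streaming filter kernel is numba-compiled with plain ascending-order
  loop arithmetic; the test suite pins it bit-for-bit against a naive
  per-sample Python reference, so vectorization can never silently change
  results.
* NLMS parameter recovery: with external white excitation and small output
  noise the filter recovers a planted 7-component weight vector to ≪1% at
  10⁵ samples. In the self-excited predictive configuration (the signal
  generated recursively from the planted weights) the steady-state weight
  noise and the slow bias mode floor per-component errors near 6–10% at
  10⁵ samples for any fixed μ; the 5% level is reached around 3×10⁵
  samples (μ ≈ 0.003), which is what the fixed-seed unit test uses.
* EDF output is 16-bit with one-second records; the physical scaling uses
  the limits exactly as serialized in the 8-character ASCII header fields
  (slightly widened so rounding still brackets the data), bounding the
  round-trip error by two quantization steps.
* Exclusion intervals are half-open `[start, end)`, 0-based, like all
  sample indices in the package.
* A cohort-table group with fewer than two subjects reports its std as NaN
  with a warning rather than a misleading zero.

## Known limitations

* The classifier is single-channel by design; no channel selection or
  multichannel fusion is attempted.
* Exhaustive leave-p-out is quadratic-free but the combination enumeration
  itself is O(C(N, p)); p = 3 at N ≈ 200 is fine, large p is not.
* The EDF reader maps common 10-20 label variants; exotic montages or
  per-channel sampling-rate mixtures are rejected rather than guessed.
* Artifact handling is limited to the exclusion-mask interface; no
  automatic artifact detection is provided.
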
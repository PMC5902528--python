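# Methods

This note documents the models, conventions and parameter choices behind
eegpipe: what each stage computes, which knobs matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Workflow model

A *pipe* is an ordered list of *step sets*; a step set is an ordered list
of registered operations with declared parameter schemas. Configurations
are validated in full before any data is read: unknown operations, unknown
argument keys, duplicate identifiers, unresolvable or cyclic
`pipe_id#step_id` source references are all reported in one error. Trunk
pipes read raw EDF/BDF; branch pipes start from the saved state of their
source step set, and a pipe with k sources runs k times into directories
named `<pipe>__src_<pipe>#<step>`. A source must point at a step set with
`save: true` — state that was never written cannot be branched from.

State snapshots are HDF5 containers holding the signal matrix as 64-bit
floats plus JSON-encoded channels, events, history, peek latencies and the
ICA decomposition; `load_state(save_state(x))` is bit-exact on signals and
value-exact on metadata. The batch looper isolates faults per recording:
an exception marks that measurement failed, writes the error and partial
history to the node's run log, and continues. Reruns with `overwrite:
false` skip measurements whose saved states all exist.

Randomness is controlled by one master seed; each measurement derives a
child seed by hashing its identifier (CRC32 mixed with the master seed,
kept below 2^31), so running a subject subset reproduces the values of the
full run.

## Signal operations

- **Re-referencing.** Average reference over EEG-type channels (EOG
  excluded from the reference computation, but re-referenced too), or a
  named channel set. Channel differences are preserved exactly.
- **High-pass filter.** Zero-phase Hamming-window FIR applied
  forward-backward; default cutoff 1 Hz with a 1 Hz transition band, the
  conventional drift removal before ICA. Tap count ≈ 3.3·fs/transition.
- **ICA.** Seeded fixed-point ICA (scikit-learn FastICA, unit-variance
  whitening, tol 1e−7) on the EEG *and* EOG channels; including the EOG
  channels lets ocular components load on them so that blink correction
  propagates to the EOG traces, mirroring common EEGLAB practice. The
  unmixing/mixing matrices are stored in full channel space; at full rank
  the decomposition reconstructs the (centred) data to ~1e−14 relative
  error. The algorithm slot is pluggable; only FastICA ships.
- **Blink-IC correction by filtering.** Rather than discarding a blink
  component outright, its activation is zero-phase high-passed at 4 Hz and
  back-projected, removing the slow blink potential while keeping any
  high-frequency brain signal the component carries. The 4 Hz default is
  this package's documented choice — the blink potential's energy lies
  below ~4 Hz — since the original correction's band is not published
  alongside the method.
- **Bad-channel interpolation.** Perrin spherical splines (stiffness m = 4,
  50 Legendre terms, ridge 1e−5) over the remaining EEG channels.
  Interpolation with more than half the montage flagged is refused.
- **Spatial-clustering diagnostic.** Interpolation borrows from
  neighbours, so a contiguous patch of bad channels is a warning sign. The
  dispersion score is the mean great-circle distance from each flagged
  channel to its nearest good channel, normalized by the montage's median
  *nearest-neighbour* distance; values above 1.5 flag a co-located
  cluster. (Normalizing by the median of all pairwise distances would
  invert the diagnostic: tight clusters would score low.)

## Detectors

All detectors return every per-item score alongside the flagged subset, so
QC reports and the sweep can re-examine decisions.

- **Channel variance.** `s_c = (v_c − median(v)) / MAD(v)` with
  `MAD(v) = median(|v − median(v)|)` — deliberately *without* the 1.4826
  Gaussian-consistency constant, so bounds are literally "in MAD units". A
  consequence worth knowing: for i.i.d. channels, s ≈ z/0.674, so half the
  channels exceed |s| = 1 by construction, and the expected null flag
  count at bounds [−5, 2.5] is ≈ 4.6% of the montage. A scalar bounds
  value t expands to symmetric [−t, +t], catching flat channels (far
  negative s) as well as noisy ones. Variance is computed on the full
  continuous signal without segmentation, and without a log transform
  (a config switch `log_transform` was considered and rejected as it does
  not change the self-normalized geometry; the score is scale-invariant
  either way).
- **Spectral.** Welch power averaged within each band, in dB (log of the
  band mean — mean of the log would dilute narrowband lines below any
  usable threshold); deviation from the across-channel mean outside
  `[−5, +5]` dB in any band flags the channel. Default bands 0–2 Hz
  (drift/flat) and 20–40 Hz (muscle/line).
- **Blink events.** VEOG band-passed to 0.5–5 Hz; peaks above 5× the MAD
  of the filtered trace with a 0.5 s refractory period. MAD scaling makes
  detection invariant to overall amplitude.
- **Blink ICs.** The peri-blink VEOG average (window −0.3…+0.5 s, ≥3
  blinks) is the template; each component is scored by the absolute
  Pearson correlation between its blink-locked average activation and the
  template, flagged above r = 0.7.
- **Multi-metric IC detector.** Five features in the spirit of
  multi-feature artifact classifiers: median absolute gradient of the
  activation, kurtosis of the scalp-map weights, slope of the log-log PSD
  over 8 Hz–fs/4, Hurst exponent by rescaled-range analysis, and maximum
  |correlation| with EOG channels. Each feature is robust-z-scored across
  components (median, MAD·1.4826 — here the constant *is* used because
  the threshold is a z-score), flagged at |z| > 3, and combined by union
  ("any", liberal) or intersection ("all", conservative). These are
  emulations of the published feature definitions, not bit-exact ports.
- **Fraction cap.** A detection can be constrained to the worst
  `floor(f·n)` items by absolute primary score (ties by item order); a
  254-channel montage capped at f = 0.05 keeps 12.

## Parameter sweep

For each grid value p_k the target detector runs on a copy of the
recording (after an optional mini-pipe of preparatory steps) and
y_k = |flagged| forms the outcome curve. Selection: with d_i =
|y_{i+1} − y_i| and σ_y the standard deviation of the whole outcome
vector (sample SD, n−1 denominator; a `sd_mode` switch exposes the
population variant since the convention is not fixed by the method's
description), the chosen step is argmin_i |d_i − σ_y| with ties to the
smallest i, and the selected value is the midpoint (p_i + p_{i+1})/2 —
strictly inside the grid. Absolute differences make the criterion
direction-free on noisy curves. The swept value is injected into the next
call of the target operation, and that call's history entry records the
sweep provenance (grid, curve, selected value).

**Known limitation.** Because the variance score is self-normalized, the
outcome curve over t = 1…6 starts at ~50% of the montage and decays
smoothly through the clean channels' score bulk before reaching the
true-artifact plateau. On such curves the early differences are closest to
σ_y, so the rule selects low values (t\* ≈ 1.1–1.5) and over-rejects:
with five ×8-noise channels among 64 the swept threshold yields F1 ≈ 0.4,
versus F1 = 1.0 anywhere on the plateau. This greediness is inherent to
the criterion, not to its implementation — the selection agrees exactly
with brute-force evaluation on 1,000 random curves — and the package
reports it honestly rather than repairing it with a different rule.

## Quality control

Peeks draw their segment latencies once per recording (uniform,
non-overlapping, ≥1 s from the edges; defaults 10 segments × 10 s, reduced
with a warning on short recordings) and store them on the recording, so
every later peek — including in downstream branch pipes, via the state
container — reuses them exactly. Per channel and segment the log records
mean, SD, min, max, range, skewness, kurtosis and a normality p-value.

The normality test defaults to the Lilliefors-corrected
Kolmogorov–Smirnov test. The naive one-sample KS against a normal with
estimated mean/SD is available (`normality_test="ks"`) but is severely
anti-conservative in p-value terms (it accepts essentially 100% of
Gaussian segments); only the Lilliefors variant holds the nominal 5%
rejection rate, which is what makes the logged p-values interpretable.

Rejections accumulate in an append-mode tab-separated ledger with a CSV
twin; percentages are `fraction_of_total × 100`. Branch comparison
aggregates each node's final peeks (mean range, mean SD) and ledger
totals, then applies the parsimony rule: among nodes whose mean range and
SD are within 10% (relative) of the best node, recommend the one with the
lowest total rejection percentage; the full table is always returned so
the user can overrule. The 10% similarity tolerance is this package's
reading of "similar quality".

## ERP analysis

Epoch windows are half-open sample intervals
`[latency + round(t_pre·fs), latency + round(t_post·fs))`, so ±1 s at
256 Hz is exactly 512 samples; out-of-bounds events are dropped and
counted. Baseline correction subtracts each epoch's mean over −1…0 s
(idempotent; baseline mean is 0 to machine precision afterwards). The
smoother is a centred moving average of `round(fs/4)` samples whose edges
shrink the window rather than pad — linear, length-preserving, interior
impulse response 1/w. Smoothing is applied per epoch before averaging; by
linearity the grand average is identical to smoothing afterwards. Subject
averages are unweighted means over epochs; the grand average is the
unweighted mean over subject averages (the usual grand-average
convention; epoch-weighted averaging would let high-trial subjects
dominate).

## Synthetic oddball generator

The generator is the package's test bed: a linear mixture of latent
sources on a standard 10-10 montage (up to 64 channels; positions from the
standard montage shipped with mne, normalized to the unit sphere), plus a
VEOG channel.

- **Event plan**: trials at 1.4 s ISI with ±0.15 s jitter; deviant
  probability 0.10; tone length (short/long) uniform; four condition
  labels written as trigger codes 1–4.
- **Background**: per-channel 1/f-shaped Gaussian noise, 10 µV RMS, with
  per-channel scale jitter uniform ±18% — real montages are not
  homogeneous, and the jitter gives the variance detector a realistic
  null spread. Posterior alpha: amplitude-modulated 10 Hz, 2.5 µV RMS at
  the occipital topography peak (an eyes-open task level; large alpha
  would itself read as a variance outlier, which is true of real data
  too but would conflate the generator's "clean" condition with an
  artifact).
- **ERP**: per event, a negative Gaussian N1 (−5 µV, 100 ms, σ 30 ms) and
  a positive P300 (6 µV, 325 ms, σ 150 ms); deviants add a configurable
  P300 surplus (default +4 µV). The ERP topography is a smooth map
  normalized to 1.0 at the nominated read-out channel (default T7), so
  injected amplitudes are in read-out units. After ±1 s epoching,
  baseline correction and fs/4 smoothing, the recovered deviant−standard
  window mean over 250–400 ms is ≈3.7–3.8 µV for a 4 µV injection — the
  attenuation is the deterministic effect of smoothing and windowing on
  the P300 shape, not noise.
- **Blinks**: Gaussian bumps (σ 80 ms) at ~15/min with ≥1.5 s separation;
  400 µV on VEOG, 140 µV at the frontal scalp peak. The latent blink time
  course is part of the ground truth; FastICA on a generated recording
  recovers it with correlation ≥ 0.9 (checked over seeds). Note the 1 Hz
  pre-ICA high-pass distorts the blink waveform itself (the filtered and
  unfiltered courses correlate ≈0.72), so source-recovery checks run ICA
  on the unfiltered recording.
- **Bad channels**: "noisy" adds white noise at k× the background scale
  (k = 8 gives a variance ratio ≥ 25× the clean median), "flat" collapses
  the channel to near-zero, "line" adds an 80 µV mains sinusoid.
- **Impulses**: optional isolated 3-sample spikes with a frontal
  topography, emulating transient non-biological artifacts.

Everything is deterministic under the seed; fixture sets are written as
BDF (24-bit) or EDF (16-bit) by a minimal writer with trigger codes on a
Status channel, cartesian electrode-location sidecars, ground-truth JSON
and a measurement sheet.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: volume-conducted spatial correlation of the
background (channels' 1/f noise is independent; only alpha, ERP, blinks
and impulses are spatially coherent), non-stationarity across a session,
electrode drift and impedance changes, muscle EMG spectra, and
autoregressive temporal structure fit to real recordings. Detector
operating points established here transfer to real data only as
qualitative behaviour.

## Study conditions used by the quantitative checks

- Detector calibration and sweep recovery: 64 channels, 60 s, five
  ×8-noise channels, 20 seeds, *no blinks* — blink topography
  legitimately inflates frontal-channel variance, and in the documented
  pipelines variance detection runs only after blink correction; the
  blink pathway is validated by its own checks.
- Sweep-curve shape: a severity continuum of eight noisy channels
  (k = 0.3…8) emulating the continuous heterogeneity of real recordings;
  with only a few extreme artifacts the curve is a long tied plateau and
  rank correlation is ill-conditioned. The reported value is the mean
  Spearman ρ over 20 seeds.
- ERP surplus recovery: 10 subjects × 200 trials at the generator's
  default noise level, averaged over 3 replicate cohorts to keep the
  Monte-Carlo error of the reported mean near 0.35 µV.
- Peek-statistics reduction: 32 channels, 120 s, blinks plus two ×8-noise
  and one flat channel; correction = blink-IC filtering plus
  spherical-spline interpolation of variance-flagged channels; observed
  reduction in synchronized peek mean range and SD is ≈50%, comfortably
  past the ≥20% contract (the effect size here is set by the generator's
  artifact amplitudes).
- Normality calibration: 500 Gaussian segments of 2,560 samples;
  Lilliefors acceptance at p > 0.05 is ≈95%.

## Known limitations

- The inflection selection rule over-rejects on smoothly decaying outcome
  curves (analysis above); a spatial-uniformity-aware objective would be
  the natural next step but is out of scope.
- The multi-metric IC features are emulations, not validated ports of the
  published toolboxes they resemble.
- Peek statistics assume the recording is long enough for non-overlapping
  segments; very short recordings degrade to fewer segments with a
  warning.
- The EDF/BDF writer covers continuous single-rate recordings with one
  trigger channel — sufficient for fixtures, not a general-purpose
  exporter. Reading goes through mne and inherits its format support.
- `run_postproc` loads a node's states with per-measurement fault
  isolation but calls the post-processing function once on the batch
  (grand averaging needs all subjects); a per-measurement post-processor
  simply iterates inside the function.
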
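# Methods

This note documents the models and procedures implemented in `tugsense`, the
parameter choices that matter, and what the synthetic evaluation does and
does not demonstrate.

## Sensor and data model

One inertial unit worn in a belt at the lower back (L3–L5), sampling a
triaxial accelerometer (gravity-inclusive, m/s²) and gyroscope (deg/s) at a
nominal 100 Hz. Axis order is fixed package-wide as (vertical V,
mediolateral ML, anterior-posterior AP). Magnetometer and barometer channels
are deliberately out of scope: the magnetometer is environment-sensitive and
the barometer too coarse for within-test height changes. Files are
delimited text with a one-line header; a column map and unit declaration
(`g` vs `m/s²`, conversion 9.81) adapt foreign layouts. Timestamps must be
strictly increasing; when jitter exceeds 10 % of the sample period the
stream is linearly resampled onto a uniform grid, because windowing assumes
a fixed rate.

## Noise filters

Each classifier filters the raw stream with its own filter before
windowing. The low-pass is realized as a 4th-order Butterworth applied
forward-backward (zero phase) with reflected edges; zero phase matters
because phase lag would systematically shift detected event boundaries
against the label track. The Gaussian smoother's σ is interpreted in
seconds (0.23 s ≈ 23 samples at 100 Hz), consistent with every other
temporal parameter in the configuration being in seconds. Filtering is
linear and preserves constants; both properties are tested.

## Windowing and features

Window length is `round(size_s · fs)` with half-up rounding (so 1.405 s at
100 Hz is 141 samples) and the hop is at least one sample; trailing partial
windows are dropped. The ten features are the standard accelerometry set;
their exact conventions here are:

- mean; population SD; RMS; signal energy (sum of squares) — per channel;
- SMA: mean over samples of |V|+|ML|+|AP| per sensor triple;
- SVM: mean per-sample Euclidean norm (implemented, not used by the default
  configurations);
- autocorrelation: mean-removed, variance-normalized coefficient at a
  configurable lag, default 0.5 s ≈ half a gait cycle, which separates
  periodic walking from aperiodic movement; the lagged product is averaged
  over the available terms so a period-p signal scores ≈ 1 at lag p;
- correlation: Pearson correlation for every channel pair inside the
  configured channel set; defined as 0 for zero-variance channels;
- pitch: `atan2(mean AP, hypot(mean V, mean ML))` in degrees — the forward
  tilt of the window's gravity estimate, computed from the acceleration
  triple regardless of the channel-set tag;
- spectral entropy: Shannon entropy of the DC-excluded normalized power
  spectrum, divided by log(bins) to [0, 1]; defined as 0 for constant
  blocks.

Degenerate inputs (constant or all-zero blocks) return finite values by
definition rather than NaN, so downstream classifiers never see invalid
vectors. The abbreviation "SE" is ambiguous in the classifier
configuration vocabulary (signal energy vs spectral entropy); the default
configurations resolve it to signal energy for the state and transition
classifiers, and feature names are always written out in full in code and
column headers.

## Hierarchical classifier

Four classifiers, each with its own method, window grid, filter and feature
set (defaults in `tugsense.defaults`):

| level | method | window/step (s) | filter |
|---|---|---|---|
| state | boosted decision trees | 1.405 / 0.072 | low-pass 6.1 Hz |
| static | MLP 5×7 | 2.511 / 0.427 | none |
| dynamic | MLP 3×44 | 1.853 / 0.249 | Gaussian σ = 0.23 s |
| transition | MLP 4×40 | 1.135 / 0.073 | low-pass 4.5 Hz |

"h HL, k HN" is read as h hidden layers of k nodes each — the only reading
consistent with both numbers. Boosted trees use the histogram-based
gradient-boosting implementation with 200 rounds and depth 3 (configurable;
decision stumps use AdaBoost at depth 1). MLPs standardize features with a
scaler fit on training data only, which travels inside the serialized
model. Training is deterministic given the seed and a saved/reloaded bundle
reproduces predictions exactly.

**Fusion.** The four grids are asynchronous, so per-sample labels are
assigned by nearest window center (ties to the earlier window): the state
track selects which specialist's track supplies each sample's fine label.
Samples covered by no window are labeled `unknown`. This makes boundary
placement accurate to about half a step width of the relevant grid
(≈ 40 ms for state and transition).

**Segmentation.** The label track is run-length encoded; runs shorter than
a minimum duration (default 0.5 s — shorter than any plausible phase,
longer than typical misclassification blips) are absorbed into the longer
neighbor, shortest first, until the output is stable and alternating.

**Cross-validation.** Five folds split at the subject level (adjacent
windows overlap heavily, so window- or recording-level splits would leak);
per-class confusion counts are pooled over folds and metrics derived from
the pooled counts.

## TUG sequence model

Segments reduce to tokens ↑ (sit-to-stand), W, T, ↓ (stand-to-sit).
Consecutive same-label segments are merged first — doubled activities such
as turn–turn are expected classifier behaviour, not errors. Sit/stand (or
unknown) segments of ≥ 1 s delimit candidate episodes, because a test
starts from and ends in sitting; shorter posture blips inside an episode
are skipped rather than invalidating the match. Within an episode the
token stream is scanned left to right and the templates tried longest
first (then by template id); a match is emitted if its span — from the
start of the first matched segment to the end of the last, including any
tolerated spurious ↑↓ pair — is under the duration ceiling (default 30 s,
configurable; beyond it an execution is not a plausible test). Matched
segments are consumed, so events never overlap.

The default model set is the nine-template grammar with per-template
recognition accuracies (15.37, 52.15, 12.35, 5.67, 4.34, 2.34, 1.67, 1.33,
1.33 %); the cumulative accuracy is their plain sum, 96.55 %. These
accuracies are cohort-derived report inputs carried by the model set for
reporting, not quantities the package estimates.

## Agreement statistics

`agreement(a, b)` reports Pearson r with a two-sided p, the OLS fit of b on
a, and Bland–Altman bias = mean(b−a) with limits bias ± 1.96 · sample
(n−1) SD. Constant inputs make r undefined and are reported as NaN. The
gamma fit is maximum likelihood with location fixed at 0 (durations are
strictly positive). Episode normalization divides duration by assumed
walking distance (6 m standard, 3.55 m chair-to-chair — the midpoint of the
observed 3–4.1 m range), yielding seconds per meter so that larger values
mean slower; the paired comparison uses a two-sided Wilcoxon signed-rank
(exact null up to 25 non-zero differences, normal approximation beyond,
zeros dropped).

## Synthetic-signal generator

The generator renders (activity, duration) scripts into labeled recordings:

- sit/stand: constant gravity components with Gaussian noise; sitting is
  distinguished by a trunk pitch of 20° (reclined against the backrest);
- walk: half-wave-rectified squared-sine vertical impulses at the step
  cadence (default 2 Hz, peak 3 m/s² — about three steps per 3 m walk at
  an older adult's ≈ 1 m/s gait speed) plus a small AP sway;
- turn: a 120 deg/s mediolateral gyroscope plateau with raised-cosine
  edges;
- transitions: a raised-cosine pitch ramp between the seated and upright
  gravity orientations — whose signed derivative appears on the
  mediolateral gyro, giving the two directions opposite signatures — plus a
  biphasic AP pulse (±2.5 m/s²), default 1.5 s;
- noise: 0.2 m/s² (acc) and 2 deg/s (gyro) white Gaussian, per channel.

Corpora mix ~12 s standard test episodes, naturalistic chair-to-chair
variants (one walk of 3–4.1 m, one turn) and distractor walk/stand
sequences, with per-subject jitter of cadence, turn rate, pitch and step
amplitude. Everything is reproducible from the seed.

**What this does and does not show.** The primitives are stylized, not
biomechanically simulated: classes are separated by the same signal
properties that separate them in real data (variance, periodicity, pitch,
turn rate), but real signals add soft-tissue artifact, sensor misalignment,
overlapping movements (turn-into-sit), pathological gaits and much larger
inter-subject variability. Passing the end-to-end suite therefore
demonstrates that the pipeline's contracts are correct — features computed
as defined, hierarchy routed and fused correctly, grammar sound and
complete, timing unbiased — not that the trained models would reach the
same scores on a clinical cohort. Cohort-level results (e.g., r ≈ 0.97–0.99
against reference timing) require the original study data and are
explicitly out of scope.

## Problem sizes and numerical choices

The end-to-end acceptance run trains on a 50-subject corpus (~25 s per
recording) and evaluates on 12 held-out noisy subjects plus 10 noise-free
subjects; it completes in well under a minute on one CPU, and the default
test suite in about half a minute. Rounding of window sizes is half-up with
a 1e-9 epsilon against binary float artifacts; fusion ties go to the
earlier window; 0/0 metric ratios are defined as 0; the detector prefers
longer templates at equal start, then earlier starts.

## Known limitations

- The per-template recognition accuracies are inputs; the package cannot
  re-estimate them without the original cohort.
- Sample-level F1 punishes boundary disagreement around short activities;
  turn/transition scores are intrinsically lower than posture scores.
- The fusion rule ignores classifier confidence; a probabilistic fusion
  could weight overlapping windows.
- The generator does not model magnetometer/barometer channels, festinating
  or shuffling gait, or sensor repositioning errors.
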
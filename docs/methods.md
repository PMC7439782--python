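# Methods

## Problem and pipeline

The package implements closed-set biometric identification from multi-channel
EEG. The working premise is that a person's resting spectral profile — how
much theta/alpha/beta/gamma power each scalp site carries — is individual and
fairly stable, so a classifier trained on short EEG segments can recognize
who is being recorded. The processing chain is:

1. **Segmentation.** Each continuous trial is cut into non-overlapping
   identification clips of 1000 samples (5 s at 200 Hz); remainder samples at
   the trial end are dropped. A 4-minute trial therefore yields exactly 48
   clips, a 15-trial session 720.
2. **Sub-windows.** Each clip is divided into five contiguous 1-s windows, so
   features carry a coarse within-clip time course.
3. **Band decomposition.** Every window is band-passed into rhythm bands with
   a zero-phase (forward–backward) Butterworth filter of order 4. Order 4 is
   the common EEG default — monotone passband, steep enough transition — and
   forward–backward application removes group delay, which the tests verify
   via zero-lag cross-correlation. Three band grids are shipped as presets,
   since the literature uses several inconsistently:
   `default` θ 4–8 / α 8–15 / β 15–32 / γ 32–40 Hz,
   `narrow` 4–7 / 8–14 / 14–31 / 32–40 Hz, and
   `lowfreq` δ 1–4 / 5–8 / 9–15 / 15–32 Hz. Single-band studies use a
   one-band `BandSet`; the band axis of every downstream tensor then has
   length 1.
4. **Differential entropy.** Each (window, band, channel) series is reduced
   to its differential entropy under the Gaussian closed form
   `h = ½ ln(2πe σ²)` in nats, with σ² the maximum-likelihood sample
   variance. Band-limited EEG windows are close to Gaussian, and on such data
   the closed form tracks nonparametric entropy estimators to within a few
   hundredths of a nat (tested against the Vasicek estimator). The variance
   is floored at 1e-12 before the log so silent channels produce a finite,
   flagged value rather than −∞. Log base is natural; the choice only shifts
   and scales features, which normalization removes anyway. Alternates: the
   window-averaged periodogram PSD (`feature="psd"`), and a Rosenstein-style
   largest-Lyapunov-exponent estimator, included for feature comparisons —
   it recovers ln 2 on the logistic map within a few percent but is orders
   of magnitude slower than DE, which is why DE is the default feature.
5. **Grid mapping.** The 62 per-channel values are scattered onto a 9×9
   scalp grid (rows front→back, columns left→right) so a 2-D convolution can
   exploit electrode adjacency. The placement ships as a JSON data file (62
   named cells, 19 structural zeros) and is treated as data: any unique
   placement of the recording's channels is accepted.
6. **Normalization.** Each (sub-window, band, grid cell) position is
   standardized to mean 0 / sd 1 across the clip sequence. Zero-spread
   positions (including the 19 empty cells) are set to 0 and flagged.

### Normalization scope

Standardization needs a population. The default scope, `session`, pools all
subjects' clips that share a session index: this removes session-global
shifts while preserving each subject's mean signature, which *is* the
identity-bearing signal. The alternative `record` scope takes statistics per
(subject, session) recording; on stationary data that subtracts each
subject's own mean spectral profile and removes nearly all identity
information — it is available for comparison but deliberately not the
default. A `channel` normalization mode (standardize across grid cells
within a slice, rather than across time) is likewise available behind a
switch; the over-time reading is the default because per-position statistics
are what make "mean 0 / sd 1 per channel over time" literally true.

## The classifier

A compact continuous CNN on the (5·n_bands)-plane 9×9 input: three 4×4
convolutions (stride 1, zero-padded to preserve 9×9; 64/128/256 maps, ReLU),
a 1×1 fusion convolution with 64 maps, a fully connected layer to a
1024-dimensional feature vector with ReLU and dropout 0.5, and a softmax over
identities. No pooling — at 9×9 there is nothing worth discarding. The 4×4
kernel needs 3 pixels of total padding per axis; it is split 1 before / 2
after. Exact parameter count with 20 input planes and 15 identities:
6,017,551 (reported at run time by `count_parameters`; the fully connected
layer dominates with 5.3 M).

The network is implemented directly on NumPy: im2col convolutions,
hand-written backprop, inverted dropout, softmax cross-entropy, and Adam
(β₁ 0.9, β₂ 0.999, ε 1e-8). At this input size a framework buys nothing,
and a pure NumPy implementation is bit-reproducible from the seed on a
single machine (cross-hardware bit equality is not promised). He
initialization; float32 parameters with the softmax taken in float64.
Training defaults follow the usual recipe (Adam, lr 1e-4, batch 128, 50
epochs, dropout 0.5); the scaled protocols below use lr 1e-3 and fewer
epochs, which on the synthetic cohorts converges in a handful of passes.

## Synthetic cohorts

The generator embodies the individual-spectral-signature premise without
physiological realism. Per subject, a channels × bands gain matrix is drawn
log-normally (`signature_spread` = sd of log-amplitude). A recording is the
gain-weighted sum of unit-variance band-limited noise carpets (white noise
through the same Butterworth band-pass the analysis uses — one filter code
path), plus white sensor noise (sd 0.3 relative to unit band amplitude).
Emotion acts multiplicatively on the beta/gamma amplitudes (+20 % positive,
−20 % negative, neutral flat), the usual direction of valence effects on
high-frequency EEG power. Session drift is one log-normal scalar gain per
(subject, session) (sd 0.1 by default). Trials are independent draws; there
is no within-trial nonstationarity, no 1/f background, no artifacts, no
event-related structure. Passing tests therefore show the pipeline recovers
identity from stationary band-power signatures — they say nothing about
robustness to the nonstationarities of real EEG.

Defaults mirror the emotional-video study design the pipeline targets: 15
subjects, 62 channels, 200 Hz, 15 four-minute trials per session (five per
emotion, cycling), three sessions.

## Evaluation

* **Rank-1**: fraction of clips whose top-scoring identity is correct.
* **EER**: softmax scores reduced one-vs-all (true-identity probability =
  genuine, every wrong-identity probability = impostor), exhaustive
  threshold sweep, FAR/FRR crossing linearly interpolated. With
  systematically inverted scores the crossing can sit slightly above 0.5;
  no clamping is applied.
* **k-fold**: stratified clip-level 10-fold splits (90 % train). Clip-level
  splitting leaks within-trial correlation between train and test — this is
  deliberate, matching the protocol the pipeline replicates; trial-aware
  splitting can be had by filtering on the `trial` column of the label
  frame.
* **Cross-emotion**: a model trained on one emotion's clips (with a 10 %
  stratified hold-out) is scored on the other emotions; training size is the
  same for the same-emotion reference.
* **Interval**: train on sessions 0–1 (90 %), report rank-1 both on the
  held-out 10 % ("NT") and on the full later session ("interval").
* Models are always retrained from scratch per fold/condition; no
  fine-tuning.

## Problem sizes and study conditions

Chosen once, as the package's own experimental design:

* **Identification regime** (the headline parameter-recovery setting):
  15 subjects × 62 channels, one session, 10-s trials (30 clips/subject,
  450 clips), `signature_spread` 0.4 ("strong" signatures), sensor noise
  0.3, 10-fold CV, 4 epochs at lr 1e-3. In this regime identification is
  essentially perfect (rank-1 ≈ 1, EER ≈ 0) and a label-shuffled control
  falls to chance (1/15).
* **Degradation regimes** (transfer and interval protocols): 10 subjects,
  `signature_spread` 0.15 — a moderate-signature setting chosen so accuracy
  is not ceiling-saturated and protocol sensitivity is measurable — with the
  default ±20 % emotion modulation, and 20 % session drift for the interval
  protocol; averaged over several cohort seeds.

## Known limitations

* The CNN is CPU-bound NumPy; it is sized for 9×9 grids, not images.
* The generator's stationarity makes the identification task easier than
  real EEG; absolute accuracies on synthetic cohorts are not comparable to
  accuracies on recorded data.
* EDF files can be read (via `mne`, optional extra) but not written; the
  native container is `.npz` + JSON sidecar.
* A published parameter count of 7,918,095 circulates for this
  architecture; the layer arithmetic as specified above gives 6,017,551,
  which is what the package reports. The discrepancy is documented rather
  than force-matched.
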
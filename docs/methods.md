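# Methods

This note documents the models and procedures implemented in `stereokit`,
the parameters that matter, the synthetic data the package is validated
on, and the design choices made where the design was genuinely open.

## Problem setting

The input is the output of a 2-D human pose estimator run on fixed-camera
video: per frame, zero or more 18-keypoint skeletons in the COCO layout
(pixel coordinates plus a confidence per joint; undetected joints are
encoded `(0, 0, 0)`). The goal is to attribute a persistent identity to
each person and to classify short windows of their movement into five
stereotyped-action classes: `sit`, `stand` (sit-to-stand), `squat`
(stand-to-crouch), `shake_body` (seated torso rocking) and `shake_hands`
(hand/arm oscillation). Clips are 1–3 s at 25 fps.

## Denoising

Four measures, in order:

1. **Unit scaling.** Both axes are divided by the image height `h`. Pixel
   coordinates have different ranges per axis and aspect ratios differ
   between recordings; dividing by a single scalar makes Euclidean
   distance isotropic, which the tracker metric and velocity features
   require. Scaled y ∈ [0, 1], scaled x ∈ [0, w/h].
2. **Head removal.** Nose, eyes and ears carry almost no action
   information; dropping them leaves 13 joints with the Neck reindexed to
   0.
3. **Invalid-frame discard.** A frame is kept iff the Neck and at least
   one hip are detected. The torso anchor is what the imputation and the
   tracker metric hinge on; frames missing only peripheral joints are
   retained. "At least one hip" (rather than both) was chosen because the
   hips are redundant anchors for the imputation rule and requiring both
   would discard usable frames.
4. **Neck-relative imputation.** A missing joint is placed at the current
   Neck plus its offset from the Neck in the *previous retained frame*
   (which may itself be imputed), so a joint missing for k consecutive
   frames keeps a constant torso offset, and a joint that is static
   relative to the torso is recovered exactly. Imputed joints carry
   `valid = False`. Degenerate cases: a joint never yet observed is placed
   at the Neck (zero offset) rather than inventing limb geometry; an
   empty sequence is an error.

A joint counts as detected iff its confidence is strictly positive; no
additional confidence cut is applied by default (`min_confidence`
configurable).

In multi-person scenes the imputation needs each person's own previous
frame, which is undefined before identities exist; `run_pipeline`
therefore applies measures 1–3 per frame, tracks, and then imputes per
tracked sequence. The single-person path applies all four in one pass.
The composed operation is idempotent.

## Tracking

Identities are assigned by mutual-nearest-neighbour matching between
consecutive frames. The inter-skeleton distance is the mean Euclidean
distance over joints valid in *both* skeletons (robust to differing
missing-joint patterns; reduces to Neck-to-Neck distance in the worst
case; +∞ when nothing is shared). A pair matches iff each is the other's
unique nearest neighbour and the distance is below `match_threshold`
(default 0.25 image heights — large enough for between-frame motion at
25 fps, small enough to separate people a body-width apart; the value is
configurable and not critical for separated people). Unmatched current
skeletons get fresh ids; ids are never reused; a person who disappears
and returns later is treated as new unless re-matching against the last
non-empty frame passes the threshold. Ties in nearest-neighbour distance
break toward the lower centre-sorted index, so the procedure is
deterministic. On the first frame, ids 0, 1, … follow ascending
Neck-to-image-centre distance.

## Sequence preparation

Classifier windows are exactly `T` frames (default 32 ≈ 1.3 s). Shorter
clips are padded with all-zero skeleton frames *at the end*; longer clips
are shortened by drawing `T` distinct frame positions uniformly at random
and keeping original order. Subsampling RNG is seeded per dataset build,
so builds are reproducible. Train/test splits are stratified per class at
the sequence level (70/30 by default) so windows of one clip never appear
on both sides. In multi-person frames destined for single-person
training data, only the skeleton nearest the image centre is kept.

## The recurrent classifier

Architecture (many-to-one): flatten 13 × 2 joints to 26 features per
frame → fully connected (width = hidden size by default) + ReLU → two
stacked LSTM layers → fully connected softmax with 5 outputs, read from
the final time step only. The LSTM cell is the standard gated recurrence
(input/forget/output gates, tanh candidate); a single-step pinned-weight
oracle test holds the implementation to the algebra at 1e-6.

Training minimizes cross-entropy with Adam at learning rate 0.001
(default epochs 100, batch 32, forget-gate bias initialized to 1,
Glorot-uniform weights, float32 throughout, exact backpropagation through
time). Training stops early once training accuracy stays ≥ 0.999 for two
consecutive epochs. Two further choices matter:

* **Input standardization.** The 26 features are standardized with the
  training set's mean/sd, stored as model buffers and applied inside the
  forward pass. Discriminative signals here can be ~1% of the coordinate
  scale (a torso lean of 0.01–0.02 against positions ~0.9 that vary by
  ±0.15 between clips); without standardization Adam reliably stalls in
  an optimum that treats near-symmetric class pairs as coin flips.
* **No masking of padded frames.** Zero-padded frames pass through the
  network like any input; with a last-step readout the tail becomes part
  of the learned signal. (After standardization a padded frame is a
  distinctive constant vector.)

A detection is reported only when the winning softmax probability
strictly exceeds 0.9 (configurable); a maximum of exactly 0.9 is *not* a
detection. The hyperparameter sweep utility retrains over a
(time-steps × hidden-states) grid, rebuilding fixed-length samples per
`T`.

## Manual-feature baselines

* **Method 1 (periodicity statistics).** For each joint and each of three
  velocity measures (per-frame change in x, in y, and overall
  displacement `δP = sqrt(δx² + δy²)`): the mean and sd of the velocity
  plus the maximum, mean and sd of the magnitudes of the
  autocorrelogram's local maxima — 15 values per joint — optionally
  augmented with the normalized per-frame joint positions. The
  autocorrelogram is the biased, variance-normalized sample
  autocorrelation at lags 1…L−2; a peak is a strict local maximum (with
  ρ(0) = 1 as the left neighbour of lag 1); no peaks, or a constant
  series, give (0, 0, 0). The original six-upper-body-joint scope is
  available via `joint_subset`.
* **Method 2 (normalized kinematics).** Joint positions expressed
  relative to the Neck and divided by the body height `H` (mean over
  frames of the Neck-to-mid-hip length, mid-hip = mean of the two hips),
  concatenated with the body velocity (per-frame Neck displacement
  magnitude — the only block that sees global motion) and the per-frame
  velocities of the normalized joints. `H = 0` (a degenerate skeleton) is
  an error.

Classifiers are scikit-learn estimators with the stated capacities:
decision tree (Method 1's classifier), linear SVM, random forest
(100 trees, depth 40) and a 100×100×100 multilayer perceptron;
hyperparameters not stated stay at library defaults.

## Synthetic data

The generator emulates the study conditions — there is no public dataset
of this kind — at 656 × 368 px, 25 fps, clip durations uniform in 25–75
frames, default 150 sequences per class. Each class is a stick-figure
motion template: a start pose, a smoothstep postural ramp (`stand`,
`squat`) and per-joint sinusoids (`shake_body`: lateral torso
oscillation at ~1.5 Hz, amplitude 0.08 scaled units ≈ 30% of trunk
length, a typical seated-rocking excursion; `shake_hands`: wrist/elbow
oscillation at ~2.5 Hz). `shake_body` deliberately shares its seated base
pose with `sit`, so that pair is distinguishable only by motion — the
confusion hardest in real data. Per-clip variation: body scale 0.9–1.1,
anchor position jitter (±0.15 x, ±0.05 y), frequency and amplitude ±20%,
random phase, random left/right mirroring. The oscillation amplitudes are
the explicit separability knob: they are set so that the five templates
are well separated under the default noise, which is the regime the
classification benchmarks assume.

Detector noise corrupts only the raw output (ground truth is returned
alongside): independent per-joint dropout (default rate 0.2, written as
`(0,0,0)`), whole-frame detection failure (default 0.05), Gaussian
coordinate jitter (default sd 0.005 scaled units ≈ 2 px), and scripted
occlusion events (a joint set of one person blanked over a frame span).
Defaults were chosen so denoising has a measurable effect while the task
stays learnable. All randomness flows from a single seed; equal seeds
give identical datasets.

What the generator does *not* model: anatomically realistic limb
kinematics, perspective effects, detector confidence correlated with
image content, inter-person joint hallucination, or real ASD movement
signatures. Passing benchmarks on this data therefore demonstrates the
pipeline's correctness and the direction of its effects (denoising
helps; the recurrent model matches or beats manual features; undersized
hidden states hurt), not clinical performance.

## Evaluation protocols

Confusion matrices (rows = true), per-class precision/recall/F1 from
one-vs-rest counts with the 0-when-undefined convention, micro accuracy
as the scalar summary. The denoising ablation trains identical networks
on denoised vs raw inputs of the same corrupted datasets (raw = unit
scaling and head removal only, missing joints left at zero, invalid and
empty frames kept); it reports per-seed paired accuracies, the gap, and
the full configuration. Stochastic experiments default to 3 seeds.

Problem sizes used by the test suite and `scripts/acceptance.py`: 150
sequences/class, T = 32, H = 128, 70/30 split, 3 seeds for stochastic
claims — about 520 training sequences per run, a scale at which a full
training run takes under a minute on one CPU core.

## Known limitations

* The tracker is purely geometric; prolonged total occlusion or people
  closer than the match threshold can swap or retire ids (appearance
  re-identification is out of scope).
* Imputation assumes the missing joint rides with the torso; fast limb
  motion during dropout is recovered with error bounded by the limb's
  true torso-relative displacement.
* The classifier expects the training frame rate and scaling; it does not
  resample inputs recorded at other rates.
* Checkpoints store NumPy arrays; no cross-framework format is provided.
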
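# Methods

This note documents the modelling choices, numerical conventions and
synthetic-data assumptions behind `fogseg`, including the points where the
design was genuinely open and a choice had to be made.

## Problem formulation

A motion-capture trial is a sequence of 3-D positions of nine lower-limb
markers (sacrum / mid-PSIS, left and right ASIS, lateral femoral condyle,
lateral malleolus, second metatarsal head) sampled at 100 Hz, with a
per-sample expert label in {FG = functional gait, FOG = freezing}.  Wand
and heel markers of the full plug-in-gait set are excluded (heel markers
sit too close to the ankle markers to add information).  The network input
is the per-sample displacement `X[t] = pos[t+1] − pos[t]` (mm/sample), so a
trial of `T` samples yields `T − 1` feature samples.

*Label alignment after differencing.*  The displacement over `[t, t+1)`
inherits the label of sample `t`.  This preserves the annotated FOG onset
index (annotation conventions anchor the onset at a heel-strike event).

*Marker gaps.*  Gaps (NaN after C3D import) are rejected by default;
an explicit `gap_fill` flag linearly interpolates gaps of at most 10
samples.  Silent interpolation would corrupt displacement magnitudes, so it
is never the default.

*Units.*  Positions stay in millimetres as stored in C3D; the input
batch-norm layer absorbs scale, so no rescaling is applied.

## Skeleton graph

The nine markers form a graph of anatomical chains: the pelvis triangle
(sacrum–L/R ASIS) and each leg's chain ASIS–knee–ankle–toe (8 edges).  The
1-hop neighborhood with self-loops is partitioned into root / centripetal /
centrifugal subsets by comparing hop distance to the center node, and each
binary partition matrix is row-degree normalized (`Λ_p^{-1} A_p`), with
zero-degree rows left zero.  Open choices and how they were resolved:

* **Center node = sacrum** — the trunk-most marker, standing in for the
  "gravity center" of whole-body skeleton models.
* **Row normalization rather than symmetric normalization** — matches the
  reference ST-GCN implementation this architecture family derives from.
* **Self-loops included before partitioning** (they land in the root
  subset) — required so a node retains its own features.

A consequence worth noting: with per-partition normalization, a node's
graph-convolution output under identity weights is its own value plus the
*average* of each nonempty neighbor subset — partitions are normalized
separately, not jointly.

## Network

Stage 1 (prediction generation): input BN → 1×1 channel adjustment → `L`
ST-GCN blocks (graph conv with learnable multiplicative edge masks `M_p`
initialized at 1 → BN → ReLU → acausal dilated temporal conv, kernel 3,
dilation `2^layer` → BN → ReLU → residual from the block input) → head
(mean-pool over markers → 1×1 conv → softmax).  Stages 2…S (refinement):
1×1 adjustment from the `l = 2` probability channels to `C` filters → `L`
residual dilated TCN blocks (conv → BN → ReLU → residual) → the same head
without pooling.  Refinements see *only* probabilities, never features.

Reference configuration: S = 5, L = 10, C = 64 — receptive field of one
stage spans 2·(2¹⁰ − 1) = 2046 samples of two-sided context (verified by a
perturbation probe in the tests).  Design points:

* **Spatial pooling = arithmetic mean** over the N markers (keeps scale
  stable and matches the classification head of the cited family).
* **Acausal padding** = symmetric zeros, `(k−1)·d/2` per side (offline
  assessment; both past and future context are legitimate).
* **Refinement blocks keep BN**; BN statistics are computed over valid
  (non-padded) samples only, per channel across the batch, with running
  estimates (momentum 0.1) used at inference.
* **Initialization**: fan-in uniform for all convolutions, BN γ=1 β=0,
  edge masks all-ones.
* **Variable-length batching**: trials grouped by similar length, padded to
  the batch maximum with a validity mask; BN, loss and metrics ignore
  padding, and activations are re-masked after each block so padding never
  contaminates valid samples through the convolutions.

Baselines: MS-TCN / TCN operate on the node-flattened `T × 27` input with
plain temporal convolutions (same stage layout); the Bi-LSTM stacks two
forward and two backward 64-cell layers with a per-sample head, plus a
sequence-recognition variant (final hidden states → feed-forward head) for
the 2-second sliding-window scheme (majority-vote window labels, ties
resolved to FG; window prediction assigned to the central sample; edge
samples take the nearest valid window).

### Compute engine

No deep-learning framework is used: `fogseg.autodiff` is a small
reverse-mode autodiff over numpy arrays with fused, hand-derived backward
passes for the dilated temporal convolution, the partitioned graph
convolution, masked batch-norm and the LSTM step loop.  Every backward pass
is verified against central finite differences in the test-suite.  This
keeps the package pure-Python/numpy and CPU-friendly at the trial sizes of
this domain (minutes of data at 100 Hz).

## Objective

Per stage: `L = L_cls + λ·L_T-MSE` with λ = 0.15, summed over stages.
`L_cls` is the mean negative log-probability of the true class (probabilities
clamped at 1e-8 before the log).  `L_T-MSE` is the truncated MSE of
consecutive log-probability differences `Δ_{t,c}`, truncated at τ = 4, with
the `t−1` term detached (gradient stopping, as in the reference multi-stage
training objective).  Two conventions that the defining equation leaves
open were resolved as follows:

* The normalizer averages over the `(T−1)·l` actually-summed terms (valid
  transitions × classes).  This makes the loss equal τ² exactly at and
  beyond the truncation boundary and bounds it by τ² always; normalizing by
  `T` instead of `T−1` would break that boundary identity for short
  sequences.
* "C" in the normalizer is read as the number of classes (the quantity the
  log-probabilities range over), not the filter count.

## Evaluation conventions

* **Segment F1@k**: predicted FOG segments processed in temporal order;
  a prediction is TP if its best-IoU same-class reference segment reaches
  the threshold and is not yet matched (each reference matchable once),
  otherwise FP; unmatched references are FN.  Edge conventions: both sides
  empty → F1 = 100; exactly one side empty → 0.
* **MCC** scaled to [−100, 100]; zero-denominator cases (e.g. constant
  predictions) return 0.
* **%TF** = percent FOG samples; **#FOG** = maximal FOG runs.  Per-subject
  pooling: segment counts (TP/FP/FN, #FOG) are summed across trials before
  F1; MCC over concatenated samples; %TF pooled over the concatenated
  samples of trials whose reference contains FOG (severity is conventionally
  reported on FOG trials; configurable to all trials).
* **Episode detection**: a reference episode counts as detected if at least
  one predicted FOG sample overlaps it; predicted segments overlapping no
  reference episode are FPs.
* **Agreement**: Pearson r with a Fisher-z 95% CI; strength labelled
  ≥0.8 strong, [0.6, 0.8) moderately strong, [0.3, 0.6) fair, <0.3 poor
  (the published bins leave (0.5, 0.6) unassigned; half-open upper-edge
  bins make the scale total without moving any stated boundary).  OLS of
  predictions on reference values; the association is called significant
  when the slope's 95% CI excludes zero.

## Synthetic cohorts

The generator emulates the *structure* of a standardized gait-lab FOG
protocol, not its biomechanics: multiple variable-length 100 Hz trials per
subject, quasi-periodic gait, FOG episodes with gait-event-anchored
boundaries and sub-second to multi-second durations, and a configurable
fraction of non-freezer subjects for false-positive auditing.

Kinematics are built in the velocity domain and integrated: pelvis markers
progress forward at the subject's walking speed (900–1300 mm/s) with
lateral sway and vertical bounce; leg markers add two harmonics of the
stride frequency (cadence 1.5–2.2 steps/s, amplitudes growing distally,
legs in antiphase, ±15% left/right asymmetry).  During an episode a
smoothed gate collapses the leg markers' forward velocity to ≈0; the
*akinetic* style suppresses oscillation entirely, the *trembling* style
adds a 3–8 Hz constant-velocity-amplitude oscillation (~2.5 mm/sample) to
ankle/toe markers.  Episode onsets/offsets snap to stride zero-crossings
(two candidate instants per cycle, offset strictly after onset), episode
durations are log-normal (median ≈ 2 s) clipped to 0.3–15 s, episode counts
shifted-Poisson, and Gaussian marker noise (1–2 mm SD) is added.  A planted
generator contract — mean forward toe displacement during FOG below 20% of
the non-FOG mean — is asserted in the tests, so labels are guaranteed to be
physically coupled to the kinematics.

What this does *not* model: festination, dual-task effects, turning
geometry, soft-tissue artifact, realistic joint kinematics.  Passing tests
on these cohorts demonstrates that the architecture, losses, training loop
and metrics are implemented correctly and that the pipeline can learn
displacement-collapse signatures; it does not certify clinical performance
on real patients.

## Benchmark experiment sizes

The reference experiments (`fogseg.experiments`) run on one CPU in minutes;
sizes were chosen as the smallest cohort that still exercises every
protocol component (LOSO with enrichment-free folds, freezer and
non-freezer subjects, multi-episode trials):

* cohort: 5 subjects (3 freezers, 2 non-freezers) × 3 trials of 8–14 s;
* model: reduced MS-GCN — 2 stages, 6 layers, 16 filters (receptive field
  2·(2⁶−1) = 126 samples per stage, ample for these trial lengths);
* training: 20 epochs, Adam lr 0.02, batch size 2.  The higher learning
  rate and small batch compensate for the small number of gradient updates
  available at this data scale (the reference recipe's 0.0005 over 100
  epochs presumes hundreds of trials); batch size 2 doubles the optimizer
  steps per epoch at identical cost.
* comparison: multi-stage vs single-stage trained on identical freezer
  folds with identical seeds, median over 3 replicate cohorts/seeds.

The two-trial memorization check trains the same reduced model for 200
epochs on one FOG and one non-FOG trial and requires training
F1@50 = 100 with loss < 0.05.

## Known limitations

* The autodiff engine is single-threaded numpy; the full 5×10×64 reference
  configuration trains, but slowly — the benchmark uses the reduced model.
* The C3D support is a deliberate subset (Intel byte order, float point
  data, no analog channels).
* Agreement CIs use the Fisher-z approximation, adequate for the n ≥ ~10
  paired-trial regimes it is applied to here.
* Synthetic cohorts are a correctness harness, not a clinical validation.
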
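# Methods

`shoulderseg` implements an automatic pipeline for functional shoulder
assessment with two wearable IMUs (wrist and arm, tri-axial accelerometer in
g and gyroscope in deg/s, 128 Hz): it identifies which of five functional
shoulder tasks (T1–T5, e.g. cleaning the head, placing an object on a high
shelf) a recorded sequence contains, and segments the sequence into its
three contiguous sub-task phases — A (lifting), B (hold / washing motion),
C (lowering) — with per-sample labels and boundary timings. This note
records the model, the choices that were genuinely open, and what the
synthetic experiments do and do not show.

## Pipeline

1. **Noise suppression (SWMA).** Each channel is smoothed with a
   symmetry-weighted moving average over an odd window of `m` samples
   (default 9). The default kernel gives the center sample weight
   `(m+1)/2`, intermediate neighbors weight 1, and the outermost pair
   weight 0.5 — for `m=5` the pattern `(0.5, 1, 3, 1, 0.5)/6`. The
   published description of the weights admits a second, triangular reading
   (`delta_i = delta_0 - i`, i.e. `(1, 2, 3, 2, 1)/9` for `m=5`) that
   contradicts the worked numeric pattern; we treat the worked pattern as
   authoritative and expose the triangular variant as
   `SwmaConfig(scheme="linear")`. Edge handling is unspecified in the
   source; we truncate the kernel to the available samples and renormalize
   by the present weights, which keeps every output a convex combination of
   inputs (constants are fixed points, interior linear ramps are exact).

2. **Features.** Every tri-axial sensor contributes 36 features — eight
   per-axis statistics (mean, SD, variance, max, min, range, kurtosis,
   skewness), three pairwise axis correlations, and three per-axis
   kinematic counts (velocity peaks, zero crossings, mean crossings) — for
   4 x 36 = 144 features per sequence or window. Operational choices the
   source leaves open: moments are population moments and kurtosis is the
   raw (non-excess) fourth standardized moment, matching the default of the
   common commercial toolboxes; peak counting requires prominence of at
   least 10 % of the window's range (guards against counting noise);
   crossings are strict sign changes with exact zeros attached to the
   preceding sign; correlations involving a zero-variance axis are defined
   as 0 with a warning.

3. **Feature selection (PCA).** Features are z-scored with training-fold
   mean/SD (zero SDs replaced by 1) before the eigendecomposition — the
   features mix units (g, deg/s, squared units, counts), so unstandardized
   covariance PCA would be dominated by the variance features. The retained
   dimensionality `l` is the smallest number of leading components whose
   eigenvalue share reaches `thres = 0.99`. Unstandardized PCA is available
   via `fit_pca(..., standardize=False)`.

4. **Task identification.** A 5-class sequence-level classifier: one-vs-all
   RBF-kernel SVM (default), kNN (k = 7, Euclidean), or Gini CART. SVM
   hyperparameters are not reported in the source; we use C = 1 and
   gamma = 1/(l x mean feature variance), both configurable. For the argmax
   decision the SVM's one-vs-rest decision values pass through a softmax —
   a monotone surrogate for class confidences, not calibrated
   probabilities. Ties break toward the lower-indexed class; kNN vote ties
   break first by smaller mean neighbor distance.

5. **Sub-task segmentation.** Sliding windows (default 0.2 s = 26 samples,
   50 % overlap, i.e. stride 13) are classified into A/B/C by per-task
   models (the identified task routes each sequence to its model —
   the hierarchical design; a single global model is selectable). Training
   windows take the majority ground-truth label within the window, with
   exact ties resolved to the earlier phase. A single left-to-right repair
   pass replaces any isolated window label whose two neighbors agree; the
   left neighbor is read from the evolving output so that one pass is
   exhaustive and idempotent, while a position is still only changed when
   its two original neighbors agree. Window labels then expand to a sample
   stream: the first `n_S - 1` labels emit `ss` samples each and the last
   emits `ws`, total `n_g = ws + ss*(n_S - 1)`. The trailing residue of at
   most `ss - 1` samples beyond `n_g` is excluded from sample-based
   evaluation.

6. **Evaluation.** Sample-based sensitivity/precision/F-score per class
   with macro-averaged "overall" values (micro selectable — the source does
   not say which its overall rows use), and mean absolute time error (MATE)
   of the A→B and B→C boundaries in ms. Each reference boundary matches the
   nearest predicted transition of the same type; reference boundaries with
   no same-type prediction are counted as unmatched and excluded from the
   means (the source does not define matching under fragmentation; nearest
   match is the least biased deterministic rule). Cross-validation is
   leave-one-subject-out with all fitting — standardization, PCA, both
   classifier stages — on training subjects only; the aggregate is the
   unweighted mean over folds. `mate_ab`/`mate_bc` average within type,
   `mate_overall` pools both types. Raw 144-d features are extracted once
   per sequence/window and reused across folds; extraction involves no
   cross-sequence statistics, so this caching cannot leak fold information.

## Synthetic data

No public recording of the study design exists, so a calibrated generator
stands in: 9 healthy + 9 frozen-shoulder (FS) subjects x 5 tasks = 90
sequences, each an A/B/C run at 128 Hz. Sub-task durations are drawn per
(task, phase, group) from the published duration table (e.g. FS patients
hold phase B of T2 for 7.81 ± 3.75 s) as truncated normals with floor
0.2 s; the underlying location is solved so the truncated mean equals the
tabulated mean exactly (plain truncation would bias heavy-truncation cells
upward by up to ~0.2 s and break calibration). Signals render a latent
elevation profile — raised-cosine ramp up, oscillating hold, mirrored ramp
down — through fixed per-task channel gain directions (accelerometers
follow the profile, gyroscopes its derivative; arm amplitudes are 0.6 x
wrist). FS profiles scale amplitude by 0.6 and tempo by 0.8, emulating the
slow, range-limited movement of patients. Measurement noise is white
Gaussian, SD 0.02 g (accelerometer) and 2 deg/s (gyroscope) — ordinary
consumer-IMU noise floors. The source reports no signal-amplitude
statistics, so all amplitudes are free parameters of the simulator, chosen
once and documented here.

**What passing on this generator shows — and does not.** The motifs are
smooth parametric templates, not biomechanics: phases differ in derivative
sign and frequency content, tasks differ in channel gain direction and
duration pattern. Synthetic recovery therefore validates the *pipeline
machinery* (feature pipeline, PCA bookkeeping, window/label algebra,
fold hygiene, metric definitions) and shows the classifiers can exploit
class structure when it exists. It does not certify clinical performance:
real inter-subject variability, sensor placement error, gravity
reorientation artifacts and compensatory movement strategies are absent.
Accordingly the published clinical figures (87.11 % task F-score, 83.23 %
sub-task F-score, 427 ms MATE) are not reproduction targets; the synthetic
experiment at the same design scale yields higher scores (task F ≈ 99–100 %,
sub-task F ≈ 94–96 %, MATE ≈ 100–110 ms), as expected from the cleaner
class structure. One visible consequence: at the 99 % variance rule the
sub-task windows keep ~70 of 144 dimensions (white noise flattens the
eigenspectrum) where the clinical study reports fewer than 50.

## Numerical and procedural details

* Window geometry follows the 1-based inclusive convention
  (`sp = 1, ep = ws`, advance by `ss` while `ep <= n_seq`,
  `n_S = floor((n_seq - ws)/ss) + 1`); all file outputs use 0-based
  half-open intervals and say so.
* Boundary indices (in memory) are the 1-based position of the first sample
  of the new run.
* `WindowConfig.from_seconds(0.2)` rounds 25.6 samples to `ws = 26`,
  `ss = 13`.
* kNN's k is clamped to the training-set size on tiny folds.
* Degenerate inputs are rejected with descriptive errors: even SWMA
  windows, sequences shorter than one window, single-class training sets,
  sub-task models missing a class (the error names task and class), empty
  task lists.
* Determinism: the generator is fully seeded (`SeedSequence` spawning per
  subject); the pipeline itself is deterministic given training data, and
  LOSO sorts sequences by (subject, task) so results are invariant to input
  order.
* Problem sizes: the bundled tests run the full 90-sequence LOSO once with
  the default SVM/0.2 s configuration and exercise everything else on small
  fixtures; duration calibration uses 1200–1500 draws per table cell, which
  puts three standard errors at ≈ 0.1–0.3 s for the widest cells.

## Known limitations

* The generator's task signatures are linearly separable by design;
  hyperparameter sensitivity (C, gamma, k) is not meaningfully exercised by
  it.
* MATE fold aggregation averages per-fold means (matching the
  fold-averaging described for the cross-validation); a pooled-boundary
  aggregate would weight subjects by sequence count instead. Within a fold,
  `mate_overall` pools boundaries.
* The rule-based repair corrects only isolated single-window errors;
  two-window fragments survive, as in the source design.
* `sensor_features` on very short windows (< ~10 samples) yields noisy
  kurtosis/skewness; the default 0.2 s window (26 samples) is above that
  regime.
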
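# shoulderseg

Automatic functional shoulder-task identification and sub-task segmentation
from two wearable IMUs, for objective frozen-shoulder assessment.

Clinical evaluation of shoulder function often asks a patient to perform
standard tasks — cleaning the head, reaching a high shelf, reaching the back
pocket — while an examiner manually marks start/end times and task identity
on the sensor trace. `shoulderseg` automates that labeling from two inertial
measurement units (wrist and arm; tri-axial accelerometer in g and gyroscope
in deg/s, sampled at 128 Hz): it identifies which of five functional tasks
T1–T5 a recorded sequence contains, and segments the sequence into its three
contiguous phases — A (lifting), B (hold/washing motion), C (lowering) —
with per-sample labels and boundary timings. It is aimed at movement-analysis
and digital-health researchers who need reproducible, objective task labels
for shoulder assessment, and ships a calibrated synthetic-signal generator so
the whole pipeline is testable without clinical recordings.

## Method

For a 12-channel sequence $S = \{s_i\}_{i=1}^{n_{seq}}$:

1. **SWMA smoothing** — each channel is filtered with a symmetry-weighted
   moving average over $m = 9$ samples; for $m = 5$ the weights are
   $(0.5, 1, 3, 1, 0.5)/6$ (center weight $(m{+}1)/2$, outermost pair 0.5).
2. **Features** — each of the 4 tri-axial sensors yields 36 statistical and
   kinematic features (mean, SD, variance, max, min, range, kurtosis,
   skewness, axis correlations, velocity-peak / zero-crossing /
   mean-crossing counts): 144 features total.
3. **PCA selection** — features are z-scored and projected onto the first
   $l$ principal components, with $l$ the smallest value satisfying
   $\sum_{i\le l}\lambda_i / \sum_i \lambda_i \ge 0.99$.
4. **Task identification** — a one-vs-all RBF SVM (or kNN with $k=7$, or
   Gini CART) assigns the label with maximal confidence,
   $\hat c = \arg\max_c p(c \mid \hat F, \theta)$.
5. **Sub-task segmentation** — sliding windows ($ws = 0.2$ s, 50 % overlap,
   so stride $ss = ws/2$) are classified into A/B/C by a per-task model;
   an isolated window label whose two neighbors agree is repaired to the
   neighbor label; window labels expand to a sample stream of length
   $n_g = ws + ss\,(n_S - 1)$.
6. **Evaluation** — leave-one-subject-out cross-validation reporting
   per-class and macro sensitivity, precision, F-score
   ($F = 2sp/(s{+}p)$), and the mean absolute time error (MATE, ms) of the
   A→B and B→C boundaries.

See `docs/methods.md` for the full model description, parameter defaults,
and what the synthetic experiments do and do not demonstrate.

## Worked example

```python
import shoulderseg as ss

# simulate a small cohort: 3 healthy + 3 frozen-shoulder subjects, 5 tasks each
dataset = ss.generate_dataset(n_healthy=3, n_fs=3, seed=42)
seq = dataset[0]
phases = {str(k): round(v, 2) for k, v in seq.subtask_durations_s().items()}
print(f"{len(dataset)} sequences; {seq.subject_id} {seq.task_id}: "
      f"{seq.n_samples} samples, phase durations (s) {phases}")

result = ss.loso_cv(dataset)  # defaults: SVM, 0.2 s windows, 50 % overlap
print(result.summary())
```

prints

```
30 sequences; H01 T1: 615 samples, phase durations (s) {'A': 1.03, 'B': 2.54, 'C': 1.23}
LOSO cross-validation over 6 subjects
task identification:   sensitivity 100.00 %  precision 100.00 %  F-score 100.00 %
sub-task segmentation: sensitivity  87.42 %  precision  89.63 %  F-score  88.13 %
boundary timing:       MATE_AB   181.2 ms  MATE_BC   111.7 ms  overall   145.5 ms  (unmatched 4)
```

Every simulated task was identified correctly; 88 % of individual samples
received the correct phase label; predicted phase boundaries land on average
~150 ms from the reference, with 4 of 60 reference boundaries having no
same-type predicted transition (excluded from the means and reported).

The same flow is available from the shell:

```sh
shoulderseg simulate --healthy 9 --fs 9 --seed 1 --out data/
shoulderseg evaluate --model svm --ws 0.2 data/ results/
shoulderseg sweep --ws-grid 0.1:1.5:0.1 data/ sweep.csv
```

plus `preprocess`, `train-task`, `train-subtask`, `identify`, and `segment`
for the individual stages.

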
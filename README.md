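# posturekit

Whole-body posture capture and work-task recognition from body-worn
IMU/MARG nodes.

Office-ergonomics and light-environment studies need to know *what a seated
worker is doing* — reciting, reading, browsing, or relaxing to music —
without cameras. `posturekit` implements the full sensing-to-recognition
chain for a suit of 9-axis nodes (3-axis accelerometer in g, gyroscope in
deg/s, magnetometer in gauss, nominally 400 Hz):

1. **Sensor calibration.** Magnetometer hard-iron offsets and per-axis scale
   errors are recovered by least-squares fitting of the axis-aligned
   ellipsoid ``(Hx−ex)²/a² + (Hy−ey)²/b² + (Hz−ez)²/c² = R²``; gyro and
   accelerometer biases come from an initial still interval.
2. **Orientation fusion.** The static attitude follows from gravity and the
   tilt-compensated magnetic field (roll = atan2(a_y, a_z),
   pitch = asin(−a_x/g), yaw = −atan2(h_Gy, h_Gx)); during motion a
   gradient-descent complementary filter (Madgwick-style) integrates the
   gyro quaternion rate ``q̇ = ½ q ⊗ (0, ω)`` and corrects it with
   ``−β ∇f/‖∇f‖``, where *f* stacks the gravity and magnetic alignment
   objectives ``f(q, n_G, n_S) = vec(q* ⊗ (0,n_G) ⊗ q) − n_S``.
3. **Skeleton reconstruction.** A 15-segment rigid tree rooted at the pelvis
   propagates endpoint positions depth-first,
   ``D₁ = D₀ + q ⊗ (0, l·û) ⊗ q*``, and joint flexion angles (breast BF,
   waist WF, shoulder SF, elbow EF, knee KF) are the inverse cosine of
   adjacent segment vectors.
4. **Recognition.** Joint-angle series are cut into 1000 ms windows with 50%
   overlap, 23 time/frequency/autoregressive features are extracted per
   channel, and five classifiers (logistic regression, decision tree, RBF
   SVM, random forest, KNN) are selected by 10-fold cross-validation and
   scored on a held-out test split (weighted precision/recall/F1,
   micro-averaged ROC-AUC and AUPRC).

A built-in simulator (`posturekit.simulate`) scripts ground-truth segment
trajectories, inverts the measurement models (gravity-reaction
accelerometer, field magnetometer through the inverse calibration map, gyro
from exact quaternion increments) and injects biases and white noise, so the
whole chain is testable without recorded data.

## Worked example

Run the five-classifier evaluation on the default synthetic four-task
dataset (100 windows per class, seed 7):

```sh
$ posturekit classify --seed 7 --windows-per-class 100 --out report.json
logistic_regression    acc 1.0000  f1 1.0000  auc 1.0000  auprc 1.0000
decision_tree          acc 1.0000  f1 1.0000  auc 1.0000  auprc 1.0000
svm                    acc 1.0000  f1 1.0000  auc 1.0000  auprc 1.0000
random_forest          acc 1.0000  f1 1.0000  auc 1.0000  auprc 1.0000
knn                    acc 1.0000  f1 1.0000  auc 1.0000  auprc 1.0000
report -> report.json
```

Each row is one classifier family's held-out test performance. The default
task recipes are separable by construction (distinct mean postures and sway
waveforms per task), so accuracies sit at the ceiling; shrinking the
between-class separation or the window budget (e.g.
`--windows-per-class 40`) starts to expose the weaker families — at 40
windows per class the decision tree drops to 0.91 accuracy while the margin-
and ensemble-based families stay at 1.0.

The full chain — simulate ten worn nodes, calibrate, fuse, reconstruct the
skeleton, extract features, classify — runs with:

```sh
posturekit run-all --seed 7 --out run/
```

which writes `node_*.csv`, `cal_*.yaml`, `track_*.csv`, `angles.csv`,
`features.csv` and `report.json` into `run/`. Library use mirrors the CLI:

```python
from posturekit import generate_task_dataset, build_dataset, evaluate_classifiers

data = generate_task_dataset(100, seed=7)      # label -> joint-angle series
windows = build_dataset(data)                  # 400 windows x 184 features
report = evaluate_classifiers(windows, seed=7)
print(report.metrics["random_forest"]["accuracy"])
```

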
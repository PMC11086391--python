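# rotometry

Markerless estimation of the shoulder internal/external rotation angle from
the 2D landmarks a pose estimator extracts from ordinary frontal video.

Shoulder rotation (humerus turning about its long axis, arm at the side,
elbow flexed 90°) is the hardest shoulder motion to measure from in front:
the motion happens almost entirely along the camera axis, so no single
projected angle exposes it, and the clinical gold standard — a handheld
goniometer — cannot be used during movement. `rotometry` is for
biomechanics, sports-medicine and rehabilitation researchers who want to
turn per-frame 33-landmark pose-estimator output into a rotation angle in
degrees, and to validate that pipeline end to end on synthetic data with
exactly known ground truth.

## Method

Each video frame supplies five landmarks in normalized image coordinates
(x/width, y/height ∈ [0, 1], y down): both shoulders, right elbow, right
wrist, right hip. Four difference vectors are formed —

* **a** = right shoulder → right elbow (upper arm)
* **b** = right elbow → right wrist (forearm)
* **c** = right shoulder → right hip (trunk)
* **d** = left shoulder → right shoulder (shoulder line)

— and seven scale-free features are computed per frame:

| feature | definition |
|---|---|
| `norm_elbow_size` | (**a** × **b**) / ‖**c**‖² |
| `norm_shoulder_size` | (**a** × **d**) / ‖**c**‖² |
| `norm_forearm_distance` | ‖**b**‖ / ‖**c**‖ |
| `norm_uparm_distance` | ‖**a**‖ / ‖**c**‖ |
| `elbow_angle` | ∠(shoulder–elbow–wrist) |
| `shoulder_angle` | ∠(elbow–shoulder–wrist) |
| `trunk_angle` | ∠(left shoulder–right shoulder–hip) |

`norm_elbow_size` is the key quantity: a *signed* parallelogram area
(upper arm × forearm) normalized by squared trunk length. In frontal view
it tracks sin θ of the rotation angle — negative for internal, positive
for external rotation — which is what makes the angle recoverable from a
head-on camera at all. A regression model (ordinary least squares, elastic
net, RBF-kernel SVR, random forest, or LightGBM gradient boosting) maps
the seven features to the angle in degrees; agreement is scored by Pearson
r and mean absolute error on held-out frames, with per-angle residual
tables, gain-share feature importance and exact SHAP attributions for
interpretation.

Because real annotated video of this protocol is not redistributable, the
package includes a forward-kinematic simulator: a rigid skeleton
(anthropometric segment ratios, 5% between-subject variation) holds each
target angle from −50° to +50° in 10° steps with 1° wobble, is projected
through a pinhole camera 2 m away at 1.5 m height, and receives Gaussian
landmark jitter — yielding fully labeled datasets of the same shape and
size (≈10,560 frames) as the emulated acquisition protocol.

## Worked example

```python
from rotometry import (ModelSpec, SimulationPlan, build_report,
                       extract_feature_table, fit, simulate, split)

feats = extract_feature_table(simulate(SimulationPlan(n_subjects=4, seed=9)))
ds = split(feats, fraction_test=0.2, seed=7, unit="frame")
print(f"{len(ds.train)} training / {len(ds.test)} test frames")
for algo in ("ordinary_least_squares", "gradient_boosted_trees"):
    model = fit(ModelSpec(algorithm=algo, seed=0), ds.train)
    r = build_report(model, ds.test)
    print(f"{algo:26s} r = {r.pearson_r:.4f}   MAE = {r.mae_deg:.3f} deg")
```

prints

```
3379 training / 845 test frames
ordinary_least_squares     r = 0.9901   MAE = 3.457 deg
gradient_boosted_trees     r = 0.9952   MAE = 1.985 deg
```

The linear model is limited by the sin-θ curvature of the feature–angle
relation; the boosted trees absorb it and roughly halve the error. Longer
narrative scripts — simulation, feature geometry, training/evaluation,
model explanation, and the one-call pipeline — live in `examples/`, and the
same stages are available from the shell:

```bash
rotometry run --config run.yaml --out rundir     # or: simulate / features / train / evaluate
```

Every pipeline run writes a `manifest.json` recording seeds, resolved
hyperparameters, row counts and output digests, so a run can be reproduced
byte-for-byte.

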
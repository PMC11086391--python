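# Methods

This note documents the models, conventions, defaults and numerical
choices behind `rotometry`, and what its synthetic validation does and
does not establish about real video.

## Problem and coordinate conventions

The quantity estimated is the glenohumeral internal/external rotation
angle θ with the arm at the side and the elbow flexed 90°: θ = 0 when the
forearm points straight anterior (toward a frontal camera), θ < 0 for
internal rotation (forearm swinging toward the trunk midline), θ > 0 for
external. Input frames are tables of named 2D landmarks in *normalized
image coordinates*: x divided by image width, y by image height, both in
[0, 1], y increasing downward — the dialect 33-landmark pose estimators
emit. Only five landmarks are used (both shoulders, right elbow, right
wrist, right hip); any others are carried through file round trips
untouched. The normalized coordinates are anisotropic whenever the image
is not square; features are computed in that raw space deliberately, so
that values are directly comparable to what a practitioner gets from
estimator output. An `image_aspect` argument to `compute_features` can
undo the anisotropy when isotropic geometry is wanted, but it defaults
off.

Frames are assumed non-mirrored (subject's right at smaller image x). The
two signed features flip sign under mirroring, so a pipeline must use a
consistent handedness convention; the file formats intentionally carry no
mirroring flag because estimator output carries none either.

## The seven features

With a = upper arm, b = forearm, c = trunk, d = shoulder line (difference
vectors of the five landmarks), the features are a×b/‖c‖², a×d/‖c‖²,
‖b‖/‖c‖, ‖a‖/‖c‖, and the interior angles at the elbow
(shoulder–elbow–wrist), at the shoulder (elbow–shoulder–wrist) and at the
right shoulder of the trunk triangle (left shoulder–right
shoulder–hip), in degrees.

Design choices:

* **Cross products stay signed.** The magnitude of a×b is the
  parallelogram area spanned by upper arm and forearm; its sign encodes
  which side of the upper-arm line the wrist falls on, which is exactly
  the internal-vs-external distinction. Taking |·| would fold θ and −θ
  onto each other.
* **Trunk normalization.** Dividing by ‖c‖² (areas) or ‖c‖ (lengths)
  removes subject size and overall image scale. All seven features are
  invariant under translation and uniform scaling of the landmark set,
  and the two signed features are antisymmetric under mirroring —
  properties enforced by tests on 1,000 random frames.
* **Angles via atan2.** Interior angles are computed as
  `atan2(|u×v|, u·v)`, stable near 0° and 180° where the arccos form
  loses precision.
* **Degenerate geometry.** A zero-length trunk or arm segment makes a
  feature undefined; such frames raise a dedicated error, and batch
  extraction either skips them (with a count in `DataFrame.attrs`) or
  rejects, per configuration.

## Synthetic data generator

The simulator is the stand-in for the acquisition protocol it emulates:
10 adult subjects standing 2 m from a camera at 1.5 m height, 11 target
angles from −50° to +50° in 10° steps, a few seconds of 30 fps video per
target (96 frames per clip by default).
It is first-class, tested code, because every quantitative claim the
package makes is measured on its output.

**Skeleton.** Rigid segments with standard anthropometric ratios scaled
to stature H = 1.683 m (the emulated cohort mean): trunk (shoulder→hip)
0.288·H, biacromial width 0.245·H, upper arm 0.186·H, forearm 0.146·H,
acromion height 0.818·H. Stature is the only anthropometric quantity
available for the cohort, and published segment-ratio tables are the
least arbitrary way to complete it. Per subject, each segment length is
drawn once with a 5% coefficient of variation (clipped to ±50% as a
physical guard).

**Pose.** Trunk and upper arm vertical; the forearm, perpendicular to the
humerus, rotates about the vertical humeral axis:
wrist = elbow + L·(−sin θ, 0, cos θ) in a world frame with y up, z toward
the camera, x the subject's left. Scapulothoracic rhythm, trunk sway and
soft-tissue artifact are outside scope.

**Camera.** Default pinhole projection, 65° horizontal field of view,
portrait 1080×1920 aspect, at (0, 1.5 m, 2.0 m) looking horizontally at
the subject plane — a plausible tablet-camera geometry for the stated
distances. An orthographic mode (fixed 2.5 m-wide metric window, a field
the projection needs but the protocol does not determine) is retained
because it has clean closed-form properties: depth invariance, exact
distance invariance of the features, and `norm_elbow_size` exactly
proportional to sin θ per subject.

**Noise.** Two stochastic terms per frame: the held angle wobbles around
the clip target (Gaussian, sd 1.0°; the per-frame value is recorded as the
ground truth, since a person cannot hold a pose exactly), and every
projected coordinate receives iid Gaussian jitter (sd 0.002 normalized
units) approximating pose-estimator noise, then is clamped to [0, 1].
Temporal correlation of estimator noise, landmark dropouts and left/right
swaps are not modeled — there is no public data from this protocol to
calibrate them. Consequently the synthetic task is *cleaner* than real
video: passing the accuracy bounds here shows the geometry, features and
models are implemented correctly and that the pipeline can recover angles
at realistic noise scales, not that any given phone video will reach the
same accuracy.

**Size.** 96 frames per clip × 11 angles × 10 subjects = 10,560 frames,
matching the scale of the emulated dataset (≈10.6k frames). The default
simulation runs in about a second, so the full-size experiment is also
the test-suite experiment; no scaled-down surrogate is needed.

## Regression models

Five algorithms, with tuned reference hyperparameters as defaults:
ordinary least squares; elastic net (α = 10⁻⁵, l1_ratio = 0.889);
RBF-kernel support-vector regression (C = 10.0, γ = 0.0046); random
forest (squared-error criterion, max depth 6, 10 trees); LightGBM
gradient boosting (MAE objective, learning rate 0.076, max depth 8).
Unlisted hyperparameters keep the underlying implementation's defaults
and are recorded verbatim in the run manifest. Two deliberate deviations:

* The "linear regression" entry is plain ordinary least squares. (A
  regularized-classifier parameterization sometimes quoted for it —
  penalty/C/solver — does not describe a regressor.)
* Elastic net's `max_iter` is raised to 50,000: at α = 10⁻⁵ on the raw
  feature scale (angles up to 180°), the coordinate-descent solver does
  not reach its tolerance within the default 1,000 iterations.

Features are deliberately *not* standardized: the reference γ and α
values assume the raw feature ranges.

Splitting is frame-level by default (seed recorded), matching the
per-image accounting of the emulated experiment; clip-level and
subject-level group splits are provided because frame-level splitting
leaks near-duplicate neighboring frames between train and test, which
flatters all models. The target is the per-frame true angle (target +
wobble), i.e. the quantity an angle sensor strapped to the forearm would
have recorded, not the nominal clip label.

All fits are single-threaded with fixed seeds and are bit-reproducible.

## Evaluation battery

* **Agreement**: Pearson product-moment correlation between predicted and
  true angles (the standard regression-agreement choice) and MAE in
  degrees, both on the held-out split.
* **Residuals**: actual − predicted, summarized per design angle by mean
  and *sample* (n−1) standard deviation; size-1 groups report SD 0 with a
  flag. The grouping key is the nominal clip target.
* **Correlation structure**: the 8×8 Pearson matrix over the seven
  features plus the angle; constant columns yield flagged-undefined
  (NaN) entries rather than a crash.
* **Importance**: per tree, each feature's share of total split gain;
  shares averaged over trees, so values sum to 1. For random forests this
  coincides with averaging per-tree normalized impurity importances.
* **SHAP**: for LightGBM models, the exact path-dependent TreeSHAP built
  into LightGBM (`pred_contrib`); for other ensembles, exact
  *interventional* Shapley values by full enumeration of all 2⁷ = 128
  feature coalitions against a background sample (≤ 64 rows by default).
  With seven features, enumeration is cheap and removes any sampling
  error; both routes satisfy local accuracy (base + Σ contributions =
  prediction) to machine precision, which the tests assert at 10⁻⁶.

## Measured properties and known limitations

* **Mechanism.** With all stochastic terms at zero and an orthographic
  frontal camera, `norm_elbow_size` is strictly increasing in θ over
  [−50°, 50°] and correlates with sin θ at r = 1 to floating point. With
  between-subject anthropometric variation left on, the pooled
  feature–sin θ correlation drops to ≈ 0.99 because the per-subject
  proportionality constant (upper-arm·forearm/trunk²) varies.
* **Distance invariance is approximate under perspective.** Trunk
  normalization cancels in-plane scale exactly (orthographic: exact;
  pinhole with a coplanar pose: exact). But the forearm points out of the
  subject plane, and perspective foreshortening of that out-of-plane
  segment depends on absolute camera distance: over 1.5–3 m the signed
  area feature drifts by a few percent of its value at |θ| ≥ 30° and more
  near its zero crossing. The tests pin this down (≤ 10% relative drift
  at |θ| ≥ 30°) rather than asserting exact invariance.
* **Model ordering.** On the default noisy dataset the tree ensembles
  beat the linear models (MAE ≈ 1.3° vs ≈ 3.2°), as expected from the
  sin-θ curvature. The kernel SVR does *not* beat the linear baseline
  here: its frozen C/γ were tuned for real recordings, and re-tuning is
  out of scope, so no ordering is asserted for it.
* **Attribution.** `norm_elbow_size` ranks first in both gain importance
  and mean |SHAP| for the boosted model on default synthetic data. This
  is asserted as a property of the simulation, not as a claim about human
  data.
* **Accuracy bounds.** Under the default study conditions (simulation
  seed 42, split seed 7), held-out accuracy is r = 0.998 / MAE = 1.27°
  (boosted) and r = 0.991 / MAE = 3.18° (least squares); with the
  landmark jitter switched off, the boosted model reaches r = 0.9997 /
  MAE = 0.44°. Across arbitrary seeds the boosted MAE varies roughly
  between 1.4° and 1.8° — the irreducible error set by jitter sd 0.002
  against a forearm arc of ≈ 0.004 normalized units per degree.
* The simulator emits only the five landmarks it models; visibility
  scores, z-coordinates and the remaining 28 landmarks of the pose
  vocabulary are accepted in input files but never used.
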
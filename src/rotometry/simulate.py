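"""Forward-kinematic synthetic landmark generation.

The acquisition protocol this emulates: a subject stands facing a camera placed 2 m
away at 1.5 m height, right arm at the side with the elbow flexed 90°, and
holds the shoulder at each of eleven target rotation angles from −50° to
+50° in 10° steps (internal rotation negative) while ~2 s of video is
recorded at 30 fps. The simulator reproduces that geometry with a minimal
rigid skeleton, projects the five landmarks of interest through a camera
model, and adds landmark jitter of the kind a pose estimator produces —
giving tables with exactly known ground truth for every frame.

World frame: y up (meters above the floor), z toward the camera (anterior,
since the subject faces it), x completing a right-handed frame (the
subject's left; the subject's right side therefore lands at smaller image x,
i.e. non-mirrored video). At rotation ``theta`` the forearm of length ``L``
points ``L * (-sin(theta), 0, cos(theta))`` from the elbow: straight at the
camera at 0°, laterally (external) for positive theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, OutOfFrameError
from .landmarks import LandmarkFrame, LandmarkTable

Role = str

#: Design target angles: −50..50 in 10° steps, internal rotation negative.
DEFAULT_ANGLES_DEG: tuple[float, ...] = tuple(float(a) for a in range(-50, 51, 10))


@dataclass(frozen=True)
class SkeletonConfig:
    """Rigid segment lengths of the simulated subject, in meters."""

    trunk_length_m: float = 0.4847
    shoulder_width_m: float = 0.4123
    upper_arm_length_m: float = 0.3130
    forearm_length_m: float = 0.2457
    shoulder_height_m: float = 1.3767

    def __post_init__(self) -> None:
        for name in (
            "trunk_length_m",
            "shoulder_width_m",
            "upper_arm_length_m",
            "forearm_length_m",
            "shoulder_height_m",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    @classmethod
    def from_stature(cls, stature_m: float = 1.683) -> "SkeletonConfig":
        """Standard anthropometric segment ratios scaled to a stature.

        Ratios: trunk (shoulder→hip) 0.288·H, biacromial width 0.245·H,
        upper arm 0.186·H, forearm 0.146·H, acromion height 0.818·H.
        The default stature 1.683 m matches the emulated cohort's mean height.
        """
        h = stature_m
        return cls(
            trunk_length_m=0.288 * h,
            shoulder_width_m=0.245 * h,
            upper_arm_length_m=0.186 * h,
            forearm_length_m=0.146 * h,
            shoulder_height_m=0.818 * h,
        )


@dataclass(frozen=True)
class CameraModel:
    """Camera pose and projection used to turn 3D poses into landmarks.

    ``pinhole`` divides by depth with the stated horizontal field of view
    (the realistic choice); ``orthographic`` drops the depth axis and maps a
    fixed metric window of width ``ortho_view_width_m`` onto the image —
    useful because it has clean closed-form properties. ``image_aspect`` is
    width:height; the default 0.5625 is portrait 1080×1920.
    """

    distance_m: float = 2.0
    height_m: float = 1.5
    projection: str = "pinhole"
    horizontal_fov_deg: float = 65.0
    image_aspect: float = 1080.0 / 1920.0
    ortho_view_width_m: float = 2.5

    def __post_init__(self) -> None:
        if self.distance_m <= 0:
            raise ConfigError("distance_m must be > 0")
        if self.projection not in ("pinhole", "orthographic"):
            raise ConfigError(f"unknown projection {self.projection!r}")
        if self.projection == "pinhole" and not (0 < self.horizontal_fov_deg < 180):
            raise ConfigError("horizontal_fov_deg must be in (0, 180)")
        if self.image_aspect <= 0 or self.ortho_view_width_m <= 0:
            raise ConfigError("image_aspect and ortho_view_width_m must be > 0")


@dataclass(frozen=True)
class SimulationPlan:
    """Study-design parameters for one synthetic dataset.

    Defaults are the emulated study conditions: 10 subjects, 11 target
    angles from −50° to +50° in 10° steps, 96 frames per clip (≈10,560
    frames total), landmark jitter with
    sd 0.002 normalized units, 5% anthropometric coefficient of variation
    between subjects, and 1° sd of within-clip wobble around each target.
    """

    n_subjects: int = 10
    angles_deg: tuple[float, ...] = DEFAULT_ANGLES_DEG
    frames_per_clip: int = 96
    landmark_noise_sd: float = 0.002
    anthropometric_cv: float = 0.05
    angle_hold_sd_deg: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.frames_per_clip < 1 or not self.angles_deg:
            raise ConfigError("plan needs >= 1 subject, angle and frame per clip")
        angles = tuple(float(a) for a in self.angles_deg)
        if list(angles) != sorted(angles):
            raise ConfigError("angles_deg must be sorted ascending")
        if any(abs(a) > 90 for a in angles):
            raise ConfigError("target angles must lie in [-90, 90] degrees")
        if min(self.landmark_noise_sd, self.anthropometric_cv, self.angle_hold_sd_deg) < 0:
            raise ConfigError("noise magnitudes must be >= 0")
        object.__setattr__(self, "angles_deg", angles)


def pose_3d(skeleton: SkeletonConfig, theta_deg: float) -> dict[Role, np.ndarray]:
    """3D positions (meters, world frame) of the five landmarks at ``theta``.

    Trunk and upper arm are vertical; the forearm is perpendicular to the
    humerus (90° elbow flexion) and rotated ``theta`` about the vertical
    humeral axis — pointing at the camera at 0°, laterally for positive
    (external) rotation.
    """
    if abs(theta_deg) > 90:
        raise ConfigError("|theta_deg| must be <= 90")
    th = math.radians(theta_deg)
    hw = skeleton.shoulder_width_m / 2.0
    hs = skeleton.shoulder_height_m
    right_shoulder = np.array([-hw, hs, 0.0])
    left_shoulder = np.array([hw, hs, 0.0])
    right_hip = right_shoulder + np.array([0.0, -skeleton.trunk_length_m, 0.0])
    right_elbow = right_shoulder + np.array([0.0, -skeleton.upper_arm_length_m, 0.0])
    right_wrist = right_elbow + skeleton.forearm_length_m * np.array(
        [-math.sin(th), 0.0, math.cos(th)]
    )
    return {
        "left_shoulder": left_shoulder,
        "right_shoulder": right_shoulder,
        "right_elbow": right_elbow,
        "right_wrist": right_wrist,
        "right_hip": right_hip,
    }


def project(
    points3d: dict[Role, np.ndarray], camera: CameraModel
) -> dict[Role, tuple[float, float]]:
    """Project world-frame 3D points to normalized image coordinates.

    Returns (x, y) in [0, 1]² with y increasing downward. Raises
    :class:`~rotometry.errors.OutOfFrameError` naming any role that falls
    outside the frame (or, for pinhole, behind the camera).
    """
    out: dict[Role, tuple[float, float]] = {}
    bad: list[str] = []
    if camera.projection == "pinhole":
        tan_h = math.tan(math.radians(camera.horizontal_fov_deg) / 2.0)
        tan_v = tan_h / camera.image_aspect
        for role, p in points3d.items():
            depth = camera.distance_m - p[2]
            if depth <= 0:
                raise OutOfFrameError(f"{role} is behind the camera (depth {depth:.3f} m)")
            x = 0.5 + (p[0] / depth) / (2.0 * tan_h)
            y = 0.5 - ((p[1] - camera.height_m) / depth) / (2.0 * tan_v)
            out[role] = (x, y)
            if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
                bad.append(role)
    else:
        w = camera.ortho_view_width_m
        h = w / camera.image_aspect
        for role, p in points3d.items():
            x = 0.5 + p[0] / w
            y = 0.5 - (p[1] - camera.height_m) / h
            out[role] = (x, y)
            if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
                bad.append(role)
    if bad:
        raise OutOfFrameError("landmark(s) project outside the frame: " + ", ".join(bad))
    return out


def _perturbed_skeleton(
    base: SkeletonConfig, cv: float, rng: np.random.Generator
) -> SkeletonConfig:
    """Draw one subject's segment lengths with coefficient of variation cv."""
    names = (
        "trunk_length_m",
        "shoulder_width_m",
        "upper_arm_length_m",
        "forearm_length_m",
        "shoulder_height_m",
    )
    factors = 1.0 + cv * rng.standard_normal(len(names))
    factors = np.clip(factors, 0.5, 1.5)  # keep lengths physical at extreme draws
    return replace(base, **{n: getattr(base, n) * f for n, f in zip(names, factors)})


def simulate(
    plan: SimulationPlan,
    skeleton_base: SkeletonConfig | None = None,
    camera: CameraModel | None = None,
) -> LandmarkTable:
    """Generate a fully labeled synthetic :class:`LandmarkTable`.

    Per subject, segment lengths are drawn once with the plan's
    anthropometric coefficient of variation. Per frame, the true angle is
    the clip target plus Gaussian wobble (recorded as ``true_angle_deg``),
    and every projected coordinate is perturbed by iid Gaussian jitter then
    clamped to [0, 1]. Fully reproducible from ``plan.seed``.
    """
    skeleton_base = skeleton_base or SkeletonConfig.from_stature()
    camera = camera or CameraModel()
    rng = np.random.default_rng(plan.seed)
    frames: list[LandmarkFrame] = []
    roles = ("left_shoulder", "right_shoulder", "right_elbow", "right_wrist", "right_hip")
    for s in range(plan.n_subjects):
        skel = _perturbed_skeleton(skeleton_base, plan.anthropometric_cv, rng)
        for target in plan.angles_deg:
            clip_id = f"angle{target:+05.0f}"
            for i in range(plan.frames_per_clip):
                theta = target
                if plan.angle_hold_sd_deg > 0:
                    theta = target + rng.normal(0.0, plan.angle_hold_sd_deg)
                theta = float(np.clip(theta, -90.0, 90.0))
                pts2d = project(pose_3d(skel, theta), camera)
                if plan.landmark_noise_sd > 0:
                    noise = rng.normal(0.0, plan.landmark_noise_sd, size=(len(roles), 2))
                    pts = {
                        r: (
                            float(np.clip(pts2d[r][0] + noise[j, 0], 0.0, 1.0)),
                            float(np.clip(pts2d[r][1] + noise[j, 1], 0.0, 1.0)),
                        )
                        for j, r in enumerate(roles)
                    }
                else:
                    pts = {r: (float(x), float(y)) for r, (x, y) in pts2d.items()}
                frames.append(
                    LandmarkFrame(
                        subject_id=f"S{s:02d}",
                        clip_id=clip_id,
                        frame_index=i,
                        true_angle_deg=theta,
                        points=pts,
                    )
                )
    return LandmarkTable(frames=frames, source="synthetic")


def nominal_angle_from_clip_id(clip_id: str) -> float:
    """Recover the clip's target angle from the simulator's clip naming."""
    if not clip_id.startswith("angle"):
        raise ValueError(f"clip_id {clip_id!r} does not encode a target angle")
    return float(clip_id[len("angle"):])
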
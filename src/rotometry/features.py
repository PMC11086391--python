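"""The seven geometric features computed from each landmark frame.

All features are built from four difference vectors in normalized image
coordinates (y down):

* ``a`` — right shoulder → right elbow (upper arm)
* ``b`` — right elbow → right wrist (forearm)
* ``c`` — right shoulder → right hip (trunk)
* ``d`` — left shoulder → right shoulder (shoulder line)

The four scale-free features divide by the trunk so they are invariant to
subject size and camera distance; the two cross-product features are kept
*signed* (internal rotation is negative by convention, and the sign is what
distinguishes it from external rotation). ``norm_elbow_size`` — the
parallelogram area spanned by upper arm and forearm over squared trunk
length — is the dominant feature: in frontal view it tracks sin(rotation
angle).

Features are computed in raw normalized (anisotropic) image coordinates;
no aspect-ratio correction is applied by default, matching the convention
of pose-estimator output. Pass ``image_aspect`` to undo the anisotropy if
isotropic geometry is wanted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, SchemaError
from .landmarks import LandmarkFrame, LandmarkTable

#: Feature column order used everywhere downstream.
FEATURE_NAMES: tuple[str, ...] = (
    "norm_elbow_size",
    "norm_shoulder_size",
    "norm_forearm_distance",
    "norm_uparm_distance",
    "elbow_angle",
    "shoulder_angle",
    "trunk_angle",
)

KEY_COLUMNS: tuple[str, ...] = ("subject_id", "clip_id", "frame_index", "true_angle_deg")


@dataclass(frozen=True)
class FeatureVector:
    """The seven per-frame features (angles in degrees, rest dimensionless)."""

    norm_elbow_size: float
    norm_shoulder_size: float
    norm_forearm_distance: float
    norm_uparm_distance: float
    elbow_angle: float
    shoulder_angle: float
    trunk_angle: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in FEATURE_NAMES)


def cross2d(u, v) -> float:
    """Signed z-component of the 2D cross product u × v.

    Equals ``u.x·v.y − u.y·v.x``; its magnitude is the area of the
    parallelogram spanned by the two vectors, its sign the orientation.
    """
    return float(u[0] * v[1] - u[1] * v[0])


def angle_at_vertex(p_end1, vertex, p_end2) -> float:
    """Interior angle in degrees at ``vertex`` between the two end points.

    Always in [0, 180]. Raises on a zero-length arm, where the angle is
    undefined.
    """
    u = np.asarray(p_end1, dtype=float) - np.asarray(vertex, dtype=float)
    v = np.asarray(p_end2, dtype=float) - np.asarray(vertex, dtype=float)
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length arm in angle computation")
    # atan2 of (|u×v|, u·v) is numerically stable near 0 and 180 degrees
    return math.degrees(math.atan2(abs(cross2d(u, v)), float(np.dot(u, v))))


def compute_features(
    frame: LandmarkFrame, image_aspect: float | None = None
) -> FeatureVector:
    """Compute the seven features for one frame.

    ``image_aspect`` (width:height), if given, rescales x by the aspect
    ratio to make the pixel grid isotropic before any geometry; default is
    the raw normalized convention.
    """
    p = {r: np.array(frame.points[r], dtype=float) for r in (
        "left_shoulder", "right_shoulder", "right_elbow", "right_wrist", "right_hip"
    )}
    if image_aspect is not None:
        for v in p.values():
            v[0] *= image_aspect
    a = p["right_elbow"] - p["right_shoulder"]
    b = p["right_wrist"] - p["right_elbow"]
    c = p["right_hip"] - p["right_shoulder"]
    d = p["right_shoulder"] - p["left_shoulder"]
    c2 = float(c @ c)
    if c2 == 0.0:
        raise DegenerateGeometryError(
            f"zero trunk length in frame {frame.key()}; features undefined"
        )
    return FeatureVector(
        norm_elbow_size=cross2d(a, b) / c2,
        norm_shoulder_size=cross2d(a, d) / c2,
        norm_forearm_distance=float(np.hypot(*b)) / math.sqrt(c2),
        norm_uparm_distance=float(np.hypot(*a)) / math.sqrt(c2),
        elbow_angle=angle_at_vertex(p["right_shoulder"], p["right_elbow"], p["right_wrist"]),
        shoulder_angle=angle_at_vertex(p["right_elbow"], p["right_shoulder"], p["right_wrist"]),
        trunk_angle=angle_at_vertex(p["left_shoulder"], p["right_shoulder"], p["right_hip"]),
    )


def extract_feature_table(
    table: LandmarkTable,
    image_aspect: float | None = None,
    on_degenerate: str = "skip",
) -> pd.DataFrame:
    """One feature row per frame, order-preserving.

    Degenerate frames (zero-length trunk or arm segments) are skipped with a
    count attached as ``df.attrs['n_degenerate']``, or rejected when
    ``on_degenerate='raise'``. Raises if every frame is degenerate.
    """
    if on_degenerate not in ("skip", "raise"):
        raise ValueError("on_degenerate must be 'skip' or 'raise'")
    rows: list[dict] = []
    n_degenerate = 0
    for f in table:
        try:
            fv = compute_features(f, image_aspect=image_aspect)
        except DegenerateGeometryError:
            if on_degenerate == "raise":
                raise
            n_degenerate += 1
            continue
        row = {
            "subject_id": f.subject_id,
            "clip_id": f.clip_id,
            "frame_index": f.frame_index,
            "true_angle_deg": f.true_angle_deg,
        }
        row.update(dict(zip(FEATURE_NAMES, fv.as_tuple())))
        rows.append(row)
    if len(table) > 0 and not rows:
        raise SchemaError("every frame in the table is geometrically degenerate")
    df = pd.DataFrame(rows, columns=list(KEY_COLUMNS) + list(FEATURE_NAMES))
    df.attrs["n_degenerate"] = n_degenerate
    return df
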
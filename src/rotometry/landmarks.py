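"""Per-frame 2D pose-landmark containers and file dialects.

A :class:`LandmarkFrame` holds one video frame's named landmarks in
normalized image coordinates (x divided by image width, y by image height,
both in [0, 1], y increasing downward) together with the ground-truth
shoulder rotation angle for that frame (degrees; internal rotation is
negative). Only five landmarks are required — the bilateral shoulders and
the right elbow, wrist and hip — but extra landmarks present in input files
are preserved.

Two on-disk dialects are supported:

``long_csv``
    One row per landmark per frame with columns ``subject_id, clip_id,
    frame_index, true_angle_deg, landmark_role, x, y``.

``mediapipe_json``
    One JSON object per frame carrying a 33-element landmark array of
    ``{x, y, z, visibility}`` in the public 33-landmark pose convention
    (index 11 left shoulder, 12 right shoulder, 14 right elbow, 16 right
    wrist, 24 right hip). ``z`` and ``visibility`` are ignored on read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import RangeError, SchemaError

#: Landmark roles every frame must provide.
REQUIRED_ROLES: tuple[str, ...] = (
    "left_shoulder",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
    "right_hip",
)

#: The public 33-landmark pose vocabulary, in index order.
POSE_LANDMARK_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye_inner",
    "left_eye",
    "left_eye_outer",
    "right_eye_inner",
    "right_eye",
    "right_eye_outer",
    "left_ear",
    "right_ear",
    "mouth_left",
    "mouth_right",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_pinky",
    "right_pinky",
    "left_index",
    "right_index",
    "left_thumb",
    "right_thumb",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
    "left_heel",
    "right_heel",
    "left_foot_index",
    "right_foot_index",
)

ROLE_TO_POSE_INDEX: dict[str, int] = {
    name: i for i, name in enumerate(POSE_LANDMARK_NAMES)
}

#: Decimal digits used when serializing coordinates.
COORD_DECIMALS = 9


@dataclass
class LandmarkFrame:
    """One frame's named 2D landmarks plus its ground-truth angle.

    Parameters
    ----------
    subject_id, clip_id :
        Identifiers of the recording; ``(subject_id, clip_id, frame_index)``
        is unique within a table.
    frame_index :
        Zero-based frame number within the clip.
    true_angle_deg :
        Ground-truth shoulder rotation angle in degrees; internal rotation
        negative, external positive.
    points :
        Mapping from landmark role to ``(x, y)`` in normalized image
        coordinates. Must contain at least :data:`REQUIRED_ROLES`.
    visibility :
        Optional per-role confidence scores carried through unchanged; never
        used by downstream computation.
    """

    subject_id: str
    clip_id: str
    frame_index: int
    true_angle_deg: float
    points: dict[str, tuple[float, float]]
    visibility: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise SchemaError(f"frame_index must be >= 0, got {self.frame_index}")
        if not math.isfinite(self.true_angle_deg):
            raise SchemaError(
                f"true_angle_deg must be finite in frame {self.key()}"
            )
        missing = [r for r in REQUIRED_ROLES if r not in self.points]
        if missing:
            raise SchemaError(
                f"frame {self.key()} is missing required landmark(s): "
                + ", ".join(missing)
            )
        for role, (x, y) in self.points.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise RangeError(f"non-finite coordinate for {role} in frame {self.key()}")
            if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
                raise RangeError(
                    f"coordinate for {role} outside [0, 1] in frame {self.key()}: "
                    f"({x}, {y})"
                )

    def key(self) -> tuple[str, str, int]:
        return (self.subject_id, self.clip_id, self.frame_index)


@dataclass
class LandmarkTable:
    """An ordered collection of :class:`LandmarkFrame` rows."""

    frames: list[LandmarkFrame]
    source: str = "imported"

    def __post_init__(self) -> None:
        keys = [f.key() for f in self.frames]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, str, int]] = set()
            for k in keys:
                if k in seen:
                    raise SchemaError(f"duplicate frame key {k}")
                seen.add(k)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def _clamp01(v: float) -> float:
    return min(1.0, max(0.0, v))


def _frame_from_points(
    subject_id: str,
    clip_id: str,
    frame_index: int,
    angle: float,
    pts: Mapping[str, tuple[float, float]],
    vis: Mapping[str, float],
    on_range_error: str,
) -> LandmarkFrame:
    if on_range_error not in ("reject", "clamp"):
        raise ValueError("on_range_error must be 'reject' or 'clamp'")
    if on_range_error == "clamp":
        pts = {r: (_clamp01(x), _clamp01(y)) for r, (x, y) in pts.items()}
    return LandmarkFrame(
        subject_id=str(subject_id),
        clip_id=str(clip_id),
        frame_index=int(frame_index),
        true_angle_deg=float(angle),
        points=dict(pts),
        visibility=dict(vis),
    )


def read_landmark_table(
    path: str | Path,
    dialect: str = "long_csv",
    on_range_error: str = "reject",
) -> LandmarkTable:
    """Read a landmark table from ``path`` in the named dialect.

    ``on_range_error`` controls how coordinates outside [0, 1] are handled:
    ``"reject"`` raises :class:`~rotometry.errors.RangeError`, ``"clamp"``
    clips them to the unit square.
    """
    path = Path(path)
    if dialect == "long_csv":
        return _read_long_csv(path, on_range_error)
    if dialect == "mediapipe_json":
        return _read_mediapipe_json(path, on_range_error)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_landmark_table(
    table: LandmarkTable, path: str | Path, dialect: str = "long_csv"
) -> Path:
    """Write ``table`` to ``path``; the file re-reads to an equal table."""
    path = Path(path)
    if dialect == "long_csv":
        _write_long_csv(table, path)
    elif dialect == "mediapipe_json":
        _write_mediapipe_json(table, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


# ---------------------------------------------------------------- long_csv

_CSV_COLUMNS = [
    "subject_id",
    "clip_id",
    "frame_index",
    "true_angle_deg",
    "landmark_role",
    "x",
    "y",
]


def _read_long_csv(path: Path, on_range_error: str) -> LandmarkTable:
    # round_trip parsing: re-reading a written table must be bit-exact
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "clip_id": str},
        float_precision="round_trip",
    )
    missing = set(_CSV_COLUMNS) - {"visibility"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    has_vis = "visibility" in df.columns
    frames: list[LandmarkFrame] = []
    grouped = df.groupby(["subject_id", "clip_id", "frame_index"], sort=False)
    for (sid, cid, idx), g in grouped:
        pts = {
            str(r.landmark_role): (float(r.x), float(r.y)) for r in g.itertuples()
        }
        vis = (
            {
                str(r.landmark_role): float(r.visibility)
                for r in g.itertuples()
                if pd.notna(r.visibility)
            }
            if has_vis
            else {}
        )
        angle = float(g["true_angle_deg"].iloc[0])
        frames.append(
            _frame_from_points(sid, cid, idx, angle, pts, vis, on_range_error)
        )
    return LandmarkTable(frames=frames, source="imported")


def _write_long_csv(table: LandmarkTable, path: Path) -> None:
    any_vis = any(f.visibility for f in table.frames)
    cols = _CSV_COLUMNS + (["visibility"] if any_vis else [])
    records = []
    for f in table.frames:
        for role, (x, y) in f.points.items():
            rec = {
                "subject_id": f.subject_id,
                "clip_id": f.clip_id,
                "frame_index": f.frame_index,
                "true_angle_deg": f.true_angle_deg,
                "landmark_role": role,
                "x": round(x, COORD_DECIMALS),
                "y": round(y, COORD_DECIMALS),
            }
            if any_vis:
                rec["visibility"] = f.visibility.get(role, "")
            records.append(rec)
    # Coordinates were rounded above; default float repr round-trips exactly.
    pd.DataFrame(records, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------- mediapipe_json


def _read_mediapipe_json(path: Path, on_range_error: str) -> LandmarkTable:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if not isinstance(payload, list):
        raise SchemaError(f"{path}: expected a JSON array of frame objects")
    frames: list[LandmarkFrame] = []
    for obj in payload:
        try:
            lms = obj["landmarks"]
            sid, cid, idx = obj["subject_id"], obj["clip_id"], obj["frame_index"]
            angle = obj["true_angle_deg"]
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"{path}: malformed frame object ({exc})") from exc
        if len(lms) != len(POSE_LANDMARK_NAMES):
            raise SchemaError(
                f"{path}: frame ({sid}, {cid}, {idx}) has {len(lms)} landmarks, "
                f"expected {len(POSE_LANDMARK_NAMES)}"
            )
        pts: dict[str, tuple[float, float]] = {}
        vis: dict[str, float] = {}
        for name in POSE_LANDMARK_NAMES:
            lm = lms[ROLE_TO_POSE_INDEX[name]]
            if lm is None:
                continue
            pts[name] = (float(lm["x"]), float(lm["y"]))
            if "visibility" in lm and lm["visibility"] is not None:
                vis[name] = float(lm["visibility"])
        frames.append(_frame_from_points(sid, cid, idx, angle, pts, vis, on_range_error))
    return LandmarkTable(frames=frames, source="imported")


def _write_mediapipe_json(table: LandmarkTable, path: Path) -> None:
    payload = []
    for f in table.frames:
        unknown = [r for r in f.points if r not in ROLE_TO_POSE_INDEX]
        if unknown:
            raise SchemaError(
                "mediapipe_json cannot serialize roles outside the 33-landmark "
                f"vocabulary: {unknown} in frame {f.key()}"
            )
        lms: list[dict | None] = [None] * len(POSE_LANDMARK_NAMES)
        for role, (x, y) in f.points.items():
            lms[ROLE_TO_POSE_INDEX[role]] = {
                "x": round(x, COORD_DECIMALS),
                "y": round(y, COORD_DECIMALS),
                "z": 0.0,
                "visibility": f.visibility.get(role, 1.0),
            }
        payload.append(
            {
                "subject_id": f.subject_id,
                "clip_id": f.clip_id,
                "frame_index": f.frame_index,
                "true_angle_deg": f.true_angle_deg,
                "landmarks": lms,
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def frames_equal(a: LandmarkFrame, b: LandmarkFrame, tol: float = 0.0) -> bool:
    """Field-by-field equality of two frames, coordinates within ``tol``."""
    if a.key() != b.key():
        return False
    if abs(a.true_angle_deg - b.true_angle_deg) > tol:
        return False
    if set(a.points) != set(b.points):
        return False
    return all(
        abs(a.points[r][0] - b.points[r][0]) <= tol
        and abs(a.points[r][1] - b.points[r][1]) <= tol
        for r in a.points
    )
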
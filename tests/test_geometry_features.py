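"""The seven per-frame geometric features and their invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rotometry import (
    DegenerateGeometryError,
    LandmarkFrame,
    LandmarkTable,
    SchemaError,
    angle_at_vertex,
    compute_features,
    cross2d,
    extract_feature_table,
)
from rotometry.features import FEATURE_NAMES
from rotometry.landmarks import REQUIRED_ROLES

# Hand-worked reference frame: every feature evaluated from the definitions.
HAND_FRAME_POINTS = {
    "left_shoulder": (0.40, 0.40),
    "right_shoulder": (0.60, 0.40),
    "right_elbow": (0.60, 0.55),
    "right_wrist": (0.72, 0.55),
    "right_hip": (0.60, 0.70),
}
HAND_FRAME_EXPECTED = {
    "norm_elbow_size": -0.20,  # (0*0 - 0.15*0.12) / 0.30^2
    "norm_shoulder_size": -1.0 / 3.0,  # (0*0 - 0.15*0.20) / 0.09
    "norm_forearm_distance": 0.40,  # 0.12 / 0.30
    "norm_uparm_distance": 0.50,  # 0.15 / 0.30
    "elbow_angle": 90.0,
    "shoulder_angle": math.degrees(math.atan2(0.12, 0.15)),  # 38.6598...
    "trunk_angle": 90.0,
}


def frame_from(points, angle=0.0, sid="s", cid="c", idx=0):
    return LandmarkFrame(sid, cid, idx, angle, dict(points))


class TestCross2d:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((1, 0), (0, 1), 1.0),  # unit basis, right-handed
            ((2, 0), (6, 0), 0.0),  # collinear
            ((0, 0.15), (0.12, 0), -0.018),  # 0*0 - 0.15*0.12
        ],
    )
    def test_signed_area(self, u, v, expected):
        assert cross2d(u, v) == pytest.approx(expected, abs=1e-15)

    def test_antisymmetry(self):
        assert cross2d((0.3, 0.7), (0.2, -0.1)) == -cross2d((0.2, -0.1), (0.3, 0.7))


class TestAngleAtVertex:
    @pytest.mark.parametrize(
        "p1, v, p2, expected",
        [
            ((0, -1), (0, 0), (1, 0), 90.0),
            ((1, 0), (0, 0), (2, 0), 0.0),
            ((-1, 0), (0, 0), (1, 0), 180.0),
            ((0, 0.15), (0, 0), (0.12, 0.15), math.degrees(math.atan2(0.12, 0.15))),
        ],
    )
    def test_interior_angle(self, p1, v, p2, expected):
        assert angle_at_vertex(p1, v, p2) == pytest.approx(expected, abs=1e-9)

    def test_zero_length_arm_raises(self):
        with pytest.raises(DegenerateGeometryError):
            angle_at_vertex((0.5, 0.5), (0.5, 0.5), (1, 0))


class TestComputeFeatures:
    def test_hand_worked_frame_reproduces_all_seven(self):
        fv = compute_features(frame_from(HAND_FRAME_POINTS))
        for name in FEATURE_NAMES:
            assert getattr(fv, name) == pytest.approx(
                HAND_FRAME_EXPECTED[name], abs=1e-9
            ), name

    def test_collinear_wrist_zeroes_signed_area(self):
        pts = dict(HAND_FRAME_POINTS, right_wrist=(0.60, 0.65))  # on shoulder-elbow line
        fv = compute_features(frame_from(pts))
        assert fv.norm_elbow_size == 0.0
        assert fv.elbow_angle in (pytest.approx(0.0, abs=1e-9), pytest.approx(180.0, abs=1e-9))

    def test_zero_trunk_raises_naming_frame(self):
        pts = dict(HAND_FRAME_POINTS, right_hip=HAND_FRAME_POINTS["right_shoulder"])
        with pytest.raises(DegenerateGeometryError, match="trunk"):
            compute_features(frame_from(pts, sid="S07"))


def random_valid_points(rng):
    """Random nondegenerate frame in the unit square."""
    while True:
        pts = {r: tuple(rng.uniform(0.2, 0.8, 2)) for r in REQUIRED_ROLES}
        a = np.subtract(pts["right_elbow"], pts["right_shoulder"])
        b = np.subtract(pts["right_wrist"], pts["right_elbow"])
        c = np.subtract(pts["right_hip"], pts["right_shoulder"])
        d = np.subtract(pts["right_shoulder"], pts["left_shoulder"])
        if min(map(np.linalg.norm, (a, b, c, d))) > 1e-3:
            return pts


@pytest.fixture(scope="module")
def random_frames():
    rng = np.random.default_rng(2718)
    return [random_valid_points(rng) for _ in range(1000)]


class TestInvariances:
    """Translation/scale invariance and mirror antisymmetry, 1,000 frames."""

    @staticmethod
    def transform(pts, fn):
        return {r: tuple(fn(np.asarray(p))) for r, p in pts.items()}

    def test_translation_invariance(self, random_frames):
        rng = np.random.default_rng(1)
        for pts in random_frames:
            off = rng.uniform(-0.15, 0.15, 2)
            fv0 = compute_features(frame_from(pts))
            fv1 = compute_features(frame_from(self.transform(pts, lambda p: p + off)))
            assert fv1.as_tuple() == pytest.approx(fv0.as_tuple(), abs=1e-9)

    def test_scale_invariance_about_any_center(self, random_frames):
        rng = np.random.default_rng(2)
        for pts in random_frames:
            s = rng.uniform(0.3, 1.2)
            center = rng.uniform(0.3, 0.7, 2)
            fv0 = compute_features(frame_from(pts))
            fv1 = compute_features(
                frame_from(self.transform(pts, lambda p: center + s * (p - center)))
            )
            assert fv1.as_tuple() == pytest.approx(fv0.as_tuple(), abs=1e-8)

    def test_mirror_antisymmetry(self, random_frames):
        for pts in random_frames:
            fv0 = compute_features(frame_from(pts))
            fv1 = compute_features(
                frame_from(self.transform(pts, lambda p: np.array([1.0 - p[0], p[1]])))
            )
            assert fv1.norm_elbow_size == pytest.approx(-fv0.norm_elbow_size, abs=1e-9)
            assert fv1.norm_shoulder_size == pytest.approx(-fv0.norm_shoulder_size, abs=1e-9)
            for name in FEATURE_NAMES[2:]:
                assert getattr(fv1, name) == pytest.approx(getattr(fv0, name), abs=1e-9)


class TestExtractFeatureTable:
    def test_row_count_matches_frames_and_order(self, tiny_table, tiny_features):
        assert len(tiny_features) == len(tiny_table)
        keys_in = [(f.subject_id, f.clip_id, f.frame_index) for f in tiny_table]
        keys_out = list(
            tiny_features[["subject_id", "clip_id", "frame_index"]].itertuples(
                index=False, name=None
            )
        )
        assert keys_in == keys_out

    def test_empty_table_gives_empty_output(self):
        df = extract_feature_table(LandmarkTable(frames=[]))
        assert len(df) == 0
        assert list(df.columns[-7:]) == list(FEATURE_NAMES)

    def test_deterministic(self, tiny_table, tiny_features):
        again = extract_feature_table(tiny_table)
        assert again.equals(tiny_features)

    def test_degenerate_frames_skipped_and_counted(self):
        good = frame_from(HAND_FRAME_POINTS, idx=0)
        bad = frame_from(
            dict(HAND_FRAME_POINTS, right_hip=HAND_FRAME_POINTS["right_shoulder"]), idx=1
        )
        df = extract_feature_table(LandmarkTable(frames=[good, bad]))
        assert len(df) == 1
        assert df.attrs["n_degenerate"] == 1
        with pytest.raises(DegenerateGeometryError):
            extract_feature_table(
                LandmarkTable(frames=[good, bad]), on_degenerate="raise"
            )

    def test_all_degenerate_raises(self):
        bad = frame_from(
            dict(HAND_FRAME_POINTS, right_hip=HAND_FRAME_POINTS["right_shoulder"])
        )
        with pytest.raises(SchemaError, match="degenerate"):
            extract_feature_table(LandmarkTable(frames=[bad]))


@settings(max_examples=50, deadline=None)
@given(
    theta=st.floats(-50, 50, allow_nan=False),
    scale=st.floats(0.5, 1.5, allow_nan=False),
)
def test_signed_area_scales_with_sine_in_closed_form(theta, scale):
    """In an idealized frontal view the parallelogram area over squared trunk
    is (upper_arm*forearm/trunk^2)*sin(theta), independent of uniform scale."""
    ua, fa, trunk = 0.15 * scale, 0.12 * scale, 0.3 * scale
    rs = np.array([0.6, 0.3])
    pts = {
        "left_shoulder": tuple(rs + [-0.2 * scale, 0.0]),
        "right_shoulder": tuple(rs),
        "right_elbow": tuple(rs + [0.0, ua]),
        "right_wrist": tuple(rs + [fa * math.sin(math.radians(theta)), ua]),
        "right_hip": tuple(rs + [0.0, trunk]),
    }
    b_len = abs(fa * math.sin(math.radians(theta)))
    if b_len < 1e-6:
        return  # wrist collapses onto elbow; angle features undefined
    fv = compute_features(frame_from(pts))
    expected = -ua * fa * math.sin(math.radians(theta)) / trunk**2
    assert fv.norm_elbow_size == pytest.approx(expected, abs=1e-12)
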
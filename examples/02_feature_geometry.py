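"""Compute the seven geometric features for a single landmark frame.

The features are built from four difference vectors: upper arm a (right
shoulder→elbow), forearm b (elbow→wrist), trunk c (right shoulder→hip) and
shoulder line d (left→right shoulder). Dividing by the trunk makes them
independent of subject size and camera distance; keeping the cross products
signed is what separates internal (negative) from external (positive)
rotation.
"""

from rotometry import LandmarkFrame, compute_features

frame = LandmarkFrame(
    subject_id="demo",
    clip_id="clip0",
    frame_index=0,
    true_angle_deg=0.0,
    points={
        "left_shoulder": (0.40, 0.40),
        "right_shoulder": (0.60, 0.40),
        "right_elbow": (0.60, 0.55),
        "right_wrist": (0.72, 0.55),
        "right_hip": (0.60, 0.70),
    },
)
fv = compute_features(frame)

print("feature               value     meaning")
print(f"norm_elbow_size       {fv.norm_elbow_size:+.4f}   signed parallelogram area"
      " (upper arm x forearm) / trunk^2")
print(f"norm_shoulder_size    {fv.norm_shoulder_size:+.4f}   signed area"
      " (upper arm x shoulder line) / trunk^2")
print(f"norm_forearm_distance {fv.norm_forearm_distance:+.4f}   forearm length / trunk length")
print(f"norm_uparm_distance   {fv.norm_uparm_distance:+.4f}   upper-arm length / trunk length")
print(f"elbow_angle           {fv.elbow_angle:7.2f}   deg at the elbow"
      " (shoulder-elbow-wrist)")
print(f"shoulder_angle        {fv.shoulder_angle:7.2f}   deg at the shoulder"
      " (elbow-shoulder-wrist)")
print(f"trunk_angle           {fv.trunk_angle:7.2f}   deg at the right shoulder"
      " (left shoulder-right shoulder-hip)")
print()
print("norm_elbow_size is negative here: the wrist sits on the subject's left of")
print("the upper-arm line in image coordinates, the signature of internal rotation.")
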
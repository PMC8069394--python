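"""Skeleton joint indexing.

The depth camera delivers 25 joints per frame. The indicator equations only
pin down ten of them (upper-trunk reference, spine middle, shoulders, hips,
knees, ankles); the remaining names follow the standard 25-joint skeleton of
the sensor and are marked "assumed" in the docs.
"""

from __future__ import annotations

N_JOINTS = 25

# Anchors used by the indicator equations.
UPPER_TRUNK = 2      # upper-trunk reference (trunk flexion)
SHOULDER_LEFT = 3
SHOULDER_RIGHT = 5
SPINE_MID = 7        # vertical trajectory, COM
HIP_RIGHT = 17
HIP_LEFT = 19
KNEE_LEFT = 20
KNEE_RIGHT = 21
ANKLE_LEFT = 22
ANKLE_RIGHT = 24

#: index -> anatomical name; anchors fixed, the rest assumed.
JOINT_NAMES: dict[int, str] = {
    0: "head",
    1: "neck",
    2: "spine_shoulder",
    3: "shoulder_left",
    4: "elbow_left",
    5: "shoulder_right",
    6: "elbow_right",
    7: "spine_mid",
    8: "wrist_left",
    9: "hand_left",
    10: "wrist_right",
    11: "hand_right",
    12: "hand_tip_left",
    13: "thumb_left",
    14: "hand_tip_right",
    15: "thumb_right",
    16: "spine_base",
    17: "hip_right",
    18: "foot_right",
    19: "hip_left",
    20: "knee_left",
    21: "knee_right",
    22: "ankle_left",
    23: "foot_left",
    24: "ankle_right",
}

# Joints that must be present for each indicator family; frames missing one of
# these contribute a NaN to that indicator only.
TRUNK_JOINTS = (UPPER_TRUNK, SPINE_MID)
SHOULDER_JOINTS = (SHOULDER_LEFT, SHOULDER_RIGHT)
COM_JOINTS = (SPINE_MID, HIP_RIGHT, HIP_LEFT)
LEG_LEFT = (HIP_LEFT, KNEE_LEFT, ANKLE_LEFT)
LEG_RIGHT = (HIP_RIGHT, KNEE_RIGHT, ANKLE_RIGHT)


def validate_joint_map(names: dict[int, str]) -> None:
    """Check a joint-index map covers exactly 0..24 with unique indices."""
    if sorted(names) != list(range(N_JOINTS)):
        raise ValueError("joint map must cover exactly indices 0..24")
    if len(set(names.values())) != N_JOINTS:
        raise ValueError("joint names must be unique")


validate_joint_map(JOINT_NAMES)
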
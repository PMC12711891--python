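"""Bundled demonstration skeletal model.

A 14-body full-body model echoing the segment list of common gait/running
models: pelvis, torso (head included), and three-segment arms and legs on both
sides.  Geometry is authored so that the all-zero (rest) pose is a standing
T-pose with the pelvis center 0.95 m above the ground and arms along ±X.

26 generalized coordinates: a 6-DOF pelvis-to-ground free joint, 2-DOF lumbar,
3-DOF hips, 2-DOF shoulders, and 1-DOF knees, ankles, elbows and wrists.
Ranges are radians (rotations) or meters (root translations), loosely modeled
on physiological ranges of motion.
"""
from __future__ import annotations

import numpy as np

from .skeletal_model import (
    BodySegment,
    Coordinate,
    Dof,
    Joint,
    SkeletalModel,
    VirtualMarker,
)

_X = (1.0, 0.0, 0.0)
_Y = (0.0, 1.0, 0.0)
_Z = (0.0, 0.0, 1.0)

_PI = float(np.pi)


def demo_model() -> SkeletalModel:
    """Build the bundled 14-body / 26-coordinate demonstration model."""
    bodies = [BodySegment(n) for n in [
        "pelvis", "torso",
        "femur_r", "tibia_r", "foot_r",
        "femur_l", "tibia_l", "foot_l",
        "humerus_r", "radius_r", "hand_r",
        "humerus_l", "radius_l", "hand_l",
    ]]

    coords = [
        Coordinate("pelvis_tilt", -_PI / 2, _PI / 2),
        Coordinate("pelvis_list", -_PI / 2, _PI / 2),
        Coordinate("pelvis_rotation", -_PI, _PI),
        Coordinate("pelvis_tx", -3.0, 3.0),
        Coordinate("pelvis_ty", -1.0, 2.0),
        Coordinate("pelvis_tz", -3.0, 3.0),
        Coordinate("lumbar_extension", -_PI / 4, _PI / 4),
        Coordinate("lumbar_bending", -_PI / 4, _PI / 4),
    ]
    for side, sign in (("r", 1.0), ("l", -1.0)):
        coords += [
            Coordinate(f"hip_flexion_{side}", -2.1, 2.1),
            Coordinate(f"hip_adduction_{side}", -0.87, 0.87),
            Coordinate(f"hip_rotation_{side}", -0.7, 0.7),
            Coordinate(f"knee_angle_{side}", -2.1, 0.17),
            Coordinate(f"ankle_angle_{side}", -0.7, 0.7),
            Coordinate(f"arm_flex_{side}", -_PI / 2, _PI),
            Coordinate(f"arm_add_{side}", -2.0, 0.5) if side == "r"
            else Coordinate(f"arm_add_{side}", -0.5, 2.0),
            Coordinate(f"elbow_flex_{side}", 0.0, 2.62) if side == "r"
            else Coordinate(f"elbow_flex_{side}", -2.62, 0.0),
            Coordinate(f"wrist_flex_{side}", -1.22, 1.22),
        ]
    # keep declared count/order tidy: interleave is fine, names are unique

    joints = [
        Joint("ground_pelvis", "ground", "pelvis",
              location_in_parent=(0.0, 0.95, 0.0), location_in_child=(0.0, 0.0, 0.0),
              dofs=[
                  Dof("pelvis_tilt", "rotation", _Z),
                  Dof("pelvis_list", "rotation", _X),
                  Dof("pelvis_rotation", "rotation", _Y),
                  Dof("pelvis_tx", "translation", _X),
                  Dof("pelvis_ty", "translation", _Y),
                  Dof("pelvis_tz", "translation", _Z),
              ]),
        Joint("back", "pelvis", "torso",
              location_in_parent=(0.0, 0.08, 0.0), location_in_child=(0.0, 0.0, 0.0),
              dofs=[
                  Dof("lumbar_extension", "rotation", _Z),
                  Dof("lumbar_bending", "rotation", _X),
              ]),
    ]
    for side, sx in (("r", 1.0), ("l", -1.0)):
        joints += [
            Joint(f"hip_{side}", "pelvis", f"femur_{side}",
                  location_in_parent=(sx * 0.09, -0.07, 0.0), location_in_child=(0.0, 0.0, 0.0),
                  dofs=[
                      Dof(f"hip_flexion_{side}", "rotation", _X),
                      Dof(f"hip_adduction_{side}", "rotation", _Z),
                      Dof(f"hip_rotation_{side}", "rotation", _Y),
                  ]),
            Joint(f"knee_{side}", f"femur_{side}", f"tibia_{side}",
                  location_in_parent=(0.0, -0.42, 0.0), location_in_child=(0.0, 0.0, 0.0),
                  dofs=[Dof(f"knee_angle_{side}", "rotation", _X)]),
            Joint(f"ankle_{side}", f"tibia_{side}", f"foot_{side}",
                  location_in_parent=(0.0, -0.43, 0.0), location_in_child=(0.0, 0.0, 0.0),
                  dofs=[Dof(f"ankle_angle_{side}", "rotation", _X)]),
            Joint(f"shoulder_{side}", "torso", f"humerus_{side}",
                  location_in_parent=(sx * 0.18, 0.30, 0.0), location_in_child=(0.0, 0.0, 0.0),
                  dofs=[
                      Dof(f"arm_flex_{side}", "rotation", _X),
                      Dof(f"arm_add_{side}", "rotation", _Z),
                  ]),
            Joint(f"elbow_{side}", f"humerus_{side}", f"radius_{side}",
                  location_in_parent=(sx * 0.28, 0.0, 0.0), location_in_child=(0.0, 0.0, 0.0),
                  dofs=[Dof(f"elbow_flex_{side}", "rotation", _Z)]),
            Joint(f"wrist_{side}", f"radius_{side}", f"hand_{side}",
                  location_in_parent=(sx * 0.25, 0.0, 0.0), location_in_child=(0.0, 0.0, 0.0),
                  dofs=[Dof(f"wrist_flex_{side}", "rotation", _Z)]),
        ]

    markers = [
        VirtualMarker("RASI", "pelvis", (0.09, 0.02, 0.11)),
        VirtualMarker("LASI", "pelvis", (-0.09, 0.02, 0.11)),
        VirtualMarker("C7", "torso", (0.0, 0.28, -0.08)),
        VirtualMarker("STRN", "torso", (0.0, 0.15, 0.12)),
        VirtualMarker("RKNE", "femur_r", (0.05, -0.42, 0.0)),
        VirtualMarker("LKNE", "femur_l", (-0.05, -0.42, 0.0)),
        VirtualMarker("RANK", "tibia_r", (0.04, -0.43, 0.0)),
        VirtualMarker("LANK", "tibia_l", (-0.04, -0.43, 0.0)),
        VirtualMarker("RWRA", "radius_r", (0.25, 0.03, 0.0)),
        VirtualMarker("LWRA", "radius_l", (-0.25, 0.03, 0.0)),
    ]

    return SkeletalModel(name="skelsynth_demo", bodies=bodies, joints=joints,
                         coordinates=coords, markers=markers)
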
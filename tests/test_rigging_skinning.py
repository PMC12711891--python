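"""Armature construction, skinning weights, LBS deformation."""
import numpy as np
import pytest

import skelsynth as ss
from skelsynth.avatar_mesh import TriangleMesh
from skelsynth.rigging_skinning import (
    Armature,
    Bone,
    WeightMatrix,
    segment_endpoints,
)


# -- armature construction ----------------------------------------------------

def test_segment_bone_spans_parent_to_distal_joint(model, rest, armature):
    centers = ss.joint_centers(model, rest)
    femur = armature.bone("femur_r")
    np.testing.assert_allclose(femur.head, centers["hip_r"], atol=1e-12)
    np.testing.assert_allclose(femur.tail, centers["knee_r"], atol=1e-12)


def test_branching_torso_tail_is_shoulder_midpoint(model, rest, armature):
    centers = ss.joint_centers(model, rest)
    torso = armature.bone("torso")
    mid = (centers["shoulder_r"] + centers["shoulder_l"]) / 2
    np.testing.assert_allclose(torso.tail, mid, atol=1e-12)


def test_leaf_bodies_continue_fixed_distance(model, rest, armature):
    hand = armature.bone("hand_r")
    assert hand.length == pytest.approx(0.12, abs=1e-9)
    # continuation follows the incoming chain direction (+X for the right arm)
    np.testing.assert_allclose((hand.tail - hand.head) / hand.length, [1, 0, 0],
                               atol=1e-9)


def test_control_bones_share_head_and_parent_segment_bones(model, armature):
    for b in model.bodies:
        seg = armature.bone(armature.body_to_segment[b.name])
        ctrl = armature.bone(armature.body_to_control[b.name])
        assert ctrl.kind == "control"
        assert seg.parent == ctrl.name
        np.testing.assert_allclose(ctrl.head, seg.head, atol=1e-12)
        assert ctrl.length == pytest.approx(0.10, abs=1e-9)


def test_connector_spans_gap_between_chain_bones(armature):
    # torso tail (shoulder midpoint) != humerus head (shoulder) -> connector
    conn = armature.bone("torso_to_humerus_r_connector")
    assert conn.kind == "connector"
    assert conn.origin_body == "torso"
    torso = armature.bone("torso")
    humerus = armature.bone("humerus_r")
    np.testing.assert_allclose(conn.head, torso.tail, atol=1e-12)
    np.testing.assert_allclose(conn.tail, humerus.head, atol=1e-12)


def test_no_connector_where_chain_is_continuous(armature):
    names = [b.name for b in armature.bones]
    assert "femur_r_to_tibia_r_connector" not in names


def test_connectors_span_every_tail_head_gap():
    """When a bone's tail (branch midpoint) differs from the next bone's head,
    a connector bone must span exactly that gap."""
    from skelsynth.skeletal_model import (
        BodySegment, Coordinate, Dof, Joint, SkeletalModel)
    m = SkeletalModel(
        name="branching",
        bodies=[BodySegment("trunk"), BodySegment("armA"), BodySegment("armB")],
        joints=[
            Joint("ground_t", "ground", "trunk", (0, 0, 0), (0, 0, 0), []),
            Joint("shA", "trunk", "armA", (0.2, 0.5, 0), (0, 0, 0),
                  dofs=[Dof("qa", "rotation", (0, 0, 1))]),
            Joint("shB", "trunk", "armB", (-0.2, 0.5, 0), (0, 0, 0),
                  dofs=[Dof("qb", "rotation", (0, 0, 1))]),
        ],
        coordinates=[Coordinate("qa", -1, 1), Coordinate("qb", -1, 1)], markers=[])
    rest = ss.rest_transforms(m)
    arm = ss.build_armature(m, rest)
    # trunk tail = midpoint of the two shoulder centers = (0, 0.5, 0)
    np.testing.assert_allclose(arm.bone("trunk").tail, [0, 0.5, 0], atol=1e-12)
    conn = sorted((b for b in arm.bones if b.kind == "connector"), key=lambda b: b.name)
    assert len(conn) == 2
    for c, child in zip(conn, ["armA", "armB"]):
        assert c.origin_body == "trunk"
        np.testing.assert_allclose(c.head, arm.bone("trunk").tail, atol=1e-12)
        np.testing.assert_allclose(c.tail, arm.bone(child).head, atol=1e-12)


def test_zero_length_bone_rejected():
    with pytest.raises(Exception):
        Bone(name="z", kind="segment", head=(0, 0, 0), tail=(0, 0, 0))


# -- weights ------------------------------------------------------------------

def _two_bone_armature():
    b0 = Bone("c0", "control", (0, 0, 0), (0, 0.1, 0))
    s0 = Bone("b0", "segment", (0, 0, 0), (1, 0, 0), parent="c0")
    b1 = Bone("c1", "control", (0, 0, 2), (0, 0.1, 2))
    s1 = Bone("b1", "segment", (0, 0, 2), (1, 0, 2), parent="c1")
    return Armature(bones=[b0, s0, b1, s1],
                    body_to_segment={"b0": "b0", "b1": "b1"},
                    body_to_control={"b0": "c0", "b1": "c1"},
                    rest_global={b.name: np.eye(4) for b in (b0, s0, b1, s1)})


def test_vertex_on_bone_axis_dominates():
    arm = _two_bone_armature()
    mesh = TriangleMesh(vertices=[[0.5, 0.0, 0.0]], faces=np.empty((0, 3)))
    with pytest.warns(UserWarning, match="no weighted vertices"):  # b1 gets none
        w = ss.compute_weights(mesh, arm)
    assert w.column("b0")[0] > 0.99


def test_equidistant_vertex_splits_evenly():
    arm = _two_bone_armature()
    mesh = TriangleMesh(vertices=[[0.5, 0.0, 1.0]], faces=np.empty((0, 3)))
    w = ss.compute_weights(mesh, arm)
    np.testing.assert_allclose(w.matrix[0], [0.5, 0.5], atol=1e-12)


def test_weight_rows_sum_to_one(weights):
    np.testing.assert_allclose(weights.matrix.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(weights.matrix >= 0)


def test_connector_transfer_conserves_mass(small_avatar, armature):
    """Raw inverse-square mass per vertex is preserved by the connector
    transfer step (recomputed here from bone geometry, pre-normalization)."""
    from skelsynth.rigging_skinning import (
        WEIGHT_EPS, WEIGHT_TRUNCATE, _point_segment_distance)
    bones = armature.segment_bones + armature.connector_bones
    V = small_avatar.vertices
    raw = np.empty((len(V), len(bones)))
    for k, b in enumerate(bones):
        d = _point_segment_distance(V, b.head, b.tail)
        raw[:, k] = 1.0 / (d * d + WEIGHT_EPS)
    raw[raw < WEIGHT_TRUNCATE * raw.max(axis=1, keepdims=True)] = 0.0
    total_before = raw.sum(axis=1)

    w = ss.compute_weights(small_avatar, armature)
    # un-normalize: reconstruct transferred mass via the same normalizer
    transferred = raw[:, :len(armature.segment_bones)].copy()
    seg_index = {b.name: i for i, b in enumerate(armature.segment_bones)}
    for k, b in enumerate(armature.connector_bones):
        transferred[:, seg_index[b.origin_body]] += raw[:, len(armature.segment_bones) + k]
    np.testing.assert_allclose(transferred.sum(axis=1), total_before, rtol=1e-12)
    np.testing.assert_allclose(
        w.matrix, transferred / transferred.sum(axis=1, keepdims=True), atol=1e-12)


def test_every_segment_owns_vertices_on_demo_avatar(model, weights):
    assign = ss.assign_vertices(weights)
    counts = np.bincount(assign, minlength=len(weights.bodies))
    for body, count in zip(weights.bodies, counts):
        assert count > 0, f"segment {body} owns no vertices"


def test_assign_vertices_argmax_and_tie_rule():
    w = WeightMatrix(matrix=[[0.7, 0.3], [0.5, 0.5], [0.2, 0.8]], bodies=["a", "b"])
    np.testing.assert_array_equal(ss.assign_vertices(w), [0, 0, 1])


# -- skinning transforms & LBS ------------------------------------------------

def test_rest_pose_skinning_transforms_are_identity(model, rest, armature):
    skin = ss.skinning_transforms(armature, rest, rest)
    for T in skin.values():
        np.testing.assert_allclose(T, np.eye(4), atol=1e-12)


def test_control_bone_equivalence_on_random_poses(model, rest, armature):
    """S_b == T_body(pose) . T_body(rest)^-1 to 1e-9 for every body and pose."""
    rng = np.random.default_rng(21)
    for _ in range(10):
        T = ss.forward_kinematics(model, ss.random_pose(model, rng))
        skin = ss.skinning_transforms(armature, T, rest)
        for b in model.bodies:
            expected = T[b.name] @ np.linalg.inv(rest[b.name])
            assert np.max(np.abs(skin[b.name] - expected)) < 1e-9


def test_single_joint_rotation_moves_tail_keeps_center(model, rest, armature):
    pose = model.zero_pose()
    pose["knee_angle_r"] = -np.pi / 2
    T = ss.forward_kinematics(model, pose)
    skin = ss.skinning_transforms(armature, T, rest)
    tibia = armature.bone("tibia_r")
    # the knee joint center is fixed by this rotation
    np.testing.assert_allclose(skin["tibia_r"][:3, :3] @ tibia.head + skin["tibia_r"][:3, 3],
                               tibia.head, atol=1e-9)
    # the ankle end swings by 90 degrees about X: -Y direction becomes +Z or -Z
    moved_tail = skin["tibia_r"][:3, :3] @ tibia.tail + skin["tibia_r"][:3, 3]
    np.testing.assert_allclose(np.linalg.norm(moved_tail - tibia.head),
                               tibia.length, atol=1e-9)
    assert abs(moved_tail[2] - tibia.head[2]) > 0.9 * tibia.length


def test_distal_body_skinning_matches_chained_fk(model, rest, armature):
    pose = model.zero_pose()
    pose["hip_flexion_r"] = 0.7
    pose["knee_angle_r"] = -0.9
    T = ss.forward_kinematics(model, pose)
    skin = ss.skinning_transforms(armature, T, rest)
    expected = T["tibia_r"] @ np.linalg.inv(rest["tibia_r"])
    np.testing.assert_allclose(skin["tibia_r"], expected, atol=1e-9)


def test_lbs_identity_transforms_leave_mesh_unchanged(small_avatar, weights):
    skin = {b: np.eye(4) for b in weights.bodies}
    out = ss.deform_mesh(small_avatar, weights, skin)
    np.testing.assert_allclose(out.vertices, small_avatar.vertices, atol=1e-12)
    np.testing.assert_array_equal(out.faces, small_avatar.faces)


def test_lbs_weight_one_vertex_moves_rigidly():
    arm = _two_bone_armature()
    mesh = TriangleMesh(vertices=[[0.5, 0.0, 0.0]], faces=np.empty((0, 3)))
    with pytest.warns(UserWarning, match="no weighted vertices"):
        w = ss.compute_weights(mesh, arm)
    S = np.eye(4)
    S[:3, 3] = [0.0, 1.0, 0.0]
    out = ss.deform_mesh(mesh, WeightMatrix(matrix=[[1.0, 0.0]], bodies=w.bodies),
                         {"b0": S, "b1": np.eye(4)})
    np.testing.assert_allclose(out.vertices[0], [0.5, 1.0, 0.0], atol=1e-12)


def test_lbs_common_rigid_motion_recovered(small_avatar, weights):
    """All bones under the same rigid T -> whole mesh rigidly transformed by T."""
    from scipy.spatial.transform import Rotation
    T = np.eye(4)
    T[:3, :3] = Rotation.from_euler("xyz", [0.3, -1.1, 0.7]).as_matrix()
    T[:3, 3] = [0.5, -0.2, 1.4]
    out = ss.deform_mesh(small_avatar, weights, {b: T for b in weights.bodies})
    expected = small_avatar.vertices @ T[:3, :3].T + T[:3, 3]
    assert np.max(np.linalg.norm(out.vertices - expected, axis=1)) < 1e-9


def test_deform_dimension_mismatch_rejected(small_avatar, weights):
    short = TriangleMesh(vertices=small_avatar.vertices[:10], faces=np.empty((0, 3)))
    with pytest.raises(ValueError):
        ss.deform_mesh(short, weights, {b: np.eye(4) for b in weights.bodies})


def test_armature_json_serialization(armature):
    import json
    data = json.loads(armature.to_json())
    assert len(data) == len(armature.bones)
    kinds = {d["kind"] for d in data}
    assert kinds == {"segment", "control", "connector"}
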
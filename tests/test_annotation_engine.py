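"""Bounding boxes, collision shapes, ray-cast occlusion counting, frame annotation."""
import numpy as np
import pytest

import skelsynth as ss
from skelsynth.annotation_engine import CollisionShape, build_collision_shapes
from skelsynth.avatar_mesh import TriangleMesh
from skelsynth.camera_geometry import Camera
from skelsynth.errors import DegenerateGeometryError


def _cube_mesh(center=(0, 0, 0), half=0.5):
    c = np.asarray(center, float)
    verts = c + half * np.array([[x, y, z] for x in (-1, 1) for y in (-1, 1)
                                 for z in (-1, 1)], float)
    return TriangleMesh(vertices=verts, faces=np.empty((0, 3)))


def _shapes_for_clouds(clouds):
    """CollisionShapeSet over point clouds, each its own body, identity rest."""
    verts = np.vstack(clouds)
    assignment = np.concatenate([[f"b{i}"] * len(c) for i, c in enumerate(clouds)])
    rest = {f"b{i}": np.eye(4) for i in range(len(clouds))}
    mesh = TriangleMesh(vertices=verts, faces=np.empty((0, 3)))
    return build_collision_shapes(mesh, assignment, rest), rest


# -- 3D bounding boxes --------------------------------------------------------

def test_bbox3d_unit_cube_step_one():
    corners = ss.bbox_3d(_cube_mesh(half=0.5), step=1)
    assert corners.shape == (8, 3)
    np.testing.assert_allclose(corners.min(axis=0), [-0.5] * 3)
    np.testing.assert_allclose(corners.max(axis=0), [0.5] * 3)


def test_bbox3d_large_step_samples_only_first_vertex():
    mesh = _cube_mesh()
    corners = ss.bbox_3d(mesh, step=25)  # only index 0 is sampled
    np.testing.assert_allclose(corners, np.tile(mesh.vertices[0], (8, 1)))


def test_bbox3d_subsampled_contained_in_full(small_avatar):
    full = ss.bbox_3d(small_avatar, step=1)
    for step in (2, 5, 17):
        sub = ss.bbox_3d(small_avatar, step=step)
        assert np.all(sub.min(axis=0) >= full.min(axis=0) - 1e-12)
        assert np.all(sub.max(axis=0) <= full.max(axis=0) + 1e-12)


def test_bbox3d_explicit_subset_replaces_stride(small_avatar):
    idx = [0, 5, 10]
    corners = ss.bbox_3d(small_avatar, step=999, subset=idx)
    pts = small_avatar.vertices[idx]
    np.testing.assert_allclose(corners.min(axis=0), pts.min(axis=0))
    np.testing.assert_allclose(corners.max(axis=0), pts.max(axis=0))


def test_bbox3d_rejects_bad_input(small_avatar):
    with pytest.raises(ValueError):
        ss.bbox_3d(small_avatar, step=0)
    with pytest.raises(DegenerateGeometryError):
        ss.bbox_3d(TriangleMesh(vertices=np.empty((0, 3)), faces=np.empty((0, 3))), 1)


# -- 2D bounding boxes --------------------------------------------------------

@pytest.fixture
def camera():
    return Camera.look_at(position=(0, 0, -5), target=(0, 0, 0), fov_vertical=60.0)


def test_bbox2d_padding_arithmetic(camera):
    corners = ss.bbox_3d(_cube_mesh(half=0.5), step=1)
    raw = ss.bbox_2d(camera, corners, padding=0.0)
    padded = ss.bbox_2d(camera, corners, padding=25.0)
    assert padded.width == pytest.approx(raw.width + 50.0)
    assert padded.height == pytest.approx(raw.height + 50.0)
    assert padded.x == pytest.approx(raw.x - 25.0)
    assert padded.y == pytest.approx(raw.y - 25.0)


def test_bbox2d_zero_padding_is_exact_extrema(camera):
    corners = ss.bbox_3d(_cube_mesh(center=(0.3, -0.2, 1.0)), step=1)
    uv, _ = ss.project(camera, corners)
    box = ss.bbox_2d(camera, corners, padding=0.0)
    assert box.x == pytest.approx(uv[:, 0].min())
    assert box.y == pytest.approx(uv[:, 1].min())
    assert box.width == pytest.approx(np.ptp(uv[:, 0]))
    assert box.height == pytest.approx(np.ptp(uv[:, 1]))


def test_bbox2d_contains_all_projected_corners(camera):
    rng = np.random.default_rng(6)
    for _ in range(20):
        corners = ss.bbox_3d(_cube_mesh(center=rng.uniform(-1, 1, 3)), step=1)
        box = ss.bbox_2d(camera, corners, padding=25.0)
        uv, _ = ss.project(camera, corners)
        assert np.all(uv[:, 0] >= box.x) and np.all(uv[:, 0] <= box.x + box.width)
        assert np.all(uv[:, 1] >= box.y) and np.all(uv[:, 1] <= box.y + box.height)


def test_bbox2d_all_corners_behind_camera_raises(camera):
    corners = ss.bbox_3d(_cube_mesh(center=(0, 0, -10)), step=1)
    with pytest.raises(DegenerateGeometryError):
        ss.bbox_2d(camera, corners, padding=25.0)


# -- collision shapes ---------------------------------------------------------

def test_cube_segment_hull_has_eight_vertices():
    shapes, _ = _shapes_for_clouds([_cube_mesh().vertices])
    assert len(shapes) == 1
    assert len(shapes.shapes[0].points_local) == 8
    assert not shapes.shapes[0].degenerate


def test_concave_cloud_hull_is_convex_closure():
    # crescent of points plus an interior probe: hull contains the probe
    theta = np.linspace(0, np.pi, 12)
    crescent = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
    cloud = np.vstack([crescent, crescent + [0, 0, 1.0]])
    shapes, _ = _shapes_for_clouds([cloud])
    sh = shapes.shapes[0]
    probe = np.array([0.0, 0.5, 0.5])  # inside the convex closure, off the crescent
    assert np.all(sh.normals @ probe + sh.offsets <= 1e-9)


def test_degenerate_segment_flagged_and_excluded():
    flat = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])  # collinear
    with pytest.warns(UserWarning, match="degenerate"):
        shapes, rest = _shapes_for_clouds([flat])
    assert shapes.shapes[0].degenerate
    cam = Camera.look_at((0, 0, -5), (0, 0, 0), fov_vertical=60)
    assert ss.count_colliders(cam, (0, 0, 0), shapes, rest) == 0


def test_avatar_yields_one_hull_per_body(model, shapes):
    assert len(shapes) == len(model.bodies)
    assert sum(s.degenerate for s in shapes) == 0


def test_collision_shapes_rigid_across_frames(small_avatar, weights, rest):
    s1 = build_collision_shapes(small_avatar, weights.vertex_bodies(), rest)
    s2 = build_collision_shapes(small_avatar, weights.vertex_bodies(), rest)
    for a, b in zip(s1.shapes, s2.shapes):
        assert np.array_equal(a.points_local, b.points_local)


# -- ray-cast collider counting -----------------------------------------------

def _count_dense_oracle(camera, landmark, shapes, transforms, n=10_000):
    """Independent oracle: dense sampling along the open camera->landmark
    segment, testing convex-hull membership per sample."""
    landmark = np.asarray(landmark, float)
    ts = np.linspace(0.0, 1.0, n, endpoint=False)
    pts = camera.position + ts[:, None] * (landmark - camera.position)
    count = 0
    for sh in shapes:
        if sh.degenerate:
            continue
        T = transforms[sh.body]
        local = (pts - T[:3, 3]) @ T[:3, :3]
        inside = np.all(local @ sh.normals.T + sh.offsets <= 1e-9, axis=1)
        count += bool(inside.any())
    return count


def test_empty_shape_set_counts_zero():
    cam = Camera.look_at((0, 0, -5), (0, 0, 0), fov_vertical=60)
    assert ss.count_colliders(cam, (0, 0, 0), ss.CollisionShapeSet(shapes=[]), {}) == 0


def test_landmark_inside_single_hull_counts_one():
    """The hip-in-femur situation: camera outside, landmark at the hull centroid."""
    shapes, rest = _shapes_for_clouds([_cube_mesh().vertices])
    cam = Camera.look_at((0, 0, -5), (0, 0, 0), fov_vertical=60)
    assert ss.count_colliders(cam, (0, 0, 0), shapes, rest) == 1


def test_two_cubes_straddling_ray_count_two():
    shapes, rest = _shapes_for_clouds([
        _cube_mesh(center=(0, 0, -3)).vertices,
        _cube_mesh(center=(0, 0, -1.5)).vertices,
    ])
    cam = Camera.look_at((0, 0, -5), (0, 0, 0), fov_vertical=60)
    assert ss.count_colliders(cam, (0, 0, 0), shapes, rest) == 2
    assert _count_dense_oracle(cam, (0, 0, 0), shapes, rest) == 2


def test_hull_beyond_landmark_not_counted():
    shapes, rest = _shapes_for_clouds([_cube_mesh(center=(0, 0, 3)).vertices])
    cam = Camera.look_at((0, 0, -5), (0, 0, 0), fov_vertical=60)
    assert ss.count_colliders(cam, (0, 0, 0), shapes, rest) == 0


def test_camera_inside_hull_counts_as_entered():
    shapes, rest = _shapes_for_clouds([_cube_mesh(center=(0, 0, -5), half=1.0).vertices])
    cam = Camera.look_at((0, 0, -5), (0, 0, 0), fov_vertical=60)
    assert ss.count_colliders(cam, (0, 0, 0), shapes, rest) == 1


def test_count_colliders_matches_dense_oracle_on_random_scenes():
    """200 randomized small scenes: slab-clipped counting == dense sampling."""
    rng = np.random.default_rng(12)
    cam_pos = np.array([0.0, 0.0, -6.0])
    mismatches = 0
    for _ in range(200):
        n_hulls = rng.integers(1, 5)
        clouds = [rng.uniform(-0.8, 0.8, size=(rng.integers(8, 16), 3))
                  + rng.uniform(-2, 2, 3) * [1, 1, 0] + [0, 0, rng.uniform(-4, 2)]
                  for _ in range(n_hulls)]
        shapes, rest = _shapes_for_clouds(clouds)
        landmark = rng.uniform(-1.5, 1.5, 3)
        cam = Camera.look_at(cam_pos, landmark, fov_vertical=60)
        fast = ss.count_colliders(cam, landmark, shapes, rest)
        slow = _count_dense_oracle(cam, landmark, shapes, rest)
        mismatches += fast != slow
    assert mismatches == 0


# -- visibility ---------------------------------------------------------------

def test_visibility_formula_values():
    assert ss.visibility(0) == 1.0
    assert ss.visibility(1) == 0.5
    assert ss.visibility(3) == 0.25


def test_visibility_monotone_decreasing_in_open_unit_interval():
    vals = [ss.visibility(n) for n in range(50)]
    assert all(0.0 < v <= 1.0 for v in vals)
    assert all(a > b for a, b in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        ss.visibility(-1)


# -- full-frame annotation ----------------------------------------------------

def test_annotate_frame_keypoint_count_and_kinds(model, rest, small_avatar, shapes):
    pose = model.zero_pose()
    cam = Camera.look_at((0, 1, 4), (0, 1, 0), fov_vertical=60)
    ann = ss.annotate_frame(model, pose, small_avatar, cam, shapes)
    assert len(ann.keypoints) == len(model.joints) + len(model.bodies) + len(model.markers)
    kinds = {k.kind for k in ann.keypoints}
    assert kinds == {"joint", "body", "marker"}
    assert set(ann.kinematics) == set(model.coordinate_names)


def test_joint_and_body_keypoints_coincide_at_shared_origin(model, rest, small_avatar, shapes):
    """Body origins sit at their parent joints in the demo model, so joint and
    body keypoints largely overlap."""
    cam = Camera.look_at((0, 1, 4), (0, 1, 0), fov_vertical=60)
    ann = ss.annotate_frame(model, model.zero_pose(), small_avatar, cam, shapes)
    by_name = {(k.kind, k.name): k for k in ann.keypoints}
    j = by_name[("joint", "hip_r")] if ("joint", "hip_r") in by_name else None
    # femur body origin == hip_r joint center
    jk = next(k for k in ann.keypoints if k.kind == "joint" and k.name == "hip_r")
    bk = next(k for k in ann.keypoints if k.kind == "body" and k.name == "femur_r")
    assert (jk.u, jk.v, jk.depth) == (bk.u, bk.v, bk.depth)


def test_annotate_frame_deterministic(model, rest, small_avatar, shapes):
    cam = Camera.look_at((0.5, 1.5, 3.5), (0, 1, 0), fov_vertical=75)
    pose = model.zero_pose()
    a1 = ss.annotate_frame(model, pose, small_avatar, cam, shapes)
    a2 = ss.annotate_frame(model, pose, small_avatar, cam, shapes)
    for k1, k2 in zip(a1.keypoints, a2.keypoints):
        assert (k1.u, k1.v, k1.depth, k1.visibility) == (k2.u, k2.v, k2.depth, k2.visibility)
    assert a1.bbox == a2.bbox
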
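"""Per-frame ground-truth annotation: keypoints, depth, visibility, bounding boxes.

Visibility of a landmark is ``1 / (1 + N)`` where ``N`` counts the rigid
per-segment convex collision shapes that a camera→landmark ray enters strictly
before reaching the landmark.  A landmark buried inside its own segment's hull
therefore scores 0.5 even when nothing else occludes it — the count is a
self-occlusion measure, not a line-of-sight test.  Collision shapes are built
once, in body-local coordinates, from the dominant-weight vertex assignment,
and only translate/rotate with the kinematics afterwards.

Bounding boxes are computed per frame on the deformed mesh: an axis-aligned 3D
box over every ``step``-th vertex (default 25), its eight corners projected to
pixels, min/max taken and padded (default 25 px per side, configurable; boxes
are *not* clipped to the image).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from . import _transforms as tr
from .avatar_mesh import TriangleMesh
from .camera_geometry import Camera, depth, project
from .errors import DegenerateGeometryError
from .skeletal_model import (
    BodyTransformSet,
    Pose,
    SkeletalModel,
    forward_kinematics,
    joint_centers,
    marker_positions,
)

RAY_EPSILON = 1e-9  # relative to ray length: "before the landmark" tie rule


@dataclass
class KeypointAnnotation:
    name: str
    kind: str  # "joint" | "body" | "marker"
    u: float
    v: float
    depth: float
    visibility: float
    behind_camera: bool

    def __post_init__(self):
        if not 0.0 < self.visibility <= 1.0:
            raise ValueError("visibility must lie in (0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass
class BoundingBox2D:
    x: float  # top-left corner, pixels
    y: float
    width: float
    height: float


@dataclass
class CollisionShape:
    body: str
    points_local: np.ndarray  # hull vertices, body-local frame
    normals: np.ndarray  # outward plane normals (K, 3); plane: n·x + c <= 0
    offsets: np.ndarray  # plane offsets c (K,)
    degenerate: bool = False


@dataclass
class CollisionShapeSet:
    shapes: List[CollisionShape]

    def __iter__(self):
        return iter(self.shapes)

    def __len__(self):
        return len(self.shapes)


@dataclass
class FrameAnnotation:
    image_id: str
    bbox: BoundingBox2D
    keypoints: List[KeypointAnnotation]
    kinematics: Dict[str, float]

    def __post_init__(self):
        names = [k.name for k in self.keypoints]
        if len(set(names)) != len(names):
            raise ValueError("keypoint names must be unique within a frame")


@dataclass
class AnnotationConfig:
    step: int = 25
    padding: float = 25.0
    vertex_subset: Optional[np.ndarray] = None  # explicit indices replacing striding


def bbox_3d(mesh: TriangleMesh, step: int,
            subset: Optional[Sequence[int]] = None) -> np.ndarray:
    """Eight corners of the axis-aligned 3D box over every ``step``-th vertex.

    ``subset`` (explicit vertex indices) replaces the striding when given.
    """
    if mesh.n_vertices == 0:
        raise DegenerateGeometryError("bbox_3d on an empty mesh")
    if step < 1:
        raise ValueError("step must be a positive integer")
    pts = mesh.vertices[np.asarray(subset, dtype=int)] if subset is not None \
        else mesh.vertices[::step]
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    return corners


def bbox_2d(camera: Camera, corners: np.ndarray, padding: float = 25.0) -> BoundingBox2D:
    """Project the 8 box corners, take the pixel min/max, pad on all four sides."""
    uv, behind = project(camera, corners)
    if np.all(behind):
        raise DegenerateGeometryError("all bounding-box corners are behind the camera")
    lo = uv.min(axis=0) - padding
    hi = uv.max(axis=0) + padding
    return BoundingBox2D(x=float(lo[0]), y=float(lo[1]),
                         width=float(hi[0] - lo[0]), height=float(hi[1] - lo[1]))


def build_collision_shapes(mesh: TriangleMesh, assignment: Sequence[str],
                           rest: BodyTransformSet) -> CollisionShapeSet:
    """One rigid convex hull per body segment, in body-local coordinates.

    ``assignment`` gives the owning body name per vertex (dominant skinning
    weight).  Built once at rest; hulls only translate/rotate afterwards.
    Segments with fewer than 4 non-coplanar vertices are flagged degenerate
    and excluded from ray casting with a warning.
    """
    assignment = np.asarray(assignment)
    if len(assignment) != mesh.n_vertices:
        raise ValueError("assignment length does not match vertex count")
    shapes: List[CollisionShape] = []
    for body in sorted(set(assignment.tolist()), key=list(rest).index):
        verts = mesh.vertices[assignment == body]
        local = tr.apply(tr.inverse(rest[body]), verts)
        try:
            hull = ConvexHull(local)
        except (QhullError, ValueError):
            warnings.warn(f"segment {body!r}: degenerate vertex set "
                          "(<4 non-coplanar points); excluded from ray casting", stacklevel=2)
            shapes.append(CollisionShape(body=body, points_local=local,
                                         normals=np.zeros((0, 3)), offsets=np.zeros(0),
                                         degenerate=True))
            continue
        shapes.append(CollisionShape(body=body,
                                     points_local=local[hull.vertices],
                                     normals=hull.equations[:, :3].copy(),
                                     offsets=hull.equations[:, 3].copy()))
    return CollisionShapeSet(shapes=shapes)


def _ray_hits_hull_before(origin: np.ndarray, direction: np.ndarray, length: float,
                          shape: CollisionShape, transform: np.ndarray) -> bool:
    """Does the ray enter this hull strictly before the landmark?

    Clips the ray against the hull's half-spaces in the body-local frame.
    A hull containing the origin counts as entered at distance 0.
    """
    R = tr.rotation(transform)
    o = R.T @ (origin - tr.translation(transform))
    d = R.T @ direction
    num = shape.normals @ o + shape.offsets  # f(t) = num + t*den <= 0 inside
    den = shape.normals @ d
    t0, t1 = 0.0, np.inf
    parallel = np.abs(den) < 1e-14
    if np.any(num[parallel] > 1e-12):
        return False
    with np.errstate(divide="ignore", invalid="ignore"):
        t_cross = -num / den
    if np.any(den > 0):
        t1 = np.min(t_cross[den > 0])
    if np.any(den < 0):
        t0 = max(0.0, np.max(t_cross[den < 0]))
    if t0 > t1 + 1e-12:
        return False
    return t0 < length * (1.0 - RAY_EPSILON) and t1 > 0.0


def count_colliders(camera: Camera, landmark, shapes: CollisionShapeSet,
                    transforms: BodyTransformSet) -> int:
    """Number N of collision shapes the camera→landmark ray enters before the landmark."""
    landmark = np.asarray(landmark, dtype=float)
    origin = camera.position
    ray = landmark - origin
    length = float(np.linalg.norm(ray))
    if length < 1e-12:
        return 0
    direction = ray / length
    n = 0
    for shape in shapes:
        if shape.degenerate:
            continue
        if _ray_hits_hull_before(origin, direction, length, shape, transforms[shape.body]):
            n += 1
    return n


def visibility(n_colliders: int) -> float:
    """Visibility label 1 / (1 + N) in the half-open interval (0, 1]."""
    if n_colliders < 0:
        raise ValueError("collider count must be non-negative")
    return 1.0 / (1.0 + int(n_colliders))


def annotate_frame(model: SkeletalModel, pose: Pose, mesh_deformed: TriangleMesh,
                   camera: Camera, shapes: CollisionShapeSet,
                   config: AnnotationConfig = AnnotationConfig(),
                   image_id: str = "000000",
                   transforms: Optional[BodyTransformSet] = None) -> FrameAnnotation:
    """Full annotation record for one frame.

    Keypoints cover every joint center, every body-frame origin, and every
    virtual marker (in model order), each with pixel coordinates, Euclidean
    depth, visibility, and a behind-camera flag.  ``transforms`` may be passed
    to reuse an existing FK result.
    """
    if transforms is None:
        transforms = forward_kinematics(model, pose)
    landmarks: List[tuple] = []
    for name, pos in joint_centers(model, transforms).items():
        landmarks.append((name, "joint", pos))
    for body in transforms:
        landmarks.append((body, "body", tr.translation(transforms[body])))
    for name, pos in marker_positions(model, transforms).items():
        landmarks.append((name, "marker", pos))

    keypoints = []
    for name, kind, pos in landmarks:
        uv, behind = project(camera, pos)
        n = count_colliders(camera, pos, shapes, transforms)
        keypoints.append(KeypointAnnotation(
            name=name, kind=kind, u=float(uv[0]), v=float(uv[1]),
            depth=float(depth(camera, pos)), visibility=visibility(n),
            behind_camera=bool(behind)))

    corners = bbox_3d(mesh_deformed, config.step, subset=config.vertex_subset)
    box = bbox_2d(camera, corners, padding=config.padding)
    return FrameAnnotation(image_id=image_id, bbox=box, keypoints=keypoints,
                           kinematics={c: float(pose[c]) for c in model.coordinate_names})
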
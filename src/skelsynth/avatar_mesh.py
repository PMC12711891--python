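"""Procedural human-like avatar mesh matched to a skeletal model's rest pose.

One capsule shell is generated per body segment, sized from the segment bone's
length and a per-segment radius preset scaled by the morphology's shape
parameter β (linear multiplier ``1 + 0.15·β``, β ∈ [−2, 2]) and sex preset.
The torso additionally receives a head capsule, since the torso body segment
includes the head.  Capsules use an even sector count so mirrored bodies
produce exactly mirror-symmetric vertex sets about the sagittal plane.

This procedural avatar is a deliberately simple, self-contained stand-in for
statistical body models: all annotations derive from the skeletal model, so
any plausibly human-shaped watertight shell exercises the full skinning and
annotation stack.  Users with their own assets can load OBJ/PLY meshes via
:func:`load_mesh`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import _transforms as tr
from .errors import DegenerateGeometryError
from .skeletal_model import BodyTransformSet, SkeletalModel

DEFAULT_RESOLUTION = 7500  # target vertex count, matching the reference mesh scale

# per-segment radius presets (m), matched by substring of the body name
_RADIUS_PRESETS = [
    ("pelvis", 0.115),
    ("torso", 0.14),
    ("femur", 0.08),
    ("tibia", 0.055),
    ("foot", 0.05),
    ("humerus", 0.047),
    ("radius", 0.04),
    ("hand", 0.035),
]
_DEFAULT_RADIUS = 0.06
# sex presets: multiplicative tweaks on shoulder (torso) and hip (pelvis) girth
_SEX_PRESETS = {
    "female": {"torso": 0.93, "pelvis": 1.08},
    "male": {"torso": 1.05, "pelvis": 0.97},
}
_HEAD_RADIUS = 0.09
_HEAD_NECK_GAP = 0.07  # head capsule start above the torso bone tail (m)
_HEAD_LENGTH = 0.14


@dataclass
class TriangleMesh:
    """Triangle mesh: N×3 vertices (m), M×3 faces, optional per-vertex RGB in [0,1]."""

    vertices: np.ndarray
    faces: np.ndarray
    colors: Optional[np.ndarray] = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise DegenerateGeometryError("mesh has non-finite vertex coordinates")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise DegenerateGeometryError("face index out of range")
            a, b, c = self.faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise DegenerateGeometryError("mesh has degenerate faces (repeated index)")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=float).reshape(-1, 3)
            if len(self.colors) != len(self.vertices):
                raise DegenerateGeometryError("per-vertex colors do not match vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class MorphologyParams:
    """Body morphology: sex preset, girth shape parameter β, and mesh resolution."""

    sex_tag: str = "female"
    shape: float = 0.0  # β in [-2, 2]
    mesh_resolution: int = DEFAULT_RESOLUTION

    def __post_init__(self):
        if self.sex_tag not in _SEX_PRESETS:
            raise ValueError(f"sex_tag must be one of {sorted(_SEX_PRESETS)}")
        if not -2.0 <= self.shape <= 2.0:
            raise ValueError("shape parameter must lie in [-2, 2]")
        if self.mesh_resolution < 500:
            raise ValueError("mesh_resolution must be at least 500")

    @property
    def radius_multiplier(self) -> float:
        return 1.0 + 0.15 * self.shape


def _segment_radius(body: str, morphology: MorphologyParams) -> float:
    base = _DEFAULT_RADIUS
    for key, r in _RADIUS_PRESETS:
        if key in body:
            base = r
            break
    for key, mult in _SEX_PRESETS[morphology.sex_tag].items():
        if key in body:
            base *= mult
    return base * morphology.radius_multiplier


def _perp_basis(d: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    # reference chosen so mirrored axes yield mirrored bases (sagittal symmetry)
    ref = np.array([0.0, 1.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(d, u)


def _capsule(head: np.ndarray, tail: np.ndarray, radius: float,
             sectors: int, rings_cyl: int, rings_cap: int) -> Tuple[np.ndarray, np.ndarray]:
    """Capsule from head to tail; even `sectors` keeps mirrored pairs symmetric."""
    axis = tail - head
    length = np.linalg.norm(axis)
    if length <= 1e-9:
        raise DegenerateGeometryError("capsule with coincident endpoints")
    d = axis / length
    u, v = _perp_basis(d)
    theta = 2.0 * np.pi * np.arange(sectors) / sectors
    circle = np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v

    rings: List[np.ndarray] = []
    # bottom cap (around head), pole to equator
    phis = np.linspace(-np.pi / 2, 0.0, rings_cap + 1)[1:]
    for phi in phis:
        center = head + d * (radius * np.sin(phi))
        rings.append(center + radius * np.cos(phi) * circle)
    # cylinder interior rings
    for t in np.linspace(0.0, 1.0, rings_cyl + 2)[1:-1]:
        rings.append(head + t * axis + radius * circle)
    # top cap (around tail), equator to pole
    phis = np.linspace(0.0, np.pi / 2, rings_cap + 1)[:-1]
    for phi in phis:
        center = tail + d * (radius * np.sin(phi))
        rings.append(center + radius * np.cos(phi) * circle)

    verts = [head - radius * d] + [p for ring in rings for p in ring] + [tail + radius * d]
    vertices = np.asarray(verts)
    n_rings = len(rings)
    faces: List[Tuple[int, int, int]] = []
    bottom, top = 0, 1 + n_rings * sectors

    def ring_idx(r: int, s: int) -> int:
        return 1 + r * sectors + (s % sectors)

    for s in range(sectors):
        faces.append((bottom, ring_idx(0, s + 1), ring_idx(0, s)))
        faces.append((top, ring_idx(n_rings - 1, s), ring_idx(n_rings - 1, s + 1)))
    for r in range(n_rings - 1):
        for s in range(sectors):
            a, b = ring_idx(r, s), ring_idx(r, s + 1)
            c, e = ring_idx(r + 1, s), ring_idx(r + 1, s + 1)
            faces.append((a, b, e))
            faces.append((a, e, c))
    return vertices, np.asarray(faces, dtype=int)


def _capsule_specs(model: SkeletalModel, morphology: MorphologyParams,
                   rest: BodyTransformSet) -> List[Tuple[str, np.ndarray, np.ndarray, float]]:
    from .rigging_skinning import segment_endpoints  # deferred: avoids import cycle

    endpoints = segment_endpoints(model, rest)
    specs = []
    for body, (head, tail) in endpoints.items():
        if np.linalg.norm(tail - head) <= 1e-9:
            raise DegenerateGeometryError(f"body {body!r}: zero-length segment bone")
        specs.append((body, head, tail, _segment_radius(body, morphology)))
        if "torso" in body:
            up = (tail - head) / np.linalg.norm(tail - head)
            h0 = tail + _HEAD_NECK_GAP * up
            specs.append((body, h0, h0 + _HEAD_LENGTH * up,
                          _HEAD_RADIUS * morphology.radius_multiplier))
    return specs


def generate_avatar(model: SkeletalModel, morphology: MorphologyParams,
                    rest: BodyTransformSet) -> TriangleMesh:
    """Generate the capsule-shell avatar at the model's rest pose.

    Vertex budgets are distributed across capsules in proportion to surface
    area so the total lands within ±20% of ``morphology.mesh_resolution``.
    Per-vertex body membership is not tracked here: skinning weights (and the
    dominant-weight vertex assignment derived from them) supersede it.
    """
    specs = _capsule_specs(model, morphology, rest)
    areas = np.array([2 * np.pi * r * np.linalg.norm(t - h) + 4 * np.pi * r * r
                      for _, h, t, r in specs])
    budgets = morphology.mesh_resolution * areas / areas.sum()

    all_v, all_f = [], []
    offset = 0
    for (body, head, tail, radius), budget in zip(specs, budgets):
        sectors = int(round(np.sqrt(budget / 2.0)))
        sectors = max(8, sectors + (sectors % 2))  # even, ≥8
        total_rows = max(5, int(round(budget / sectors)))
        length = np.linalg.norm(tail - head)
        cap_frac = 2 * radius / (length + 2 * radius)
        rings_cap = max(2, int(round(total_rows * cap_frac / 2)))
        rings_cyl = max(1, total_rows - 2 * rings_cap)
        v, f = _capsule(head, tail, radius, sectors, rings_cyl, rings_cap)
        all_v.append(v)
        all_f.append(f + offset)
        offset += len(v)
    return TriangleMesh(vertices=np.vstack(all_v), faces=np.vstack(all_f))


def mesh_summary(mesh: TriangleMesh) -> Dict[str, object]:
    """Vertex/face counts and axis-aligned bounding extents of a mesh."""
    if mesh.n_vertices == 0:
        raise DegenerateGeometryError("cannot summarize an empty mesh")
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    return {
        "n_vertices": mesh.n_vertices,
        "n_faces": mesh.n_faces,
        "extents": hi - lo,
        "min_corner": lo,
        "max_corner": hi,
    }


def load_mesh(path) -> TriangleMesh:
    """Load an external OBJ/PLY mesh (hook for users with their own avatars)."""
    import trimesh

    tm = trimesh.load(str(path), force="mesh")
    return TriangleMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


def save_mesh(mesh: TriangleMesh, path) -> None:
    import trimesh

    trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False).export(str(path))
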
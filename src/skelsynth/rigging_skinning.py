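"""Armature construction, distance-based skinning weights, linear blend skinning.

The armature mirrors the skeletal model with three bone kinds:

* **segment bones** — one per body segment, head at the body's parent-joint
  center and tail at the next joint center along the kinematic chain (leaf
  bodies continue for a fixed distance; branching bodies end at the midpoint
  of their distal joint centers).  They drive mesh deformation.
* **control bones** — one per body, fixed length, sharing the segment bone's
  head, with rest rotation equal to the body's rest rotation.  During posing
  the body's simulated global motion is applied to the control bone and the
  parented segment bone follows, so the effective skinning transform of body
  ``b`` is exactly ``T_b(pose) ∘ T_b(rest)^-1``.
* **connector bones** — inserted wherever a segment bone's tail and the next
  segment bone's head do not coincide.  They take part in the raw weight
  computation (emphasizing otherwise under-weighted short bones) and their
  weight mass is then transferred to the segment bone they originate from.

Weights follow an inverse-square point-to-segment distance law,
``w = 1 / (d² + ε)`` with ε = 1e-6 m², truncated below 1e-3 of the row
maximum, connector-transferred, and row-normalized to sum to one.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import _transforms as tr
from .avatar_mesh import TriangleMesh
from .errors import DegenerateGeometryError
from .skeletal_model import (
    GROUND,
    BodyTransformSet,
    SkeletalModel,
    joint_centers,
)

DEFAULT_CONTROL_LENGTH = 0.10  # m; the construction only needs "fixed length"
DEFAULT_LEAF_EXTENSION = 0.12  # m; continuation of leaf segment bones
WEIGHT_EPS = 1e-6  # m², regularizer of the inverse-square law
WEIGHT_TRUNCATE = 1e-3  # relative to the row maximum


@dataclass
class Bone:
    name: str
    kind: str  # "segment" | "control" | "connector"
    head: np.ndarray
    tail: np.ndarray
    parent: Optional[str] = None
    connected: bool = False
    rest_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    origin_body: Optional[str] = None  # connector bones: segment they originate from

    def __post_init__(self):
        self.head = np.asarray(self.head, dtype=float)
        self.tail = np.asarray(self.tail, dtype=float)
        self.rest_rotation = np.asarray(self.rest_rotation, dtype=float)
        if np.linalg.norm(self.tail - self.head) <= 1e-6:
            raise DegenerateGeometryError(f"bone {self.name!r}: head and tail coincide")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.tail - self.head))


@dataclass
class Armature:
    bones: List[Bone]
    body_to_segment: Dict[str, str]
    body_to_control: Dict[str, str]
    rest_global: Dict[str, np.ndarray]

    def bone(self, name: str) -> Bone:
        return self._index[name]

    def __post_init__(self):
        self._index = {b.name: b for b in self.bones}
        for body, seg in self.body_to_segment.items():
            ctrl = self.body_to_control[body]
            if self._index[seg].parent != ctrl:
                raise ValueError(f"segment bone {seg!r} must be parented to its control bone")
            if np.linalg.norm(self._index[seg].head - self._index[ctrl].head) > 1e-9:
                raise ValueError(f"control bone {ctrl!r} must share its head with {seg!r}")

    @property
    def segment_bones(self) -> List[Bone]:
        return [b for b in self.bones if b.kind == "segment"]

    @property
    def connector_bones(self) -> List[Bone]:
        return [b for b in self.bones if b.kind == "connector"]

    def to_json(self) -> str:
        return json.dumps([
            {
                "name": b.name, "kind": b.kind,
                "head": b.head.tolist(), "tail": b.tail.tolist(),
                "parent": b.parent, "connected": b.connected,
                "rest_rotation": b.rest_rotation.tolist(),
                "origin_body": b.origin_body,
            }
            for b in self.bones
        ], indent=2)


@dataclass
class WeightMatrix:
    """Per-vertex skinning weights over the segment bones (one column per body)."""

    matrix: np.ndarray  # N_vertices x N_bodies
    bodies: List[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.bodies):
            raise ValueError("weight matrix shape does not match body list")
        if np.any(self.matrix < 0):
            raise ValueError("weights must be non-negative")
        rows = self.matrix.sum(axis=1)
        if self.matrix.shape[0] and np.max(np.abs(rows - 1.0)) > 1e-9:
            raise ValueError("every weight row must sum to 1")

    def column(self, body: str) -> np.ndarray:
        return self.matrix[:, self.bodies.index(body)]

    def vertex_bodies(self) -> List[str]:
        return [self.bodies[i] for i in assign_vertices(self)]


def segment_endpoints(model: SkeletalModel, transforms: BodyTransformSet,
                      leaf_extension: float = DEFAULT_LEAF_EXTENSION
                      ) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Head/tail of every body's segment bone in the given (usually rest) pose.

    Head is the body's parent-joint center.  Tail is the distal joint center
    (single chain), the midpoint of all distal joint centers (branching), or a
    fixed-length continuation of the incoming chain direction (leaf bodies and
    degenerate zero-length cases, with a warning for the latter).
    """
    centers = joint_centers(model, transforms)
    heads = {b.name: centers[model.parent_joint_of(b.name).name] for b in model.bodies}

    def incoming_direction(body: str) -> np.ndarray:
        parent = model.parent_joint_of(body).parent_body
        if parent != GROUND:
            d = heads[body] - heads[parent]
            n = np.linalg.norm(d)
            if n > 1e-9:
                return d / n
        # fallback: body-frame -Y (a downward limb direction at rest)
        return tr.rotation(transforms[body]) @ np.array([0.0, -1.0, 0.0])

    out = {}
    for b in model.bodies:
        head = heads[b.name]
        distal = model.distal_joints_of(b.name)
        if distal:
            tail = np.mean([centers[j.name] for j in distal], axis=0)
            if np.linalg.norm(tail - head) <= 1e-6:
                warnings.warn(
                    f"body {b.name!r}: distal joints coincide with head; "
                    "falling back to leaf continuation rule", stacklevel=2)
                tail = head + leaf_extension * incoming_direction(b.name)
        else:
            tail = head + leaf_extension * incoming_direction(b.name)
        out[b.name] = (head, tail)
    return out


def build_armature(model: SkeletalModel, rest: BodyTransformSet,
                   control_length: float = DEFAULT_CONTROL_LENGTH,
                   leaf_extension: float = DEFAULT_LEAF_EXTENSION) -> Armature:
    """Build the segment/control/connector armature at the rest pose."""
    endpoints = segment_endpoints(model, rest, leaf_extension)
    bones: List[Bone] = []
    body_to_segment, body_to_control = {}, {}
    for b in model.bodies:
        head, tail = endpoints[b.name]
        R = tr.rotation(rest[b.name])
        ctrl_name = f"{b.name}_control"
        parent_body = model.parent_joint_of(b.name).parent_body
        parent_bone = None if parent_body == GROUND else parent_body
        bones.append(Bone(name=ctrl_name, kind="control", head=head,
                          tail=head + control_length * (R @ np.array([0.0, 1.0, 0.0])),
                          parent=parent_bone, connected=False, rest_rotation=R))
        bones.append(Bone(name=b.name, kind="segment", head=head, tail=tail,
                          parent=ctrl_name, connected=False, rest_rotation=R))
        body_to_segment[b.name] = b.name
        body_to_control[b.name] = ctrl_name

    for j in model.joints:
        if j.parent_body == GROUND:
            continue
        p_tail = endpoints[j.parent_body][1]
        c_head = endpoints[j.child_body][0]
        if np.linalg.norm(c_head - p_tail) > 1e-6:
            bones.append(Bone(name=f"{j.parent_body}_to_{j.child_body}_connector",
                              kind="connector", head=p_tail, tail=c_head,
                              parent=j.parent_body, connected=True,
                              rest_rotation=np.eye(3), origin_body=j.parent_body))

    rest_global = {b.name: tr.rt(b.rest_rotation, b.head) for b in bones}
    return Armature(bones=bones, body_to_segment=body_to_segment,
                    body_to_control=body_to_control, rest_global=rest_global)


def _point_segment_distance(points: np.ndarray, head: np.ndarray, tail: np.ndarray) -> np.ndarray:
    d = tail - head
    denom = float(d @ d)
    t = np.clip((points - head) @ d / denom, 0.0, 1.0)
    closest = head + t[:, None] * d
    return np.linalg.norm(points - closest, axis=1)


def compute_weights(mesh: TriangleMesh, armature: Armature,
                    eps: float = WEIGHT_EPS, truncate: float = WEIGHT_TRUNCATE) -> WeightMatrix:
    """Inverse-square distance weights with connector transfer and normalization."""
    if len(mesh.vertices) == 0:
        raise DegenerateGeometryError("cannot weight an empty mesh")
    seg = armature.segment_bones
    if not seg:
        raise DegenerateGeometryError("armature has no segment bones")
    conn = armature.connector_bones
    bones = seg + conn
    V = mesh.vertices
    raw = np.empty((len(V), len(bones)))
    for k, b in enumerate(bones):
        d = _point_segment_distance(V, b.head, b.tail)
        raw[:, k] = 1.0 / (d * d + eps)
    raw[raw < truncate * raw.max(axis=1, keepdims=True)] = 0.0
    # transfer connector mass to the segment bone each connector originates from
    seg_index = {b.name: i for i, b in enumerate(seg)}
    W = raw[:, :len(seg)].copy()
    for k, b in enumerate(conn):
        W[:, seg_index[b.origin_body]] += raw[:, len(seg) + k]
    empty = np.where(W.sum(axis=0) == 0)[0]
    if empty.size:
        warnings.warn("segment bones with no weighted vertices: "
                      f"{[seg[i].name for i in empty]}", stacklevel=2)
    W /= W.sum(axis=1, keepdims=True)
    return WeightMatrix(matrix=W, bodies=[b.name for b in seg])


def skinning_transforms(armature: Armature, transforms: BodyTransformSet,
                        rest: BodyTransformSet) -> Dict[str, np.ndarray]:
    """Per-segment-bone skinning transforms for the posed body transforms.

    The body's global motion ``T(pose) ∘ T(rest)^-1`` is applied to the control
    bone; the parented segment bone inherits it through its rest offset, and
    the returned transform for segment bone ``b`` is
    ``G_b(pose) ∘ G_b(rest)^-1`` — identical to the body motion itself.
    """
    out = {}
    for body, seg_name in armature.body_to_segment.items():
        if body not in transforms:
            raise KeyError(f"no posed transform for body {body!r}")
        if body not in rest:
            raise KeyError(f"no rest transform for body {body!r}")
        motion = transforms[body] @ tr.inverse(rest[body])
        ctrl_rest = armature.rest_global[armature.body_to_control[body]]
        seg_rest = armature.rest_global[seg_name]
        ctrl_pose = motion @ ctrl_rest
        seg_pose = ctrl_pose @ (tr.inverse(ctrl_rest) @ seg_rest)  # parenting offset
        out[seg_name] = seg_pose @ tr.inverse(seg_rest)
    return out


def deform_mesh(mesh: TriangleMesh, weights: WeightMatrix,
                skin: Dict[str, np.ndarray]) -> TriangleMesh:
    """Linear blend skinning: v' = Σ_b w_vb · S_b(v).  Faces are unchanged."""
    if weights.matrix.shape[0] != len(mesh.vertices):
        raise ValueError("weight matrix rows do not match mesh vertex count")
    V = mesh.vertices
    out = np.zeros_like(V)
    for j, body in enumerate(weights.bodies):
        w = weights.matrix[:, j]
        if not np.any(w):
            continue
        out += w[:, None] * tr.apply(skin[body], V)
    return TriangleMesh(vertices=out, faces=mesh.faces.copy(),
                        colors=None if mesh.colors is None else mesh.colors.copy())


def assign_vertices(weights: WeightMatrix) -> np.ndarray:
    """Body-column index of the dominant weight per vertex (ties -> lowest index)."""
    return np.argmax(weights.matrix, axis=1)
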
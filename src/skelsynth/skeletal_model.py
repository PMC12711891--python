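"""Simplified musculoskeletal skeletal model: topology, coordinates, forward kinematics.

A :class:`SkeletalModel` is a tree of rigid body segments connected by joints.
Each joint carries an ordered list of degrees of freedom (DOFs); every DOF
references one *generalized coordinate* (a joint angle in radians or a root
translation component in meters).  Posing the model means assigning a value to
every coordinate; forward kinematics then composes joint transforms along the
tree to produce the global rigid transform of every body segment, from which
joint centers and virtual-marker positions follow.

Conventions
-----------
* Ground frame: right-handed, Y-up, meters.
* Rotation DOFs are applied in their listed order about per-DOF axes expressed
  in the joint frame (intrinsic composition).
* The *rest pose* is the pose with every coordinate at zero; bundled model
  geometry is authored so that the rest pose is a standing T-pose.

The on-disk representation is a small, documented JSON/YAML schema carrying
exactly the fields below (a deliberately minimal stand-in for OpenSim ``.osim``
files, of which only topology, DOFs, coordinate ranges and markers are used).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from . import _transforms as tr
from .errors import FormatError, IncompletePoseError, TopologyError

GROUND = "ground"
FORMAT_VERSION = "1"

#: A pose is a plain mapping: coordinate name -> value (radians / meters).
Pose = Dict[str, float]

#: Body transforms: body name -> 4x4 rigid transform in the ground frame.
BodyTransformSet = Dict[str, np.ndarray]


@dataclass
class BodySegment:
    name: str


@dataclass
class Dof:
    coordinate: str
    kind: str  # "rotation" | "translation"
    axis: np.ndarray  # unit 3-vector in the joint frame

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        if self.kind not in ("rotation", "translation"):
            raise FormatError(f"DOF kind must be rotation|translation, got {self.kind!r}")
        n = np.linalg.norm(self.axis)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise FormatError(f"DOF axis for {self.coordinate!r} must be unit norm (got {n:.6g})")


@dataclass
class Joint:
    name: str
    parent_body: str  # body name or "ground"
    child_body: str
    location_in_parent: np.ndarray  # meters, parent body frame
    location_in_child: np.ndarray  # meters, child body frame
    dofs: List[Dof] = field(default_factory=list)

    def __post_init__(self):
        self.location_in_parent = np.asarray(self.location_in_parent, dtype=float)
        self.location_in_child = np.asarray(self.location_in_child, dtype=float)
        if len(self.dofs) > 6:
            raise FormatError(f"joint {self.name!r} has more than 6 DOFs")


@dataclass
class Coordinate:
    name: str
    range_min: float
    range_max: float
    default: float = 0.0

    def __post_init__(self):
        if not self.range_min < self.range_max:
            raise FormatError(f"coordinate {self.name!r}: range_min must be < range_max")
        if not self.range_min <= self.default <= self.range_max:
            raise FormatError(f"coordinate {self.name!r}: default outside range")


@dataclass
class VirtualMarker:
    name: str
    body: str
    offset: np.ndarray  # meters, body frame

    def __post_init__(self):
        self.offset = np.asarray(self.offset, dtype=float)


@dataclass
class SkeletalModel:
    """Validated tree of body segments, joints, coordinates and markers."""

    name: str
    bodies: List[BodySegment]
    joints: List[Joint]
    coordinates: List[Coordinate]
    markers: List[VirtualMarker] = field(default_factory=list)

    def __post_init__(self):
        self._validate()

    # -- validation & topology ------------------------------------------------

    def _validate(self) -> None:
        body_names = [b.name for b in self.bodies]
        if len(set(body_names)) != len(body_names):
            raise TopologyError("body names are not unique")
        if GROUND in body_names:
            raise TopologyError(f"{GROUND!r} is reserved and cannot be a body name")
        coord_names = [c.name for c in self.coordinates]
        if len(set(coord_names)) != len(coord_names):
            raise TopologyError("coordinate names are not unique")
        self._coords = {c.name: c for c in self.coordinates}
        known = set(body_names) | {GROUND}

        parent_joint: Dict[str, Joint] = {}
        for j in self.joints:
            if j.parent_body not in known:
                raise TopologyError(f"joint {j.name!r} references unknown parent body {j.parent_body!r}")
            if j.child_body not in set(body_names):
                raise TopologyError(f"joint {j.name!r} references unknown child body {j.child_body!r}")
            if j.child_body in parent_joint:
                raise TopologyError(f"body {j.child_body!r} is the child of more than one joint")
            parent_joint[j.child_body] = j
            for d in j.dofs:
                if d.coordinate not in self._coords:
                    raise TopologyError(
                        f"joint {j.name!r} DOF references unknown coordinate {d.coordinate!r}")
        used = set()
        for j in self.joints:
            for d in j.dofs:
                if d.coordinate in used:
                    raise TopologyError(f"coordinate {d.coordinate!r} used by more than one DOF")
                used.add(d.coordinate)

        roots = [b.name for b in self.bodies
                 if b.name in parent_joint and parent_joint[b.name].parent_body == GROUND]
        orphans = [b.name for b in self.bodies if b.name not in parent_joint]
        if orphans:
            raise TopologyError(f"bodies without a parent joint: {orphans}")
        if len(roots) != 1:
            raise TopologyError(f"model must have exactly one root body attached to ground, found {roots}")
        self._root = roots[0]
        self._parent_joint = parent_joint

        # joint topological order (parents before children); also detects cycles
        order: List[Joint] = []
        resolved = {GROUND}
        pending = list(self.joints)
        while pending:
            progressed = False
            for j in list(pending):
                if j.parent_body in resolved:
                    order.append(j)
                    resolved.add(j.child_body)
                    pending.remove(j)
                    progressed = True
            if not progressed:
                raise TopologyError(
                    f"joint graph contains a cycle or unreachable bodies: {[j.name for j in pending]}")
        self._topo_joints = order

        for m in self.markers:
            if m.body not in set(body_names):
                raise TopologyError(f"marker {m.name!r} references unknown body {m.body!r}")
        marker_names = [m.name for m in self.markers]
        if len(set(marker_names)) != len(marker_names):
            raise TopologyError("marker names are not unique")

    # -- accessors ------------------------------------------------------------

    @property
    def root_body(self) -> str:
        return self._root

    @property
    def coordinate_names(self) -> List[str]:
        return [c.name for c in self.coordinates]

    def coordinate(self, name: str) -> Coordinate:
        return self._coords[name]

    def parent_joint_of(self, body: str) -> Joint:
        return self._parent_joint[body]

    def distal_joints_of(self, body: str) -> List[Joint]:
        return [j for j in self.joints if j.parent_body == body]

    @property
    def topo_joints(self) -> List[Joint]:
        return list(self._topo_joints)

    def root_translation_coordinates(self) -> List[str]:
        """Coordinates driving translation DOFs of the root (ground) joint."""
        root_joint = self._parent_joint[self._root]
        return [d.coordinate for d in root_joint.dofs if d.kind == "translation"]

    def rotational_coordinates(self) -> List[str]:
        out = []
        for j in self.joints:
            for d in j.dofs:
                if d.kind == "rotation":
                    out.append(d.coordinate)
        return out

    # -- poses ----------------------------------------------------------------

    def zero_pose(self) -> Pose:
        """The rest pose: every coordinate at zero."""
        return {c.name: 0.0 for c in self.coordinates}

    def default_pose(self) -> Pose:
        return {c.name: c.default for c in self.coordinates}

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "name": self.name,
            "bodies": [{"name": b.name} for b in self.bodies],
            "joints": [
                {
                    "name": j.name,
                    "parent_body": j.parent_body,
                    "child_body": j.child_body,
                    "location_in_parent": [float(x) for x in j.location_in_parent],
                    "location_in_child": [float(x) for x in j.location_in_child],
                    "dofs": [
                        {"coordinate": d.coordinate, "kind": d.kind,
                         "axis": [float(x) for x in d.axis]}
                        for d in j.dofs
                    ],
                }
                for j in self.joints
            ],
            "coordinates": [
                {"name": c.name, "range": [float(c.range_min), float(c.range_max)],
                 "default": float(c.default)}
                for c in self.coordinates
            ],
            "markers": [
                {"name": m.name, "body": m.body, "offset": [float(x) for x in m.offset]}
                for m in self.markers
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SkeletalModel":
        try:
            version = str(data.get("format_version", FORMAT_VERSION))
            if version != FORMAT_VERSION:
                raise FormatError(f"unsupported format_version {version!r}")
            bodies = [BodySegment(name=b["name"]) for b in data["bodies"]]
            joints = [
                Joint(
                    name=j["name"],
                    parent_body=j["parent_body"],
                    child_body=j["child_body"],
                    location_in_parent=j["location_in_parent"],
                    location_in_child=j["location_in_child"],
                    dofs=[Dof(coordinate=d["coordinate"], kind=d["kind"], axis=d["axis"])
                          for d in j.get("dofs", [])],
                )
                for j in data["joints"]
            ]
            coords = [
                Coordinate(name=c["name"], range_min=c["range"][0], range_max=c["range"][1],
                           default=c.get("default", 0.0))
                for c in data["coordinates"]
            ]
            markers = [
                VirtualMarker(name=m["name"], body=m["body"], offset=m["offset"])
                for m in data.get("markers", [])
            ]
        except (KeyError, TypeError, IndexError) as exc:
            raise FormatError(f"malformed model data: missing/invalid field {exc}") from exc
        return cls(name=data.get("name", "unnamed"), bodies=bodies, joints=joints,
                   coordinates=coords, markers=markers)


def load_model(path) -> SkeletalModel:
    """Load and validate a skeletal model from a JSON or YAML file.

    The format is selected by suffix (``.json`` vs ``.yaml``/``.yml``).
    """
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        elif path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            raise FormatError(f"unrecognized model file suffix {path.suffix!r} (want .json/.yaml)")
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise FormatError(f"{path.name}: parse failure: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"{path.name}: top level must be a mapping")
    return SkeletalModel.from_dict(data)


def save_model(model: SkeletalModel, path) -> None:
    path = Path(path)
    data = model.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    elif path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        raise FormatError(f"unrecognized model file suffix {path.suffix!r} (want .json/.yaml)")


# -- kinematics ---------------------------------------------------------------


def _dof_matrix(dof: Dof, value: float) -> np.ndarray:
    if dof.kind == "rotation":
        return tr.rotate_axis(dof.axis, value)
    return tr.translate(dof.axis * value)


def validate_pose(model: SkeletalModel, pose: Pose, strict: bool = False) -> None:
    """Check completeness/finiteness; warn (or raise if strict) on out-of-range values."""
    missing = [c for c in model.coordinate_names if c not in pose]
    if missing:
        raise IncompletePoseError(f"pose is missing coordinates: {missing}")
    bad = [c for c in model.coordinate_names if not np.isfinite(pose[c])]
    if bad:
        raise IncompletePoseError(f"pose has non-finite values for: {bad}")
    out = [c.name for c in model.coordinates
           if not (c.range_min - 1e-12 <= pose[c.name] <= c.range_max + 1e-12)]
    if out:
        msg = f"pose values outside coordinate ranges: {out}"
        if strict:
            raise IncompletePoseError(msg)
        warnings.warn(msg, stacklevel=3)


def forward_kinematics(model: SkeletalModel, pose: Pose, strict: bool = False) -> BodyTransformSet:
    """Global rigid transform of every body segment for the given pose.

    Each child transform is
    ``parent ∘ translate(location_in_parent) ∘ DOF transforms (in order) ∘
    translate(-location_in_child)``.
    """
    with warnings.catch_warnings():
        if not strict:
            warnings.simplefilter("ignore")  # out-of-range is tolerated here
        validate_pose(model, pose, strict=strict)
    transforms: BodyTransformSet = {}
    ground = tr.identity()
    for joint in model.topo_joints:
        T = ground if joint.parent_body == GROUND else transforms[joint.parent_body]
        T = T @ tr.translate(joint.location_in_parent)
        for dof in joint.dofs:
            T = T @ _dof_matrix(dof, pose[dof.coordinate])
        T = T @ tr.translate(-joint.location_in_child)
        transforms[joint.child_body] = T
    return transforms


def rest_transforms(model: SkeletalModel) -> BodyTransformSet:
    """Body transforms at the rest (all-zero) pose."""
    return forward_kinematics(model, model.zero_pose())


def joint_centers(model: SkeletalModel, transforms: BodyTransformSet) -> Dict[str, np.ndarray]:
    """Ground-frame joint centers, computed child-side (they follow the body).

    For purely rotational joints the parent-side value
    ``T_parent(location_in_parent)`` must agree with the child-side value
    ``T_child(location_in_child)`` to 1e-9 m; this identity is asserted as an
    internal consistency check on the kinematics.  Joints with translation
    DOFs (the root free joint) have no fixed parent-side center — the
    translation carries the child away from the parent anchor — so only the
    child-side value is meaningful there.
    """
    centers = {}
    for j in model.joints:
        child_side = tr.apply(transforms[j.child_body], j.location_in_child)
        if all(d.kind == "rotation" for d in j.dofs):
            Tp = tr.identity() if j.parent_body == GROUND else transforms[j.parent_body]
            parent_side = tr.apply(Tp, j.location_in_parent)
            if np.max(np.abs(parent_side - child_side)) > 1e-9:
                raise AssertionError(
                    f"joint {j.name!r}: parent/child joint-center mismatch "
                    f"({parent_side} vs {child_side})")
        centers[j.name] = child_side
    return centers


def marker_positions(model: SkeletalModel, transforms: BodyTransformSet) -> Dict[str, np.ndarray]:
    """Ground-frame positions of the model's virtual markers."""
    out = {}
    for m in model.markers:
        if m.body not in transforms:
            raise KeyError(f"marker {m.name!r}: no transform for body {m.body!r}")
        out[m.name] = tr.apply(transforms[m.body], m.offset)
    return out


def random_pose(model: SkeletalModel, rng: np.random.Generator,
                translation_policy: str = "fixed") -> Pose:
    """Sample a pose uniformly within each coordinate's allowed range.

    Root translation coordinates are kept at their defaults when
    ``translation_policy == "fixed"`` (the avatar stays in place and only the
    camera moves), or sampled uniformly like the rest when ``"sampled"``.
    """
    if translation_policy not in ("fixed", "sampled"):
        raise ValueError(f"unknown translation_policy {translation_policy!r}")
    fixed = set(model.root_translation_coordinates()) if translation_policy == "fixed" else set()
    pose: Pose = {}
    for c in model.coordinates:
        if c.name in fixed:
            pose[c.name] = float(c.default)
        else:
            pose[c.name] = float(rng.uniform(c.range_min, c.range_max))
    return pose
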
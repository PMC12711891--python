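"""Dataset orchestration: permute poses × cameras × morphologies, write everything.

Output layout (one directory per generated subset)::

    <out>/
      images/       000000.jpg ...          RGB renders
      silhouettes/  000000.png ...          full-body masks
      segments/     000000_<body>.png ...   one mask per modelled body segment
      annotations/  annotations.csv         per-image keypoints, bbox, kinematics
                    metadata.csv            camera, morphology, seeds per image

``annotations.csv`` schema (versioned by a leading ``# schema_version=1``
comment line): ``image_id, bbox_x, bbox_y, bbox_w, bbox_h``, then for each
keypoint ``K`` (order fixed by the model: joints, bodies, markers) the
quadruple ``K_u, K_v, K_depth, K_visibility``, then one column per
generalized coordinate.  UTF-8, "." decimal, 6 significant digits.

The whole pipeline is deterministic given the config's master seed: the plan,
the CSVs and the pre-compression pixel content are reproducible bit-for-bit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .annotation_engine import (
    AnnotationConfig,
    FrameAnnotation,
    annotate_frame,
    build_collision_shapes,
)
from .avatar_mesh import MorphologyParams, generate_avatar
from .camera_geometry import Camera, CameraRanges, sample_camera
from .demo import demo_model
from .motion_io import MotionTrial, extract_equal_frames, pose_from_frame, read_mot
from .rendering import (
    RenderSettings,
    render_rgb,
    render_segment_mask,
    render_silhouette,
    save_mask,
    save_rgb,
)
from .rigging_skinning import (
    build_armature,
    compute_weights,
    deform_mesh,
    skinning_transforms,
)
from .skeletal_model import (
    SkeletalModel,
    forward_kinematics,
    load_model,
    random_pose,
    rest_transforms,
)

logger = logging.getLogger("skelsynth")

SCHEMA_VERSION = 1
_BACKGROUNDS = [
    ("gradient", (0.45, 0.55, 0.70), (0.80, 0.80, 0.85)),
    ("gradient", (0.25, 0.30, 0.25), (0.70, 0.75, 0.65)),
    ("gradient", (0.55, 0.45, 0.40), (0.85, 0.80, 0.75)),
    ("solid", (0.35, 0.35, 0.38)),
    ("solid", (0.75, 0.72, 0.68)),
]


@dataclass
class DatasetConfig:
    output_dir: str
    subset: str = "random"  # "real" | "random"
    n_images: int = 10
    motion_paths: Sequence[str] = ()
    model: Optional[SkeletalModel] = None  # None -> bundled demo model
    morphologies: Sequence[MorphologyParams] = field(
        default_factory=lambda: [MorphologyParams()])
    camera_ranges: Optional[CameraRanges] = None  # target is set per frame
    padding: float = 25.0
    step: int = 25
    segment_threshold: float = 0.5
    seed: int = 0
    width: int = 1024
    height: int = 1024
    translation_policy: str = "fixed"
    resume: bool = False

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.subset not in ("real", "random"):
            raise ValueError("subset must be 'real' or 'random'")
        if self.subset == "real" and not self.motion_paths:
            raise ValueError("subset 'real' needs at least one .mot motion source")
        if not self.morphologies:
            raise ValueError("need at least one morphology")


@dataclass
class PlanRecord:
    image_id: str
    pose_source: str  # "<trial>:<frame>" or "random:<seed>"
    trial: Optional[str]
    frame: Optional[int]
    pose_seed: Optional[int]
    morphology_index: int
    camera_seed: int
    appearance_seed: int
    background_index: int


@dataclass
class PermutationPlan:
    records: List[PlanRecord]

    def __post_init__(self):
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("image ids must be unique")

    def __len__(self):
        return len(self.records)


def _load_trials(config: DatasetConfig, model: SkeletalModel) -> List[MotionTrial]:
    return [read_mot(p, model=model) for p in config.motion_paths]


def plan_permutations(config: DatasetConfig,
                      trials: Optional[List[MotionTrial]] = None) -> PermutationPlan:
    """Deterministic per-image plan: pose reference, morphology, seeds, background.

    Real subsets draw pose frames via :func:`extract_equal_frames` (cycling
    when ``n_images`` exceeds the selected frame count); random subsets give
    each image its own pose seed.  Morphologies are assigned round-robin.
    """
    model = config.model or demo_model()
    rng = np.random.default_rng(config.seed)
    records: List[PlanRecord] = []
    pairs: List[Tuple[str, int]] = []
    if config.subset == "real":
        trials = trials if trials is not None else _load_trials(config, model)
        available = sum(t.n_frames for t in trials)
        pairs = extract_equal_frames(trials, min(config.n_images, available))
    n_morph = len(config.morphologies)
    for i in range(config.n_images):
        pose_seed = None
        trial = frame = None
        if config.subset == "real":
            trial, frame = pairs[i % len(pairs)]
            source = f"{trial}:{frame}"
        else:
            pose_seed = int(rng.integers(0, 2**31 - 1))
            source = f"random:{pose_seed}"
        records.append(PlanRecord(
            image_id=f"{i:06d}",
            pose_source=source,
            trial=trial,
            frame=frame,
            pose_seed=pose_seed,
            morphology_index=i % n_morph,
            camera_seed=int(rng.integers(0, 2**31 - 1)),
            appearance_seed=int(rng.integers(0, 2**31 - 1)),
            background_index=int(rng.integers(0, len(_BACKGROUNDS))),
        ))
    return PermutationPlan(records=records)


def _appearance_colors(n_vertices: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    base = np.array([0.78, 0.62, 0.52]) * rng.uniform(0.75, 1.15)
    noise = rng.normal(0.0, 0.015, size=(n_vertices, 3))
    return np.clip(base + noise, 0.0, 1.0)


def _format_value(v: float) -> str:
    return f"{v:.6g}"


def write_annotations_csv(records: Sequence[FrameAnnotation], path) -> None:
    """Write the wide one-row-per-image annotation table (6 significant digits)."""
    if not records:
        raise ValueError("no annotation records to write")
    kp_names = [k.name for k in records[0].keypoints]
    coord_names = list(records[0].kinematics)
    for r in records:
        if [k.name for k in r.keypoints] != kp_names or list(r.kinematics) != coord_names:
            raise ValueError(f"inconsistent keypoint/coordinate sets at image {r.image_id}")
    header = ["image_id", "bbox_x", "bbox_y", "bbox_w", "bbox_h"]
    for name in kp_names:
        header += [f"{name}_u", f"{name}_v", f"{name}_depth", f"{name}_visibility"]
    header += coord_names
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        fh.write(",".join(header) + "\n")
        for r in records:
            row = [r.image_id] + [_format_value(v) for v in
                                  (r.bbox.x, r.bbox.y, r.bbox.width, r.bbox.height)]
            for k in r.keypoints:
                row += [_format_value(v) for v in (k.u, k.v, k.depth, k.visibility)]
            row += [_format_value(r.kinematics[c]) for c in coord_names]
            fh.write(",".join(row) + "\n")


def write_metadata_csv(plan: PermutationPlan, cameras: Dict[str, Camera],
                       config: DatasetConfig, path) -> None:
    """Per-image generation metadata: subset, pose source, morphology, camera, seeds."""
    header = ["image_id", "subset", "pose_source", "morphology_index", "sex_tag",
              "shape", "mesh_resolution",
              "cam_x", "cam_y", "cam_z",
              *[f"cam_r{i}{j}" for i in range(3) for j in range(3)],
              "fov_vertical", "width", "height", "background_index",
              "camera_seed", "appearance_seed", "master_seed"]
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        fh.write(",".join(header) + "\n")
        for r in plan.records:
            m = config.morphologies[r.morphology_index]
            cam = cameras[r.image_id]
            row = [r.image_id, config.subset, r.pose_source, str(r.morphology_index),
                   m.sex_tag, _format_value(m.shape), str(m.mesh_resolution),
                   *[_format_value(v) for v in cam.position],
                   *[_format_value(v) for v in cam.rotation.ravel()],
                   _format_value(cam.fov_vertical), str(cam.width), str(cam.height),
                   str(r.background_index), str(r.camera_seed), str(r.appearance_seed),
                   str(config.seed)]
            fh.write(",".join(row) + "\n")


def generate_dataset(config: DatasetConfig) -> dict:
    """Run the full pipeline; returns a manifest with paths and counts."""
    out = Path(config.output_dir)
    dirs = {name: out / name for name in ("images", "silhouettes", "segments", "annotations")}
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)

    model = config.model or demo_model()
    rest = rest_transforms(model)
    trials = _load_trials(config, model) if config.subset == "real" else None
    trial_by_name = {t.name: t for t in (trials or [])}
    plan = plan_permutations(config, trials=trials)

    # per-morphology machinery, built once (collision shapes are rigid thereafter)
    cache = {}
    for idx in sorted({r.morphology_index for r in plan.records}):
        mesh = generate_avatar(model, config.morphologies[idx], rest)
        armature = build_armature(model, rest)
        weights = compute_weights(mesh, armature)
        shapes = build_collision_shapes(mesh, weights.vertex_bodies(), rest)
        cache[idx] = (mesh, armature, weights, shapes)
        logger.info("morphology %d: mesh with %d vertices", idx, mesh.n_vertices)

    ann_config = AnnotationConfig(step=config.step, padding=config.padding)
    annotations: List[FrameAnnotation] = []
    cameras: Dict[str, Camera] = {}
    body_names = [b.name for b in model.bodies]

    for r in plan.records:
        mesh, armature, weights, shapes = cache[r.morphology_index]
        if config.subset == "real":
            pose = pose_from_frame(model, trial_by_name[r.trial], r.frame)
        else:
            pose = random_pose(model, np.random.default_rng(r.pose_seed),
                               translation_policy=config.translation_policy)
        transforms = forward_kinematics(model, pose)
        skin = skinning_transforms(armature, transforms, rest)
        deformed = deform_mesh(mesh, weights, skin)
        ranges = config.camera_ranges or CameraRanges()
        ranges = replace(ranges, target=deformed.vertices.mean(axis=0),
                         width=config.width, height=config.height)
        camera = sample_camera(np.random.default_rng(r.camera_seed), ranges)
        cameras[r.image_id] = camera
        annotations.append(annotate_frame(model, pose, deformed, camera, shapes,
                                          config=ann_config, image_id=r.image_id,
                                          transforms=transforms))

        settings = RenderSettings(width=config.width, height=config.height,
                                  background=_BACKGROUNDS[r.background_index],
                                  segment_threshold=config.segment_threshold)
        rgb_path = dirs["images"] / f"{r.image_id}.jpg"
        if not (config.resume and rgb_path.exists()):
            colors = _appearance_colors(mesh.n_vertices, r.appearance_seed)
            save_rgb(render_rgb(deformed, camera, settings, appearance=colors),
                     rgb_path, quality=settings.jpeg_quality)
            save_mask(render_silhouette(deformed, camera, settings),
                      dirs["silhouettes"] / f"{r.image_id}.png")
            for body in body_names:
                save_mask(render_segment_mask(deformed, weights, body, camera, settings),
                          dirs["segments"] / f"{r.image_id}_{body}.png")
        logger.info("generated image %s (%s)", r.image_id, r.pose_source)

    ann_path = dirs["annotations"] / "annotations.csv"
    meta_path = dirs["annotations"] / "metadata.csv"
    write_annotations_csv(annotations, ann_path)
    write_metadata_csv(plan, cameras, config, meta_path)
    return {
        "output_dir": str(out),
        "n_images": len(plan),
        "n_segment_masks": len(plan) * len(body_names),
        "annotations_csv": str(ann_path),
        "metadata_csv": str(meta_path),
    }


def load_config(path, seed: Optional[int] = None,
                output_dir: Optional[str] = None) -> DatasetConfig:
    """Build a :class:`DatasetConfig` from a YAML mapping (CLI entry point)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    model = load_model(data["model"]) if "model" in data else None
    morphs = [MorphologyParams(**m) for m in data.get("morphologies", [{}])]
    ranges = CameraRanges(**data["camera_ranges"]) if "camera_ranges" in data else None
    return DatasetConfig(
        output_dir=output_dir or data.get("output_dir", "skelsynth_out"),
        subset=data.get("subset", "random"),
        n_images=int(data.get("n_images", 10)),
        motion_paths=data.get("motion_paths", ()),
        model=model,
        morphologies=morphs,
        camera_ranges=ranges,
        padding=float(data.get("padding", 25.0)),
        step=int(data.get("step", 25)),
        segment_threshold=float(data.get("segment_threshold", 0.5)),
        seed=int(data.get("seed", 0) if seed is None else seed),
        width=int(data.get("width", 1024)),
        height=int(data.get("height", 1024)),
        translation_policy=data.get("translation_policy", "fixed"),
        resume=bool(data.get("resume", False)),
    )
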
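"""Quality-control experiments: bbox step sensitivity, coordinate distributions.

The step experiment quantifies how subsampling the mesh vertices (every N-th
vertex) when computing the 3D bounding box changes the projected 2D box
dimensions, relative to using every vertex (step 1).  Differences are
one-sided: the subsampled box is always contained in the full box.

``coordinate_distributions`` summarizes a set of poses per generalized
coordinate with a range-bounded histogram and a Kolmogorov–Smirnov statistic
against the uniform distribution on the coordinate's allowed range.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_engine import bbox_2d, bbox_3d
from .avatar_mesh import MorphologyParams, generate_avatar
from .camera_geometry import CameraRanges, sample_camera
from .demo import demo_model
from .rigging_skinning import (
    build_armature,
    compute_weights,
    deform_mesh,
    skinning_transforms,
)
from .skeletal_model import (
    Pose,
    SkeletalModel,
    forward_kinematics,
    random_pose,
    rest_transforms,
)

DEFAULT_STEPS = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50)


@dataclass
class StepExperimentResult:
    """Absolute 2D bbox dimension differences vs step 1, per step parameter."""

    steps: Tuple[int, ...]
    delta_width: Dict[int, np.ndarray]  # step -> |Δwidth| per image, pixels
    delta_height: Dict[int, np.ndarray]

    def summary(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            dw, dh = self.delta_width[s], self.delta_height[s]
            rows.append({
                "step": s,
                "median_dw": float(np.median(dw)),
                "median_dh": float(np.median(dh)),
                "max_dw": float(np.max(dw)),
                "max_dh": float(np.max(dh)),
                "median_all": float(np.median(np.concatenate([dw, dh]))),
            })
        return pd.DataFrame(rows)

    def pooled_median(self, steps: Optional[Sequence[int]] = None) -> float:
        """Median of all |Δwidth| and |Δheight| values pooled over the given steps."""
        steps = [s for s in (steps or self.steps) if s != 1]
        pool = np.concatenate([np.concatenate([self.delta_width[s], self.delta_height[s]])
                               for s in steps])
        return float(np.median(pool))


def bbox_step_experiment(model: Optional[SkeletalModel] = None,
                         morphology: Optional[MorphologyParams] = None,
                         n_images: int = 100,
                         steps: Sequence[int] = DEFAULT_STEPS,
                         seed: int = 0,
                         width: int = 1024, height: int = 1024) -> StepExperimentResult:
    """Bounding-box step-sensitivity experiment on seeded random poses.

    For each of ``n_images`` uniformly random poses with a randomized camera,
    the unpadded 2D bounding box of the deformed avatar is computed at step 1
    and at each step in ``steps``; absolute width/height differences are
    collected.  Projection only — no rendering — so this runs at desk scale.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    model = model or demo_model()
    morphology = morphology or MorphologyParams()
    rest = rest_transforms(model)
    mesh = generate_avatar(model, morphology, rest)
    armature = build_armature(model, rest)
    weights = compute_weights(mesh, armature)

    rng = np.random.default_rng(seed)
    steps = tuple(steps)
    dw = {s: np.empty(n_images) for s in steps}
    dh = {s: np.empty(n_images) for s in steps}
    for i in range(n_images):
        pose = random_pose(model, rng, translation_policy="fixed")
        transforms = forward_kinematics(model, pose)
        skin = skinning_transforms(armature, transforms, rest)
        deformed = deform_mesh(mesh, weights, skin)
        ranges = CameraRanges(target=deformed.vertices.mean(axis=0),
                              width=width, height=height)
        camera = sample_camera(rng, ranges)
        full = bbox_2d(camera, bbox_3d(deformed, 1), padding=0.0)
        for s in steps:
            if s == 1:
                dw[s][i] = dh[s][i] = 0.0
                continue
            sub = bbox_2d(camera, bbox_3d(deformed, s), padding=0.0)
            dw[s][i] = abs(full.width - sub.width)
            dh[s][i] = abs(full.height - sub.height)
    return StepExperimentResult(steps=steps, delta_width=dw, delta_height=dh)


def coordinate_distributions(frames: Sequence[Pose], model: SkeletalModel,
                             bins: int = 20) -> Dict[str, dict]:
    """Per-coordinate histogram (bounded to the allowed range) and KS-vs-uniform stat."""
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    out = {}
    for c in model.coordinates:
        vals = np.array([f[c.name] for f in frames])
        hist, edges = np.histogram(vals, bins=bins, range=(c.range_min, c.range_max))
        ks = stats.kstest(vals, stats.uniform(loc=c.range_min,
                                              scale=c.range_max - c.range_min).cdf)
        out[c.name] = {
            "histogram": hist,
            "bin_edges": edges,
            "ks_statistic": float(ks.statistic),
            "ks_pvalue": float(ks.pvalue),
        }
    return out


def keypoint_set_distance(set_a: Mapping[str, Sequence[float]],
                          set_b: Mapping[str, Sequence[float]]) -> dict:
    """Per-name Euclidean pixel distance between two keypoint sets.

    Returns ``{"distances": {name: px}, "only_a": [...], "only_b": [...]}``.
    Raises on an empty name intersection.
    """
    shared = sorted(set(set_a) & set(set_b))
    if not shared:
        raise ValueError("keypoint sets share no names")
    distances = {
        name: float(np.linalg.norm(np.asarray(set_a[name], dtype=float)
                                   - np.asarray(set_b[name], dtype=float)))
        for name in shared
    }
    return {
        "distances": distances,
        "only_a": sorted(set(set_a) - set(set_b)),
        "only_b": sorted(set(set_b) - set(set_a)),
    }
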
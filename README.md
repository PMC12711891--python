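# skelsynth

Synthetic, automatically annotated images of human skeletal motion, generated
from musculoskeletal forward kinematics.

Training human pose estimation (HPE) models needs tens of thousands of
annotated images, and hand-annotated datasets carry the anatomical
imprecision of their annotators. `skelsynth` takes the opposite route: a
simplified musculoskeletal (MSK) model — a tree of rigid body segments with
bounded generalized coordinates — is posed by forward kinematics, a skinned
procedural avatar follows the skeleton, and every rendered frame is annotated
*from the model*: 2D keypoints for joint centers, body origins and virtual
markers; per-keypoint depth and occlusion-based visibility; padded bounding
boxes; silhouette and per-segment masks; and the full kinematics vector. The
annotations are exact by construction, and new annotation points are added by
editing the model's virtual marker set.

## The model in brief

- **Forward kinematics.** For each joint,
  `T_child = T_parent · Trans(p) · D_1 ⋯ D_k · Trans(−c)` with rotation/
  translation DOF transforms applied in listed order; ground frame Y-up,
  meters, radians.
- **Rigging.** The armature mirrors the skeleton with three bone kinds
  (segment / control / connector). The construction guarantees the skinning
  transform of body *b* is `S_b = T_b(pose)·T_b(rest)⁻¹`.
- **Skinning.** Linear blend skinning with inverse-square point-to-segment
  weights `w ∝ 1/(d² + ε)`, connector mass transferred to its origin bone,
  rows normalized to 1.
- **Visibility.** `visibility = 1/(1+N)` ∈ (0, 1], where `N` is the number of
  rigid per-segment convex hulls a camera→landmark ray enters before the
  landmark (a self-occlusion measure; a landmark inside its own segment's
  hull scores 0.5).
- **Bounding box.** Axis-aligned 3D box over every 25th mesh vertex,
  projected, min/max, padded 25 px per side (both configurable).

A bundled demo model (14 bodies, 26 coordinates, pelvis-rooted, T-pose at the
zero pose) and a procedural capsule avatar (~7,500 vertices by default) make
everything runnable with no external assets. OpenSim `.mot` motion files are
read natively; `real` subsets pose the avatar from motion trials, `random`
subsets sample coordinates uniformly within their allowed ranges.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

```python
import skelsynth as ss

model = ss.demo_model()
rest = ss.rest_transforms(model)
mesh = ss.generate_avatar(model, ss.MorphologyParams(), rest)
armature = ss.build_armature(model, rest)
weights = ss.compute_weights(mesh, armature)
shapes = ss.build_collision_shapes(mesh, weights.vertex_bodies(), rest)

pose = model.zero_pose()
pose.update(hip_flexion_r=0.6, knee_angle_r=-1.0, arm_flex_l=1.2)
T = ss.forward_kinematics(model, pose)
deformed = ss.deform_mesh(mesh, weights, ss.skinning_transforms(armature, T, rest))

camera = ss.Camera.look_at(position=(0.5, 1.4, 3.2), target=(0, 0.9, 0),
                           fov_vertical=60)
ann = ss.annotate_frame(model, pose, deformed, camera, shapes, transforms=T)

print(f"mesh: {mesh.n_vertices} vertices, {mesh.n_faces} faces")
print(f"bbox: x={ann.bbox.x:.1f} y={ann.bbox.y:.1f} "
      f"w={ann.bbox.width:.1f} h={ann.bbox.height:.1f}")
for k in ann.keypoints:
    if k.name in ("knee_r", "ankle_r", "RWRA"):
        print(f"{k.kind:6s} {k.name:8s} u={k.u:7.1f} v={k.v:7.1f} "
              f"depth={k.depth:.3f} m vis={k.visibility:.2f}")
```

prints

```
mesh: 7500 vertices, 14940 faces
bbox: x=253.8 y=291.7 w=531.2 h=536.3
joint  knee_r   u=  543.3 v=  594.1 depth=3.568 m vis=0.50
joint  ankle_r  u=  537.6 v=  703.7 depth=3.529 m vis=1.00
marker RWRA     u=  712.8 v=  386.7 depth=3.207 m vis=0.50
```

The flexed right knee sits at pixel (543, 594), 3.57 m from the camera, with
visibility 0.5 — the ray enters the femur's own collision hull before
reaching the joint center (N = 1), the expected score for a landmark buried
in its own segment. The ankle's ray happens to graze between the shank and
foot hulls, so N = 0 and visibility is exactly 1. Pixel coordinates use a
top-left origin with v pointing down.

## Generating a dataset

```sh
cat > config.yaml << 'YAML'
subset: random
n_images: 25
width: 1024
height: 1024
morphologies:
  - {sex_tag: female, shape: 0.0}
  - {sex_tag: male, shape: 1.0}
YAML
skelsynth generate --config config.yaml --seed 42 --out out/
```

writes `out/images/*.jpg`, `out/silhouettes/*.png`, one
`out/segments/<id>_<body>.png` per body segment, and
`out/annotations/{annotations,metadata}.csv`. Reruns with the same seed are
byte-identical in the CSVs. `skelsynth plan` previews the permutation plan;
`skelsynth qc bbox-steps` and `skelsynth qc coord-dist` run the QC
experiments.

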
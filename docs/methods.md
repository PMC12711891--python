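# Methods

`skelsynth` generates synthetic, automatically annotated images of human
skeletal motion. A simplified musculoskeletal (MSK) model is posed by forward
kinematics; a procedural skinned avatar follows the skeleton by linear blend
skinning; a pinhole camera and a software rasterizer produce images, and every
frame is annotated from the model itself — not from the pixels. This note
records the model, its assumptions, the tunable parameters, and the design
choices made where the design was genuinely open.

## Skeletal model and forward kinematics

A model is a tree of rigid body segments connected by joints, rooted at a
single body (the pelvis) attached to ground. The ground frame is right-handed,
Y-up, in meters. Each joint carries an ordered list of DOFs, each referencing
one generalized coordinate (radians for rotations, meters for translations)
with a bounded range. A child body's global transform is

```
T_child = T_parent · Trans(location_in_parent) · D_1 · … · D_k · Trans(−location_in_child)
```

with the DOF transforms `D_i` applied in listed order (intrinsic composition
about per-DOF axes, matching the common custom-joint semantics of gait
models). The *rest pose* is the all-zero pose; bundled geometry is authored so
this is a standing T-pose.

Out-of-range pose values are tolerated with a warning (motion files produced
by inverse kinematics routinely exceed ranges slightly); a `strict` flag turns
the warning into an error.

**Joint centers.** Centers are computed child-side,
`T_child(location_in_child)`, so they follow the annotated body. For purely
rotational joints the parent-side value must agree to 1e-9 m and this identity
is asserted on every call — it is a strong internal check on the FK
composition. Joints with translation DOFs (the 6-DOF root) have no fixed
parent-side center: the translation DOF carries the child away from the
parent-side anchor, so only the child-side value is meaningful.

**Bundled demo model.** 14 bodies (pelvis; torso including the head; three
segments per limb) and 26 coordinates: 6-DOF root, 2-DOF lumbar, 3-DOF hips,
2-DOF shoulders, 1-DOF knees, ankles, elbows and wrists. Ranges approximate
physiological ranges of motion. Virtual markers use conventional motion-capture
names (RASI, C7, RKNE, …).

**Model files.** A documented JSON/YAML schema (`format_version: "1"`)
carries exactly these fields. It is a deliberate, minimal stand-in for
OpenSim `.osim` files, of which only topology, DOFs, coordinate ranges, and
markers are needed here; a full `.osim` parser is out of scope.

## Motion files

OpenSim `.mot` text files are read and written natively (no maintained
standalone `.mot` reader exists among this package's dependencies). Header
keys are case-insensitive; `inDegrees` defaults to `yes` (the OpenSim
convention). Which columns are rotational — and therefore converted to
radians — is decided by the bound model when one is supplied, else by an
overridable heuristic (every non-`time` column without a `_t`/`_tx`/`_ty`/`_tz`
suffix is rotational).

Equal-frame extraction spreads a total frame budget across trials:
`floor(total/n)` per trial with the remainder given to the first trials in
input order, and evenly strided indices `round(k·(F−1)/(q−1))` within each
trial, so every motion type is represented.

## Avatar mesh

One capsule shell per body segment, sized from the segment bone's length and a
per-segment radius preset. Morphology has three knobs:

| parameter | default | meaning |
|---|---|---|
| `shape` (β) | 0.0 | girth multiplier `1 + 0.15·β`, β ∈ [−2, 2] |
| `sex_tag` | `"female"` | shoulder/hip radius presets |
| `mesh_resolution` | 7500 | target vertex count (±20%) |

β is a single scalar standing in for the ten shape parameters of statistical
body models, chosen to reproduce the −2…+2 girth sweep qualitatively. The
default resolution matches the scale of the reference skin mesh the
annotation pipeline is designed around (~7.5k vertices). Vertex budgets are
distributed over capsules in proportion to surface area. Sector counts are
even, which makes mirrored bodies produce exactly mirror-symmetric vertex
sets about the sagittal plane — a property the tests exploit. The torso
capsule gets an additional head capsule because the torso body includes the
head. OBJ/PLY import is provided for users with their own meshes.

What the procedural avatar does **not** emulate: realistic skin/clothing
appearance, soft-tissue deformation, anthropometric covariance between
segments. Annotations derive from the skeleton, not the mesh surface, so
passing tests demonstrate the correctness of the annotation machinery — not
photorealism or anatomical fidelity of the images.

## Rigging and skinning

Three bone kinds:

- **Segment bones** drive deformation: head at the body's parent-joint
  center; tail at the distal joint center, at the midpoint of several distal
  joint centers (branching bodies like the torso), or continued for a fixed
  0.12 m along the incoming chain direction (leaf bodies like hands; also the
  fallback for degenerate zero-length cases, with a warning).
- **Control bones** (fixed length 0.10 m, sharing the segment bone's head,
  rest rotation = the body's rest rotation) receive the body's simulated
  motion; the parented segment bone follows. The construction makes the
  effective skinning transform of body *b* exactly
  `S_b = T_b(pose)·T_b(rest)⁻¹`, and the test suite asserts this identity to
  1e-9 for random poses. The two fixed lengths are config defaults, not
  claims — only "fixed" matters for the construction.
- **Connector bones** span any gap between a segment bone's tail and the next
  segment bone's head (these arise at branch midpoints in this construction).
  They participate in the raw weight computation and their mass is then
  transferred to the segment bone they originate from, emphasizing short
  bones (e.g. the pelvis, whose branch-midpoint tail makes it tiny) that
  would otherwise lose weights to their longer neighbours.

Weights use an inverse-square point-to-segment law `w = 1/(d² + ε)`,
ε = 1e-6 m², truncated below 1e-3 of the row maximum (keeps the matrix
sparse; configurable), connector-transferred, then row-normalized. This is a
deliberately transparent stand-in for heat-diffusion weighting: it preserves
the governing behaviour (the nearest bone dominates; exactly equidistant
vertices split evenly) while being exactly testable. Deformation is plain
linear blend skinning, `v′ = Σ_b w_vb·S_b(v)`; no dual quaternions, no
pose-space correction, so candy-wrapper artifacts at extreme twists are
expected and accepted.

## Camera

Pinhole, square pixels, **vertical** FOV; image origin at the **top-left
corner**, `u` right, `v` down — stated prominently because keypoint datasets
differ and nothing downstream re-documents it. Behind-camera points are
flagged, not dropped; the annotation layer keeps them so every landmark is
present in every row. Randomized cameras sit on a spherical shell around the
avatar centroid: radius U(2.5, 5) m, azimuth U(0, 2π), elevation
U(−20°, 45°), look-at jitter ±0.1 m per axis, FOV U(30°, 120°). Only the FOV
range is externally prescribed; the rest are this package's documented
defaults chosen to keep the avatar in frame at 1024×1024 while varying
framing substantially.

## Annotations

Per frame: every joint center, body-frame origin, and virtual marker is
projected (kinds `joint`/`body`/`marker`; joint and body keypoints largely
coincide because body origins sit at their parent joints). Depth is the
Euclidean camera-to-landmark distance in meters. Kinematics labels are the
full generalized-coordinate vector.

**Visibility** is `1/(1+N)`, in (0, 1], where `N` counts the per-segment
convex collision shapes the camera→landmark ray *enters* strictly before the
landmark. Hulls are built once from the dominant-weight vertex assignment,
expressed body-locally, and only translate/rotate afterwards — deformation is
deliberately ignored, adding some inconsistency in extreme poses. A landmark
inside its own segment's hull scores 0.5 unoccluded (the hip-inside-femur
case); a ray grazing between two hulls can yield N = 0; both emerge naturally
and are not special-cased. The entry tie rule uses a relative epsilon of
1e-9 of the ray length (scale-free; the absolute and relative readings only
differ for rays near 1 m, far below hull dimensions). Ray–hull intersection
is half-space slab clipping; the tests cross-check it against a dense
10,000-sample membership oracle on 200 randomized scenes. Segments with
fewer than four non-coplanar vertices are flagged degenerate and excluded
with a warning.

**Bounding boxes** are recomputed per frame on the deformed mesh: 3D
axis-aligned box over every `step`-th vertex (default 25; an explicit vertex
subset may replace striding), its 8 corners projected, 2D min/max taken, then
padded on all four sides (default 25 px). The default follows the generation
protocol's stated padding; the validation discussion mentions 30 px — both
are one config value away. Boxes are not clipped to the image; negative
corners are downstream's choice to clip.

## Rendering

A z-buffered software rasterizer with pixel-center sampling, no anti-aliasing
(masks stay exactly binary) and flat Lambertian shading
(`0.3 + 0.7·max(0, n·l)`, face normal oriented toward the camera). Depth is
interpolated linearly in screen space — an approximation acceptable for
opaque single-mesh scenes. Triangles with any vertex at non-positive
view-space depth are dropped rather than clipped; full-body framing keeps the
avatar inside the frustum. Silhouettes are, by construction, the z-buffer hit
set of the same rasterization path as RGB. Segment masks hide vertices whose
weight to the segment is below the threshold (default 0.5, a **hard cutoff**:
exactly 0.5 is shown) and rasterize a triangle iff all three vertices are
shown; the triangle-boundary semantics of per-vertex hiding are otherwise
unspecified, so an `"any"` rule is available as a switch. RGB is saved as
JPEG (quality 90); masks as PNG, because lossy masks would corrupt labels.

## Dataset pipeline

A deterministic plan (master seed → per-image pose/camera/appearance seeds,
round-robin morphology, background choice) drives generation. `real` subsets
take poses from `.mot` trials via equal-frame extraction, cycling when more
images than frames are requested; `random` subsets sample uniformly within
coordinate ranges (root translations pinned by default — the camera, not the
avatar, moves). Outputs: `images/`, `silhouettes/`, `segments/`
(`<id>_<body>.png`, one mask per modelled body), `annotations/annotations.csv`
and `metadata.csv`. The CSV column layout is this package's own (versioned by
a `# schema_version` comment line); only the folder/file layout mirrors the
published dataset's organization, not its exact columns. Same config + seed
reproduce the CSVs byte-for-byte and the pre-compression pixels exactly.

## QC experiments and problem sizes

`bbox_step_experiment` measures |Δwidth| and |Δheight| of the unpadded 2D box
for steps 5…50 vs step 1 over seeded random poses; by construction the
subsampled box is contained in the full box, so differences are one-sided.
The headline statistic is the pooled median over both dimensions and all
steps — "mostly below" operationalized as a median. The experiment is
projection-only (no rendering), so the standard run of 100 images at
1024×1024 with the default ~7,500-vertex avatar completes in seconds.
`coordinate_distributions` provides range-bounded histograms and per
coordinate KS-vs-uniform statistics; `keypoint_set_distance` gives per-name
pixel distances for users comparing external detections against annotations
(no pose-estimation model is run here).

Test problem sizes: most image-producing tests run at 160–512 px with
1,500–2,000-vertex avatars; default-resolution checks (vertex-count band,
1024×1024 output, step experiment) run at full scale. These sizes are chosen
so the whole suite exercises every default while staying fast enough to run
habitually.

## Known limitations

- Single-person scenes only; visibility is a self-occlusion measure (no
  environment colliders).
- Rigid collision hulls and rigid capsules ignore mesh deformation; extreme
  random poses can interpenetrate segments.
- No lens distortion, shadows, textures, or HDRI backgrounds; appearance is
  per-vertex color over procedural backgrounds.
- The weight law is distance-based, not diffusion-based; weights near complex
  junctions (armpit, neck) are cruder than heat-based rigging would give.
- No muscle paths, dynamics, inverse kinematics, or model scaling to subject
  anthropometry.
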
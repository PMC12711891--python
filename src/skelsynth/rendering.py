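"""Deterministic software rasterizer: RGB renders, silhouettes, segment masks.

A z-buffered triangle rasterizer with Lambertian flat shading
(``0.3 ambient + 0.7·max(0, n·l)`` with the face normal oriented toward the
camera).  Sampling is at pixel centers with no anti-aliasing, so masks are
exactly binary; silhouettes are, by construction, the set of pixels where the
z-buffer recorded a hit.  Triangles with any vertex at non-positive view-space
depth are dropped (no near-plane clipping — full-body scenes keep the avatar
well inside the frustum).  Depth is interpolated linearly in screen space.

Segment masks follow a vertex-threshold rule: a vertex is *shown* for a
segment iff its skinning weight to that segment's bone is ≥ the threshold
(default 0.5, a hard cutoff: exactly 0.5 is shown), and a triangle is
rasterized iff all three of its vertices are shown (switchable to "any").
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
from PIL import Image

from .avatar_mesh import TriangleMesh
from .camera_geometry import Camera, project
from .rigging_skinning import WeightMatrix

#: background: ("solid", rgb) | ("gradient", top_rgb, bottom_rgb) | ("image", path)
BackgroundSpec = Tuple


@dataclass
class RenderSettings:
    width: int = 1024
    height: int = 1024
    background: BackgroundSpec = ("gradient", (0.45, 0.55, 0.70), (0.80, 0.80, 0.85))
    light_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.3, -0.8, 0.5]) / np.linalg.norm([0.3, -0.8, 0.5]))
    segment_threshold: float = 0.5
    hide_rule: str = "all"  # "all": triangle shown iff all 3 vertices shown; or "any"
    jpeg_quality: int = 90

    def __post_init__(self):
        self.light_direction = np.asarray(self.light_direction, dtype=float)
        self.light_direction /= np.linalg.norm(self.light_direction)
        if not 0.0 < self.segment_threshold < 1.0:
            raise ValueError("segment_threshold must lie in (0, 1)")
        if self.width < 16 or self.height < 16:
            raise ValueError("resolution must be at least 16x16")
        if self.hide_rule not in ("all", "any"):
            raise ValueError("hide_rule must be 'all' or 'any'")


def rasterize(mesh: TriangleMesh, camera: Camera, settings: RenderSettings,
              face_mask: Optional[np.ndarray] = None
              ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize; returns (zbuffer, face_index, hit_mask) of shape (H, W).

    ``face_index`` holds the index of the nearest triangle per pixel (-1 where
    none).  ``face_mask`` optionally restricts rasterization to a face subset.
    """
    W, H = settings.width, settings.height
    zbuf = np.full((H, W), np.inf)
    fidx = np.full((H, W), -1, dtype=np.int64)
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        return zbuf, fidx, np.zeros((H, W), dtype=bool)

    cam = Camera(position=camera.position, rotation=camera.rotation,
                 fov_vertical=camera.fov_vertical, width=W, height=H)
    uv, _ = project(cam, mesh.vertices)
    z = cam.view_coords(mesh.vertices)[:, 2]

    faces = mesh.faces if face_mask is None else mesh.faces[face_mask]
    face_ids = np.arange(mesh.n_faces) if face_mask is None else np.flatnonzero(face_mask)
    in_front = np.all(z[faces] > 1e-6, axis=1)
    faces = faces[in_front]
    face_ids = face_ids[in_front]

    for f, fid in zip(faces, face_ids):
        p0, p1, p2 = uv[f]
        lo = np.floor(np.minimum(np.minimum(p0, p1), p2) - 0.5).astype(int)
        hi = np.ceil(np.maximum(np.maximum(p0, p1), p2) + 0.5).astype(int)
        x0, y0 = np.maximum(lo, 0)
        x1, y1 = np.minimum(hi, [W - 1, H - 1])
        if x1 < x0 or y1 < y0:
            continue
        area = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p1[1] - p0[1]) * (p2[0] - p0[0])
        if abs(area) < 1e-12:
            continue
        xs = np.arange(x0, x1 + 1) + 0.5
        ys = np.arange(y0, y1 + 1) + 0.5
        px, py = np.meshgrid(xs, ys)
        w0 = ((p2[0] - p1[0]) * (py - p1[1]) - (p2[1] - p1[1]) * (px - p1[0])) / area
        w1 = ((p0[0] - p2[0]) * (py - p2[1]) - (p0[1] - p2[1]) * (px - p2[0])) / area
        w2 = 1.0 - w0 - w1
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        zpix = w0 * z[f[0]] + w1 * z[f[1]] + w2 * z[f[2]]
        tile = zbuf[y0:y1 + 1, x0:x1 + 1]
        closer = inside & (zpix < tile)
        tile[closer] = zpix[closer]
        fidx[y0:y1 + 1, x0:x1 + 1][closer] = fid
    return zbuf, fidx, fidx >= 0


def background_image(settings: RenderSettings) -> np.ndarray:
    """(H, W, 3) float background in [0, 1] per the settings' background spec."""
    W, H = settings.width, settings.height
    kind = settings.background[0]
    if kind == "solid":
        return np.broadcast_to(np.asarray(settings.background[1], dtype=float),
                               (H, W, 3)).copy()
    if kind == "gradient":
        top = np.asarray(settings.background[1], dtype=float)
        bottom = np.asarray(settings.background[2], dtype=float)
        t = np.linspace(0.0, 1.0, H)[:, None, None]
        return np.broadcast_to((1 - t) * top + t * bottom, (H, W, 3)).copy()
    if kind == "image":
        img = Image.open(settings.background[1]).convert("RGB").resize((W, H))
        return np.asarray(img, dtype=float) / 255.0
    raise ValueError(f"unknown background kind {kind!r}")


def render_rgb(mesh: TriangleMesh, camera: Camera, settings: RenderSettings,
               appearance: Optional[np.ndarray] = None) -> np.ndarray:
    """Shaded (H, W, 3) uint8 RGB image over the configured background.

    ``appearance`` overrides per-vertex colors (RGB in [0, 1]); default is the
    mesh's own colors or a neutral skin tone.
    """
    img = background_image(settings)
    zbuf, fidx, hit = rasterize(mesh, camera, settings)
    if hit.any():
        colors = appearance if appearance is not None else mesh.colors
        if colors is None:
            colors = np.broadcast_to(np.array([0.78, 0.62, 0.52]), (mesh.n_vertices, 3))
        v = mesh.vertices
        f = mesh.faces
        e1 = v[f[:, 1]] - v[f[:, 0]]
        e2 = v[f[:, 2]] - v[f[:, 0]]
        normals = np.cross(e1, e2)
        norms = np.linalg.norm(normals, axis=1, keepdims=True)
        normals = normals / np.where(norms < 1e-12, 1.0, norms)
        centers = v[f].mean(axis=1)
        toward = camera.position - centers
        flip = np.sign(np.sum(normals * toward, axis=1))
        normals *= np.where(flip == 0, 1.0, flip)[:, None]
        lam = 0.3 + 0.7 * np.maximum(0.0, normals @ -settings.light_direction)
        face_color = np.asarray(colors)[f].mean(axis=1) * lam[:, None]
        img[hit] = face_color[fidx[hit]]
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


def render_silhouette(mesh: TriangleMesh, camera: Camera,
                      settings: RenderSettings) -> np.ndarray:
    """Binary (H, W) uint8 mask: 255 wherever the rasterizer recorded a hit."""
    _, _, hit = rasterize(mesh, camera, settings)
    return hit.astype(np.uint8) * 255


def segment_face_mask(mesh: TriangleMesh, weights: WeightMatrix, segment: str,
                      settings: RenderSettings) -> np.ndarray:
    """Boolean face mask for one segment under the vertex-threshold hiding rule."""
    shown = weights.column(segment) >= settings.segment_threshold
    per_face = shown[mesh.faces]
    return per_face.all(axis=1) if settings.hide_rule == "all" else per_face.any(axis=1)


def render_segment_mask(mesh: TriangleMesh, weights: WeightMatrix, segment: str,
                        camera: Camera, settings: RenderSettings) -> np.ndarray:
    """Binary (H, W) uint8 mask of one body segment, white on black."""
    if segment not in weights.bodies:
        raise KeyError(f"unknown segment {segment!r}")
    fmask = segment_face_mask(mesh, weights, segment, settings)
    _, _, hit = rasterize(mesh, camera, settings, face_mask=fmask)
    return hit.astype(np.uint8) * 255


def save_rgb(image: np.ndarray, path, quality: int = 90) -> None:
    Image.fromarray(image, mode="RGB").save(str(path), format="JPEG", quality=quality)


def save_mask(mask: np.ndarray, path) -> None:
    Image.fromarray(mask, mode="L").save(str(path), format="PNG")
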
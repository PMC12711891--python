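"""Pinhole camera: projection, keypoint depth, unprojection, randomized sampling.

Pixel convention (stated prominently because keypoint datasets differ): the
image origin is the **top-left corner**, ``u`` grows rightward and ``v``
downward; continuous coordinates lie in ``[0, W) × [0, H)`` when the point is
inside the frame.  The field of view is **vertical** (square pixels; with the
default square 1024×1024 images it equals the horizontal FOV).

The camera frame has x right, y down, z forward; a point with non-positive
view-space depth is flagged behind-camera but its (extrapolated) pixel
coordinates are still returned, so the annotation layer can decide handling.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np


@dataclass
class Camera:
    """Pinhole camera state: position, orientation, vertical FOV, resolution."""

    position: np.ndarray
    rotation: np.ndarray  # 3x3; rows are the camera axes (x right, y down, z forward)
    fov_vertical: float  # degrees
    width: int = 1024
    height: int = 1024

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if not 0.0 < self.fov_vertical < 180.0:
            raise ValueError("fov_vertical must lie in (0, 180) degrees")
        if self.width < 1 or self.height < 1:
            raise ValueError("resolution must be at least 1x1")

    @classmethod
    def look_at(cls, position, target, fov_vertical: float,
                up=(0.0, 1.0, 0.0), width: int = 1024, height: int = 1024) -> "Camera":
        position = np.asarray(position, dtype=float)
        forward = np.asarray(target, dtype=float) - position
        n = np.linalg.norm(forward)
        if n < 1e-12:
            raise ValueError("camera position and look-at target coincide")
        forward /= n
        up = np.asarray(up, dtype=float)
        right = np.cross(forward, up)
        rn = np.linalg.norm(right)
        if rn < 1e-9:
            raise ValueError("up vector is parallel to the view direction")
        right /= rn
        down = np.cross(forward, right)  # right-handed with y pointing down
        R = np.vstack([right, down, forward])
        return cls(position=position, rotation=R, fov_vertical=fov_vertical,
                   width=width, height=height)

    @property
    def focal_pixels(self) -> float:
        return (self.height / 2.0) / np.tan(np.deg2rad(self.fov_vertical) / 2.0)

    def view_coords(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (p - self.position) @ self.rotation.T


def project(camera: Camera, points) -> Tuple[np.ndarray, np.ndarray]:
    """Project 3D points to continuous pixel coordinates.

    Returns ``(uv, behind)``: an (N, 2) array and a boolean behind-camera flag
    array.  A single (3,) point yields a (2,) array and a scalar flag.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pv = camera.view_coords(pts)
    z = pv[:, 2]
    behind = z <= 0.0
    # guard the division; flagged points get extrapolated coordinates
    z_safe = np.where(np.abs(z) < 1e-12, 1e-12, z)
    f = camera.focal_pixels
    u = camera.width / 2.0 + f * pv[:, 0] / z_safe
    v = camera.height / 2.0 + f * pv[:, 1] / z_safe
    uv = np.column_stack([u, v])
    if single:
        return uv[0], bool(behind[0])
    return uv, behind


def depth(camera: Camera, points) -> np.ndarray:
    """Euclidean distance (m) between the camera position and each point."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    d = np.linalg.norm(np.atleast_2d(pts) - camera.position, axis=1)
    return float(d[0]) if single else d


def unproject(camera: Camera, uv, d: float) -> np.ndarray:
    """Inverse of :func:`project` along the pixel ray, scaled to Euclidean distance d."""
    if d <= 0:
        raise ValueError("unproject needs a positive Euclidean distance")
    u, v = np.asarray(uv, dtype=float)
    f = camera.focal_pixels
    ray = np.array([(u - camera.width / 2.0) / f, (v - camera.height / 2.0) / f, 1.0])
    ray /= np.linalg.norm(ray)
    return camera.position + d * (camera.rotation.T @ ray)


@dataclass
class CameraRanges:
    """Randomization ranges for :func:`sample_camera`.

    The camera sits on a spherical shell around ``target`` (the avatar
    centroid), at a uniform radius, azimuth, and elevation, looking at the
    target plus a uniform jitter; the vertical FOV is uniform on ``fov_range``
    (default 30–120 degrees).
    """

    target: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius_range: Tuple[float, float] = (2.5, 5.0)
    azimuth_range: Tuple[float, float] = (0.0, 2.0 * np.pi)
    elevation_range_deg: Tuple[float, float] = (-20.0, 45.0)
    fov_range: Tuple[float, float] = (30.0, 120.0)
    target_jitter: float = 0.1  # m, per-axis uniform
    width: int = 1024
    height: int = 1024

    def __post_init__(self):
        self.target = np.asarray(self.target, dtype=float)
        for name in ("radius_range", "azimuth_range", "elevation_range_deg", "fov_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")


def sample_camera(rng: np.random.Generator, ranges: CameraRanges) -> Camera:
    """Draw a randomized camera; reproducible for a given seeded generator."""
    r = rng.uniform(*ranges.radius_range)
    az = rng.uniform(*ranges.azimuth_range)
    el = np.deg2rad(rng.uniform(*ranges.elevation_range_deg))
    offset = r * np.array([np.cos(el) * np.cos(az), np.sin(el), np.cos(el) * np.sin(az)])
    jitter = rng.uniform(-ranges.target_jitter, ranges.target_jitter, size=3)
    fov = rng.uniform(*ranges.fov_range)
    return Camera.look_at(position=ranges.target + offset, target=ranges.target + jitter,
                          fov_vertical=fov, width=ranges.width, height=ranges.height)
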
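"""Homogeneous rigid-transform helpers (4x4 matrices, row-vector-free API).

All transforms map body/local coordinates to the ground frame unless stated
otherwise.  The ground frame is right-handed, Y-up, in meters.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation as _R

__all__ = [
    "identity",
    "translate",
    "rotate_axis",
    "rt",
    "rotation",
    "translation",
    "inverse",
    "apply",
    "is_rotation",
]


def identity() -> np.ndarray:
    return np.eye(4)


def translate(v) -> np.ndarray:
    T = np.eye(4)
    T[:3, 3] = np.asarray(v, dtype=float)
    return T


def rotate_axis(axis, angle: float) -> np.ndarray:
    """Rotation by `angle` (radians) about a unit `axis`."""
    T = np.eye(4)
    T[:3, :3] = _R.from_rotvec(np.asarray(axis, dtype=float) * float(angle)).as_matrix()
    return T


def rt(R, t) -> np.ndarray:
    T = np.eye(4)
    T[:3, :3] = np.asarray(R, dtype=float)
    T[:3, 3] = np.asarray(t, dtype=float)
    return T


def rotation(T) -> np.ndarray:
    return np.asarray(T)[:3, :3]


def translation(T) -> np.ndarray:
    return np.asarray(T)[:3, 3]


def inverse(T) -> np.ndarray:
    # exploit rigidity: inv([R t]) = [R' -R't]
    R = rotation(T)
    t = translation(T)
    return rt(R.T, -R.T @ t)


def apply(T, points) -> np.ndarray:
    """Apply rigid transform to one point (3,) or a stack (N, 3)."""
    p = np.asarray(points, dtype=float)
    return p @ rotation(T).T + translation(T)


def is_rotation(R, tol: float = 1e-9) -> bool:
    R = np.asarray(R)
    if R.shape != (3, 3):
        return False
    ortho = np.max(np.abs(R.T @ R - np.eye(3))) < tol
    return bool(ortho and abs(np.linalg.det(R) - 1.0) < max(tol, 1e-12))
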
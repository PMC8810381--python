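"""Small geometric utilities shared across modules.

Frames are right-handed orthonormal triads; rotation helpers operate on
arrays of shape (..., 3, 3) so whole time series can be transformed at
once.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Frame",
    "rot_x",
    "rot_y",
    "rot_z",
    "angular_velocity_body",
    "periodic_gradient",
    "segments_intersect",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class Frame:
    """Right-handed orthonormal reference frame.

    ``axes`` holds the three unit vectors as rows, expressed in the parent
    (laboratory) frame, so ``axes.T @ v_local`` maps local to parent
    coordinates.
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-8):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(axes) < 0:
            raise ValueError("frame axes must be right-handed (det = +1)")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    def to_parent(self, v_local: np.ndarray) -> np.ndarray:
        """Map local coordinates/vectors of shape (..., 3) to the parent frame."""
        return np.asarray(v_local) @ self.axes

    def to_local(self, v_parent: np.ndarray) -> np.ndarray:
        return np.asarray(v_parent) @ self.axes.T

    def point_to_parent(self, p_local: np.ndarray) -> np.ndarray:
        return self.to_parent(p_local) + self.origin


def _rot(c, s, kind: str) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    s = np.asarray(s, dtype=float)
    out = np.zeros(c.shape + (3, 3))
    i, j, k = {"x": (0, 1, 2), "y": (1, 2, 0), "z": (2, 0, 1)}[kind]
    out[..., i, i] = 1.0
    out[..., j, j] = c
    out[..., k, k] = c
    out[..., k, j] = s
    out[..., j, k] = -s
    return out


def rot_x(angle_rad) -> np.ndarray:
    """Rotation matrices about the x axis; broadcasts over array input."""
    return _rot(np.cos(angle_rad), np.sin(angle_rad), "x")


def rot_y(angle_rad) -> np.ndarray:
    return _rot(np.cos(angle_rad), np.sin(angle_rad), "y")


def rot_z(angle_rad) -> np.ndarray:
    return _rot(np.cos(angle_rad), np.sin(angle_rad), "z")


def periodic_gradient(y: np.ndarray, dt: float, axis: int = 0) -> np.ndarray:
    """Central differences assuming ``y`` samples one full period on [0, T).

    The grid must exclude the duplicated endpoint; the stencil wraps around.
    """
    y = np.asarray(y, dtype=float)
    return (np.roll(y, -1, axis=axis) - np.roll(y, 1, axis=axis)) / (2.0 * dt)


def angular_velocity_body(R: np.ndarray, dt: float, periodic: bool = True) -> np.ndarray:
    """Body-frame angular velocity (rad per time unit) from a rotation series.

    ``R`` has shape (n, 3, 3) mapping body to lab coordinates (columns are the
    body axes in lab frame).  Uses omega_x = R^T dR/dt un-skewed.
    """
    R = np.asarray(R, dtype=float)
    if periodic:
        dR = periodic_gradient(R, dt, axis=0)
    else:
        dR = np.gradient(R, dt, axis=0)
    S = np.einsum("nji,njk->nik", R, dR)  # R^T dR, skew-symmetric
    omega = np.empty((R.shape[0], 3))
    omega[:, 0] = 0.5 * (S[:, 2, 1] - S[:, 1, 2])
    omega[:, 1] = 0.5 * (S[:, 0, 2] - S[:, 2, 0])
    omega[:, 2] = 0.5 * (S[:, 1, 0] - S[:, 0, 1])
    return omega


def segments_intersect(p1, p2, q1, q2, eps: float = 1e-12) -> bool:
    """True if closed 2-D segments [p1,p2] and [q1,q2] share a point."""
    p1, p2, q1, q2 = (np.asarray(a, dtype=float)[:2] for a in (p1, p2, q1, q2))

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        scale = max(abs(b[0] - a[0]), abs(b[1] - a[1]), abs(c[0] - a[0]), abs(c[1] - a[1]), 1.0)
        if abs(v) <= eps * scale * scale:
            return 0
        return 1 if v > 0 else -1

    def on_seg(a, b, c):
        return (min(a[0], b[0]) - eps <= c[0] <= max(a[0], b[0]) + eps
                and min(a[1], b[1]) - eps <= c[1] <= max(a[1], b[1]) + eps)

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    if o1 != o2 and o3 != o4:
        return True
    for a, b, c in ((p1, p2, q1), (p1, p2, q2), (q1, q2, p1), (q1, q2, p2)):
        if orient(a, b, c) == 0 and on_seg(a, b, c):
            return True
    return False
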
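"""Differentiable pinhole-camera geometry.

The view-synthesis core of the whole system: a target-frame pixel with depth
``D_t`` is back-projected through the intrinsics ``K``, moved by the relative
camera motion ``M_{t->s}`` and re-projected into the source frame,

    h(p_{s->t}) = [K|0] M_{t->s} [D_t K^{-1} h(p_t); 1],

after which the source image is bilinearly sampled at ``p_{s->t}``.

Intrinsics are stored normalised by image width/height so the same camera
object serves every pyramid scale; pixel-space matrices are materialised per
working resolution. Coordinates are 0-based with pixel centres at integers.
The low-level functions operate on autodiff tensors so gradients reach the
pose, intrinsics and depth predictors; the dataclass API at the top works on
plain NumPy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from . import autodiff as ad
from .autodiff import Tensor, as_tensor

_DEPTH_EPS = 1e-6


# --------------------------------------------------------------------- types

@dataclass(frozen=True)
class Intrinsics:
    """Normalised pinhole intrinsics: focals and principal point divided by
    image width (fx, cx) and height (fy, cy)."""

    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self):
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError(f"focal lengths must be positive, got "
                             f"fx={self.fx}, fy={self.fy}")
        if not (0 < self.cx < 1 and 0 < self.cy < 1):
            raise ValueError(f"principal point must lie inside the image, "
                             f"got cx={self.cx}, cy={self.cy}")

    def to_matrix(self, width: int, height: int) -> np.ndarray:
        if width < 2 or height < 2:
            raise ValueError("resolution must be at least 2x2")
        return np.array([[self.fx * width, 0.0, self.cx * width],
                         [0.0, self.fy * height, self.cy * height],
                         [0.0, 0.0, 1.0]])

    @staticmethod
    def from_matrix(k: np.ndarray, width: int, height: int) -> "Intrinsics":
        k = np.asarray(k, dtype=float)
        return Intrinsics(fx=k[0, 0] / width, fy=k[1, 1] / height,
                          cx=k[0, 2] / width, cy=k[1, 2] / height)


@dataclass(frozen=True)
class RigidMotion:
    """6-DoF rigid motion: axis-angle rotation (radians) + translation."""

    rotation: tuple
    translation: tuple

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3,) or t.shape != (3,):
            raise ValueError("rotation and translation must be 3-vectors")
        if not (np.isfinite(r).all() and np.isfinite(t).all()):
            raise ValueError("rigid motion must be finite")
        object.__setattr__(self, "rotation", tuple(r))
        object.__setattr__(self, "translation", tuple(t))

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = Rotation.from_rotvec(self.rotation).as_matrix()
        m[:3, 3] = self.translation
        return m

    @staticmethod
    def from_matrix(m: np.ndarray) -> "RigidMotion":
        m = np.asarray(m, dtype=float)
        rot = Rotation.from_matrix(m[:3, :3]).as_rotvec()
        return RigidMotion(tuple(rot), tuple(m[:3, 3]))

    def inverse(self) -> "RigidMotion":
        return RigidMotion.from_matrix(np.linalg.inv(self.to_matrix()))

    def compose(self, other: "RigidMotion") -> "RigidMotion":
        """Motion applying `other` first, then `self` (matrix product)."""
        return RigidMotion.from_matrix(self.to_matrix() @ other.to_matrix())


@dataclass
class WarpResult:
    """Synthesised view plus the per-pixel validity of the sample."""

    image: np.ndarray
    valid_mask: np.ndarray


def pixel_grid(width: int, height: int) -> tuple[np.ndarray, np.ndarray]:
    """(u, v) coordinate arrays of shape (height, width), 0-based integers."""
    v, u = np.mgrid[0:height, 0:width].astype(np.float64)
    return u, v


# ------------------------------------------------- differentiable primitives

def rotate_points(rotvec: Tensor, x: Tensor, y: Tensor, z: Tensor):
    """Rodrigues rotation of per-pixel points by a batched axis-angle vector.

    rotvec: (N, 3); x, y, z: (N, H, W). Stable through the zero-rotation
    limit (the epsilon keeps the angle away from 0/0 while leaving the
    rotation and its gradient exact to machine precision).
    """
    n = rotvec.shape[0]
    rx = rotvec[:, 0].reshape(n, 1, 1)
    ry = rotvec[:, 1].reshape(n, 1, 1)
    rz = rotvec[:, 2].reshape(n, 1, 1)
    theta = ad.sqrt(rx * rx + ry * ry + rz * rz + 1e-30)
    kx, ky, kz = rx / theta, ry / theta, rz / theta
    ct, st = ad.cos(theta), ad.sin(theta)
    one_m_ct = 1.0 - ct
    dot = kx * x + ky * y + kz * z
    cx_ = ky * z - kz * y
    cy_ = kz * x - kx * z
    cz_ = kx * y - ky * x
    xo = x * ct + cx_ * st + kx * dot * one_m_ct
    yo = y * ct + cy_ * st + ky * dot * one_m_ct
    zo = z * ct + cz_ * st + kz * dot * one_m_ct
    return xo, yo, zo


def grid_sample(f: Tensor, u: Tensor, v: Tensor) -> Tensor:
    """Bilinear sampling of f (N,C,H,W) at pixel coordinates u, v (N,Ho,Wo).

    Out-of-bounds corners contribute zero. Differentiable in both the image
    and the sampling coordinates.
    """
    n, _, h, w = f.shape
    u0 = np.floor(u.data).astype(np.intp)
    v0 = np.floor(v.data).astype(np.intp)
    au = (u - u0.astype(np.float64)).reshape(n, 1, *u.shape[1:])
    av = (v - v0.astype(np.float64)).reshape(n, 1, *v.shape[1:])
    out = None
    for dy, wy in ((0, 1.0 - av), (1, av)):
        for dx, wx in ((0, 1.0 - au), (1, au)):
            yy = v0 + dy
            xx = u0 + dx
            inb = ((yy >= 0) & (yy < h) & (xx >= 0) & (xx < w))
            val = ad.take_pixels(f, np.clip(yy, 0, h - 1),
                                 np.clip(xx, 0, w - 1))
            val = val * inb[:, None].astype(np.float64)
            term = val * (wy * wx)
            out = term if out is None else out + term
    return out


def project_warp(source: Tensor, depth: Tensor, rotvec: Tensor, trans: Tensor,
                 fx: Tensor, fy: Tensor, cx: Tensor, cy: Tensor):
    """Warp `source` (N,C,H,W) into the target view.

    depth: target depth (N,H,W); rotvec/trans: (N,3) motion target->source;
    fx..cy: normalised intrinsics, scalar tensors or shape (N,1,1).
    Returns (warped Tensor (N,C,H,W), valid ndarray (N,H,W)).
    """
    n, _, h, w = source.shape
    ug, vg = pixel_grid(w, h)
    ug = ug[None]
    vg = vg[None]

    def _b(t):
        t = as_tensor(t)
        if t.ndim == 0:
            return t.reshape(1, 1, 1)
        if t.ndim == 1:
            return t.reshape(t.shape[0], 1, 1)
        return t

    fx, fy, cx, cy = _b(fx), _b(fy), _b(cx), _b(cy)
    x = (ug - cx * w) / (fx * w) * depth
    y = (vg - cy * h) / (fy * h) * depth
    z = depth
    xr, yr, zr = rotate_points(rotvec, x, y, z)
    xr = xr + trans[:, 0].reshape(n, 1, 1)
    yr = yr + trans[:, 1].reshape(n, 1, 1)
    zr = zr + trans[:, 2].reshape(n, 1, 1)
    front = zr.data > _DEPTH_EPS
    z_safe = ad.where(front, zr, 1.0)
    us = fx * w * (xr / z_safe) + cx * w
    vs = fy * h * (yr / z_safe) + cy * h
    # tolerance absorbs round-off of the back-project/re-project round trip
    tol = 1e-6
    valid = (front & (us.data >= -tol) & (us.data <= w - 1 + tol)
             & (vs.data >= -tol) & (vs.data <= h - 1 + tol))
    warped = grid_sample(source, us, vs)
    warped = warped * valid[:, None].astype(np.float64)
    return warped, valid


def flow_warp(source: Tensor, flow_u: Tensor, flow_v: Tensor) -> Tensor:
    """Sample `source` (N,C,H,W) at p + flow(p); flow in pixels, (N,H,W)."""
    n, _, h, w = source.shape
    ug, vg = pixel_grid(w, h)
    return grid_sample(source, flow_u + ug[None], flow_v + vg[None])


# ----------------------------------------------------------- NumPy-facing API

def intrinsics_to_matrix(intr: Intrinsics, width: int, height: int) -> np.ndarray:
    """Pixel-space 3x3 camera matrix at the given resolution."""
    return intr.to_matrix(width, height)


def motion_to_matrix(m: RigidMotion) -> np.ndarray:
    """Homogeneous 4x4 matrix of a rigid motion."""
    return m.to_matrix()


def _chw(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        img = img[:, :, None]
    return img.transpose(2, 0, 1)[None]


def warp_to_source(source_image: np.ndarray, target_depth: np.ndarray,
                   motion: RigidMotion, intr: Intrinsics) -> WarpResult:
    """Synthesise the target view by inverse warping the source image.

    source_image: (H, W) or (H, W, C); target_depth: (H, W), strictly
    positive. Pixels whose projection leaves the source frame (or lands at
    non-positive depth) get value 0 and valid_mask 0.
    """
    src = np.asarray(source_image, dtype=np.float64)
    depth = np.asarray(target_depth, dtype=np.float64)
    if src.shape[:2] != depth.shape:
        raise ValueError(f"resolution mismatch: image {src.shape[:2]} "
                         f"vs depth {depth.shape}")
    if not np.isfinite(depth).all():
        raise ValueError("depth map contains non-finite values")
    if (depth <= 0).any():
        raise ValueError("depth must be strictly positive")
    squeeze = src.ndim == 2
    warped, valid = project_warp(
        Tensor(_chw(src)), Tensor(depth[None]),
        Tensor(np.asarray(motion.rotation)[None]),
        Tensor(np.asarray(motion.translation)[None]),
        Tensor(intr.fx), Tensor(intr.fy), Tensor(intr.cx), Tensor(intr.cy))
    img = warped.data[0].transpose(1, 2, 0)
    if squeeze:
        img = img[:, :, 0]
    return WarpResult(image=img, valid_mask=valid[0].astype(np.float64))


def warp_features_at_plane(source_features: np.ndarray, plane_depth: float,
                           motion: RigidMotion, intr: Intrinsics) -> WarpResult:
    """Warp a feature map assuming a fronto-parallel plane at `plane_depth`.

    Equivalent to :func:`warp_to_source` with a constant depth map; the
    normalised intrinsics adapt to the feature resolution automatically.
    """
    if plane_depth <= 0:
        raise ValueError("plane depth must be positive")
    feats = np.asarray(source_features, dtype=np.float64)
    h, w = feats.shape[:2]
    return warp_to_source(feats, np.full((h, w), float(plane_depth)),
                          motion, intr)
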
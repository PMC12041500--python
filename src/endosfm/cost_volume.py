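"""Plane-sweep cost volume over learned features.

A set of fronto-parallel depth planes, linearly spaced in [d_min, d_max], is
swept through the target view: for every plane the source feature map is
warped into the target frame with the predicted ego-motion and intrinsics
(as if the whole scene lay on that plane), and the per-pixel L1 feature
distance to the target features becomes the matching cost at that plane.
Only past frames serve as sources. A second depth network reads the volume
(concatenated with the target features) and predicts the cost-volume depth
branch; because the warp depends on pose and intrinsics, supervision applied
to that branch backpropagates into the pose and camera predictors — the
auxiliary-supervision mechanism this package exists for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Tensor, as_tensor
from .geometry import Intrinsics, project_warp
from .networks import DepthNet, disparity_to_depth

__all__ = [
    "DepthPlaneSet", "CostVolume", "make_depth_planes",
    "build_cost_volume", "build_cost_volume_tensors",
    "CostVolumeDepthNet", "argmin_depth",
]


@dataclass(frozen=True)
class DepthPlaneSet:
    d_min: float
    d_max: float
    count: int
    values: tuple

    def __len__(self):
        return self.count


@dataclass
class CostVolume:
    """costs: (P, h, w) per-pixel, per-plane L1 feature distance (>= 0);
    locations whose warp left the source view hold the per-pixel maximum of
    the valid costs, so they can never win the arg-min."""

    costs: np.ndarray
    planes: DepthPlaneSet


def make_depth_planes(d_min: float, d_max: float, count: int) -> DepthPlaneSet:
    """Linearly spaced depth planes from d_min to d_max inclusive."""
    if not 0 < d_min < d_max:
        raise ValueError("require 0 < d_min < d_max")
    if count < 2:
        raise ValueError("need at least two depth planes")
    values = tuple(np.linspace(d_min, d_max, count))
    return DepthPlaneSet(d_min=float(d_min), d_max=float(d_max),
                         count=int(count), values=values)


def build_cost_volume_tensors(f_t: Tensor, f_sources: list, rots: list,
                              transs: list, fx, fy, cx, cy,
                              planes: DepthPlaneSet) -> Tensor:
    """Differentiable cost volume.

    f_t: (N, C, h, w); f_sources: list of (N, C, h, w); rots/transs: per
    source, (N, 3); fx..cy: normalised intrinsics, scalar or (N,) tensors.
    Returns costs (N, P, h, w). All P plane warps of one source are batched
    into a single projection call.
    """
    if not f_sources:
        raise ValueError("cost volume needs at least one source feature map")
    n, c, h, w = f_t.shape
    p = planes.count
    plane_depth = np.repeat(np.asarray(planes.values), n).reshape(p, n)
    plane_depth = np.broadcast_to(
        plane_depth.transpose(1, 0)[:, :, None, None], (n, p, h, w))
    plane_depth = Tensor(plane_depth.reshape(n * p, h, w))

    def _tile_vec(t: Tensor) -> Tensor:       # (N,3) -> (N*P,3)
        return ad.broadcast_to(t.reshape(n, 1, 3), (n, p, 3)).reshape(n * p, 3)

    def _tile_scalar(t) -> Tensor:            # scalar or (N,) -> (N*P,)
        t = as_tensor(t)
        if t.ndim == 0:
            return t
        return ad.broadcast_to(t.reshape(n, 1), (n, p)).reshape(n * p)

    fx_t, fy_t = _tile_scalar(fx), _tile_scalar(fy)
    cx_t, cy_t = _tile_scalar(cx), _tile_scalar(cy)
    num = None
    den = None
    for f_s, rot, trans in zip(f_sources, rots, transs):
        f_big = ad.broadcast_to(f_s.reshape(n, 1, c, h, w),
                                (n, p, c, h, w)).reshape(n * p, c, h, w)
        warped, valid = project_warp(f_big, plane_depth,
                                     _tile_vec(rot), _tile_vec(trans),
                                     fx_t, fy_t, cx_t, cy_t)
        f_t_big = ad.broadcast_to(f_t.reshape(n, 1, c, h, w),
                                  (n, p, c, h, w)).reshape(n * p, c, h, w)
        diff = (warped - f_t_big).abs().mean(axis=1)     # (N*P, h, w)
        vmask = valid.astype(np.float64)
        term = diff * vmask
        num = term if num is None else num + term
        den = vmask if den is None else den + vmask
    cost = num / np.maximum(den, 1.0)
    cost = cost.reshape(n, p, h, w)
    den = den.reshape(n, p, h, w)
    valid_any = den > 0
    # constant fill: per-pixel max over the valid planes (0 if none valid)
    masked = np.where(valid_any, cost.data, -np.inf)
    mx = masked.max(axis=1, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    fill = np.broadcast_to(mx, cost.shape)
    return ad.where(valid_any, cost, Tensor(fill.copy()))


def build_cost_volume(f_t: np.ndarray, f_sources: list, motions: list,
                      intr: Intrinsics, planes: DepthPlaneSet) -> CostVolume:
    """NumPy facade: f_t and each source are (h, w, C) feature maps; one
    rigid motion (target -> source) per source frame."""
    if not f_sources:
        raise ValueError("cost volume needs at least one source feature map")
    if len(f_sources) != len(motions):
        raise ValueError("need exactly one motion per source")
    ft = Tensor(np.asarray(f_t, float).transpose(2, 0, 1)[None])
    fs = [Tensor(np.asarray(f, float).transpose(2, 0, 1)[None])
          for f in f_sources]
    rots = [Tensor(np.asarray(m.rotation)[None]) for m in motions]
    transs = [Tensor(np.asarray(m.translation)[None]) for m in motions]
    costs = build_cost_volume_tensors(
        ft, fs, rots, transs,
        Tensor(intr.fx), Tensor(intr.fy), Tensor(intr.cx), Tensor(intr.cy),
        planes)
    return CostVolume(costs=costs.data[0], planes=planes)


def argmin_depth(volume: CostVolume) -> np.ndarray:
    """Per-pixel depth of the cheapest plane (diagnostic readout); ties break
    towards the smaller depth."""
    costs = np.asarray(volume.costs)
    if not np.isfinite(costs).all():
        raise ValueError("cost volume contains non-finite values")
    idx = costs.argmin(axis=0)
    return np.asarray(volume.planes.values)[idx]


class CostVolumeDepthNet(Module):
    """Depth predictor reading [target features, cost volume] channels.

    Operates at the feature resolution with a shallow trunk; the disparity
    is upsampled back to the frame resolution before conversion to depth.
    """

    def __init__(self, feature_channels: int, planes: DepthPlaneSet,
                 min_depth: float, max_depth: float,
                 channels: tuple = (16, 24), upsample_factor: int = 4,
                 head_scale: float = 1.0,
                 rng: np.random.Generator | None = None):
        self.net = DepthNet(in_channels=feature_channels + planes.count,
                            channels=channels, num_scales=1,
                            head_scale=head_scale, rng=rng)
        self.planes = planes
        self.min_depth = min_depth
        self.max_depth = max_depth
        self.upsample_factor = upsample_factor
        self.feature_channels = feature_channels

    def __call__(self, f_t: Tensor, costs: Tensor) -> Tensor:
        """Returns depth (N, 1, H, W) at frame resolution."""
        if f_t.shape[1] != self.feature_channels:
            raise ValueError(f"expected {self.feature_channels} feature "
                             f"channels, got {f_t.shape[1]}")
        if costs.shape[1] != self.planes.count:
            raise ValueError(f"expected {self.planes.count} cost channels, "
                             f"got {costs.shape[1]}")
        x = ad.concatenate([f_t, costs], axis=1)
        disp = self.net(x)[0]
        disp = ad.upsample_nearest(disp, self.upsample_factor)
        return disparity_to_depth(disp, self.min_depth, self.max_depth)
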
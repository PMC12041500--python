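"""The five trainable components.

* ``DepthNet`` — residual encoder + U-Net decoder emitting a 4-scale
  disparity pyramid, each map sigmoid-bounded in (0, 1).
* ``PoseCameraNet`` — shared residual encoder on a concatenated frame pair,
  with a pose decoder (axis-angle + translation, scaled by 0.01 so the
  initial prediction leans towards the identity) and a camera decoder
  (convolution -> global average pooling -> a softplus focal head and a
  linear principal-point head added to 0.5).
* ``OFNet`` — encoder/decoder predicting forward and backward optical flow
  between the target and a source frame.
* ``AFNet`` — small convolutional stack predicting the per-pixel additive
  brightness-calibration image C(p).

Channel widths and the number of downsampling stages are constructor
arguments; the defaults are deliberately small so the whole system trains on
a CPU in minutes. Input height and width must be divisible by
``2**len(channels)``.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Conv2d, Module, Tensor
from .geometry import (Intrinsics, RigidMotion, grid_sample, pixel_grid)

__all__ = [
    "DepthNet", "PoseCameraNet", "OFNet", "AFNet",
    "visibility_from_flow", "disparity_to_depth",
]

# bias making softplus(bias) = 1, i.e. the focal head starts at a
# normalised focal length of 1.0
_FOCAL_BIAS = float(np.log(np.e - 1.0))


class ResidualBlock(Module):
    def __init__(self, cin: int, cout: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, rng, stride=stride)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.proj = (Conv2d(cin, cout, 1, rng, stride=stride, padding=0)
                     if (stride != 1 or cin != cout) else None)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv2(ad.relu(self.conv1(x)))
        skip = x if self.proj is None else self.proj(x)
        return ad.relu(y + skip)


class Encoder(Module):
    """Residual encoder; returns features at 1/2, 1/4, ... resolution."""

    def __init__(self, cin: int, channels: tuple, rng: np.random.Generator):
        self.channels = tuple(channels)
        self.stem = Conv2d(cin, channels[0], 3, rng, stride=2)
        self.blocks = [ResidualBlock(channels[i - 1], channels[i], 2, rng)
                       for i in range(1, len(channels))]

    def __call__(self, x: Tensor) -> list:
        feats = [ad.relu(self.stem(x))]
        for blk in self.blocks:
            feats.append(blk(feats[-1]))
        return feats


def _check_divisible(h: int, w: int, stages: int) -> None:
    d = 2 ** stages
    if h % d or w % d:
        raise ValueError(f"input resolution {w}x{h} must be divisible by {d}")


class _UNet(Module):
    """Encoder/decoder trunk returning decoder features, coarsest first,
    at resolutions 1/2^(S-1) ... 1/1."""

    def __init__(self, cin: int, channels: tuple, rng: np.random.Generator):
        self.encoder = Encoder(cin, channels, rng)
        ch = list(channels)
        self.upconvs = []
        self.iconvs = []
        prev = ch[-1]
        # decode from 1/2^S up to full resolution
        for lvl in range(len(ch) - 1, -1, -1):
            out_c = ch[max(lvl - 1, 0)]
            self.upconvs.append(Conv2d(prev, out_c, 3, rng))
            skip_c = ch[lvl - 1] if lvl >= 1 else 0
            self.iconvs.append(Conv2d(out_c + skip_c, out_c, 3, rng))
            prev = out_c
        self.channels = ch

    def __call__(self, x: Tensor) -> list:
        _check_divisible(x.shape[-2], x.shape[-1], len(self.channels))
        enc = self.encoder(x)
        feats = []
        y = enc[-1]
        n_levels = len(self.channels)
        for i, lvl in enumerate(range(n_levels - 1, -1, -1)):
            y = ad.elu(self.upconvs[i](y))
            y = ad.upsample_nearest(y, 2)
            if lvl >= 1:
                y = ad.concatenate([y, enc[lvl - 1]], axis=1)
            y = ad.elu(self.iconvs[i](y))
            feats.append(y)
        return feats  # resolutions 1/2^(S-1), ..., 1/2, 1/1


class DepthNet(Module):
    """Disparity pyramid predictor; also consumes cost-volume channels when
    `in_channels` is set accordingly."""

    def __init__(self, in_channels: int = 3,
                 channels: tuple = (8, 16, 24, 32),
                 num_scales: int = 4,
                 head_scale: float = 1.0,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        if num_scales > len(channels):
            raise ValueError("cannot emit more scales than decoder levels")
        self.trunk = _UNet(in_channels, channels, rng)
        self.num_scales = num_scales
        self.head_scale = head_scale
        # heads attach to the finest `num_scales` decoder levels; decoder
        # level widths are channels[max(lvl-1, 0)] walking coarse->fine.
        # With head_scale < 1 the heads are zero-initialised so disparity
        # starts at exactly 0.5 and moves slowly — this keeps the sigmoid out
        # of its saturated (vanishing-gradient) bands while depth is still
        # unobservable early in training.
        ch = self.trunk.channels
        head_in = [ch[max(lvl - 1, 0)]
                   for lvl in range(len(ch) - 1, -1, -1)][-num_scales:]
        zero = head_scale != 1.0
        self.heads = [Conv2d(c, 1, 3, rng, zero_init=zero) for c in head_in]

    def __call__(self, x: Tensor) -> list:
        """Returns disparity maps finest-first: full, 1/2, 1/4, ... ."""
        feats = self.trunk(x)
        outs = []
        for feat, head in zip(feats[-self.num_scales:], self.heads):
            raw = head(feat)
            if self.head_scale != 1.0:
                raw = raw * self.head_scale
            outs.append(ad.sigmoid(raw))
        return outs[::-1]


class PoseCameraNet(Module):
    """`pose_scale` and `cam_scale` multiply the raw head outputs before the
    axis-angle/translation readout and the softplus/offset readouts
    respectively. Both heads are zero-initialised, so predictions start at
    the identity motion and at fx = fy = 1, cx = cy = 0.5; the scales set
    how fast each head can move under an adaptive optimiser and can be
    reduced to keep the (initially unobservable) camera parameters from
    drifting before depth and pose carry signal."""

    def __init__(self, channels: tuple = (8, 16, 24, 32),
                 hidden: int = 16, pose_scale: float = 0.01,
                 cam_scale: float = 1.0, offset_scale: float | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.encoder = Encoder(6, channels, rng)
        c = channels[-1]
        self.pose_scale = pose_scale
        self.cam_scale = cam_scale
        # the principal point starts at the image centre — correct for
        # almost any camera — so its head may move slower than the focal
        # head, which must travel; None means "same as cam_scale"
        self.offset_scale = cam_scale if offset_scale is None else offset_scale
        self.pose_conv1 = Conv2d(c, hidden, 1, rng, padding=0)
        self.pose_conv2 = Conv2d(hidden, hidden, 3, rng)
        self.pose_out = Conv2d(hidden, 6, 1, rng, padding=0, zero_init=True)
        self.cam_conv = Conv2d(c, hidden, 3, rng)
        self.focal_head = Conv2d(hidden, 2, 1, rng, padding=0,
                                 zero_init=True)
        self.offset_head = Conv2d(hidden, 2, 1, rng, padding=0,
                                  zero_init=True)

    def __call__(self, target: Tensor, source: Tensor):
        """Returns (rot (N,3), trans (N,3), fx, fy, cx, cy each (N,))."""
        if target.shape != source.shape:
            raise ValueError(f"frame shape mismatch: {target.shape} vs "
                             f"{source.shape}")
        _check_divisible(target.shape[-2], target.shape[-1],
                         len(self.encoder.channels))
        x = ad.concatenate([target, source], axis=1)
        feat = self.encoder(x)[-1]
        p = ad.relu(self.pose_conv1(feat))
        p = ad.relu(self.pose_conv2(p))
        p = self.pose_out(p).mean(axis=(2, 3)) * self.pose_scale   # (N, 6)
        rot, trans = p[:, :3], p[:, 3:]
        c = ad.relu(self.cam_conv(feat)).mean(axis=(2, 3), keepdims=True)
        raw_f = self.focal_head(c).reshape(c.shape[0], 2) * self.cam_scale
        focal = ad.softplus(raw_f + _FOCAL_BIAS)
        offset = (self.offset_head(c).reshape(c.shape[0], 2)
                  * self.offset_scale + 0.5)
        return (rot, trans, focal[:, 0], focal[:, 1],
                offset[:, 0], offset[:, 1])

    def predict(self, target: np.ndarray, source: np.ndarray):
        """Convenience inference on (H, W, 3) arrays; returns
        (RigidMotion, Intrinsics)."""
        t = Tensor(np.asarray(target).transpose(2, 0, 1)[None])
        s = Tensor(np.asarray(source).transpose(2, 0, 1)[None])
        rot, trans, fx, fy, cx, cy = self(t, s)
        return (RigidMotion(tuple(rot.data[0]), tuple(trans.data[0])),
                Intrinsics(float(fx.data[0]), float(fy.data[0]),
                           float(cx.data[0]), float(cy.data[0])))


class OFNet(Module):
    """Forward and backward optical-flow predictor (pixels)."""

    def __init__(self, channels: tuple = (8, 16, 24),
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.trunk = _UNet(6, channels, rng)
        self.head = Conv2d(channels[0], 4, 3, rng, zero_init=True)

    def __call__(self, target: Tensor, source: Tensor):
        """Returns (fwd, bwd) flow tensors of shape (N, 2, H, W)."""
        if target.shape != source.shape:
            raise ValueError(f"frame shape mismatch: {target.shape} vs "
                             f"{source.shape}")
        feat = self.trunk(ad.concatenate([target, source], axis=1))[-1]
        flows = self.head(feat)
        return flows[:, :2], flows[:, 2:]


class AFNet(Module):
    """Brightness-calibration predictor: C(p) added to the target frame
    before the photometric comparison."""

    def __init__(self, hidden: int = 8, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.conv1 = Conv2d(6, hidden, 3, rng)
        self.conv2 = Conv2d(hidden, hidden, 3, rng)
        self.out = Conv2d(hidden, 3, 3, rng, zero_init=True)

    def __call__(self, target: Tensor, flow_warped_source: Tensor) -> Tensor:
        if target.shape != flow_warped_source.shape:
            raise ValueError(f"frame shape mismatch: {target.shape} vs "
                             f"{flow_warped_source.shape}")
        x = ad.concatenate([target, flow_warped_source], axis=1)
        return self.out(ad.elu(self.conv2(ad.elu(self.conv1(x)))))


def visibility_from_flow(fwd: np.ndarray, bwd: np.ndarray,
                         tau: float = 1.0) -> np.ndarray:
    """Forward/backward-consistency visibility mask.

    V(p) = 1 where ||fwd(p) + bwd(p + fwd(p))|| < tau (pixels), else 0.
    Inputs are (N, 2, H, W) arrays (or tensors; values are read only — the
    mask is treated as a constant weight during training).
    """
    fwd = fwd.data if isinstance(fwd, Tensor) else np.asarray(fwd, float)
    bwd = bwd.data if isinstance(bwd, Tensor) else np.asarray(bwd, float)
    if fwd.shape != bwd.shape:
        raise ValueError("flow field shapes must match")
    n, _, h, w = fwd.shape
    ug, vg = pixel_grid(w, h)
    u = Tensor(fwd[:, 0] + ug[None])
    v = Tensor(fwd[:, 1] + vg[None])
    bwd_at = grid_sample(Tensor(bwd), u, v).data
    diff = fwd + bwd_at
    mag = np.sqrt((diff ** 2).sum(axis=1))
    return (mag < tau).astype(np.float64)


def disparity_to_depth(disp, min_depth: float, max_depth: float):
    """Map sigmoid disparity in (0, 1) to depth in [min_depth, max_depth]:
    depth = 1 / (a * disp + b) with a = 1/min - 1/max, b = 1/max."""
    if not 0 < min_depth < max_depth:
        raise ValueError("require 0 < min_depth < max_depth")
    a = 1.0 / min_depth - 1.0 / max_depth
    b = 1.0 / max_depth
    if isinstance(disp, Tensor):
        return 1.0 / (disp * a + b)
    return 1.0 / (np.asarray(disp, dtype=np.float64) * a + b)
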
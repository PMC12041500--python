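"""Training objectives for the self-supervised system.

The total loss is a data-fidelity term plus a Tikhonov regulariser,

    L = D(p) + kappa * (lambda1 * L_rs + lambda2 * L_ax + lambda3 * L_es)
        + w_c * L_consistency,

where D(p) is the visibility-masked photometric error between the
geometrically synthesised target view and the brightness-calibrated target
frame, L_rs smooths the calibration field, L_ax supervises the appearance
branch through the flow-synthesised view, L_es is edge-aware disparity
smoothness and L_consistency ties the two depth branches (plain and
cost-volume) together.

Every operation accepts either autodiff tensors (for training) or NumPy
arrays (coerced to constant tensors), always in NCHW layout, and returns a
scalar tensor. Per-pixel sums in the defining formulas are implemented as
means so loss magnitudes are resolution independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter

from . import autodiff as ad
from .autodiff import Tensor, as_tensor

__all__ = [
    "LossWeights", "LossBreakdown", "ssim", "photometric", "data_fidelity",
    "residual_smoothness", "auxiliary_loss", "edge_aware_smoothness",
    "depth_consistency", "total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """alpha: SSIM/L1 mix; kappa: regulariser weight; lambda1..3: weights of
    the residual-smoothness, auxiliary and edge-smoothness terms."""

    alpha: float = 0.85
    kappa: float = 1.0
    lambda1: float = 0.01
    lambda2: float = 0.001
    lambda3: float = 0.0001

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if min(self.kappa, self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossBreakdown:
    data_fidelity: float
    residual_smoothness: float
    auxiliary: float
    edge_smoothness: float
    consistency: float
    total: float


def _nchw(x) -> Tensor:
    t = as_tensor(x)
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 3:
        t = t.reshape(1, *t.shape)
    if t.ndim != 4:
        raise ValueError(f"expected <=4 dims, got shape {t.shape}")
    return t


def _check_same_hw(*tensors: Tensor) -> None:
    shapes = {t.shape[-2:] for t in tensors}
    if len(shapes) > 1:
        raise ValueError(f"resolution mismatch among inputs: {sorted(shapes)}")


_box3 = ad.box3_mean


def ssim(a, b) -> Tensor:
    """Per-pixel structural similarity with a uniform 3x3 window.

    Stabilising constants C1 = 0.01^2, C2 = 0.03^2 assume inputs in [0, 1].
    Returns a map the same shape as the inputs, values in [-1, 1].
    """
    a, b = _nchw(a), _nchw(b)
    _check_same_hw(a, b)
    c1, c2 = 0.01 ** 2, 0.03 ** 2
    mu_a, mu_b = _box3(a), _box3(b)
    var_a = _box3(a * a) - mu_a * mu_a
    var_b = _box3(b * b) - mu_b * mu_b
    cov = _box3(a * b) - mu_a * mu_b
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)
    den = (mu_a * mu_a + mu_b * mu_b + c1) * (var_a + var_b + c2)
    return num / den


def photometric(a, b, alpha: float = 0.85) -> Tensor:
    """Per-pixel photometric cost: alpha*(1-SSIM)/2 + (1-alpha)*|a-b|,
    channel-averaged. Returns an (N,1,H,W) map."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    a, b = _nchw(a), _nchw(b)
    _check_same_hw(a, b)
    l1 = (a - b).abs().mean(axis=1, keepdims=True)
    if alpha == 0.0:
        return l1
    s = ssim(a, b).mean(axis=1, keepdims=True)
    return alpha * ((1.0 - s) * 0.5) + (1.0 - alpha) * l1


def _as_pair(item):
    """Normalise a warp argument to an (image, mask-or-None) pair."""
    if hasattr(item, "image") and hasattr(item, "valid_mask"):
        return item.image, item.valid_mask
    if isinstance(item, (list, tuple)) and len(item) == 2:
        return item[0], item[1]
    return item, None


def _masked_photometric(warped, valid_mask, target, calib, vis,
                        alpha) -> Tensor:
    target = _nchw(target)
    warped = _nchw(warped)
    _check_same_hw(warped, target)
    refined = target if calib is None else target + _nchw(calib)
    phi = photometric(warped, refined, alpha)
    if vis is not None:
        phi = phi * _nchw(vis)
    if valid_mask is None:
        return phi.mean()
    mask = np.asarray(valid_mask if not isinstance(valid_mask, Tensor)
                      else valid_mask.data, dtype=np.float64)
    mask = mask.reshape(phi.shape[0], 1, *phi.shape[2:])
    if alpha > 0.0:
        # the SSIM window reaches one pixel past each position, and invalid
        # warped pixels hold arbitrary fill values; erode the mask so no
        # retained pixel's window touches an invalid one
        mask = minimum_filter(mask, size=(1, 1, 3, 3), mode="nearest")
    total = mask.sum()
    if total == 0:
        warnings.warn("photometric mask is empty; loss contribution is zero",
                      RuntimeWarning, stacklevel=3)
    # average over the retained pixels only, so the loss cannot be lowered
    # by warping more of the frame out of the source view
    return (phi * mask).sum() * (1.0 / max(total, 1.0))


def data_fidelity(warped, target, calib=None, vis=None,
                  alpha: float = 0.85) -> Tensor:
    """Visibility-masked photometric error of the geometric reconstruction.

    `warped` is one reconstruction or a list over the nearby source frames
    (both neighbours of the target); a list is averaged. Each entry may be a
    WarpResult, an (image, valid_mask) pair, or a bare image (mask of ones);
    `calib` and `vis` may likewise be lists aligned with `warped`.
    """
    items = list(warped) if isinstance(warped, list) else [warped]
    vis_list = list(vis) if isinstance(vis, list) else [vis] * len(items)
    cal_list = list(calib) if isinstance(calib, list) else [calib] * len(items)
    total = None
    for it, v, c in zip(items, vis_list, cal_list):
        img, mask = _as_pair(it)
        term = _masked_photometric(img, mask, target, c, v, alpha)
        total = term if total is None else total + term
    return total * (1.0 / len(items))


def auxiliary_loss(flow_warped, target, calib=None, vis=None,
                   alpha: float = 0.85) -> Tensor:
    """Same contract as :func:`data_fidelity`, applied to the optical-flow
    reconstruction; this is what supervises the appearance branch."""
    return data_fidelity(flow_warped, target, calib=calib, vis=vis,
                         alpha=alpha)


def _grad_x(t: Tensor) -> Tensor:
    return t[:, :, :, 1:] - t[:, :, :, :-1]


def _grad_y(t: Tensor) -> Tensor:
    return t[:, :, 1:, :] - t[:, :, :-1, :]


def residual_smoothness(calib, target, warped) -> Tensor:
    """Smoothness of the brightness-calibration field, relaxed across strong
    gradients of the reconstruction residual It - Is->t."""
    c, t, wp = _nchw(calib), _nchw(target), _nchw(warped)
    _check_same_hw(c, t, wp)
    res = t - wp
    loss = None
    for grad in (_grad_x, _grad_y):
        gc = grad(c).abs().mean(axis=1, keepdims=True)
        gr = grad(res).abs().mean(axis=1, keepdims=True)
        term = (gc * ad.exp(-gr)).mean()
        loss = term if loss is None else loss + term
    return loss


def edge_aware_smoothness(disp_or_depth, target,
                          mean_normalize: bool = True) -> Tensor:
    """Edge-aware smoothness of a disparity (or depth) map: gradients are
    penalised except across image edges. The map is mean-normalised by
    default, which removes the incentive to shrink the prediction globally."""
    d, t = _nchw(disp_or_depth), _nchw(target)
    _check_same_hw(d, t)
    if mean_normalize:
        m = d.mean()
        if m.item() == 0:
            raise ValueError("cannot mean-normalise an all-zero map")
        d = d / m
    loss = None
    for grad in (_grad_x, _grad_y):
        gd = grad(d).abs().mean(axis=1, keepdims=True)
        gi = grad(t).abs().mean(axis=1, keepdims=True)
        term = (gd * ad.exp(-gi)).mean()
        loss = term if loss is None else loss + term
    return loss


def depth_consistency(d_sfm, d_cv) -> Tensor:
    """Symmetric, scale-robust discrepancy between the two depth branches:
    mean |a - b| / (a + b), in [0, 1)."""
    a, b = _nchw(d_sfm), _nchw(d_cv)
    _check_same_hw(a, b)
    if (a.data <= 0).any() or (b.data <= 0).any():
        raise ValueError("depth consistency requires strictly positive depths")
    return ((a - b).abs() / (a + b)).mean()


def total_loss(data_fidelity, residual_smoothness, auxiliary,
               edge_smoothness, consistency, weights: LossWeights,
               consistency_weight: float = 0.05) -> LossBreakdown:
    """Combine the loss terms; inputs may be tensors or floats. The returned
    breakdown's `total` is a tensor when any input is one, so it can be
    backpropagated."""
    parts = {"data_fidelity": data_fidelity,
             "residual_smoothness": residual_smoothness,
             "auxiliary": auxiliary,
             "edge_smoothness": edge_smoothness,
             "consistency": consistency}
    for name, p in parts.items():
        val = p.data if isinstance(p, Tensor) else p
        if not np.all(np.isfinite(val)):
            raise FloatingPointError(f"loss term '{name}' is not finite")
    reg = (weights.lambda1 * residual_smoothness
           + weights.lambda2 * auxiliary
           + weights.lambda3 * edge_smoothness)
    total = (data_fidelity + weights.kappa * reg
             + consistency_weight * consistency)

    def as_f(p):
        return p.item() if isinstance(p, Tensor) else float(p)

    return LossBreakdown(
        data_fidelity=as_f(data_fidelity),
        residual_smoothness=as_f(residual_smoothness),
        auxiliary=as_f(auxiliary),
        edge_smoothness=as_f(edge_smoothness),
        consistency=as_f(consistency),
        total=total if isinstance(total, Tensor) else float(total))
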
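"""Independent scalar reference implementations used by the tests.

Everything here is written with explicit per-pixel Python loops and plain
NumPy scalars, deliberately sharing no code path with the package, so that
agreement between the two is evidence of correctness rather than of
consistency.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

TOL = 1e-6  # in-bounds tolerance mirrored from the warping contract


def brute_force_warp(source: np.ndarray, depth: np.ndarray,
                     rotation: tuple, translation: tuple,
                     fx: float, fy: float, cx: float, cy: float):
    """Per-pixel inverse warping: back-project, move, re-project, bilinearly
    sample. source: (H, W, C); depth: (H, W); normalised intrinsics.
    Returns (image (H, W, C), valid (H, W))."""
    src = np.asarray(source, dtype=np.float64)
    dep = np.asarray(depth, dtype=np.float64)
    h, w, c = src.shape
    rot = Rotation.from_rotvec(rotation).as_matrix()
    t = np.asarray(translation, dtype=np.float64)
    k = np.array([[fx * w, 0.0, cx * w],
                  [0.0, fy * h, cy * h],
                  [0.0, 0.0, 1.0]])
    k_inv = np.linalg.inv(k)
    out = np.zeros((h, w, c))
    valid = np.zeros((h, w), dtype=bool)
    for v in range(h):
        for u in range(w):
            p_cam = k_inv @ np.array([u, v, 1.0]) * dep[v, u]
            p_src = rot @ p_cam + t
            if p_src[2] <= 1e-6:
                continue
            us = k[0, 0] * p_src[0] / p_src[2] + k[0, 2]
            vs = k[1, 1] * p_src[1] / p_src[2] + k[1, 2]
            if not (-TOL <= us <= w - 1 + TOL and -TOL <= vs <= h - 1 + TOL):
                continue
            valid[v, u] = True
            out[v, u] = _bilinear(src, us, vs)
    return out, valid


def _bilinear(img: np.ndarray, u: float, v: float) -> np.ndarray:
    """Bilinear sample with out-of-bounds corners contributing zero."""
    h, w = img.shape[:2]
    u0, v0 = int(np.floor(u)), int(np.floor(v))
    au, av = u - u0, v - v0
    acc = np.zeros(img.shape[2])
    for dv, wv in ((0, 1.0 - av), (1, av)):
        for du, wu in ((0, 1.0 - au), (1, au)):
            yy, xx = v0 + dv, u0 + du
            if 0 <= yy < h and 0 <= xx < w:
                acc += wv * wu * img[yy, xx]
    return acc


def box3_mean_scalar(x: np.ndarray) -> np.ndarray:
    """Clipped-window 3x3 local mean of an (H, W) array."""
    h, w = x.shape
    out = np.zeros_like(x, dtype=np.float64)
    for i in range(h):
        for j in range(w):
            acc, cnt = 0.0, 0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w:
                        acc += x[ii, jj]
                        cnt += 1
            out[i, j] = acc / cnt
    return out


def ssim_scalar(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pixel SSIM map of two (H, W) images, 3x3 clipped windows,
    C1 = 0.01^2, C2 = 0.03^2."""
    c1, c2 = 0.01 ** 2, 0.03 ** 2
    mu_a, mu_b = box3_mean_scalar(a), box3_mean_scalar(b)
    var_a = box3_mean_scalar(a * a) - mu_a ** 2
    var_b = box3_mean_scalar(b * b) - mu_b ** 2
    cov = box3_mean_scalar(a * b) - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
    return num / den


def photometric_scalar(a: np.ndarray, b: np.ndarray,
                       alpha: float = 0.85) -> np.ndarray:
    """Per-pixel photometric cost of (H, W, C) images: channel-averaged
    alpha*(1-SSIM)/2 + (1-alpha)*L1."""
    c = a.shape[2]
    s = np.mean([ssim_scalar(a[:, :, k], b[:, :, k]) for k in range(c)],
                axis=0)
    l1 = np.mean(np.abs(a - b), axis=2)
    return alpha * (1.0 - s) / 2.0 + (1.0 - alpha) * l1


def data_fidelity_scalar(warped: np.ndarray, target: np.ndarray,
                         calib: np.ndarray, vis: np.ndarray,
                         alpha: float = 0.85) -> float:
    """D = mean_p V(p) * Phi(warped(p), target(p) + C(p)) for one source,
    every array (H, W, C) except vis (H, W)."""
    phi = photometric_scalar(warped, target + calib, alpha)
    return float(np.mean(vis * phi))


def residual_smoothness_scalar(calib: np.ndarray, target: np.ndarray,
                               warped: np.ndarray) -> float:
    """Lrs = mean |grad C| * exp(-|grad (It - Is->t)|), channel-averaged
    gradients, x and y contributions summed (each averaged over its own
    support)."""
    res = target - warped
    total = 0.0
    for axis in (1, 0):   # x then y
        gc = np.mean(np.abs(np.diff(calib, axis=axis)), axis=2)
        gr = np.mean(np.abs(np.diff(res, axis=axis)), axis=2)
        total += float(np.mean(gc * np.exp(-gr)))
    return total


def edge_smoothness_scalar(disp: np.ndarray, target: np.ndarray,
                           mean_normalize: bool = True) -> float:
    """Les = mean |grad d| * exp(-|grad I|) with mean-normalised disparity;
    disp (H, W), target (H, W, C)."""
    d = disp / disp.mean() if mean_normalize else disp
    total = 0.0
    for axis in (1, 0):
        gd = np.abs(np.diff(d, axis=axis))
        gi = np.mean(np.abs(np.diff(target, axis=axis)), axis=2)
        total += float(np.mean(gd * np.exp(-gi)))
    return total


def depth_metrics_scalar(pred: np.ndarray, gt: np.ndarray) -> dict:
    """The five depth error metrics, straight from their definitions."""
    d, dstar = pred.ravel(), gt.ravel()
    ratio = np.maximum(dstar / d, d / dstar)
    return {
        "abs_rel": float(np.mean(np.abs(dstar - d) / dstar)),
        "sq_rel": float(np.mean((dstar - d) ** 2 / dstar)),
        "rmse": float(np.sqrt(np.mean((dstar - d) ** 2))),
        "rmse_log": float(np.sqrt(np.mean((np.log(dstar) - np.log(d)) ** 2))),
        "delta_1": float(np.mean(ratio < 1.25) * 100.0),
    }


def numeric_gradient(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function of an array."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat = x.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = fn(x)
        flat[i] = orig - eps
        fm = fn(x)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return g
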
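"""Depth, ego-motion and intrinsic evaluation.

Monocular self-supervision recovers depth only up to a global scale, so
predictions are median-scaled against ground truth before metric
computation,

    D_scaled = D_pred * median(D_gt) / median(D_pred),

then capped (200 mm on millimetre-scale endoscopic data). The five depth
metrics are the standard Abs Rel, Sq Rel, RMSE, RMSE log (natural log) and
the delta < 1.25 / 1.25^2 / 1.25^3 accuracy percentages. Ego-motion errors
are per-pair L2 norms between predicted and ground-truth axis-angle
rotations, and per-frame L2 position errors after integrating the relative
motions and scale-aligning the trajectories. Intrinsic errors are reported
per parameter as mean +/- std over the test set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import Intrinsics

__all__ = [
    "DepthMetrics", "MeanStd", "EgoMotionErrors", "IntrinsicErrors",
    "median_scale", "cap_depth", "depth_metrics", "ego_motion_errors",
    "intrinsic_errors", "export_trajectory", "read_trajectory",
    "integrate_trajectory",
]


@dataclass(frozen=True)
class DepthMetrics:
    abs_rel: float
    sq_rel: float
    rmse: float
    rmse_log: float
    delta_1: float     # percentages in [0, 100]
    delta_2: float
    delta_3: float


@dataclass(frozen=True)
class MeanStd:
    mean: float
    std: float

    def __str__(self):
        return f"{self.mean:.4f}±{self.std:.4f}"


@dataclass(frozen=True)
class EgoMotionErrors:
    rotation_error: MeanStd
    trajectory_error: MeanStd


@dataclass(frozen=True)
class IntrinsicErrors:
    fx: MeanStd
    fy: MeanStd
    cx: MeanStd
    cy: MeanStd
    ground_truth: Intrinsics

    def report(self) -> str:
        gt = self.ground_truth
        lines = ["param  predicted        ground truth"]
        for name in ("fx", "fy", "cx", "cy"):
            lines.append(f"{name:5s}  {getattr(self, name)!s:15s}  "
                         f"{getattr(gt, name):.3f}")
        return "\n".join(lines)


def _valid_mask(gt: np.ndarray) -> np.ndarray:
    return np.isfinite(gt) & (gt > 0)


def median_scale(pred: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Rescale `pred` by median(gt)/median(pred) over gt-valid pixels."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    mask = _valid_mask(gt)
    if not mask.any():
        raise ValueError("ground truth has no valid pixels")
    med_pred = np.median(pred[mask])
    if med_pred <= 0:
        raise ValueError("median of predicted depth must be positive")
    return pred * (np.median(gt[mask]) / med_pred)


def cap_depth(d: np.ndarray, cap: float) -> np.ndarray:
    """Clamp depth values to at most `cap` (idempotent)."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return np.minimum(np.asarray(d, dtype=np.float64), cap)


def depth_metrics(pred_scaled: np.ndarray, gt: np.ndarray,
                  cap: float | None = None) -> DepthMetrics:
    """Five-way depth error over valid pixels (gt > 0, and gt <= cap when a
    cap is given; the cap is also applied to the predictions)."""
    pred = np.asarray(pred_scaled, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    mask = _valid_mask(gt)
    if cap is not None:
        mask &= gt <= cap
        pred = cap_depth(pred, cap)
    if not mask.any():
        raise ValueError("no valid pixels to evaluate")
    d, dstar = pred[mask], gt[mask]
    err = dstar - d
    ratio = np.maximum(dstar / d, d / dstar)
    return DepthMetrics(
        abs_rel=float(np.mean(np.abs(err) / dstar)),
        sq_rel=float(np.mean(err ** 2 / dstar)),
        rmse=float(np.sqrt(np.mean(err ** 2))),
        rmse_log=float(np.sqrt(np.mean((np.log(dstar) - np.log(d)) ** 2))),
        delta_1=float(np.mean(ratio < 1.25) * 100.0),
        delta_2=float(np.mean(ratio < 1.25 ** 2) * 100.0),
        delta_3=float(np.mean(ratio < 1.25 ** 3) * 100.0))


def integrate_trajectory(motions: list) -> np.ndarray:
    """Camera positions from a chain of relative motions.

    `motions[i]` maps frame-i camera coordinates to frame-(i+1) camera
    coordinates; returns (len+1, 3) positions starting at the origin.
    """
    pose = np.eye(4)
    positions = [pose[:3, 3].copy()]
    for m in motions:
        pose = pose @ np.linalg.inv(m.to_matrix())
        positions.append(pose[:3, 3].copy())
    return np.asarray(positions)


def ego_motion_errors(pred_motions: list, gt_motions: list) -> EgoMotionErrors:
    """Rotation and scale-aligned trajectory errors, mean +/- std."""
    if len(pred_motions) != len(gt_motions):
        raise ValueError("pose sequences must have equal length")
    if not pred_motions:
        raise ValueError("pose sequences are empty")
    rot_err = [float(np.linalg.norm(np.asarray(p.rotation)
                                    - np.asarray(g.rotation)))
               for p, g in zip(pred_motions, gt_motions)]
    pred_pos = integrate_trajectory(pred_motions)
    gt_pos = integrate_trajectory(gt_motions)
    denom = float((pred_pos ** 2).sum())
    scale = float((pred_pos * gt_pos).sum()) / denom if denom > 0 else 1.0
    traj_err = np.linalg.norm(scale * pred_pos - gt_pos, axis=1)
    return EgoMotionErrors(
        rotation_error=MeanStd(float(np.mean(rot_err)),
                               float(np.std(rot_err))),
        trajectory_error=MeanStd(float(np.mean(traj_err)),
                                 float(np.std(traj_err))))


def intrinsic_errors(preds: list, gt: Intrinsics) -> IntrinsicErrors:
    """Per-parameter mean +/- std of predicted normalised intrinsics."""
    if not preds:
        raise ValueError("no intrinsic predictions to evaluate")
    stats = {}
    for name in ("fx", "fy", "cx", "cy"):
        vals = np.asarray([getattr(p, name) for p in preds], dtype=np.float64)
        stats[name] = MeanStd(float(vals.mean()), float(vals.std()))
    return IntrinsicErrors(ground_truth=gt, **stats)


def export_trajectory(poses: list, path) -> None:
    """Write camera-to-world poses (4x4 matrices) in TUM trajectory format:
    `timestamp tx ty tz qx qy qz qw`, one line per frame."""
    lines = []
    for i, pose in enumerate(poses):
        pose = np.asarray(pose, dtype=np.float64)
        q = Rotation.from_matrix(pose[:3, :3]).as_quat()  # x, y, z, w
        vals = [float(i), *pose[:3, 3], *q]
        lines.append(" ".join(format(v, ".17g") for v in vals))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_trajectory(path) -> list:
    """Read a TUM-format trajectory back into 4x4 camera-to-world poses."""
    poses = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            vals = [float(x) for x in line.split()]
            if len(vals) != 8:
                raise ValueError(f"malformed TUM line: {line!r}")
            pose = np.eye(4)
            pose[:3, :3] = Rotation.from_quat(vals[4:8]).as_matrix()
            pose[:3, 3] = vals[1:4]
            poses.append(pose)
    return poses
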
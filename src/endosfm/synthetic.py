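"""Pinhole-consistent synthetic video for testing every stage end to end.

Scenes are textured Lambertian surfaces (fronto-parallel plane, tilted plane
or sphere patch) rendered by exact ray casting through a pinhole camera
moving on a smooth constant-twist SE(3) trajectory. Because frames, analytic
depth maps, poses and intrinsics all come from the same generative model as
the view-synthesis warp, photometric consistency holds by construction up to
bilinear resampling error — which is what makes the generator a ground-truth
oracle for the geometry, cost-volume and training modules.

The default intrinsics (fx=0.82, fy=1.02, cx=cy=0.5, normalised) are the
kind of mid-FOV endoscope calibration the evaluation module reports against.
A rotation-rich trajectory is the regime in which camera self-calibration is
well conditioned, so the per-step rotation magnitude is a first-class knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .geometry import Intrinsics, RigidMotion, pixel_grid

__all__ = ["SceneSpec", "RenderedSequence", "Snippet", "render_sequence",
           "make_snippets", "apply_brightness_perturbation"]

_SURFACES = ("plane", "tilted_plane", "sphere")


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for a synthetic sequence; same seed -> bit-identical output."""

    surface: str = "plane"
    depth_range: tuple = (1.0, 2.0)
    resolution: tuple = (64, 48)            # (width, height)
    n_frames: int = 5
    intrinsics: Intrinsics = field(
        default_factory=lambda: Intrinsics(0.82, 1.02, 0.5, 0.5))
    rotation_per_step: tuple = (0.0, 0.0, 0.0)      # axis-angle, radians
    translation_per_step: tuple = (0.0, 0.0, 0.0)   # scene units
    brightness_amplitude: float = 0.0
    texture_cells: int = 192
    texture_smooth: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.surface not in _SURFACES:
            raise ValueError(f"surface must be one of {_SURFACES}")
        lo, hi = self.depth_range
        if not 0 < lo < hi:
            raise ValueError("depth_range must satisfy 0 < lo < hi")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.brightness_amplitude < 0:
            raise ValueError("brightness amplitude must be >= 0")


@dataclass
class RenderedSequence:
    frames: list          # (H, W, 3) float in [0, 1]
    depths: list          # (H, W) float, camera-frame depth
    poses: list           # (4, 4) camera-to-world matrices
    intrinsics: Intrinsics


@dataclass
class Snippet:
    """{t-1, t, t+1} training triple with its ground truth."""

    target: np.ndarray
    prev: np.ndarray
    next: np.ndarray
    motion_to_prev: RigidMotion     # target -> source rigid motion
    motion_to_next: RigidMotion
    target_depth: np.ndarray
    intrinsics: Intrinsics


def _make_texture(spec: SceneSpec, extent: float):
    rng = np.random.default_rng(spec.seed)
    n = spec.texture_cells
    tex = rng.standard_normal((n, n, 3))
    tex = gaussian_filter(tex, sigma=(spec.texture_smooth,
                                      spec.texture_smooth, 0))
    lo, hi = tex.min(), tex.max()
    tex = 0.15 + 0.7 * (tex - lo) / (hi - lo)

    def sample(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        gx = (x + extent) / (2 * extent) * (n - 1)
        gy = (y + extent) / (2 * extent) * (n - 1)
        out = np.empty((*x.shape, 3))
        for c in range(3):
            out[..., c] = map_coordinates(tex[..., c], [gy, gx],
                                          order=1, mode="nearest")
        return out

    return sample


def _trajectory(spec: SceneSpec) -> list:
    step = RigidMotion(spec.rotation_per_step,
                       spec.translation_per_step).to_matrix()
    poses = [np.eye(4)]
    for _ in range(spec.n_frames - 1):
        poses.append(poses[-1] @ step)     # body-frame increment
    return poses


def _intersect(spec: SceneSpec, origin: np.ndarray, dirs: np.ndarray):
    """Ray/surface intersection. dirs: (H, W, 3) world rays with unit
    camera-z component, so the ray parameter equals camera depth."""
    lo, hi = spec.depth_range
    if spec.surface == "plane":
        z0 = 0.5 * (lo + hi)
        denom = dirs[..., 2]
        t = (z0 - origin[2]) / denom
    elif spec.surface == "tilted_plane":
        # normal tilted about x so depth sweeps roughly lo..hi over the FOV
        half_fov = 0.5 / spec.intrinsics.fy
        slope = (hi - lo) / (2 * half_fov * 0.5 * (lo + hi))
        nrm = np.array([0.0, -slope, 1.0])
        nrm /= np.linalg.norm(nrm)
        d = nrm @ np.array([0.0, 0.0, 0.5 * (lo + hi)])
        denom = dirs @ nrm
        t = (d - nrm @ origin) / denom
    else:  # sphere
        radius = hi
        center = np.array([0.0, 0.0, lo + radius])
        oc = origin - center
        b = dirs @ oc
        dd = (dirs ** 2).sum(-1)
        disc = b ** 2 - dd * ((oc ** 2).sum() - radius ** 2)
        if (disc <= 0).any():
            raise ValueError("trajectory leaves the sphere's visibility")
        t = (-b - np.sqrt(disc)) / dd
    if not np.isfinite(t).all() or (t <= 0).any():
        raise ValueError("trajectory leaves the surface's visibility")
    return t


def render_sequence(spec: SceneSpec) -> RenderedSequence:
    """Ray-cast the scene along the trajectory.

    Returns frames, exact analytic depth maps, camera-to-world poses and
    the ground-truth intrinsics.
    """
    w, h = spec.resolution
    intr = spec.intrinsics
    lo, hi = spec.depth_range
    lateral = hi * (0.5 / min(intr.fx, intr.fy))
    margin = 1.0 + 3.0 * (abs(np.asarray(spec.rotation_per_step)).sum()
                          + abs(np.asarray(spec.translation_per_step)).sum()
                          ) * spec.n_frames
    extent = lateral * 1.5 * min(margin, 4.0)
    texture = _make_texture(spec, extent)
    poses = _trajectory(spec)
    ug, vg = pixel_grid(w, h)
    dirs_cam = np.stack([(ug - intr.cx * w) / (intr.fx * w),
                         (vg - intr.cy * h) / (intr.fy * h),
                         np.ones_like(ug)], axis=-1)
    frames, depths = [], []
    for pose in poses:
        rmat, origin = pose[:3, :3], pose[:3, 3]
        dirs_world = dirs_cam @ rmat.T
        t = _intersect(spec, origin, dirs_world)
        pts = origin + t[..., None] * dirs_world
        frames.append(texture(pts[..., 0], pts[..., 1]))
        depths.append(t.copy())
    if spec.brightness_amplitude > 0:
        frames = apply_brightness_perturbation(
            frames, spec.brightness_amplitude, spec.seed + 1)
    return RenderedSequence(frames=frames, depths=depths, poses=poses,
                            intrinsics=intr)


def make_snippets(seq: RenderedSequence) -> list:
    """Sliding-window {t-1, t, t+1} snippets with ground-truth relative
    motions (target -> source convention, as consumed by the warp)."""
    n = len(seq.frames)
    if n < 3:
        raise ValueError("need at least three frames to build snippets")
    out = []
    for t in range(1, n - 1):
        w2c_t = np.linalg.inv(seq.poses[t])
        m_prev = RigidMotion.from_matrix(
            np.linalg.inv(seq.poses[t - 1]) @ seq.poses[t])
        m_next = RigidMotion.from_matrix(
            np.linalg.inv(seq.poses[t + 1]) @ seq.poses[t])
        del w2c_t
        out.append(Snippet(target=seq.frames[t], prev=seq.frames[t - 1],
                           next=seq.frames[t + 1],
                           motion_to_prev=m_prev, motion_to_next=m_next,
                           target_depth=seq.depths[t],
                           intrinsics=seq.intrinsics))
    return out


def apply_brightness_perturbation(frames: list, amplitude: float,
                                  seed: int) -> list:
    """Smooth, spatially varying gain/offset perturbation per frame.

    The mean intensity shift of any frame is bounded by `amplitude`;
    amplitude 0 returns the frames unchanged.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return [f.copy() for f in frames]
    rng = np.random.default_rng(seed)
    out = []
    for f in frames:
        h, w = f.shape[:2]

        def smooth_field():
            g = gaussian_filter(rng.standard_normal((h, w)),
                                sigma=max(h, w) / 8.0)
            peak = np.abs(g).max()
            return g / peak if peak > 0 else g

        gain = 1.0 + 0.5 * amplitude * smooth_field()
        offset = 0.5 * amplitude * smooth_field()
        out.append(np.clip(f * gain[..., None] + offset[..., None], 0.0, 1.0))
    return out
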
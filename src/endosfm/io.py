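"""Dataset readers/writers and run configuration.

Frames are PNG/JPEG sequences ordered by a numeric-aware sort; depth maps
are 16-bit grayscale PNGs with a stated scale (units per integer step, so
the default 0.01 covers 0-655 scene units); trajectories use the TUM text
format and intrinsics a small JSON sidecar. Splits are assigned per video
sequence — frames of one sequence never straddle a split.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from skimage.transform import resize

from .geometry import Intrinsics

__all__ = [
    "DatasetManifest", "load_sequence", "load_frames", "split_by_sequence",
    "read_depth_png", "write_depth_png", "write_frames",
    "read_intrinsics_json", "write_intrinsics_json",
    "load_config", "config_hash",
]

DEPTH_SCALE_DEFAULT = 0.01


@dataclass
class DatasetManifest:
    frame_paths: list
    depth_paths: list | None = None
    trajectory_path: Path | None = None
    intrinsics: Intrinsics | None = None
    split: str | None = None
    name: str = ""


def _numeric_key(path: Path):
    parts = re.split(r"(\d+)", path.name)
    return [int(p) if p.isdigit() else p for p in parts]


def load_sequence(root, pattern: str = "*.png") -> DatasetManifest:
    """Collect an ordered frame manifest from a directory."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"sequence directory not found: {root}")
    paths = sorted(root.glob(pattern), key=_numeric_key)
    if not paths:
        raise FileNotFoundError(
            f"no frames matching {pattern!r} under {root}")
    depth_dir = root / "depth"
    depth_paths = None
    if depth_dir.is_dir():
        depth_paths = sorted(depth_dir.glob("*.png"), key=_numeric_key)
        if len(depth_paths) != len(paths):
            raise ValueError(
                f"{root}: {len(paths)} frames but {len(depth_paths)} depth maps")
    intr = None
    sidecar = root / "intrinsics.json"
    if sidecar.exists():
        intr = read_intrinsics_json(sidecar)
    traj = root / "trajectory.txt"
    return DatasetManifest(frame_paths=list(paths), depth_paths=depth_paths,
                           trajectory_path=traj if traj.exists() else None,
                           intrinsics=intr, name=root.name)


def load_frames(manifest: DatasetManifest,
                resolution: tuple | None = None) -> list:
    """Decode frames to float RGB in [0, 1], optionally resized with
    anti-aliasing to (width, height)."""
    frames = []
    for p in manifest.frame_paths:
        img = iio.imread(p)
        img = np.asarray(img, dtype=np.float64)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        img = img[:, :, :3] / 255.0
        if resolution is not None:
            w, h = resolution
            if img.shape[:2] != (h, w):
                img = resize(img, (h, w), anti_aliasing=True)
        frames.append(img)
    return frames


def split_by_sequence(manifests: list, ratios: tuple = (0.8, 0.1, 0.1),
                      seed: int = 0):
    """Assign whole sequences to (train, val, test) splits at the given
    ratios, each split getting at least one sequence."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    if len(manifests) < 3:
        raise ValueError("need at least one sequence per split")
    order = np.random.default_rng(seed).permutation(len(manifests))
    n = len(manifests)
    n_train = max(1, round(ratios[0] * n))
    n_val = max(1, round(ratios[1] * n))
    n_train = min(n_train, n - 2)
    n_val = min(n_val, n - n_train - 1)
    groups = (order[:n_train], order[n_train:n_train + n_val],
              order[n_train + n_val:])
    out = []
    for tag, idxs in zip(("train", "val", "test"), groups):
        chunk = []
        for i in sorted(idxs):
            m = manifests[i]
            m.split = tag
            chunk.append(m)
        out.append(chunk)
    return tuple(out)


def write_depth_png(path, depth: np.ndarray,
                    scale: float = DEPTH_SCALE_DEFAULT) -> None:
    """Store depth as 16-bit PNG; integer value = depth / scale."""
    depth = np.asarray(depth, dtype=np.float64)
    q = np.round(depth / scale)
    if (q < 0).any() or (q > 65535).any():
        raise ValueError("depth out of range for 16-bit encoding at this scale")
    iio.imwrite(Path(path), q.astype(np.uint16))


def read_depth_png(path, scale: float = DEPTH_SCALE_DEFAULT) -> np.ndarray:
    """Read a 16-bit depth PNG; zero pixels decode to 0 (invalid)."""
    arr = iio.imread(Path(path))
    if arr.dtype != np.uint16:
        raise ValueError(f"{path}: expected a 16-bit depth PNG, "
                         f"got dtype {arr.dtype}")
    return arr.astype(np.float64) * scale


def write_frames(directory, frames: list) -> list:
    """Write frames as 8-bit PNGs named frame_0000.png, ... ."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, f in enumerate(frames):
        p = directory / f"frame_{i:04d}.png"
        iio.imwrite(p, (np.clip(f, 0, 1) * 255).round().astype(np.uint8))
        paths.append(p)
    return paths


def write_intrinsics_json(path, intr: Intrinsics) -> None:
    with open(path, "w") as fh:
        json.dump({"fx": intr.fx, "fy": intr.fy,
                   "cx": intr.cx, "cy": intr.cy}, fh, indent=2)


def read_intrinsics_json(path) -> Intrinsics:
    with open(path) as fh:
        d = json.load(fh)
    return Intrinsics(fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"])


CONFIG_VERSION = 1


def load_config(path, known_keys: set) -> dict:
    """Load a versioned YAML config; unknown keys are hard errors (silent
    typos being the main failure mode of run configs)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    version = raw.pop("version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise ValueError(f"unsupported config version {version}")
    unknown = set(raw) - known_keys
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return raw


def config_hash(cfg: dict) -> str:
    """Stable hash of a resolved configuration (logged and stored in
    checkpoints so a run is fully identified)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
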
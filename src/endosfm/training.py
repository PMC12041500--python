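"""Joint optimisation of depth, pose, intrinsics, flow and brightness nets.

One training step takes a {t-1, t, t+1} snippet and

1. predicts the relative motion to each neighbour and the camera intrinsics
   (the intrinsics from the (t, t-1) pair are shared by both branches),
2. runs the plain branch: disparity pyramid on the target frame, optical
   flow + visibility masks + brightness calibration per source, and the
   photometric / smoothness losses at every pyramid scale on
   full-resolution-upsampled disparities,
3. runs the cost-volume branch on the past frame only, producing a second
   depth map whose agreement with the plain branch is enforced by the
   consistency loss — the route through which the plane-sweep geometry
   supervises the intrinsic and pose predictors,
4. combines everything into the total loss and applies one Adam step with
   gradient clipping.

The default configuration mirrors the published training protocol
(alpha=0.85, kappa=1, lambda=0.01/0.001/0.0001, Adam beta=(0.9, 0.99),
lr 1e-4 decayed x0.1 every 10 epochs for 20 epochs, 320x256 input,
plane-sweep range [0.1, 10]); :meth:`TrainConfig.desk_scale` shrinks the
resolution and network widths to something a CPU trains in minutes while
keeping every mechanism intact.
"""

from __future__ import annotations

import csv
import pickle
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor, clip_grad_norm
from .cost_volume import (CostVolumeDepthNet, build_cost_volume_tensors,
                          make_depth_planes)
from .geometry import flow_warp, project_warp
from .io import config_hash, load_config
from .losses import (LossBreakdown, LossWeights, data_fidelity,
                     depth_consistency, edge_aware_smoothness,
                     residual_smoothness, total_loss)
from .networks import (AFNet, DepthNet, Encoder, OFNet, PoseCameraNet,
                       disparity_to_depth, visibility_from_flow)

__all__ = ["TrainConfig", "ModelBundle", "lr_schedule", "train_step", "fit",
           "save_checkpoint", "load_checkpoint", "evaluate_intrinsics",
           "predict_snippet"]


@dataclass(frozen=True)
class TrainConfig:
    # loss weights
    alpha: float = 0.85
    kappa: float = 1.0
    lambda1: float = 0.01
    lambda2: float = 0.001
    lambda3: float = 0.0001
    consistency_weight: float = 0.05
    # optimiser / schedule
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99
    batch_size: int = 12
    initial_lr: float = 1e-4
    lr_decay_factor: float = 0.1
    lr_decay_every_epochs: int = 10
    total_epochs: int = 20
    grad_clip: float = 10.0
    # geometry
    width: int = 320
    height: int = 256
    min_depth: float = 0.1
    max_depth: float = 10.0
    num_planes: int = 64
    num_past_frames: int = 1
    num_scales: int = 4
    visibility_tau: float = 1.0
    # architecture widths
    depth_channels: tuple = (16, 32, 64, 128, 256)
    pose_channels: tuple = (16, 32, 64, 128, 256)
    pose_scale: float = 0.01
    cam_scale: float = 1.0
    offset_scale: float | None = None
    depth_head_scale: float = 1.0
    flow_channels: tuple = (16, 32, 64)
    cv_feature_channels: int = 16
    cv_channels: tuple = (32, 64)
    # switches
    use_flow_brightness: bool = True
    use_cost_volume: bool = True
    stop_feature_gradients: bool = False
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.initial_lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.total_epochs < 1:
            raise ValueError("need at least one epoch")
        d = 2 ** len(self.depth_channels)
        if self.width % d or self.height % d:
            raise ValueError(f"resolution {self.width}x{self.height} must be "
                             f"divisible by {d}")

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        """CPU-sized configuration: 64x48 frames, narrow networks, 32
        depth planes, batch of one."""
        base = dict(width=64, height=48, batch_size=1, total_epochs=1,
                    num_planes=32,
                    depth_channels=(8, 12, 16, 16),
                    pose_channels=(8, 12, 16, 16),
                    flow_channels=(8, 12, 16),
                    cv_feature_channels=8,
                    cv_channels=(12, 16),
                    initial_lr=1e-3)
        base.update(overrides)
        return cls(**base)

    def weights(self) -> LossWeights:
        return LossWeights(alpha=self.alpha, kappa=self.kappa,
                           lambda1=self.lambda1, lambda2=self.lambda2,
                           lambda3=self.lambda3)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        known = set(cls.__dataclass_fields__)
        raw = load_config(path, known)
        for key in ("depth_channels", "pose_channels", "flow_channels",
                    "cv_channels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class ModelBundle:
    """All five trainable components plus the cost-volume branch."""

    def __init__(self, config: TrainConfig,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.config = config
        self.depth_net = DepthNet(3, config.depth_channels,
                                  config.num_scales,
                                  head_scale=config.depth_head_scale,
                                  rng=rng)
        self.pose_cam_net = PoseCameraNet(config.pose_channels,
                                          pose_scale=config.pose_scale,
                                          cam_scale=config.cam_scale,
                                          offset_scale=config.offset_scale,
                                          rng=rng)
        self.of_net = OFNet(config.flow_channels, rng=rng)
        self.af_net = AFNet(rng=rng)
        self.cv_encoder = Encoder(3, (config.cv_feature_channels,
                                      config.cv_feature_channels), rng)
        planes = make_depth_planes(config.min_depth, config.max_depth,
                                   config.num_planes)
        self.planes = planes
        self.cv_depth_net = CostVolumeDepthNet(
            config.cv_feature_channels, planes,
            config.min_depth, config.max_depth,
            channels=config.cv_channels, upsample_factor=4,
            head_scale=config.depth_head_scale, rng=rng)

    def _components(self):
        return {"depth_net": self.depth_net,
                "pose_cam_net": self.pose_cam_net,
                "of_net": self.of_net,
                "af_net": self.af_net,
                "cv_encoder": self.cv_encoder,
                "cv_depth_net": self.cv_depth_net}

    def parameters(self):
        out = []
        for comp in self._components().values():
            out.extend(comp.parameters())
        return out

    def zero_grad(self):
        for comp in self._components().values():
            comp.zero_grad()

    def state_dict(self) -> dict:
        state = {}
        for name, comp in self._components().items():
            for k, v in comp.state_dict().items():
                state[f"{name}.{k}"] = v
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, comp in self._components().items():
            prefix = name + "."
            sub = {k[len(prefix):]: v for k, v in state.items()
                   if k.startswith(prefix)}
            comp.load_state_dict(sub)

    # ------------------------------------------------------------ inference
    def predict_depth(self, frame: np.ndarray) -> np.ndarray:
        """Depth map (H, W) for one (H, W, 3) frame, plain branch."""
        t = Tensor(np.asarray(frame, float).transpose(2, 0, 1)[None])
        disp = self.depth_net(t)[0]
        depth = disparity_to_depth(disp, self.config.min_depth,
                                   self.config.max_depth)
        return depth.data[0, 0]

    def predict_pose_intrinsics(self, target: np.ndarray,
                                source: np.ndarray):
        return self.pose_cam_net.predict(target, source)


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Step decay: lr = initial * factor^floor(epoch / every)."""
    if not 0 <= epoch < config.total_epochs:
        raise ValueError(f"epoch {epoch} outside schedule")
    return config.initial_lr * config.lr_decay_factor ** (
        epoch // config.lr_decay_every_epochs)


def _stack(frames: list) -> Tensor:
    return Tensor(np.stack([np.asarray(f, float).transpose(2, 0, 1)
                            for f in frames]))


def _scale_factors(num_scales: int):
    return [2 ** i for i in range(num_scales)]


def compute_losses(batch: list, bundle: ModelBundle,
                   config: TrainConfig):
    """Forward pass over a batch of snippets; returns (breakdown, total
    tensor, diagnostics dict)."""
    target = _stack([s.target for s in batch])
    prev = _stack([s.prev for s in batch])
    nxt = _stack([s.next for s in batch])
    n, _, h, w = target.shape

    # motion + intrinsics: prediction from the (t, t-1) pair is shared
    rot_p, trans_p, fx, fy, cx, cy = bundle.pose_cam_net(target, prev)
    rot_n, trans_n = bundle.pose_cam_net(target, nxt)[:2]
    sources = [(prev, rot_p, trans_p), (nxt, rot_n, trans_n)]

    # flow / brightness branch
    calibs, vises, flow_warps = [], [], []
    if config.use_flow_brightness:
        for src, _, _ in sources:
            fwd, bwd = bundle.of_net(target, src)
            vis = visibility_from_flow(fwd, bwd, config.visibility_tau)
            warped_flow = flow_warp(src, fwd[:, 0], fwd[:, 1])
            calib = bundle.af_net(target, warped_flow)
            calibs.append(calib)
            vises.append(vis)
            flow_warps.append(warped_flow)
    else:
        calibs = [None, None]
        vises = [None, None]

    # disparity pyramid, upsampled to frame resolution
    disps = bundle.depth_net(target)
    weights = config.weights()
    d_terms, les_terms = [], []
    depth_full_finest = None
    first_warp = None
    for i, disp in enumerate(disps[:config.num_scales]):
        disp_full = ad.upsample_nearest(disp, _scale_factors(config.num_scales)[i])
        depth_full = disparity_to_depth(disp_full, config.min_depth,
                                        config.max_depth)
        if i == 0:
            depth_full_finest = depth_full
        warped_pairs = []
        for src, rot, trans in sources:
            warped, valid = project_warp(src, depth_full.reshape(n, h, w),
                                         rot, trans, fx, fy, cx, cy)
            warped_pairs.append((warped, valid))
            if first_warp is None:
                first_warp = warped
        d_terms.append(data_fidelity(warped_pairs, target, calib=calibs,
                                     vis=vises, alpha=config.alpha))
        les_terms.append(edge_aware_smoothness(disp_full, target))

    d_term = sum(d_terms[1:], d_terms[0]) * (1.0 / len(d_terms))
    les_term = sum(les_terms[1:], les_terms[0]) * (1.0 / len(les_terms))

    if config.use_flow_brightness:
        lrs = sum((residual_smoothness(c, target, fw)
                   for c, fw in zip(calibs[1:], flow_warps[1:])),
                  residual_smoothness(calibs[0], target, flow_warps[0])) \
            * (1.0 / len(calibs))
        lax = data_fidelity([(fw, None) for fw in flow_warps], target,
                            calib=calibs, vis=vises, alpha=config.alpha)
    else:
        lrs = Tensor(0.0)
        lax = Tensor(0.0)

    diagnostics = {"intrinsics": (fx.data.copy(), fy.data.copy(),
                                  cx.data.copy(), cy.data.copy()),
                   "rot_prev": rot_p.data.copy(),
                   "trans_prev": trans_p.data.copy(),
                   "rot_next": rot_n.data.copy(),
                   "trans_next": trans_n.data.copy()}

    if config.use_cost_volume:
        f_t = bundle.cv_encoder(target)[-1]
        f_prev = bundle.cv_encoder(prev)[-1]
        if config.stop_feature_gradients:
            f_t, f_prev = f_t.detach(), f_prev.detach()
        costs = build_cost_volume_tensors(
            f_t, [f_prev], [rot_p], [trans_p], fx, fy, cx, cy, bundle.planes)
        d_cv = bundle.cv_depth_net(f_t, costs)
        consistency = depth_consistency(depth_full_finest, d_cv)
        diagnostics["cv_depth"] = d_cv.data.copy()
    else:
        consistency = Tensor(0.0)

    breakdown = total_loss(d_term, lrs, lax, les_term, consistency,
                           weights, config.consistency_weight)
    diagnostics["depth"] = depth_full_finest.data.copy()
    return breakdown, breakdown.total, diagnostics


def train_step(batch, bundle: ModelBundle, optimizer: Adam,
               config: TrainConfig) -> LossBreakdown:
    """One optimisation step on a snippet (or list of snippets)."""
    if not isinstance(batch, list):
        batch = [batch]
    breakdown, total, _ = compute_losses(batch, bundle, config)
    if not np.isfinite(total.data):
        raise FloatingPointError("total loss is not finite")
    bundle.zero_grad()
    total.backward()
    clip_grad_norm(bundle.parameters(), config.grad_clip)
    optimizer.step()
    return breakdown


# ------------------------------------------------------------- checkpointing

def save_checkpoint(path, bundle: ModelBundle, optimizer: Adam,
                    rng: np.random.Generator, epoch: int = 0) -> None:
    """Single-archive checkpoint: all networks, optimiser state, RNG state,
    epoch counter and the config hash."""
    cfg = asdict(bundle.config)
    payload = {"model": bundle.state_dict(),
               "optimizer": optimizer.state_dict(),
               "rng": rng.bit_generator.state,
               "epoch": epoch,
               "config": cfg,
               "config_hash": config_hash(cfg)}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path):
    """Returns (bundle, optimizer, rng, epoch) reconstructed from a
    checkpoint archive."""
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    cfg_dict = payload["config"]
    for key in ("depth_channels", "pose_channels", "flow_channels",
                "cv_channels"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = TrainConfig(**cfg_dict)
    bundle = ModelBundle(config)
    bundle.load_state_dict(payload["model"])
    optimizer = Adam(bundle.parameters(), lr=payload["optimizer"]["lr"],
                     betas=(config.adam_beta1, config.adam_beta2))
    optimizer.load_state_dict(payload["optimizer"])
    rng = np.random.default_rng()
    rng.bit_generator.state = payload["rng"]
    return bundle, optimizer, rng, payload["epoch"]


def fit(snippets: list, config: TrainConfig,
        checkpoint_dir=None, resume=None, log_path=None,
        val_snippets: list | None = None):
    """Full training loop with seeded shuffling, step-decay learning rate,
    per-epoch checkpointing and CSV loss logging.

    Returns (bundle, history) where history is a list of per-step
    LossBreakdowns.
    """
    if not snippets:
        raise ValueError("empty dataset")
    if resume is not None:
        bundle, optimizer, rng, start_epoch = load_checkpoint(resume)
        config = bundle.config
    else:
        rng = np.random.default_rng(config.seed)
        bundle = ModelBundle(config, rng)
        optimizer = Adam(bundle.parameters(), lr=config.initial_lr,
                         betas=(config.adam_beta1, config.adam_beta2))
        start_epoch = 0
    history: list[LossBreakdown] = []
    log_rows = []
    for epoch in range(start_epoch, config.total_epochs):
        optimizer.lr = lr_schedule(epoch, config)
        order = rng.permutation(len(snippets))
        for b0 in range(0, len(order), config.batch_size):
            batch = [snippets[i] for i in order[b0:b0 + config.batch_size]]
            bd = train_step(batch, bundle, optimizer, config)
            history.append(bd)
            log_rows.append({"epoch": epoch, "step": len(history),
                             "lr": optimizer.lr,
                             "total": float(bd.total.item()
                                            if isinstance(bd.total, Tensor)
                                            else bd.total),
                             "data_fidelity": bd.data_fidelity,
                             "residual_smoothness": bd.residual_smoothness,
                             "auxiliary": bd.auxiliary,
                             "edge_smoothness": bd.edge_smoothness,
                             "consistency": bd.consistency})
        if checkpoint_dir is not None:
            checkpoint_dir = Path(checkpoint_dir)
            checkpoint_dir.mkdir(parents=True, exist_ok=True)
            save_checkpoint(checkpoint_dir / f"epoch_{epoch:03d}.ckpt",
                            bundle, optimizer, rng, epoch + 1)
        if val_snippets:
            preds = evaluate_intrinsics(bundle, val_snippets)
            log_rows[-1]["val_fx"] = float(np.mean([p.fx for p in preds]))
            log_rows[-1]["val_fy"] = float(np.mean([p.fy for p in preds]))
    if log_path is not None:
        keys = sorted({k for row in log_rows for k in row})
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(log_rows)
    return bundle, history


def evaluate_intrinsics(bundle: ModelBundle, snippets: list) -> list:
    """Predicted intrinsics for each snippet's (t, t-1) pair."""
    out = []
    for s in snippets:
        _, intr = bundle.pose_cam_net.predict(s.target, s.prev)
        out.append(intr)
    return out


def predict_snippet(bundle: ModelBundle, snippet):
    """Inference on one snippet: (depth map, motion to t-1, motion to t+1,
    intrinsics)."""
    depth = bundle.predict_depth(snippet.target)
    m_prev, intr = bundle.pose_cam_net.predict(snippet.target, snippet.prev)
    m_next, _ = bundle.pose_cam_net.predict(snippet.target, snippet.next)
    return depth, m_prev, m_next, intr
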
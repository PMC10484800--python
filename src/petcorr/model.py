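"""Correction-map predictor: preprocessing, residual encoder–decoder, training.

The network sees three co-registered 2D axial channels — Dixon in-phase,
Dixon out-of-phase and the four-class µ-map — each min–max scaled to [0, 1]
per volume and zeroed outside the body contour. It regresses the voxel-wise
correction map with an L2 loss evaluated only where the target map is
defined (masked MSE), trained with Adam under a learning rate that is
constant for the first half of training and then decays linearly to zero.

The architecture is a fully-convolutional residual encoder–decoder: a
convolutional front-end downsamples the slice (default to one-fourth
resolution), a stack of residual blocks (default nine) transforms it at low
resolution, and a transposed-convolution back-end restores the input
resolution with a linear single-channel output (correction values can be
negative, so no saturating output activation).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .correction import CorrectionMap, DEFAULT_CLAMP, clamp_correction_map
from .mumap import MuMap
from .phantom import Phantom, body_contour_mask
from .volume import ImageVolume, VolumeError, resample_to_grid


@dataclass(frozen=True)
class NetConfig:
    n_res_blocks: int = 9
    base_filters: int = 64
    downsample_factor: int = 4
    epochs: int = 100
    lr: float = 2e-4
    batch_size: int = 16
    lr_decay_start_epoch: int = 50
    seed: int = 0

    def __post_init__(self):
        f = self.downsample_factor
        if f < 1 or (f & (f - 1)) != 0:
            raise ValueError("downsample factor must be a power of 2")
        if not (1 <= self.lr_decay_start_epoch < self.epochs):
            raise ValueError("LR decay must start before the final epoch")
        if self.n_res_blocks < 1 or self.base_filters < 1:
            raise ValueError("need at least 1 residual block and 1 filter")


@dataclass
class TrainingSample:
    """One axial slice: three input channels in [0,1], target map, weight mask."""

    channels: np.ndarray            # (3, H, W) float32
    target: np.ndarray | None = None   # (H, W) float32
    weight: np.ndarray | None = None   # (H, W) float32, 0 outside valid region

    def __post_init__(self):
        c = self.channels
        if c.ndim != 3 or c.shape[0] != 3:
            raise ValueError("channels must have shape (3, H, W)")
        if c.size and (c.min() < -1e-6 or c.max() > 1 + 1e-6):
            raise ValueError("channels must be min–max scaled to [0, 1]")
        for arr in (self.target, self.weight):
            if arr is not None and arr.shape != c.shape[1:]:
                raise ValueError("target/weight shape must match channel slices")


def _minmax(volume: np.ndarray) -> np.ndarray:
    lo, hi = float(volume.min()), float(volume.max())
    if hi == lo:
        raise VolumeError("constant volume cannot be min–max scaled")
    return ((volume - lo) / (hi - lo)).astype(np.float32)


def preprocess(
    phantom: Phantom,
    mu4c: MuMap,
    pet_grid: ImageVolume | None = None,
    body_mask: np.ndarray | None = None,
) -> list[TrainingSample]:
    """Build per-slice network inputs from a phantom and its four-class µ-map.

    Volumes not already on ``pet_grid`` are linearly resampled to it. Each
    volume is min–max scaled to [0, 1] as a whole (per volume, not per slice,
    so axial intensity relations survive), then zeroed outside the body
    contour, and axial slices are emitted in order.
    """
    vols = [phantom.dixon_ip, phantom.dixon_op, mu4c.volume]
    if pet_grid is not None:
        vols = [resample_to_grid(v, pet_grid) for v in vols]
    ref = vols[0]
    if body_mask is None:
        body_mask = body_contour_mask(ref)
    if body_mask.shape != ref.shape:
        raise VolumeError("body mask shape mismatch")
    scaled = []
    for v in vols:
        s = _minmax(np.asarray(v.data, dtype=np.float64))
        s[~body_mask] = 0.0
        scaled.append(s)
    stack = np.stack(scaled)  # (3, nx, ny, nz)
    return [TrainingSample(np.ascontiguousarray(stack[:, :, :, k]))
            for k in range(ref.shape[2])]


def attach_targets(samples: list[TrainingSample], cmap: CorrectionMap,
                   clamp: tuple[float, float] = DEFAULT_CLAMP) -> list[TrainingSample]:
    """Pair preprocessed input slices with correction-map targets and weights.

    Targets are clamped to the same physical range that predicted maps are
    clamped to before application: values outside it are unreachable by the
    corrected image anyway, and leaving the rare extreme low-activity voxels
    unclamped would let them dominate the L2 loss.
    """
    nz = cmap.volume.shape[2]
    if len(samples) != nz:
        raise ValueError(f"{len(samples)} slices vs {nz} correction-map slices")
    lo, hi = clamp
    out = []
    for k, s in enumerate(samples):
        out.append(TrainingSample(
            s.channels,
            np.clip(np.asarray(cmap.data[:, :, k], dtype=np.float32), lo, hi),
            cmap.valid_mask[:, :, k].astype(np.float32),
        ))
    return out


def build_network(cfg: NetConfig) -> nn.Sequential:
    """Assemble the residual encoder–decoder; parameter init is seeded."""
    rng = np.random.default_rng(cfg.seed)
    n_down = int(np.log2(cfg.downsample_factor))
    layers: list[nn.Layer] = [nn.Conv2D(3, cfg.base_filters, 3, 1, 1, rng=rng), nn.ReLU()]
    ch = cfg.base_filters
    for _ in range(n_down):
        layers += [nn.Conv2D(ch, ch * 2, 3, 2, 1, rng=rng), nn.ReLU()]
        ch *= 2
    for _ in range(cfg.n_res_blocks):
        layers.append(nn.ResidualBlock(ch, rng=rng))
    for _ in range(n_down):
        layers += [nn.ConvTranspose2D(ch, ch // 2, 4, 2, 1, rng=rng), nn.ReLU()]
        ch //= 2
    # small-scale linear output head: early predictions start near zero
    layers.append(nn.Conv2D(ch, 1, 3, 1, 1, rng=rng, w_scale=0.1))
    return nn.Sequential(layers)


def _check_divisible(shape, factor):
    if shape[0] % factor or shape[1] % factor:
        raise ValueError(
            f"slice shape {shape} not divisible by downsample factor {factor}")


def lr_schedule(epoch: int, cfg: NetConfig) -> float:
    """Constant LR through ``lr_decay_start_epoch``, then linear decay to 0
    at the final epoch (epochs are 1-indexed)."""
    if epoch <= cfg.lr_decay_start_epoch:
        return cfg.lr
    return cfg.lr * (cfg.epochs - epoch) / (cfg.epochs - cfg.lr_decay_start_epoch)


@dataclass
class TrainResult:
    model: nn.Sequential
    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int
    best_state: list[np.ndarray]


def _batch(samples, idx):
    x = np.stack([samples[i].channels for i in idx]).astype(np.float32)
    t = np.stack([samples[i].target for i in idx])[:, None].astype(np.float32)
    w = np.stack([samples[i].weight for i in idx])[:, None].astype(np.float32)
    return x, t, w


def evaluate_loss(model: nn.Sequential, samples, batch_size=16) -> float:
    """Masked MSE over a sample set, without updating parameters."""
    num, den = 0.0, 0.0
    for i0 in range(0, len(samples), batch_size):
        x, t, w = _batch(samples, range(i0, min(i0 + batch_size, len(samples))))
        pred = model.forward(x)
        num += float((w * (pred - t) ** 2).sum())
        den += float(w.sum())
    return num / max(den, 1e-30)


def train(model: nn.Sequential, samples: list[TrainingSample], cfg: NetConfig,
          val_samples: list[TrainingSample] | None = None,
          log=None) -> TrainResult:
    """Train with Adam on the masked L2 loss; retains the best-validation state.

    Without a validation set the training loss drives snapshot selection.
    """
    if not samples:
        raise ValueError("empty training set")
    _check_divisible(samples[0].channels.shape[1:], cfg.downsample_factor)
    opt = nn.Adam(model.params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    val = val_samples if val_samples else samples
    train_hist, val_hist = [], []
    best = (np.inf, 0, model.get_state())
    n = len(samples)
    for epoch in range(1, cfg.epochs + 1):
        lr = lr_schedule(epoch, cfg)
        order = rng.permutation(n)
        ep_num, ep_den = 0.0, 0.0
        for i0 in range(0, n, cfg.batch_size):
            idx = order[i0:i0 + cfg.batch_size]
            x, t, w = _batch(samples, idx)
            pred = model.forward(x)
            loss, grad = nn.masked_mse(pred, t, w)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (lr={lr:.2e}); "
                    "lower the learning rate or check the targets")
            model.backward(grad)
            if lr > 0:
                opt.step(lr)
            ep_num += loss * float(w.sum())
            ep_den += float(w.sum())
        train_hist.append(ep_num / max(ep_den, 1e-30))
        vloss = evaluate_loss(model, val, cfg.batch_size)
        val_hist.append(vloss)
        if vloss < best[0]:
            best = (vloss, epoch, model.get_state())
        if log:
            log(f"epoch {epoch:3d}  lr {lr:.2e}  train {train_hist[-1]:.5f}  val {vloss:.5f}")
    model.set_state(best[2])
    return TrainResult(model, train_hist, val_hist, best[1], best[2])


def predict_correction_map(
    model: nn.Sequential,
    phantom: Phantom,
    mu4c: MuMap,
    pelvic_mask: np.ndarray,
    pet_grid: ImageVolume | None = None,
    clamp: tuple[float, float] = DEFAULT_CLAMP,
    batch_size: int = 16,
) -> CorrectionMap:
    """Slice-wise inference reassembled into a 3D clamped correction map,
    zeroed outside the pelvic mask."""
    samples = preprocess(phantom, mu4c, pet_grid)
    ref = phantom.dixon_ip if pet_grid is None else pet_grid
    pred = np.zeros(ref.shape, dtype=np.float64)
    for i0 in range(0, len(samples), batch_size):
        chunk = samples[i0:i0 + batch_size]
        x = np.stack([s.channels for s in chunk]).astype(np.float32)
        out = model.forward(x)[:, 0]
        for j, sl in enumerate(out):
            pred[:, :, i0 + j] = sl
    pred[~pelvic_mask] = 0.0
    cmap = CorrectionMap(
        ImageVolume(pred, ref.spacing, ref.origin, "dimensionless"), pelvic_mask.copy())
    return clamp_correction_map(cmap, clamp)
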
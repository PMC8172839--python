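"""Segmentation losses, predictors, training, and heatmap stitching.

Loss
----
Tumor pixels are a minuscule fraction of a slide, so plain cross-entropy
collapses onto the background class.  Training therefore minimizes a hybrid
loss

    Loss = alpha * CL + beta * DL_BG + gamma * DL_FG

where CL is mean binary cross-entropy, DL_FG the soft dice loss

    DL = 1 - 2 * sum(p_i g_i) / (sum(p_i^2) + sum(g_i^2) + eps)

on the tumor (foreground) channel and DL_BG the same on the complements
(1-p, 1-g).  With the default weights (0.5, 0.25, 0.25) the cross-entropy
and dice terms carry equal weight.

Predictors and stitching
------------------------
A predictor maps an RGB patch to a posterior probability map of identical
spatial dims; an ensemble is averaged pixel-wise.  Slide-level output is
assembled by predicting on an overlapping patch grid and averaging the
probabilities wherever patches overlap (sum grid / coverage-count grid),
which removes the blockish seam artifacts of non-overlapping tiling.

The shipped trainable predictor is :class:`MiniFCN`, a small numpy
encoder–decoder network (conv/pool encoder, upsample/conv decoder, sigmoid
head) trained with ADAM by manual backpropagation — enough capacity to
learn the stain-contrast segmentation of the synthetic slides while keeping
the whole pipeline runnable on one CPU.  Deterministic mock predictors
(constant, ground-truth oracle, noisy oracle, color-threshold) exercise the
pipeline contracts in tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from wsikit.wsi_core import LevelPoint, PyramidImage, default_mask_level
from wsikit.tissue import MaskParams, TissueMask, compute_tissue_mask, preprocess_black_borders
from wsikit.patches import PatchGrid, build_inference_grid

__all__ = [
    "LossWeights",
    "dice_loss",
    "cross_entropy_loss",
    "hybrid_loss",
    "Predictor",
    "ConstantPredictor",
    "GroundTruthPredictor",
    "NoisyPredictor",
    "ColorThresholdPredictor",
    "MiniFCN",
    "TrainingSchedule",
    "train_segmentation_model",
    "ensemble_predict",
    "StitchedHeatmap",
    "stitch_heatmap",
    "run_slide_inference",
    "dice_coefficient",
    "save_model_bundle",
    "load_model_bundle",
]

DICE_EPS = 1e-6
CE_CLIP = 1e-7


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LossWeights:
    """Hybrid-loss weights (alpha: cross-entropy, beta: background dice,
    gamma: foreground dice)."""

    alpha: float = 0.5
    beta: float = 0.25
    gamma: float = 0.25

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("loss weights must be non-negative")


def _check_pair(p: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs target {g.shape}")
    return p, g


def dice_loss(p: np.ndarray, g: np.ndarray, eps: float = DICE_EPS) -> float:
    """Soft dice loss 1 - 2*sum(pg) / (sum(p^2) + sum(g^2) + eps)."""
    p, g = _check_pair(p, g)
    num = 2.0 * float((p * g).sum()) + eps
    den = float((p * p).sum() + (g * g).sum()) + eps
    return 1.0 - num / den


def cross_entropy_loss(p: np.ndarray, g: np.ndarray, clip: float = CE_CLIP) -> float:
    """Mean binary cross-entropy; predictions clipped to [clip, 1-clip]."""
    p, g = _check_pair(p, g)
    pc = np.clip(p, clip, 1.0 - clip)
    return float(-(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean())


def hybrid_loss(
    p: np.ndarray, g: np.ndarray, weights: LossWeights = LossWeights()
) -> float:
    """alpha*CE + beta*dice(1-p, 1-g) + gamma*dice(p, g)."""
    p, g = _check_pair(p, g)
    return (
        weights.alpha * cross_entropy_loss(p, g)
        + weights.beta * dice_loss(1.0 - p, 1.0 - g)
        + weights.gamma * dice_loss(p, g)
    )


def hybrid_loss_grad(
    p: np.ndarray, g: np.ndarray, weights: LossWeights = LossWeights()
) -> np.ndarray:
    """d(hybrid_loss)/dp, used by MiniFCN backprop."""
    p, g = _check_pair(p, g)
    n = p.size
    pc = np.clip(p, CE_CLIP, 1.0 - CE_CLIP)
    d_ce = (pc - g) / (pc * (1.0 - pc)) / n

    def d_dice(pp: np.ndarray, gg: np.ndarray) -> np.ndarray:
        a = float((pp * gg).sum())
        b = float((pp * pp).sum() + (gg * gg).sum()) + DICE_EPS
        return (2.0 * (2.0 * a + DICE_EPS) * pp - 2.0 * gg * b) / (b * b)

    grad = weights.alpha * d_ce + weights.gamma * d_dice(p, g)
    grad -= weights.beta * d_dice(1.0 - p, 1.0 - g)
    return grad


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Hard Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks (1.0 when
    both are empty)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    s = a.sum() + b.sum()
    if s == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(s)


# ---------------------------------------------------------------------------
# predictor contract and deterministic mocks
# ---------------------------------------------------------------------------


@runtime_checkable
class Predictor(Protocol):
    """An RGB patch -> posterior probability map of the same spatial dims.

    ``center`` (level-0 patch center) is forwarded by slide-level drivers;
    content-based predictors ignore it, location-based oracles require it.
    """

    def predict(self, patch: np.ndarray, center: LevelPoint | None = None) -> np.ndarray: ...


class ConstantPredictor:
    """Returns a constant probability everywhere (pipeline plumbing mock)."""

    def __init__(self, value: float):
        if not 0.0 <= value <= 1.0:
            raise ValueError("constant probability must lie in [0, 1]")
        self.value = float(value)

    def predict(self, patch: np.ndarray, center: LevelPoint | None = None) -> np.ndarray:
        return np.full(patch.shape[:2], self.value, dtype=np.float32)


class GroundTruthPredictor:
    """Oracle that returns the ground-truth tumor-mask crop at the patch
    location (pixels outside the slide are 0)."""

    def __init__(self, tumor_mask0: np.ndarray):
        self.mask = np.asarray(tumor_mask0).astype(np.float32)

    def predict(self, patch: np.ndarray, center: LevelPoint | None = None) -> np.ndarray:
        if center is None:
            raise ValueError("GroundTruthPredictor needs the patch center")
        size = patch.shape[0]
        h, w = self.mask.shape
        x0, y0 = center.x - size // 2, center.y - size // 2
        out = np.zeros((size, size), dtype=np.float32)
        sx0, sy0 = max(x0, 0), max(y0, 0)
        sx1, sy1 = min(x0 + size, w), min(y0 + size, h)
        if sx1 > sx0 and sy1 > sy0:
            out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = self.mask[sy0:sy1, sx0:sx1]
        return out


class NoisyPredictor:
    """Wraps a predictor with deterministic location-keyed noise."""

    def __init__(self, base: Predictor, sigma: float = 0.05, seed: int = 0):
        self.base = base
        self.sigma = float(sigma)
        self.seed = int(seed)

    def predict(self, patch: np.ndarray, center: LevelPoint | None = None) -> np.ndarray:
        p = self.base.predict(patch, center)
        key = (self.seed, center.x, center.y) if center is not None else (self.seed,)
        rng = np.random.default_rng(abs(hash(key)) % (2**31))
        return np.clip(p + rng.normal(0.0, self.sigma, p.shape), 0.0, 1.0).astype(
            np.float32
        )


class ColorThresholdPredictor:
    """Equivariant content-based mock: dark (nuclei-dense) pixels score
    high.  p = sigmoid((threshold - mean RGB) / softness)."""

    def __init__(self, threshold: float = 150.0, softness: float = 12.0):
        self.threshold = float(threshold)
        self.softness = float(softness)

    def predict(self, patch: np.ndarray, center: LevelPoint | None = None) -> np.ndarray:
        gray = patch.astype(np.float32).mean(axis=2)
        return _sigmoid((self.threshold - gray) / self.softness)


def ensemble_predict(
    models: Sequence[Predictor], patch: np.ndarray, center: LevelPoint | None = None
) -> np.ndarray:
    """Pixel-wise arithmetic mean of the member posterior maps."""
    if not models:
        raise ValueError("need at least one model")
    maps = [np.asarray(m.predict(patch, center), dtype=np.float32) for m in models]
    shapes = {m.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"ensemble members disagree on output dims: {shapes}")
    return np.mean(maps, axis=0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# MiniFCN: small numpy encoder-decoder with manual backprop
# ---------------------------------------------------------------------------


class _Conv:
    """k×k same-padding convolution on (H, W, Cin) float32 maps."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * cin))
        self.W = (rng.standard_normal((k * k * cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.cin, self.cout = k, cin, cout
        self._col: np.ndarray | None = None
        self._shape: tuple[int, int] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, w, _ = x.shape
        pad = self.k // 2
        if pad:
            x = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
        win = sliding_window_view(x, (self.k, self.k), axis=(0, 1))  # H,W,cin,k,k
        col = np.ascontiguousarray(win.transpose(0, 1, 3, 4, 2)).reshape(
            h * w, self.k * self.k * self.cin
        )
        self._col, self._shape = col, (h, w)
        return (col @ self.W + self.b).reshape(h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._shape
        dyf = dy.reshape(h * w, self.cout).astype(np.float32)
        self.dW = self._col.T @ dyf
        self.db = dyf.sum(axis=0)
        dcol = (dyf @ self.W.T).reshape(h, w, self.k, self.k, self.cin)
        pad = self.k // 2
        dxp = np.zeros((h + 2 * pad, w + 2 * pad, self.cin), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[i : i + h, j : j + w] += dcol[:, :, i, j, :]
        return dxp[pad : pad + h, pad : pad + w] if pad else dxp

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


def _pool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    return x[: h // 2 * 2, : w // 2 * 2].reshape(h // 2, 2, w // 2, 2, c).mean(axis=(1, 3))


def _pool2_back(dy: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    h, w, c = shape
    dx = np.zeros(shape, dtype=np.float32)
    up = np.repeat(np.repeat(dy, 2, axis=0), 2, axis=1) / 4.0
    dx[: up.shape[0], : up.shape[1]] = up
    return dx


def _up2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=0), 2, axis=1)


def _up2_back(dy: np.ndarray) -> np.ndarray:
    h, w, c = dy.shape
    return dy.reshape(h // 2, 2, w // 2, 2, c).sum(axis=(1, 3))


class MiniFCN:
    """Small encoder–decoder FCN (numpy, CPU).

    Encoder: conv3×3(3→c) → ReLU → 2×2 mean-pool → conv3×3(c→2c) → ReLU.
    Decoder: 2× nearest upsample → conv3×3(2c→c) → ReLU → conv1×1(c→1)
    → sigmoid.  Patches are normalized (mean/std stored with the model)
    before entering the network.  Inference is deterministic.
    """

    pretrained_encoder = False

    def __init__(self, channels: int = 8, seed: int = 0,
                 norm_mean: float = 0.5, norm_std: float = 0.25):
        rng = np.random.default_rng(seed)
        c = channels
        self.channels = c
        self.norm_mean = float(norm_mean)
        self.norm_std = float(norm_std)
        self.enc1 = _Conv(3, c, 3, rng)
        self.enc2 = _Conv(c, 2 * c, 3, rng)
        self.dec1 = _Conv(2 * c, c, 3, rng)
        self.head = _Conv(c, 1, 1, rng)
        self._cache: dict = {}

    # -- parameter groups (encoder freezing during early epochs) ----------

    def encoder_layers(self) -> list[_Conv]:
        return [self.enc1, self.enc2]

    def decoder_layers(self) -> list[_Conv]:
        return [self.dec1, self.head]

    def layers(self) -> list[_Conv]:
        return self.encoder_layers() + self.decoder_layers()

    # -- forward / backward ----------------------------------------------

    def _normalize(self, patch: np.ndarray) -> np.ndarray:
        x = patch.astype(np.float32)
        if patch.dtype == np.uint8:
            x = x / 255.0
        return (x - self.norm_mean) / self.norm_std

    def forward(self, patch: np.ndarray) -> np.ndarray:
        x = self._normalize(patch)
        a1 = self.enc1.forward(x)
        r1 = np.maximum(a1, 0.0)
        p1 = _pool2(r1)
        a2 = self.enc2.forward(p1)
        r2 = np.maximum(a2, 0.0)
        u = _up2(r2)
        a3 = self.dec1.forward(u)
        r3 = np.maximum(a3, 0.0)
        z = self.head.forward(r3)[..., 0]
        prob = _sigmoid(z)
        self._cache = {"r1": r1, "r2": r2, "r3": r3, "prob": prob, "shape1": r1.shape}
        return prob

    def backward(self, dprob: np.ndarray) -> None:
        c = self._cache
        prob = c["prob"]
        dz = (dprob * prob * (1.0 - prob))[..., None].astype(np.float32)
        d3 = self.head.backward(dz)
        d3 *= c["r3"] > 0
        du = self.dec1.backward(d3)
        d2 = _up2_back(du)
        d2 *= c["r2"] > 0
        dp1 = self.enc2.backward(d2)
        d1 = _pool2_back(dp1, c["shape1"])
        d1 *= c["r1"] > 0
        self.enc1.backward(d1)

    def predict(self, patch: np.ndarray, center: LevelPoint | None = None) -> np.ndarray:
        return self.forward(patch)

    # -- (de)serialization ------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in zip(("enc1", "enc2", "dec1", "head"), self.layers()):
            out[f"{name}.W"] = layer.W.copy()
            out[f"{name}.b"] = layer.b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in zip(("enc1", "enc2", "dec1", "head"), self.layers()):
            layer.W = np.array(state[f"{name}.W"], dtype=np.float32)
            layer.b = np.array(state[f"{name}.b"], dtype=np.float32)


# ---------------------------------------------------------------------------
# training contract
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainingSchedule:
    """ADAM schedule: stepwise learning-rate decay, encoder freezing for
    the first ``freeze_encoder_epochs`` epochs when the model declares a
    pretrained encoder, early stop on validation-loss increase."""

    max_epochs: int = 20
    learning_rate: float = 1e-4
    decay_every: int = 4
    decay_factor: float = 0.5
    freeze_encoder_epochs: int = 2
    patience: int = 1
    seed: int = 0


def train_segmentation_model(
    model: MiniFCN,
    train_set: Sequence[tuple[np.ndarray, np.ndarray]],
    val_set: Sequence[tuple[np.ndarray, np.ndarray]],
    weights: LossWeights = LossWeights(),
    schedule: TrainingSchedule = TrainingSchedule(),
) -> tuple[MiniFCN, dict[str, list[float]]]:
    """Train a MiniFCN on (patch, binary mask) pairs by minimizing the
    hybrid loss with ADAM.

    Returns the model restored to its best-validation weights plus the
    per-epoch ``{"train_loss": [...], "val_loss": [...]}`` history.
    Deterministic for a fixed schedule seed.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(schedule.seed)
    adam_m = [np.zeros_like(p) for layer in model.layers() for p in layer.params()]
    adam_v = [np.zeros_like(p) for layer in model.layers() for p in layer.params()]
    step = 0
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = model.state_dict()
    bad_epochs = 0

    for epoch in range(schedule.max_epochs):
        lr = schedule.learning_rate * schedule.decay_factor ** (epoch // schedule.decay_every)
        freeze_encoder = (
            model.pretrained_encoder and epoch < schedule.freeze_encoder_epochs
        )
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        for idx in order:
            patch, mask = train_set[idx]
            g = np.asarray(mask, dtype=np.float32)
            prob = model.forward(patch)
            epoch_loss += hybrid_loss(prob, g, weights)
            model.backward(hybrid_loss_grad(prob, g, weights).astype(np.float32))
            step += 1
            _adam_step(model, adam_m, adam_v, step, lr, freeze_encoder)
        history["train_loss"].append(epoch_loss / len(train_set))

        val_loss = float(
            np.mean([hybrid_loss(model.forward(px), np.asarray(mk, np.float32), weights)
                     for px, mk in val_set])
        ) if len(val_set) else history["train_loss"][-1]
        history["val_loss"].append(val_loss)

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= schedule.patience:
                break

    model.load_state_dict(best_state)
    return model, history


def _adam_step(
    model: MiniFCN,
    m: list[np.ndarray],
    v: list[np.ndarray],
    t: int,
    lr: float,
    freeze_encoder: bool,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> None:
    i = 0
    encoder = set(id(l) for l in model.encoder_layers())
    for layer in model.layers():
        frozen = freeze_encoder and id(layer) in encoder
        for p, g in zip(layer.params(), layer.grads()):
            if not frozen:
                m[i][...] = beta1 * m[i] + (1 - beta1) * g
                v[i][...] = beta2 * v[i] + (1 - beta2) * g * g
                mh = m[i] / (1 - beta1**t)
                vh = v[i] / (1 - beta2**t)
                p -= lr * mh / (np.sqrt(vh) + eps)
            i += 1


# ---------------------------------------------------------------------------
# heatmap stitching and slide inference
# ---------------------------------------------------------------------------


@dataclass
class StitchedHeatmap:
    """Slide-level probability grid with its coverage-count companion.

    ``prob`` is the mean posterior wherever ``count`` > 0 and 0 elsewhere;
    ``downsample`` maps heatmap pixels to level-0 pixels; ``level`` is the
    pyramid level index when the heatmap is aligned to one.
    """

    prob: np.ndarray
    count: np.ndarray
    downsample: float = 1.0
    level: int | None = None


def stitch_heatmap(
    grid: PatchGrid,
    patch_probs: Sequence[np.ndarray],
    slide_dims: tuple[int, int],
    out_downsample: float = 1.0,
    level: int | None = None,
) -> StitchedHeatmap:
    """Assemble per-patch probability maps into a seam-free slide heatmap.

    Each map is accumulated into level-0 sum and coverage-count grids
    (double-precision sums, so the result matches a per-pixel mean oracle
    to ~1e-12); the final probability is sum/count wherever covered, so
    every pixel equals the mean of all patch predictions covering it.  With
    ``out_downsample`` > 1 sum and count are block-reduced first and the
    ratio is taken at the reduced scale (a coverage-weighted block mean).
    """
    if len(patch_probs) != len(grid.centers):
        raise ValueError(
            f"{len(patch_probs)} probability maps for {len(grid.centers)} grid centers"
        )
    w0, h0 = slide_dims
    s = grid.patch_size
    acc = np.zeros((h0, w0), dtype=np.float64)
    cnt = np.zeros((h0, w0), dtype=np.int32)
    for center, pmap in zip(grid.centers, patch_probs):
        pmap = np.asarray(pmap, dtype=np.float64)
        if pmap.shape != (s, s):
            raise ValueError(f"patch map shape {pmap.shape} != ({s}, {s})")
        x0, y0 = center.x - s // 2, center.y - s // 2
        sx0, sy0 = max(x0, 0), max(y0, 0)
        sx1, sy1 = min(x0 + s, w0), min(y0 + s, h0)
        if sx1 <= sx0 or sy1 <= sy0:
            continue
        acc[sy0:sy1, sx0:sx1] += pmap[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0]
        cnt[sy0:sy1, sx0:sx1] += 1
    if out_downsample != 1.0:
        f = int(round(out_downsample))
        hh, ww = h0 // f, w0 // f
        acc = acc[: hh * f, : ww * f].reshape(hh, f, ww, f).sum(axis=(1, 3))
        cnt = cnt[: hh * f, : ww * f].reshape(hh, f, ww, f).sum(axis=(1, 3))
    prob = np.zeros_like(acc)
    covered = cnt > 0
    prob[covered] = acc[covered] / cnt[covered]
    return StitchedHeatmap(prob, cnt, float(out_downsample), level)


def run_slide_inference(
    img: PyramidImage,
    models: Sequence[Predictor],
    patch_size: int = 1024,
    stride: int = 512,
    mask_level: int | None = None,
    out_level: int | None = None,
    mask_params: MaskParams = MaskParams(),
    black_border_preprocess: bool = False,
    tissue: TissueMask | None = None,
) -> StitchedHeatmap:
    """Full slide inference: tissue mask → patch grid → per-patch ensemble
    prediction → overlap-averaged stitching.

    The heatmap is materialized at ``out_level`` (default: the mask level)
    to bound memory.  Output is independent of patch order.
    """
    if mask_level is None:
        mask_level = default_mask_level(img)
    if out_level is None:
        out_level = mask_level
    img._check_level(out_level)
    if tissue is None:
        low = img.levels[mask_level]
        if black_border_preprocess:
            low = preprocess_black_borders(low)
        tissue = compute_tissue_mask(low, mask_params, level=mask_level)
    f_mask = img.downsample_factors[mask_level]
    grid = build_inference_grid(
        tissue, patch_size, stride, mask_downsample=f_mask,
        slide_dims=(img.width0, img.height0),
    )
    probs = [
        ensemble_predict(models, img.read_region(c, patch_size, level=0), c)
        for c in grid.centers
    ]
    return stitch_heatmap(
        grid,
        probs,
        (img.width0, img.height0),
        out_downsample=img.downsample_factors[out_level],
        level=out_level,
    )


# ---------------------------------------------------------------------------
# model bundles
# ---------------------------------------------------------------------------


def save_model_bundle(
    path: str | Path,
    models: Sequence[MiniFCN],
    patch_size: int = 256,
    extra_meta: dict | None = None,
) -> Path:
    """Persist an ensemble: one npz of weights per member plus a JSON with
    normalization constants, patch size, and encoder-freeze metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_members": len(models),
        "patch_size": patch_size,
        "members": [],
    }
    for i, m in enumerate(models):
        np.savez(path / f"member_{i}.npz", **m.state_dict())
        meta["members"].append(
            {
                "channels": m.channels,
                "norm_mean": m.norm_mean,
                "norm_std": m.norm_std,
                "pretrained_encoder": bool(m.pretrained_encoder),
            }
        )
    if extra_meta:
        meta.update(extra_meta)
    (path / "bundle.json").write_text(json.dumps(meta, indent=2))
    return path


def load_model_bundle(path: str | Path) -> tuple[list[MiniFCN], dict]:
    path = Path(path)
    meta = json.loads((path / "bundle.json").read_text())
    models = []
    for i, mm in enumerate(meta["members"]):
        m = MiniFCN(
            channels=mm["channels"], norm_mean=mm["norm_mean"], norm_std=mm["norm_std"]
        )
        with np.load(path / f"member_{i}.npz") as st:
            m.load_state_dict({k: st[k] for k in st.files})
        models.append(m)
    return models, meta
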
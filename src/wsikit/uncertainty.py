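"""Patch-based aleatoric and epistemic uncertainty maps.

Two variance decompositions are computed per pixel of the posterior map:

* **aleatoric** — variance of one model's predictions across a set of
  invertible test-time augmentations (TTA): the patch is transformed,
  predicted, and the prediction mapped back through the inverse transform;
  the per-pixel *population* variance of the aligned maps estimates
  data-driven uncertainty,

      var_al(x, Phi) ≈ E_t[(Phi(x|w,t) - E_t[Phi(x|w,t)])^2].

* **epistemic** — population variance across the ensemble members'
  predictions on the same patch, attributing uncertainty to model
  diversity,

      var_ep ≈ E_phi[(phi(x|w) - E_phi[phi(x|w)])^2].

Slide-wide maps reuse the same patch grid and overlap-averaged stitching
machinery as the probability heatmaps.  Since predictions live in [0, 1],
every variance is bounded by 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from wsikit.wsi_core import LevelPoint, PyramidImage, default_mask_level
from wsikit.tissue import MaskParams, TissueMask, compute_tissue_mask, preprocess_black_borders
from wsikit.patches import build_inference_grid
from wsikit.segmentation import Predictor, StitchedHeatmap, stitch_heatmap

__all__ = [
    "TTATransform",
    "TTASet",
    "DEFAULT_TTA",
    "aleatoric_patch",
    "epistemic_patch",
    "run_slide_uncertainty",
]


@dataclass(frozen=True)
class TTATransform:
    """An invertible pixel-grid transform (forward, inverse, name)."""

    name: str
    apply: Callable[[np.ndarray], np.ndarray]
    invert: Callable[[np.ndarray], np.ndarray]

    def check_invertible(self, shape: tuple[int, int] = (8, 8)) -> None:
        probe = np.arange(shape[0] * shape[1], dtype=np.float32).reshape(shape)
        back = self.invert(self.apply(probe))
        if back.shape != probe.shape or not np.array_equal(back, probe):
            raise ValueError(f"transform {self.name!r} has no exact inverse on the pixel grid")


def _rot(k: int) -> TTATransform:
    return TTATransform(
        f"rot{90 * k}",
        lambda a, k=k: np.ascontiguousarray(np.rot90(a, k)),
        lambda a, k=k: np.ascontiguousarray(np.rot90(a, -k)),
    )


#: Identity plus the three right-angle rotations and both flips — every
#: member has an exact pixel-grid inverse.
DEFAULT_TTA: list[TTATransform] = [
    TTATransform("identity", lambda a: a, lambda a: a),
    _rot(1),
    _rot(2),
    _rot(3),
    TTATransform(
        "vflip",
        lambda a: np.ascontiguousarray(a[::-1]),
        lambda a: np.ascontiguousarray(a[::-1]),
    ),
    TTATransform(
        "hflip",
        lambda a: np.ascontiguousarray(a[:, ::-1]),
        lambda a: np.ascontiguousarray(a[:, ::-1]),
    ),
]

TTASet = Sequence[TTATransform]


def aleatoric_patch(
    model: Predictor,
    patch: np.ndarray,
    tta: TTASet = DEFAULT_TTA,
    center: LevelPoint | None = None,
) -> np.ndarray:
    """Per-pixel population variance of inverse-aligned TTA predictions."""
    if len(tta) < 2:
        raise ValueError("need at least 2 test-time augmentations")
    for t in tta:
        t.check_invertible()
    maps = []
    for t in tta:
        pred = model.predict(t.apply(patch), center)
        maps.append(t.invert(np.asarray(pred, dtype=np.float64)))
    stack = np.stack(maps)
    return stack.var(axis=0)  # population variance (ddof=0)


def epistemic_patch(
    models: Sequence[Predictor],
    patch: np.ndarray,
    center: LevelPoint | None = None,
) -> np.ndarray:
    """Per-pixel population variance across ensemble members."""
    if len(models) < 2:
        raise ValueError("epistemic uncertainty needs at least 2 models")
    stack = np.stack(
        [np.asarray(m.predict(patch, center), dtype=np.float64) for m in models]
    )
    return stack.var(axis=0)


def run_slide_uncertainty(
    img: PyramidImage,
    models: Sequence[Predictor],
    kind: str = "epistemic",
    patch_size: int = 1024,
    stride: int = 512,
    tta: TTASet = DEFAULT_TTA,
    mask_level: int | None = None,
    out_level: int | None = None,
    mask_params: MaskParams = MaskParams(),
    black_border_preprocess: bool = False,
    tissue: TissueMask | None = None,
) -> StitchedHeatmap:
    """Slide-wide uncertainty map, stitched like a probability heatmap.

    ``kind`` is ``"aleatoric"`` (TTA variance, averaged across ensemble
    members) or ``"epistemic"`` (cross-member variance).  Overlapping patch
    variances are averaged by the same sum/count stitching as inference.
    """
    if kind not in ("aleatoric", "epistemic"):
        raise ValueError("kind must be 'aleatoric' or 'epistemic'")
    if mask_level is None:
        mask_level = default_mask_level(img)
    if out_level is None:
        out_level = mask_level
    if tissue is None:
        low = img.levels[mask_level]
        if black_border_preprocess:
            low = preprocess_black_borders(low)
        tissue = compute_tissue_mask(low, mask_params, level=mask_level)
    grid = build_inference_grid(
        tissue, patch_size, stride,
        mask_downsample=img.downsample_factors[mask_level],
        slide_dims=(img.width0, img.height0),
    )
    var_maps = []
    for c in grid.centers:
        patch = img.read_region(c, patch_size, level=0)
        if kind == "epistemic":
            var_maps.append(epistemic_patch(models, patch, c))
        else:
            per_member = [aleatoric_patch(m, patch, tta, c) for m in models]
            var_maps.append(np.mean(per_member, axis=0))
    return stitch_heatmap(
        grid, var_maps, (img.width0, img.height0),
        out_downsample=img.downsample_factors[out_level], level=out_level,
    )
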
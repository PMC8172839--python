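"""Tissue-from-glass segmentation at low resolution.

Glass background is near-white and therefore nearly unsaturated, while
stained tissue (eosin pink / hematoxylin purple) is strongly saturated, so
the tissue mask is computed by Otsu thresholding the 8-bit HSV saturation
channel of a low-resolution slide level, followed by binary morphology
(closing then opening) to stabilize small tissue fragments and borders.

Some scanners leave black border regions on the slide; because black is
also unsaturated-*dark*, it can wreck the Otsu split.  The dedicated
pre-cleaning step (:func:`preprocess_black_borders`) replaces near-black
pixels with white and median-blurs with a 7×7 kernel before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, opening, remove_small_holes

__all__ = ["MaskParams", "TissueMask", "compute_tissue_mask", "preprocess_black_borders"]


@dataclass(frozen=True)
class MaskParams:
    """Tissue-mask parameters.

    closing_radius / opening_radius are structuring-disk radii in pixels at
    the mask level; fill_holes_area > 0 additionally fills enclosed holes
    smaller than that many pixels.  degenerate_eps is the minimum
    saturation-histogram range (8-bit counts) below which the raster is
    declared textureless and the mask comes back empty with a warning flag.
    """

    closing_radius: int = 2
    opening_radius: int = 2
    fill_holes_area: int = 0
    degenerate_eps: float = 8.0


@dataclass
class TissueMask:
    """Binary tissue mask computed at a stated pyramid level."""

    grid: np.ndarray
    level: int
    source_shape: tuple[int, int]
    degenerate: bool = False
    otsu_threshold: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.shape != tuple(self.source_shape):
            raise ValueError("mask shape must match the source level raster")

    @property
    def area(self) -> int:
        return int(self.grid.sum())


def saturation_u8(rgb: np.ndarray) -> np.ndarray:
    """8-bit HSV saturation channel of an 8-bit RGB raster."""
    sat = rgb2hsv(rgb)[..., 1]
    return np.round(sat * 255.0).astype(np.uint8)


def compute_tissue_mask(
    low_res_rgb: np.ndarray,
    params: MaskParams = MaskParams(),
    level: int = 0,
) -> TissueMask:
    """Segment tissue from glass on a low-resolution RGB raster.

    Otsu's threshold is computed on the 256-bin histogram of the 8-bit
    saturation channel; pixels strictly above the threshold are tissue.
    Closing (radius ``closing_radius``) then opening (``opening_radius``)
    clean up fragments.  If the saturation histogram is degenerate (range
    below ``degenerate_eps``, e.g. a pure-white raster) the mask is empty
    and ``degenerate`` is set instead of trusting a meaningless threshold.
    """
    rgb = np.asarray(low_res_rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    sat = saturation_u8(rgb)
    if float(sat.max()) - float(sat.min()) < params.degenerate_eps:
        return TissueMask(
            np.zeros(sat.shape, dtype=bool), level, sat.shape, degenerate=True
        )
    thr = threshold_otsu(sat, nbins=256)
    mask = sat > thr
    mask = cleanup_mask(mask, params)
    return TissueMask(mask, level, sat.shape, degenerate=False, otsu_threshold=float(thr))


def cleanup_mask(mask: np.ndarray, params: MaskParams) -> np.ndarray:
    """Morphological cleanup: closing, opening, optional hole filling.

    Idempotent at fixed radii (closing and opening are idempotent
    operators), which a unit test pins down.
    """
    out = mask.astype(bool)
    if params.closing_radius > 0:
        out = closing(out, disk(params.closing_radius))
    if params.opening_radius > 0:
        out = opening(out, disk(params.opening_radius))
    if params.fill_holes_area > 0:
        out = remove_small_holes(out, max_size=params.fill_holes_area)
    return out


def preprocess_black_borders(
    low_res_rgb: np.ndarray,
    black_threshold: int = 10,
    median_kernel: int = 7,
) -> np.ndarray:
    """Pre-clean a raster with black scanner-border artifacts.

    Pixels whose channels are all below ``black_threshold`` are replaced by
    white, then the whole image is median-blurred with a
    ``median_kernel``×``median_kernel`` window per channel.  The median blur
    smooths tissue regions and removes noise at the tissue/glass boundary
    while preserving tissue edges.
    """
    rgb = np.asarray(low_res_rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    out = rgb.copy()
    black = (out < black_threshold).all(axis=2)
    out[black] = 255
    out = median_filter(out, size=(median_kernel, median_kernel, 1))
    return out
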
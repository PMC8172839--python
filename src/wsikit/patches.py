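"""Patch sampling for training and inference.

Training patches are sampled *class-balanced*: an equal number of tumorous
and non-tumorous coordinates, where a patch counts as tumorous iff at least
one pixel of its level-0 footprint lies in the tumor mask.  Tumor regions
occupy a minuscule fraction of a slide, so balanced sampling (plus random
center perturbation between epochs and photometric/geometric augmentation)
is what keeps segmentation training from collapsing onto the background
class.

Inference uses a uniform lattice of patch centers laid out with a given
stride, restricted to tissue-positive positions of the low-resolution
tissue mask; centers are expressed in level-0 pixels.  A stride of half the
patch size (50% linear overlap between neighboring patches) is the default
trade-off between seam suppression and compute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.color import hsv2rgb, rgb2hsv
from scipy.ndimage import gaussian_filter

from wsikit.wsi_core import LevelPoint
from wsikit.tissue import TissueMask

__all__ = [
    "PatchCoordinate",
    "PatchGrid",
    "AugmentationParams",
    "extract_training_coordinates",
    "perturb_coordinate",
    "augment_patch",
    "normalize_patch",
    "build_inference_grid",
    "patch_footprint_is_tumor",
]

# photometric augmentation ceilings (fractional units on a [0, 1] image)
MAX_BRIGHTNESS_DELTA = 64.0 / 255.0
MAX_CONTRAST_DELTA = 0.75
MAX_HUE_DELTA = 0.25
MAX_SATURATION_DELTA = 0.04
DEFAULT_PERTURB_RADIUS = 128


@dataclass(frozen=True)
class PatchCoordinate:
    """A level-0 patch center with an optional training label."""

    center: LevelPoint
    label: str | None = None  # "tumor" | "normal" for training coordinates


@dataclass
class PatchGrid:
    """Ordered level-0 patch centers plus the geometry that produced them."""

    centers: list[LevelPoint]
    patch_size: int
    stride: int
    grid_level: int

    def __len__(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class AugmentationParams:
    """Augmentation switches and photometric deltas.

    Deltas are the half-widths of the uniform distributions the shifts are
    drawn from; they may not exceed the module-level maxima (brightness
    64/255, contrast 0.75, hue 0.25, saturation 0.04, all fractional).
    """

    flips: bool = True
    rot90: bool = True
    gaussian_blur: bool = False
    blur_sigma_max: float = 1.5
    brightness_delta: float = MAX_BRIGHTNESS_DELTA
    contrast_delta: float = MAX_CONTRAST_DELTA
    hue_delta: float = MAX_HUE_DELTA
    saturation_delta: float = MAX_SATURATION_DELTA
    seed: int = 0

    def __post_init__(self) -> None:
        limits = [
            (self.brightness_delta, MAX_BRIGHTNESS_DELTA, "brightness"),
            (self.contrast_delta, MAX_CONTRAST_DELTA, "contrast"),
            (self.hue_delta, MAX_HUE_DELTA, "hue"),
            (self.saturation_delta, MAX_SATURATION_DELTA, "saturation"),
        ]
        for value, ceiling, name in limits:
            if not 0 <= value <= ceiling + 1e-12:
                raise ValueError(f"{name} delta {value} outside [0, {ceiling}]")


# -- training-coordinate extraction ---------------------------------------


def patch_footprint_is_tumor(
    tumor_mask0: np.ndarray, center: LevelPoint, patch_size: int
) -> bool:
    """Brute-force footprint rule: tumorous iff >= 1 tumor pixel inside
    the level-0 patch square."""
    h, w = tumor_mask0.shape
    x0 = max(center.x - patch_size // 2, 0)
    y0 = max(center.y - patch_size // 2, 0)
    x1 = min(center.x - patch_size // 2 + patch_size, w)
    y1 = min(center.y - patch_size // 2 + patch_size, h)
    if x1 <= x0 or y1 <= y0:
        return False
    return bool(tumor_mask0[y0:y1, x0:x1].any())


def extract_training_coordinates(
    tissue: TissueMask,
    tumor_mask0: np.ndarray,
    n_per_class: int,
    patch_size: int = 256,
    seed: int = 0,
    mask_downsample: float = 1.0,
) -> tuple[list[PatchCoordinate], bool]:
    """Sample `n_per_class` tumor and `n_per_class` normal patch centers.

    ``tissue`` is the mask at its stated level, ``tumor_mask0`` the level-0
    tumor ground truth, ``mask_downsample`` the factor mapping mask pixels
    to level-0 pixels.  Eligible tumor centers are found on a tumor mask
    dilated by half the patch size (the footprint rule made efficient);
    every returned label is then verified with the exact footprint test.
    Returns ``(coordinates, short_flag)`` where ``short_flag`` is True when
    a class had fewer eligible centers than requested (with a warning,
    never silent duplication).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if tissue.area == 0:
        raise ValueError("empty tissue mask: no eligible patch centers")
    rng = np.random.default_rng(seed)
    f = mask_downsample

    half_ml = max(1, int(round(patch_size / 2 / f)))
    tumor_ml = _to_mask_level(tumor_mask0, tissue.grid.shape)
    dilated = binary_dilation(tumor_ml, structure=np.ones((3, 3)), iterations=half_ml) if tumor_ml.any() else tumor_ml

    tumor_elig = tissue.grid & dilated
    normal_elig = tissue.grid & ~dilated

    def sample(eligible: np.ndarray, want_tumor: bool) -> list[PatchCoordinate]:
        ys, xs = np.nonzero(eligible)
        if len(xs) == 0:
            return []
        picks: list[PatchCoordinate] = []
        order = rng.permutation(len(xs))
        for idx in order:
            cx = int(round(xs[idx] * f + rng.uniform(0, f)))
            cy = int(round(ys[idx] * f + rng.uniform(0, f)))
            cx = min(max(cx, 0), tumor_mask0.shape[1] - 1)
            cy = min(max(cy, 0), tumor_mask0.shape[0] - 1)
            center = LevelPoint(cx, cy, 0)
            is_tumor = patch_footprint_is_tumor(tumor_mask0, center, patch_size)
            if is_tumor == want_tumor:
                picks.append(
                    PatchCoordinate(center, "tumor" if want_tumor else "normal")
                )
            if len(picks) == n_per_class:
                break
        return picks

    tumor_coords = sample(tumor_elig, True) if tumor_ml.any() else []
    normal_coords = sample(normal_elig, False)
    short = len(tumor_coords) < n_per_class or len(normal_coords) < n_per_class
    if short:
        warnings.warn(
            f"requested {n_per_class} per class, found "
            f"{len(tumor_coords)} tumor / {len(normal_coords)} normal eligible centers",
            stacklevel=2,
        )
    return tumor_coords + normal_coords, short


def _to_mask_level(mask0: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Reduce a level-0 binary mask onto the tissue-mask grid (block any())."""
    if mask0.shape == tuple(target_shape):
        return mask0.astype(bool)
    fy = mask0.shape[0] / target_shape[0]
    fx = mask0.shape[1] / target_shape[1]
    f = int(round((fy + fx) / 2))
    hh, ww = target_shape
    blocks = mask0[: hh * f, : ww * f].astype(bool).reshape(hh, f, ww, f)
    return blocks.any(axis=(1, 3))


def perturb_coordinate(
    c: PatchCoordinate,
    radius: float = DEFAULT_PERTURB_RADIUS,
    seed: int = 0,
    bounds: tuple[int, int] | None = None,
) -> PatchCoordinate:
    """Offset a patch center uniformly within a disk of the given radius.

    Re-sampling the offset every epoch diversifies the patches actually
    extracted for a fixed coordinate set.  The offset is uniform over the
    disk (mean offset length 2r/3), deterministic per seed, and clipped to
    ``bounds`` = (width0, height0) when given.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.uniform())
    phi = rng.uniform(0.0, 2.0 * np.pi)
    x = int(round(c.center.x + r * np.cos(phi)))
    y = int(round(c.center.y + r * np.sin(phi)))
    if bounds is not None:
        x = min(max(x, 0), bounds[0] - 1)
        y = min(max(y, 0), bounds[1] - 1)
    return PatchCoordinate(LevelPoint(x, y, c.center.level), c.label)


# -- augmentation ---------------------------------------------------------


def augment_patch(
    patch: np.ndarray,
    mask: np.ndarray | None,
    params: AugmentationParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply geometric + photometric augmentation to a patch.

    Geometric transforms (flips, right-angle rotations) are applied
    identically to patch and mask; photometric shifts (brightness,
    contrast, hue, saturation, optional Gaussian blur) touch the patch
    only.  With all switches off and zero deltas this is the identity.
    """
    if mask is not None and patch.shape[:2] != mask.shape[:2]:
        raise ValueError("patch and mask spatial dims must match")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    img = patch.astype(np.float32) / 255.0
    out_mask = None if mask is None else np.asarray(mask)

    if params.flips:
        if rng.uniform() < 0.5:
            img = img[:, ::-1]
            out_mask = None if out_mask is None else out_mask[:, ::-1]
        if rng.uniform() < 0.5:
            img = img[::-1]
            out_mask = None if out_mask is None else out_mask[::-1]
    if params.rot90:
        k = int(rng.integers(0, 4))
        if k:
            img = np.rot90(img, k)
            out_mask = None if out_mask is None else np.rot90(out_mask, k)

    if params.brightness_delta > 0:
        img = img + rng.uniform(-params.brightness_delta, params.brightness_delta)
    if params.contrast_delta > 0:
        factor = 1.0 + rng.uniform(-params.contrast_delta, params.contrast_delta)
        img = (img - img.mean()) * factor + img.mean()
    if params.hue_delta > 0 or params.saturation_delta > 0:
        dh = rng.uniform(-params.hue_delta, params.hue_delta) if params.hue_delta > 0 else 0.0
        ds = (
            rng.uniform(-params.saturation_delta, params.saturation_delta)
            if params.saturation_delta > 0
            else 0.0
        )
        img = shift_hue_saturation(np.clip(img, 0, 1), dh, ds)
    if params.gaussian_blur and rng.uniform() < 0.5:
        sigma = rng.uniform(0.0, params.blur_sigma_max)
        if sigma > 0.05:
            img = gaussian_filter(img, sigma=(sigma, sigma, 0))

    img = np.clip(img, 0.0, 1.0)
    out = np.round(img * 255.0).astype(patch.dtype) if patch.dtype == np.uint8 else img
    return np.ascontiguousarray(out), (
        None if out_mask is None else np.ascontiguousarray(out_mask)
    )


def shift_hue_saturation(img01: np.ndarray, dh: float, ds: float) -> np.ndarray:
    """Shift hue (cyclic, fraction of the hue circle) and saturation
    (additive, clipped) of a float RGB image in [0, 1]."""
    hsv = rgb2hsv(img01)
    hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] + ds, 0.0, 1.0)
    return hsv2rgb(hsv)


def normalize_patch(
    patch: np.ndarray, mean: float = 0.5, std: float = 0.25
) -> np.ndarray:
    """Scale an 8-bit patch to [0, 1] and standardize with the bundle's
    normalization constants."""
    img = patch.astype(np.float32) / 255.0 if patch.dtype == np.uint8 else patch.astype(np.float32)
    return (img - mean) / std


# -- inference grid -------------------------------------------------------


def build_inference_grid(
    tissue: TissueMask,
    patch_size: int = 1024,
    stride: int = 512,
    mask_downsample: float = 1.0,
    slide_dims: tuple[int, int] | None = None,
) -> PatchGrid:
    """Lay out the inference patch-center lattice over the tissue mask.

    Candidate centers are spaced ``stride`` level-0 pixels apart starting
    at ``patch_size // 2`` (so the patch union covers the full frame); a
    center survives iff its pixel at the mask level is tissue, which skips
    glass-only patches entirely.  Centers come back row-major in level-0
    coordinates.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride > patch_size:
        raise ValueError("stride must not exceed patch_size (gaps would appear)")
    f = mask_downsample
    mh, mw = tissue.grid.shape
    if slide_dims is None:
        w0, h0 = int(round(mw * f)), int(round(mh * f))
    else:
        w0, h0 = slide_dims
    centers: list[LevelPoint] = []
    xs = _lattice(w0, patch_size, stride)
    ys = _lattice(h0, patch_size, stride)
    if tissue.area == 0:
        warnings.warn("empty tissue mask: empty inference grid", stacklevel=2)
        return PatchGrid([], patch_size, stride, tissue.level)
    for y in ys:
        my = min(int(y / f), mh - 1)
        for x in xs:
            mx = min(int(x / f), mw - 1)
            if tissue.grid[my, mx]:
                centers.append(LevelPoint(int(x), int(y), 0))
    return PatchGrid(centers, patch_size, stride, tissue.level)


def _lattice(extent: int, patch_size: int, stride: int) -> list[int]:
    """1-D center positions: patch/2, patch/2 + stride, … covering [0, extent)."""
    if extent <= patch_size:
        return [extent // 2]
    n = int(np.ceil((extent - patch_size) / stride)) + 1
    return [patch_size // 2 + k * stride for k in range(n)]
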
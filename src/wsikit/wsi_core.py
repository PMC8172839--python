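"""Level-addressable pyramidal image model and coordinate mapping.

A whole-slide image (WSI) is stored as a resolution pyramid: level 0 is the
full-resolution scan (typically 0.25–4 µm/pixel) and each higher level is a
progressively downsampled copy.  :class:`PyramidImage` holds the pyramid
in memory as plain RGB arrays, which keeps the reader format-agnostic: any
source that can produce per-level rasters (a standard multi-page pyramidal
TIFF, or a directory of PNGs with a JSON sidecar) can back it.

Coordinate conventions: 0-based, ``x`` = column, ``y`` = row.  Region reads
are *center*-addressed (patch-grid centers are the natural currency of
patch-based inference); conversion to the top-left corner uses
``floor(center - size/2)``.  Pixels read outside the slide are filled with
white (255), the glass-background value, so padding can never masquerade as
tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

__all__ = [
    "PyramidImage",
    "LevelPoint",
    "read_region",
    "map_point",
    "write_png_pyramid",
    "read_png_pyramid",
    "write_tiff_pyramid",
    "read_tiff_pyramid",
]

GLASS_VALUE = 255


@dataclass(frozen=True)
class LevelPoint:
    """A pixel coordinate attached to a pyramid level."""

    x: int
    y: int
    level: int = 0


@dataclass
class PyramidImage:
    """An in-memory multi-resolution RGB pyramid.

    Parameters
    ----------
    levels:
        Ordered list of ``(H, W, 3)`` uint8 rasters, level 0 first
        (highest resolution).
    downsample_factors:
        Factor mapping level-k pixel units to level-0 pixel units;
        ``downsample_factors[0]`` must be 1 and factors must strictly
        increase.
    mpp0:
        Physical resolution at level 0, microns per pixel.
    """

    levels: list[np.ndarray]
    downsample_factors: list[float]
    mpp0: float = 0.25
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("a pyramid needs at least one level")
        if len(self.levels) != len(self.downsample_factors):
            raise ValueError("one downsample factor per level required")
        if self.downsample_factors[0] != 1:
            raise ValueError("downsample factor at level 0 must be 1")
        if any(b <= a for a, b in zip(self.downsample_factors, self.downsample_factors[1:])):
            raise ValueError("downsample factors must strictly increase with level")
        for k, lvl in enumerate(self.levels):
            if lvl.ndim != 3 or lvl.shape[2] != 3:
                raise ValueError(f"level {k} is not an RGB (H, W, 3) raster")
            expect_w = self.width0 / self.downsample_factors[k]
            expect_h = self.height0 / self.downsample_factors[k]
            if abs(lvl.shape[1] - expect_w) > 1.5 or abs(lvl.shape[0] - expect_h) > 1.5:
                raise ValueError(
                    f"level {k} dims {lvl.shape[1]}x{lvl.shape[0]} inconsistent with "
                    f"factor {self.downsample_factors[k]}"
                )

    # -- geometry ---------------------------------------------------------

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def width0(self) -> int:
        return self.levels[0].shape[1]

    @property
    def height0(self) -> int:
        return self.levels[0].shape[0]

    def dimensions(self, level: int) -> tuple[int, int]:
        """(width, height) of the given level."""
        self._check_level(level)
        h, w = self.levels[level].shape[:2]
        return w, h

    def mpp(self, level: int) -> float:
        """Microns per pixel at `level`."""
        self._check_level(level)
        return self.mpp0 * self.downsample_factors[level]

    def _check_level(self, level: int) -> None:
        if not 0 <= level < self.n_levels:
            raise ValueError(
                f"invalid level {level}; available levels: {list(range(self.n_levels))}"
            )

    # -- convenience method forms -----------------------------------------

    def read_region(self, center: LevelPoint, size: int, level: int = 0) -> np.ndarray:
        return read_region(self, center, size, level)

    def map_point(self, p: LevelPoint, to_level: int) -> LevelPoint:
        return map_point(self, p, to_level)


def map_point(img: PyramidImage, p: LevelPoint, to_level: int) -> LevelPoint:
    """Map a point between pyramid levels.

    Coordinates are scaled by the ratio of downsample factors and rounded to
    the nearest integer, so a level-0 → level-k → level-0 round trip errs by
    at most ``downsample_factor[k] / 2`` pixels per axis.
    """
    img._check_level(p.level)
    img._check_level(to_level)
    ratio = img.downsample_factors[p.level] / img.downsample_factors[to_level]
    return LevelPoint(int(round(p.x * ratio)), int(round(p.y * ratio)), to_level)


def read_region(img: PyramidImage, center: LevelPoint, size: int, level: int = 0) -> np.ndarray:
    """Read a ``size``×``size`` RGB crop at `level`, centered at `center`.

    `center` is given at level 0 and mapped down; out-of-slide pixels are
    filled with white (glass).
    """
    if size <= 0:
        raise ValueError("size must be positive")
    img._check_level(level)
    if center.level != 0:
        center = map_point(img, center, 0)
    c = map_point(img, center, level)
    raster = img.levels[level]
    h, w = raster.shape[:2]
    x0 = c.x - size // 2
    y0 = c.y - size // 2
    out = np.full((size, size, 3), GLASS_VALUE, dtype=raster.dtype)
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x0 + size, w), min(y0 + size, h)
    if sx1 > sx0 and sy1 > sy0:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = raster[sy0:sy1, sx0:sx1]
    return out


# -- persistence: directory-of-PNG pyramid --------------------------------


def write_png_pyramid(img: PyramidImage, path: str | Path) -> Path:
    """Write the pyramid as ``level_0.png … level_k.png`` + ``pyramid.json``."""
    from PIL import Image

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for k, lvl in enumerate(img.levels):
        Image.fromarray(lvl).save(path / f"level_{k}.png")
    sidecar = {
        "downsample_factors": list(map(float, img.downsample_factors)),
        "mpp0": float(img.mpp0),
        "metadata": img.metadata,
    }
    (path / "pyramid.json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_png_pyramid(path: str | Path) -> PyramidImage:
    from PIL import Image

    path = Path(path)
    sidecar = json.loads((path / "pyramid.json").read_text())
    factors = sidecar["downsample_factors"]
    levels = [
        np.asarray(Image.open(path / f"level_{k}.png").convert("RGB"))
        for k in range(len(factors))
    ]
    return PyramidImage(levels, factors, sidecar["mpp0"], sidecar.get("metadata", {}))


# -- persistence: multi-page pyramidal TIFF -------------------------------


def write_tiff_pyramid(img: PyramidImage, path: str | Path) -> Path:
    """Write a standard multi-page TIFF, one page per level (page 0 = level 0)."""
    import tifffile

    path = Path(path)
    meta = {
        "downsample_factors": list(map(float, img.downsample_factors)),
        "mpp0": float(img.mpp0),
    }
    with tifffile.TiffWriter(path) as tw:
        for k, lvl in enumerate(img.levels):
            tw.write(lvl, description=json.dumps(meta) if k == 0 else None)
    return path


def read_tiff_pyramid(path: str | Path, mpp0: float | None = None) -> PyramidImage:
    """Read a multi-page TIFF pyramid.

    Downsample factors and mpp0 are taken from the level-0 page description
    when present (as written by :func:`write_tiff_pyramid`); otherwise the
    factors are inferred from page dimensions and `mpp0` must be supplied.
    """
    import tifffile

    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
        desc = tf.pages[0].description
    levels = [np.atleast_3d(p) for p in pages]
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if "downsample_factors" in meta:
        factors = meta["downsample_factors"]
    else:
        w0 = levels[0].shape[1]
        factors = [w0 / lvl.shape[1] for lvl in levels]
        factors[0] = 1.0
    resolved_mpp = meta.get("mpp0", mpp0)
    if resolved_mpp is None:
        raise ValueError("mpp0 not stored in TIFF; pass mpp0 explicitly")
    return PyramidImage(levels, factors, float(resolved_mpp))


def mask_to_level(mask: np.ndarray, factor: float) -> np.ndarray:
    """Downsample a level-0 binary mask by `factor` (block mean > 0.5)."""
    if factor == 1:
        return mask.astype(bool)
    f = int(round(factor))
    h, w = mask.shape
    hh, ww = h // f, w // f
    blocks = mask[: hh * f, : ww * f].astype(np.float32).reshape(hh, f, ww, f)
    return blocks.mean(axis=(1, 3)) > 0.5


def default_mask_level(img: PyramidImage, target_long_side: int = 2000) -> int:
    """Pick the level whose longer side is nearest `target_long_side` px.

    Tissue masking only needs an approximate boundary, so it runs on a
    low-resolution copy; ~2 000 px on the long side balances border fidelity
    against cost.
    """
    best, best_d = 0, float("inf")
    for k in range(img.n_levels):
        w, h = img.dimensions(k)
        d = abs(max(w, h) - target_long_side)
        if d < best_d:
            best, best_d = k, d
    return best
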
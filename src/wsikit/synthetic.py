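"""Deterministic generator of H&E-like pyramidal slides with ground truth.

Real histology slides are gigapixel scans: glass background (near-white),
eosin-pink stroma and hematoxylin-purple nuclei-dense regions.  This module
emulates those gross properties at desk scale — white background, saturated
elliptical tissue blobs with texture noise, darker "tumor" ellipses strictly
inside tissue, an optional black scanner-border artifact — and emits the
ground-truth tissue / tumor / whole-tumor masks alongside, so segmentation,
staging and burden estimation are all testable end to end without any slide
download.

All randomness flows from the single ``seed`` through one named
``numpy.random.Generator``; identical spec + seed gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from skimage.color import hsv2rgb
from skimage.morphology import convex_hull_image

from wsikit.wsi_core import PyramidImage, mask_to_level

__all__ = [
    "SyntheticSlideSpec",
    "SyntheticSlide",
    "generate_slide",
    "generate_patient",
    "METASTASIS_SIZE_BANDS_MM",
]

#: Inner sampling bands (mm, major axis) used when planting a labeled lesion.
#: They sit strictly inside the clinical size criteria (ITC ≤ 0.2 mm,
#: micro ≤ 2 mm, macro > 2 mm) so rasterization cannot push a lesion
#: across a band edge.
METASTASIS_SIZE_BANDS_MM: dict[str, tuple[float, float]] = {
    "itc": (0.08, 0.18),
    "micro": (0.6, 1.6),
    "macro": (2.3, 2.9),
}

PYRAMID_STEP = 4  # downsample factor between consecutive levels


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Parameters of one synthetic slide.

    ``tumor_size_range`` is the major-axis length of each tumor ellipse in
    level-0 pixels (min, max); ``tumor_circularity`` is the minor/major
    aspect range (set to ``(1.0, 1.0)`` for circular lesions).
    ``stain_jitter`` in [0, 1] scales per-blob hue/saturation variation.
    """

    width0: int = 2048
    height0: int = 2048
    n_tissue_blobs: int = 2
    n_tumor_regions: int = 1
    tumor_size_range: tuple[float, float] = (150.0, 400.0)
    tumor_circularity: tuple[float, float] = (0.7, 0.95)
    mpp0: float = 4.0
    n_levels: int = 3
    add_black_border: bool = False
    stain_jitter: float = 0.5
    blob_axis_frac_range: tuple[float, float] = (0.18, 0.28)
    blob_aspect_range: tuple[float, float] = (0.55, 0.9)
    seed: int = 0


@dataclass
class SyntheticSlide:
    """A generated slide plus its ground truth (masks at level 0)."""

    image: PyramidImage
    tissue_mask: np.ndarray
    tumor_mask: np.ndarray
    whole_tumor_mask: np.ndarray
    spec: SyntheticSlideSpec

    def tissue_mask_at(self, level: int) -> np.ndarray:
        return mask_to_level(self.tissue_mask, self.image.downsample_factors[level])

    def tumor_mask_at(self, level: int) -> np.ndarray:
        return mask_to_level(self.tumor_mask, self.image.downsample_factors[level])

    @property
    def ground_truth_burden(self) -> float:
        whole = self.whole_tumor_mask.sum()
        return float(self.tumor_mask.sum() / whole) if whole else 0.0


def _ellipse_mask(h: int, w: int, cx: float, cy: float, a: float, b: float, theta: float) -> np.ndarray:
    """Boolean raster of a rotated ellipse (semi-axes a >= b, angle theta)."""
    yy, xx = np.mgrid[0:h, 0:w]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _hsv_color(rng: np.random.Generator, h: float, s: float, v: float,
               jitter: float) -> np.ndarray:
    hsv = np.array([
        (h + jitter * rng.uniform(-0.05, 0.05)) % 1.0,
        np.clip(s + jitter * rng.uniform(-0.08, 0.08), 0.25, 1.0),
        np.clip(v + jitter * rng.uniform(-0.05, 0.05), 0.05, 0.95),
    ])
    return hsv2rgb(hsv[None, None, :])[0, 0] * 255.0


def generate_slide(spec: SyntheticSlideSpec,
                   tumor_sizes_px: Sequence[float] | None = None) -> SyntheticSlide:
    """Generate one synthetic H&E-like pyramidal slide.

    Parameters
    ----------
    spec:
        Slide parameters; ``width0``/``height0`` must be >= 256.
    tumor_sizes_px:
        Optional explicit major-axis lengths (level-0 px), one per tumor
        region, overriding ``spec.tumor_size_range``.  Used by
        :func:`generate_patient` to plant lesions in clinical size bands.

    Raises
    ------
    ValueError
        If a requested tumor cannot fit strictly inside any tissue blob.
    """
    if spec.width0 < 256 or spec.height0 < 256:
        raise ValueError("slide dimensions must be >= 256")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height0, spec.width0

    canvas = np.clip(rng.normal(250.0, 2.0, size=(h, w, 3)), 244, 255)

    # tissue blobs
    blobs: list[tuple[np.ndarray, float, float, float]] = []  # mask, cx, cy, bmin
    tissue = np.zeros((h, w), dtype=bool)
    lo, hi = spec.blob_axis_frac_range
    for _ in range(spec.n_tissue_blobs):
        a = rng.uniform(lo, hi) * min(w, h)
        b = rng.uniform(*spec.blob_aspect_range) * a
        margin = a + 0.04 * min(w, h)
        cx = rng.uniform(margin, w - margin) if w > 2 * margin else w / 2
        cy = rng.uniform(margin, h - margin) if h > 2 * margin else h / 2
        theta = rng.uniform(0, np.pi)
        mask = _ellipse_mask(h, w, cx, cy, a, b, theta)
        color = _hsv_color(rng, 0.87, 0.38, 0.82, spec.stain_jitter)
        canvas[mask] = color
        blobs.append((mask, cx, cy, b))
        tissue |= mask

    # tumor regions, each strictly inside a blob (contained in the blob's
    # inscribed disk of radius b_min)
    tumor = np.zeros((h, w), dtype=bool)
    n_tumors = len(tumor_sizes_px) if tumor_sizes_px is not None else spec.n_tumor_regions
    for k in range(n_tumors):
        if tumor_sizes_px is not None:
            major = float(tumor_sizes_px[k])
        else:
            major = rng.uniform(*spec.tumor_size_range)
        a_t = major / 2.0
        host = None
        for mask, cx, cy, bmin in sorted(blobs, key=lambda bl: -bl[3]):
            if a_t * 1.1 + 2 < bmin:
                host = (cx, cy, bmin)
                break
        if host is None:
            raise ValueError(
                f"tumor major axis {major:.0f}px exceeds every tissue blob "
                f"(largest inscribed radius {max(bl[3] for bl in blobs):.0f}px)"
            )
        cx_b, cy_b, bmin = host
        ratio = rng.uniform(*spec.tumor_circularity)
        off_max = max(0.0, bmin - a_t * 1.1 - 2)
        r_off = off_max * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        cx_t = cx_b + r_off * np.cos(phi)
        cy_t = cy_b + r_off * np.sin(phi)
        theta_t = rng.uniform(0, np.pi)
        t_mask = _ellipse_mask(h, w, cx_t, cy_t, a_t, ratio * a_t, theta_t)
        color = _hsv_color(rng, 0.78, 0.60, 0.45, spec.stain_jitter)
        canvas[t_mask] = color
        tumor |= t_mask
    tumor &= tissue  # containment by construction; enforce the invariant exactly

    # texture noise (stronger on tissue, mild on glass)
    noise = rng.normal(0.0, 2.0, size=(h, w, 1))
    noise[tissue] = rng.normal(0.0, 6.0, size=(int(tissue.sum()), 1))
    canvas = canvas + noise

    if spec.add_black_border:
        band = max(8, int(0.03 * w))
        canvas[:, :band] = rng.uniform(0, 8, size=(h, band, 3))

    level0 = np.clip(canvas, 0, 255).astype(np.uint8)

    levels = [level0]
    factors = [1.0]
    for k in range(1, spec.n_levels):
        prev = levels[-1].astype(np.float32)
        hh, ww = prev.shape[0] // PYRAMID_STEP, prev.shape[1] // PYRAMID_STEP
        blocks = prev[: hh * PYRAMID_STEP, : ww * PYRAMID_STEP].reshape(
            hh, PYRAMID_STEP, ww, PYRAMID_STEP, 3
        )
        levels.append(np.clip(blocks.mean(axis=(1, 3)), 0, 255).astype(np.uint8))
        factors.append(float(PYRAMID_STEP ** k))

    whole = convex_hull_image(tumor) & tissue if tumor.any() else np.zeros_like(tumor)

    image = PyramidImage(levels, factors, spec.mpp0, metadata={"synthetic": True})
    return SyntheticSlide(image, tissue, tumor, whole, spec)


def generate_patient(
    n_slides: int,
    label_plan: Sequence[str],
    seed: int = 0,
    base_spec: SyntheticSlideSpec | None = None,
) -> list[tuple[SyntheticSlide, str]]:
    """Generate a patient's lymph-node slides with planted metastasis labels.

    Each slide carries at most one lesion whose physical major-axis length
    (via ``mpp0``) is sampled inside the clinical size band for its label:
    ITC ≤ 0.2 mm, micro-metastasis in (0.2, 2] mm, macro-metastasis > 2 mm;
    ``negative`` slides carry no lesion.  The bands used for sampling
    (:data:`METASTASIS_SIZE_BANDS_MM`) keep a safety margin from the band
    edges so the rule-based classifier recovers the plan exactly.
    """
    if len(label_plan) != n_slides:
        raise ValueError("label_plan length must equal n_slides")
    valid = {"negative", "itc", "micro", "macro"}
    plan = [str(lab).lower() for lab in label_plan]
    if not set(plan) <= valid:
        raise ValueError(f"labels must be drawn from {sorted(valid)}")

    base = base_spec or SyntheticSlideSpec()
    rng = np.random.default_rng(seed)
    out: list[tuple[SyntheticSlide, str]] = []
    for i, label in enumerate(plan):
        slide_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(base, seed=slide_seed)
        if label == "negative":
            slide = generate_slide(spec, tumor_sizes_px=[])
        else:
            lo_mm, hi_mm = METASTASIS_SIZE_BANDS_MM[label]
            min_dim = min(base.width0, base.height0)
            # largest lesion any blob can host (frac <= 0.32, aspect >= 0.92)
            max_major_px = max(0.0, (0.32 * 0.92 * min_dim - 4.0) / 1.1 * 2.0)
            lo_px = lo_mm * 1000.0 / base.mpp0
            hi_px = min(hi_mm * 1000.0 / base.mpp0, max_major_px)
            if hi_px < lo_px:
                raise ValueError(
                    f"a {label} lesion (>= {lo_mm} mm = {lo_px:.0f}px at "
                    f"mpp0={base.mpp0}) cannot fit on a {base.width0}x{base.height0} "
                    f"slide; enlarge the slide or increase mpp0"
                )
            major_px = rng.uniform(lo_px, hi_px)
            # size the host blob to the lesion
            req_b = major_px / 2.0 * 1.1 + 4.0
            frac_lo = req_b / (0.92 * min_dim)
            frac_hi = min(max(frac_lo + 0.01, spec.blob_axis_frac_range[1]), 0.32)
            spec = replace(
                spec,
                blob_axis_frac_range=(max(frac_lo, spec.blob_axis_frac_range[0]), frac_hi),
                blob_aspect_range=(0.92, 0.96),
            )
            slide = generate_slide(spec, tumor_sizes_px=[major_px])
        out.append((slide, label))
    return out
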
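"""Shared fixtures: small synthetic slides generated once per session."""

import numpy as np
import pytest

from wsikit.synthetic import SyntheticSlideSpec, generate_slide
from wsikit.tissue import compute_tissue_mask


SMALL_SPEC = SyntheticSlideSpec(
    width0=768,
    height0=768,
    n_tissue_blobs=2,
    n_tumor_regions=1,
    tumor_size_range=(120.0, 200.0),
    seed=7,
)


@pytest.fixture(scope="session")
def small_slide():
    """A 768x768 slide with one planted tumor (3 pyramid levels)."""
    return generate_slide(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_tissue_l1(small_slide):
    """Tissue mask of the small slide computed at level 1 (factor 4)."""
    return compute_tissue_mask(small_slide.image.levels[1], level=1)


@pytest.fixture(scope="session")
def small_tissue_l0(small_slide):
    return compute_tissue_mask(small_slide.image.levels[0], level=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
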
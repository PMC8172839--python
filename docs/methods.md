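# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of `wsikit`, in the spirit of a package-level methods
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Slide model and coordinates

A slide is an in-memory RGB pyramid (`PyramidImage`): level 0 is full
resolution, each level carries a downsample factor (strictly increasing,
factor 1 at level 0) and `mpp0` gives microns per pixel at level 0.
Coordinates are 0-based with `x` = column and `y` = row.  Region reads are
*center*-addressed, because patch grids are defined by their centers; the
top-left corner is `floor(center − size/2)`.  Pixels read outside the
slide are filled with white (255,255,255) — the glass value — so padding
can never be mistaken for tissue by the saturation-based mask.  Point
mapping between levels multiplies by the factor ratio and rounds to
nearest, so a level-0 → level-k → level-0 round trip errs by at most
`factor_k / 2` pixels per axis.

Persistence is deliberately format-light: a standard multi-page TIFF
(one page per level, factors in the page description) or a directory of
PNGs with a JSON sidecar.  Vendor WSI containers (MRXS, NDPI) and JPEG2000
codecs are out of scope; any reader that yields per-level rasters can back
the type.

## Synthetic slides

The generator emulates the gross photometric structure of an H&E slide,
not its microanatomy: near-white background (RGB ≈ 244–255), elliptical
tissue blobs colored near the H&E pink/purple hue (HSV hue ≈ 0.87,
saturation ≥ 0.25 so Otsu separates cleanly), darker nuclei-dense "tumor"
ellipses strictly inside tissue (hue ≈ 0.78, value ≈ 0.45), Gaussian
texture noise (σ = 6 on tissue, 2 on glass), an optional near-black border
band emulating the scanner artifact, and a ≥ 3-level pyramid built by
factor-4 block means.  All randomness flows from one seed through a single
named `numpy.random.Generator`; identical spec + seed is bit-identical.

Scale: the default slide is 2048² at `mpp0 = 4 µm/px` (8.2 mm of tissue),
chosen so that all clinical lesion-size bands — ITC ≤ 0.2 mm, micro ≤ 2 mm,
macro > 2 mm — fit inside a host tissue blob at desk scale.  When a patient
is generated with a label plan, each lesion's major axis is drawn from an
*inner* band (0.08–0.18, 0.6–1.6, 2.3–2.9 mm) so rasterization cannot push
it across a clinical boundary, and the host blob is sized to the lesion
(the lesion is kept inside the blob's inscribed disk with a 10 % margin).
A lesion whose band floor cannot fit on the requested slide raises rather
than silently shrinking.

What passing tests on these slides show — and do not show: they validate
the *pipeline contracts* (geometry, balancing, stitching, typing rules,
burden arithmetic) and that the training loop can learn a color/texture
separable segmentation.  They do not demonstrate performance on real
H&E tissue, which has stain variability, nuclear texture, ambiguous
boundaries and artifacts (pen marks, folds) that the generator does not
model.

## Tissue masking

Otsu's threshold is computed on the 256-bin histogram of the 8-bit HSV
saturation channel; pixels strictly above threshold are tissue.  The
morphology defaults are closing then opening with radius-2 disks (the
operations' idempotence is a pinned test); hole filling is off by default.
A saturation histogram with range < 8 grey levels (e.g. a pure-white
raster) is declared degenerate: empty mask plus a flag, rather than a
meaningless threshold.  The black-border pre-cleaning replaces pixels with
all channels < 10 by white, then applies a 7×7 per-channel median blur.
The default mask level is the pyramid level whose longer side is nearest
2 000 px — coarse enough to be cheap, fine enough for patch eligibility.
Kernel radii, the black threshold and the level are all configurable since
reasonable alternatives exist.

## Patch sampling

A training coordinate is *tumorous* iff its level-0 patch footprint
contains at least one tumor pixel.  Eligible tumor centers are found on
the tumor mask dilated by half the patch size (evaluated at mask level),
which makes the footprint rule efficient; every returned label is then
re-verified with the exact footprint test, and a unit test checks the
dilation shortcut against brute force.  If a class lacks eligible centers
the function returns fewer with a warning — never silent duplication.
Center perturbation is uniform over the disk (radius 128 px by default;
mean offset length 2r/3, pinned statistically at 10 000 draws).

Photometric deltas are interpreted as fractional units on a [0, 1] image:
brightness additive ± 64/255, contrast multiplicative 1 ± 0.75 about the
patch mean, hue additive ± 0.25 (cyclic), saturation additive ± 0.04.
Gaussian-blur σ is drawn from [0, 1.5] when enabled.  Augmentation is the
identity when all switches are off; normalization (scale to [0, 1], then
standardize with constants stored in the model bundle, default mean 0.5 /
std 0.25) is a separate step applied inside the predictor.

The inference grid starts at `patch_size/2` and steps by the stride, so
the patch union covers the full frame; a center survives iff its
mask-level pixel is tissue.  Defaults: training patches 256 px; inference
patches 1024 px with stride 512 (50 % linear overlap), the balance point
between seam suppression and compute.

## Losses and training

Dice loss uses squared-norm denominators with ε = 1e−6 in numerator and
denominator; cross-entropy clips predictions to [1e−7, 1 − 1e−7] and is
implemented *negated with a mean-over-pixels reduction* so that it is
non-negative and minimization is well-posed; the hybrid weights default to
(0.5, 0.25, 0.25).  The analytic gradient of the hybrid loss is verified
against central differences to ~1e−10.

The shipped trainable predictor (`MiniFCN`) is a small numpy
encoder–decoder: conv3×3(3→c)–ReLU–meanpool2–conv3×3(c→2c)–ReLU on the
encoder side, nearest-upsample2–conv3×3(2c→c)–ReLU–conv1×1(c→1)–sigmoid on
the decoder side (c = 8 by default), trained by manual backpropagation
with ADAM.  The training contract mirrors standard transfer-learning
practice: when a model declares a pretrained encoder, encoder parameters
are frozen for the first two epochs; the learning rate decays stepwise
(default ×0.5 every 4 epochs; the mini-FCN uses a larger initial rate,
3e−3, than a pretrained backbone would); training stops on the first
validation-loss increase (patience 1 by default) and the best-validation
weights are restored.  Training is deterministic per seed.  Ensemble
members train on distinct folds of the training data and their posteriors
are averaged pixel-wise at inference.

Problem sizes: training checks use 200 patches of 256² pixels drawn
balanced from two synthetic slides (160 train / 40 held out), where the
mini-FCN converges within 2–3 epochs; unit-level training tests use 64²
patches.

## Stitching

Patch posteriors are accumulated into level-0 sum and coverage-count
grids; the heatmap is sum/count wherever covered and 0 elsewhere, so every
pixel is exactly the mean of all patch predictions covering it (no seams;
linear in the patch maps; order-invariant).  Accumulation is
double-precision so the result agrees with a brute-force per-pixel mean to
1e−12.  For output at a coarser level, sum and count are block-reduced
separately and divided at the reduced scale — a coverage-weighted block
mean that avoids diluting edge blocks with uncovered zeros.

## Uncertainty

Both uncertainty kinds are *population* variances (ddof = 0), matching
their definition as expectations over a finite transform/member set.  The
TTA set is identity + the three right-angle rotations + both axis flips —
each with an exact pixel-grid inverse, checked at call time.  Aleatoric
maps are computed per model and averaged across ensemble members by
default (a flagged alternative emits per-member maps); epistemic variance
is taken across members on the raw patch.  Since predictions live in
[0, 1], any variance is ≤ 0.25.  Slide-wide maps reuse the inference grid
and stitching.

## Staging

The 32-feature schema is fixed: largest region's major axis at p = 0.9 and
p = 0.5; largest region's area at p = 0.5; tumor/tissue pixel ratio and
non-zero count at p = 0.9; {maximum, mean, variance, skewness, kurtosis}
of {area, perimeter, eccentricity, extent, solidity} over the p = 0.9
regions (25); mean of regions' mean confidence and region count at
p = 0.9.  Components are 8-connected; lengths stay in pixels with
`mpp_at_level` carried alongside for mm conversion (major axis × mpp /
1000).  No regions → zero vector; fewer than two regions → variance /
skewness / kurtosis are 0 (biased moment estimators are used when ≥ 2).

SMOTE oversamples each minority class to parity by interpolating between
a sample and one of its k ≤ 5 same-class nearest neighbors; Tomek links
(mutual nearest neighbors of opposite class) are then removed — both
endpoints, which cleans the boundary symmetrically.  A minority class of
size 1 is rejected by name, since interpolation needs a neighbor.

The Random-Forest ensemble defaults to 4 members spanning 2 seeded 80 %
data subsets × 2 balancing variants (raw vs SMOTE+Tomek); prediction is
majority vote with ties resolved toward the higher metastasis category —
the clinically conservative choice.  pN staging: ITC-only nodes do not
count toward the pN1/pN2 metastatic-node tally (otherwise pN0(i+) could
not exist); patients with more than 9 metastatic nodes clamp to pN2,
unreachable with the usual 5 nodes per patient.  Stage monotonicity under
label upgrades is a property test.

## Tumor burden

Post-processing binarizes at 0.5, removes objects smaller than 0.05 % of
the tissue area and fills holes smaller than 0.01 % (both sizes
configurable; the fractions are defaults where no principled size exists).
The whole tumor is one global convex hull over all viable pixels — the
modeled tissue carries a single whole-tumor region — intersected with the
tissue mask; per-component hulls would under-span multifocal nests.
Burden is the viable/whole pixel ratio, 0 when the whole region is empty,
and is invariant to the working level within ~2 % discretization (a pinned
test), so it is computed at the heatmap's own level.

## Known limitations

* The mini-FCN is a deliberately small CPU model for validating the
  training/inference contracts; it is not a stand-in for a modern
  pretrained segmentation backbone, and no claim about real-slide Dice
  follows from its synthetic-slide performance.
* The tissue mask assumes stained-vs-glass saturation contrast; pen marks,
  folds and coverslip artifacts are not modeled or handled.
* Cell counts for the ITC rule are accepted as optional input, never
  estimated from pixels.
* The whole-tumor convex-hull approximation under-estimates concave whole
  tumors; refinement (e.g. active contours seeded by the hull) is out of
  scope.
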
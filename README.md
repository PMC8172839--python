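# wsikit

Patch-based segmentation and analysis of whole-slide histopathology images
(WSI): tissue masking, balanced patch sampling, hybrid-loss segmentation
training, ensemble inference with overlap-averaged heatmap stitching,
patch-based uncertainty maps, lymph-node metastasis typing / pN staging,
and viable-tumor-burden estimation.

## Who this is for

WSIs are gigapixel scans (a 20 mm × 15 mm slide at 0.25 µm/pixel is
80 000 × 60 000 pixels), so tumor segmentation has to proceed
divide-and-conquer: detect tissue at low resolution, extract
high-resolution patches on a sampling grid, predict per patch, and stitch
the posteriors back into a slide-wide probability heatmap that downstream
clinical analyses consume.  `wsikit` implements that pipeline as a tested,
desk-scale library and CLI.  Its deterministic synthetic-slide generator
emulates H&E-stained slides (white glass, saturated pink/purple tissue
blobs, darker tumor nests, optional black scanner borders) with exact
ground-truth masks, so every stage — and your own predictors behind the
`Predictor` contract — can be validated end to end without any slide
download.

## The method

**Tissue masking.** Glass is near-white (unsaturated); stained tissue is
strongly saturated.  The mask is Otsu's threshold on the 8-bit HSV
saturation channel of a low-resolution pyramid level, followed by binary
closing/opening.  Slides with black scanner borders are pre-cleaned by
replacing near-black pixels with white and median-blurring (7×7) before
thresholding.

**Balanced patch sampling.** Tumor pixels are a minuscule slide fraction.
Training draws an equal number of tumorous and non-tumorous patch centers
(a patch is tumorous iff ≥ 1 tumor pixel lies in its level-0 footprint),
re-perturbs each center uniformly within a 128 px radius every epoch, and
augments with flips, right-angle rotations, Gaussian blur and
brightness/contrast/hue/saturation shifts (max deltas 64/255, 0.75, 0.25,
0.04).

**Hybrid loss.** With `p_i` the predicted posterior and `g_i` the binary
ground truth over `N` pixels,

```
DL(p, g) = 1 − 2 Σ p_i g_i / (Σ p_i² + Σ g_i² + ε)
CL(p, g) = −(1/N) Σ [ g_i log p_i + (1 − g_i) log(1 − p_i) ]
Loss     = α·CL + β·DL(1−p, 1−g) + γ·DL(p, g),   (α, β, γ) = (0.5, 0.25, 0.25)
```

so cross-entropy and the foreground/background dice terms carry equal
weight, which keeps training from collapsing onto the background class.

**Ensemble inference and stitching.** Member predictors are trained on
distinct data folds; the slide heatmap averages their posteriors, predicted
on an overlapping patch grid (default 1024 px patches, stride 512 = 50 %
overlap) and stitched by per-pixel sum/coverage-count division — every
heatmap pixel is exactly the mean of all patch predictions covering it,
which removes blockish seam artifacts.

**Uncertainty.** Aleatoric uncertainty is the per-pixel population variance
of one model's predictions across invertible test-time augmentations
(identity, right-angle rotations, flips), aligned through the inverse
transforms; epistemic uncertainty is the population variance across
ensemble members.

**pN staging.** Heatmaps are binarized at p = 0.5 and 0.9; 32 geometric and
morphological features of the connected regions feed a majority-vote
Random-Forest ensemble (ties resolve to the higher category); per-node
labels (negative < ITC < micro < macro, by lesion major-axis length:
≤ 0.2 mm / ≤ 2 mm / > 2 mm) aggregate to the patient pN stage
(pN0, pN0(i+), pN1mi, pN1, pN2).  SMOTE oversampling + Tomek-link removal
balance the training classes.

**Tumor burden.** The viable-tumor prediction is cleaned morphologically;
the whole tumor is approximated as the convex hull of the viable region
intersected with the tissue mask; burden = area(viable) / area(whole).

## Worked example

Generate a three-node patient with planted lesions (macro, micro,
negative), type each node from its stitched heatmap, stage the patient,
and estimate the first node's tumor burden:

```bash
cat > cfg.json <<'EOF'
{
  "seed": 11,
  "synth": {"width0": 1024, "height0": 1024, "mpp0": 8.0},
  "patches": {"inference_patch_size": 256, "stride": 128}
}
EOF
wsikit synth --config cfg.json --labels macro,micro,negative --out patient
wsikit stage --config cfg.json --patient-dir patient \
       --models oracle:@SLIDE/tumor_mask.png --out stages.csv
wsikit infer --config cfg.json --slide patient/slide_0 \
       --models oracle:patient/slide_0/tumor_mask.png --out heat.tiff
wsikit burden --config cfg.json --heatmap heat.tiff \
       --tissue-mask patient/slide_0/tissue_mask.png --out burden.json
```

`stages.csv` shows each node's recovered metastasis type and the patient
stage — one macro-metastasis among ≤ 3 metastatic nodes is pN1:

```
slide_id,predicted_label
slide_0,macro
slide_1,micro
slide_2,negative
patient,pN1
```

`burden.json` reports the viable/whole areas and their ratio; the planted
lesion is a single convex nest, so the whole-tumor hull adds only a thin
boundary and the burden is near 1:

```
{
  "burden": 0.9958432538377554,
  "viable_area_px": 75705,
  "whole_area_px": 76021,
  ...
}
```

The `oracle:` predictor returns the ground-truth mask crop at each patch
location; swap in a trained bundle directory (`wsikit train …`) or any
object with a `predict(patch, center)` method to run a real model through
the identical machinery.

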
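"""Lymph-node metastasis typing and patient pN staging from tumor heatmaps.

Pipeline: each slide's probability heatmap is binarized at p = 0.5 and
p = 0.9; connected components (8-connectivity) of the thresholded maps are
measured with region properties, composing a fixed 32-feature vector per
slide.  A small ensemble of Random Forest classifiers (trained on distinct
data subsets × balancing variants, majority vote with ties broken toward
the higher category) predicts the slide's metastasis type; the patient's
pN stage is then derived from the per-node labels.

Clinical size bands (lesion major-axis length):

    negative   no lesion
    ITC        <= 0.2 mm, or fewer than 200 cells
    micro      >  0.2 mm but <= 2 mm
    macro      >  2 mm

pN stage from the per-node labels:

    pN0       no metastases of any kind
    pN0(i+)   only ITCs
    pN1mi     micro-metastases present, no macro
    pN1       >= 1 macro, metastases (micro/macro) in 1-3 nodes
    pN2       >= 1 macro, metastases (micro/macro) in 4-9 nodes

ITC-only nodes do not count toward the pN1/pN2 node tally (otherwise the
pN0(i+) category could not exist).  Class imbalance in the training set is
handled with SMOTE oversampling followed by Tomek-link removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from skimage.measure import label as cc_label, regionprops
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

from wsikit.segmentation import StitchedHeatmap
from wsikit.tissue import TissueMask

__all__ = [
    "LABEL_ORDER",
    "PN_STAGES",
    "FEATURE_NAMES",
    "extract_slide_features",
    "balance_training_set",
    "smote_oversample",
    "tomek_links",
    "RandomForestEnsemble",
    "train_rf_ensemble",
    "classify_metastasis",
    "metastasis_type_from_size",
    "assign_pn_stage",
    "classify_slide_rule_based",
]

#: Ordinal metastasis categories, lowest to highest.
LABEL_ORDER: list[str] = ["negative", "itc", "micro", "macro"]
PN_STAGES: list[str] = ["pN0", "pN0(i+)", "pN1mi", "pN1", "pN2"]

ITC_MAX_MM = 0.2
MICRO_MAX_MM = 2.0
ITC_MAX_CELLS = 200

_REGION_STATS = ["max", "mean", "var", "skew", "kurt"]
_REGION_PROPS = ["area", "perimeter", "eccentricity", "extent", "solidity"]


def _build_feature_names() -> list[str]:
    names = [
        "largest_major_axis_p090",
        "largest_major_axis_p050",
        "largest_area_p050",
        "tumor_tissue_ratio_p090",
        "nonzero_count_p090",
    ]
    for prop in _REGION_PROPS:
        names += [f"{prop}_{s}_p090" for s in _REGION_STATS]
    names += ["mean_region_confidence_p090", "n_regions_p090"]
    return names


#: Schema of the 32-feature slide vector, in fixed order:
#: largest region's major axis at p=0.9 and p=0.5 (2), largest region's
#: area at p=0.5 (1), tumor/tissue ratio and non-zero pixel count at
#: p=0.9 (2), five statistics (maximum, mean, variance, skewness,
#: kurtosis) of five region properties (area, perimeter, eccentricity,
#: extent, solidity) at p=0.9 (25), mean region confidence and region
#: count at p=0.9 (2).
FEATURE_NAMES: list[str] = _build_feature_names()
assert len(FEATURE_NAMES) == 32


def _region_stats(values: list[float]) -> list[float]:
    """maximum, mean, variance, skewness, kurtosis over regions; higher
    moments are 0 with fewer than 2 regions (or degenerate spread)."""
    if not values:
        return [0.0] * 5
    arr = np.asarray(values, dtype=np.float64)
    out = [float(arr.max()), float(arr.mean())]
    if arr.size < 2 or float(arr.var()) < 1e-18:
        return out + [float(arr.var()), 0.0, 0.0]
    return out + [
        float(arr.var()),
        float(stats.skew(arr, bias=True)),
        float(stats.kurtosis(arr, bias=True)),
    ]


def extract_slide_features(
    heatmap: StitchedHeatmap,
    tissue: TissueMask,
    mpp_at_level: float,
) -> np.ndarray:
    """Compose the 32-feature vector from a slide heatmap.

    Lengths/areas are in pixels at the heatmap level; ``mpp_at_level`` is
    carried by callers for downstream mm conversion.  An empty heatmap
    gives the all-zero vector.
    """
    prob = np.asarray(heatmap.prob, dtype=np.float64)
    if prob.shape != tissue.grid.shape:
        raise ValueError(
            f"heatmap {prob.shape} and tissue mask {tissue.grid.shape} misaligned"
        )
    fv = np.zeros(32, dtype=np.float64)

    def regions_at(thr: float):
        lab = cc_label(prob > thr, connectivity=2)
        return regionprops(lab, intensity_image=prob)

    r090 = regions_at(0.9)
    r050 = regions_at(0.5)

    fv[0] = max((r.axis_major_length for r in r090), default=0.0)
    fv[1] = max((r.axis_major_length for r in r050), default=0.0)
    fv[2] = max((r.area for r in r050), default=0.0)
    tissue_area = tissue.area
    nonzero_090 = float((prob > 0.9).sum())
    fv[3] = nonzero_090 / tissue_area if tissue_area else 0.0
    fv[4] = nonzero_090
    idx = 5
    for prop in _REGION_PROPS:
        attr = {"area": "area", "perimeter": "perimeter", "eccentricity": "eccentricity",
                "extent": "extent", "solidity": "solidity"}[prop]
        fv[idx : idx + 5] = _region_stats([float(getattr(r, attr)) for r in r090])
        idx += 5
    fv[30] = float(np.mean([r.intensity_mean for r in r090])) if r090 else 0.0
    fv[31] = float(len(r090))
    if not np.isfinite(fv).all():
        fv = np.nan_to_num(fv)
    return fv


# ---------------------------------------------------------------------------
# class balancing: SMOTE oversampling + Tomek-link cleanup
# ---------------------------------------------------------------------------


def smote_oversample(
    X: np.ndarray, y: np.ndarray, seed: int = 0, k_neighbors: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every minority class to parity with the largest class by
    interpolating between a sample and one of its k nearest same-class
    neighbors (the SMOTE construction).  Deterministic per seed."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to balance")
    target = counts.max()
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [y]
    for cls, cnt in zip(classes, counts):
        need = target - cnt
        if need == 0:
            continue
        if cnt < 2:
            raise ValueError(
                f"class {cls!r} has only {cnt} sample(s); SMOTE needs >= 2 for interpolation"
            )
        Xc = X[y == cls]
        k = min(k_neighbors, cnt - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, nbr = nn.kneighbors(Xc)
        base = rng.integers(0, cnt, size=need)
        pick = rng.integers(1, k + 1, size=need)  # skip self at column 0
        lam = rng.uniform(0.0, 1.0, size=(need, 1))
        xi = Xc[base]
        xj = Xc[nbr[base, pick]]
        new_X.append(xi + lam * (xj - xi))
        new_y.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(new_X), np.concatenate(new_y)


def tomek_links(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of all samples participating in a Tomek link (mutual
    nearest neighbors of opposite class)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n = len(X)
    if n < 2:
        return np.array([], dtype=int)
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    _, nbr = nn.kneighbors(X)
    nearest = nbr[:, 1]
    linked = set()
    for i in range(n):
        j = nearest[i]
        if nearest[j] == i and y[i] != y[j]:
            linked.add(i)
            linked.add(int(j))
    return np.array(sorted(linked), dtype=int)


def balance_training_set(
    X: np.ndarray, y: np.ndarray, seed: int = 0, k_neighbors: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE oversampling to class parity, then removal of every sample in
    a Tomek link (boundary cleanup).  Already-balanced, well-separated
    data passes through unchanged."""
    Xs, ys = smote_oversample(X, y, seed=seed, k_neighbors=k_neighbors)
    drop = tomek_links(Xs, ys)
    keep = np.setdiff1d(np.arange(len(Xs)), drop)
    return Xs[keep], ys[keep]


# ---------------------------------------------------------------------------
# Random-Forest ensemble over slide features
# ---------------------------------------------------------------------------


@dataclass
class RandomForestEnsemble:
    """Majority-vote ensemble; ties resolve to the higher metastasis
    category (a clinically conservative rule)."""

    members: list[RandomForestClassifier] = field(default_factory=list)

    def predict_one(self, fv: np.ndarray) -> str:
        votes = [str(m.predict(fv.reshape(1, -1))[0]) for m in self.members]
        return _majority_vote(votes)

    def predict(self, X: np.ndarray) -> list[str]:
        return [self.predict_one(np.asarray(row)) for row in X]


def _majority_vote(votes: Sequence[str]) -> str:
    tally: dict[str, int] = {}
    for v in votes:
        tally[v] = tally.get(v, 0) + 1
    best = max(tally.values())
    tied = [v for v, c in tally.items() if c == best]
    return max(tied, key=LABEL_ORDER.index)


def train_rf_ensemble(
    X: np.ndarray,
    y: Sequence[str],
    n_members: int = 4,
    seed: int = 0,
    n_estimators: int = 200,
) -> RandomForestEnsemble:
    """Train the Random-Forest ensemble on slide feature vectors.

    Members differ in their training-data subset (seeded 80% draws) and in
    whether that subset is SMOTE+Tomek balanced (alternating members), so
    a 4-member ensemble spans 2 data splits × 2 balancing variants.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray([str(v).lower() for v in y])
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are single-class; nothing to learn")
    rng = np.random.default_rng(seed)
    members = []
    n = len(X)
    for i in range(n_members):
        idx = rng.choice(n, size=max(2, int(0.8 * n)), replace=False)
        Xi, yi = X[idx], y[idx]
        if len(np.unique(yi)) < 2:  # resample until the subset keeps >= 2 classes
            idx = np.arange(n)
            Xi, yi = X, y
        if i % 2 == 1 and (np.unique(yi, return_counts=True)[1] >= 2).all():
            Xi, yi = balance_training_set(Xi, yi, seed=seed + i)
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed + i, n_jobs=1
        )
        clf.fit(Xi, yi)
        members.append(clf)
    return RandomForestEnsemble(members)


def classify_metastasis(ensemble: RandomForestEnsemble, fv: np.ndarray) -> str:
    """Slide metastasis type by ensemble majority vote."""
    return ensemble.predict_one(np.asarray(fv, dtype=np.float64))


# ---------------------------------------------------------------------------
# rule tables: lesion size -> type, node labels -> pN stage
# ---------------------------------------------------------------------------


def metastasis_type_from_size(
    major_axis_mm: float, cell_count: int | None = None
) -> str:
    """Metastasis type from lesion major-axis length (mm) and optional
    cell count.

    A zero-size lesion is negative; <= 0.2 mm (or < 200 cells) is an
    isolated-tumor-cell cluster; anything larger up to 2 mm is a
    micro-metastasis; above 2 mm a macro-metastasis.
    """
    if major_axis_mm < 0:
        raise ValueError("lesion size cannot be negative")
    if major_axis_mm == 0:
        return "negative"
    if major_axis_mm <= ITC_MAX_MM or (cell_count is not None and cell_count < ITC_MAX_CELLS):
        return "itc"
    if major_axis_mm <= MICRO_MAX_MM:
        return "micro"
    return "macro"


def assign_pn_stage(slide_labels: Sequence[str]) -> str:
    """Patient pN stage from per-node metastasis labels."""
    if not slide_labels:
        raise ValueError("a patient needs at least one lymph-node slide")
    labels = [str(lab).lower() for lab in slide_labels]
    unknown = set(labels) - set(LABEL_ORDER)
    if unknown:
        raise ValueError(f"unknown metastasis labels: {sorted(unknown)}")
    n_macro = labels.count("macro")
    n_micro = labels.count("micro")
    n_itc = labels.count("itc")
    if n_macro == 0 and n_micro == 0 and n_itc == 0:
        return "pN0"
    if n_macro == 0 and n_micro == 0:
        return "pN0(i+)"
    if n_macro == 0:
        return "pN1mi"
    n_met_nodes = n_macro + n_micro  # ITC-only nodes excluded from the tally
    return "pN1" if n_met_nodes <= 3 else "pN2"


def classify_slide_rule_based(
    heatmap: StitchedHeatmap,
    mpp_at_level: float,
    threshold: float = 0.5,
    min_region_px: int = 0,
) -> str:
    """Rule-based slide typing: largest thresholded heatmap region's
    major-axis length converted to mm, then the clinical size bands."""
    binary = np.asarray(heatmap.prob) > threshold
    lab = cc_label(binary, connectivity=2)
    regs = [r for r in regionprops(lab) if r.area >= min_region_px]
    if not regs:
        return "negative"
    major_px = max(r.axis_major_length for r in regs)
    return metastasis_type_from_size(major_px * mpp_at_level / 1000.0)
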
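"""Slide features, class balancing, RF ensemble, rule tables, pN staging."""

import numpy as np
import pytest
from skimage.measure import label as cc_label, regionprops

from wsikit.segmentation import StitchedHeatmap
from wsikit.tissue import TissueMask
from wsikit.staging import (
    FEATURE_NAMES,
    LABEL_ORDER,
    _majority_vote,
    assign_pn_stage,
    balance_training_set,
    classify_slide_rule_based,
    extract_slide_features,
    metastasis_type_from_size,
    smote_oversample,
    tomek_links,
    train_rf_ensemble,
)


def _heatmap(prob):
    prob = np.asarray(prob, dtype=np.float32)
    return StitchedHeatmap(prob, (prob > 0).astype(np.int32), 1.0)


def _tissue(shape):
    return TissueMask(np.ones(shape, dtype=bool), 0, shape)


class TestFeatureExtraction:
    def test_empty_heatmap_gives_zero_vector(self):
        fv = extract_slide_features(_heatmap(np.zeros((32, 32))), _tissue((32, 32)), 1.0)
        assert fv.shape == (32,)
        assert (fv == 0).all()

    def test_always_32_features_with_schema(self, rng):
        prob = rng.uniform(size=(64, 64)).astype(np.float32)
        fv = extract_slide_features(_heatmap(prob), _tissue((64, 64)), 1.0)
        assert fv.shape == (32,)
        assert len(FEATURE_NAMES) == 32
        assert np.isfinite(fv).all()

    def test_unit_square_against_region_properties_oracle(self):
        """A single 10x10 block at p=1: area/count/region-count by direct
        geometry; the remaining statistics against regionprops."""
        prob = np.zeros((64, 64), dtype=np.float32)
        prob[10:20, 30:40] = 1.0
        fv = dict(zip(FEATURE_NAMES, extract_slide_features(_heatmap(prob), _tissue((64, 64)), 1.0)))
        assert fv["area_max_p090"] == 100
        assert fv["nonzero_count_p090"] == 100
        assert fv["n_regions_p090"] == 1
        assert fv["largest_area_p050"] == 100
        assert fv["tumor_tissue_ratio_p090"] == pytest.approx(100 / 64**2)
        assert fv["mean_region_confidence_p090"] == pytest.approx(1.0)
        (region,) = regionprops(cc_label(prob > 0.9))
        assert fv["largest_major_axis_p090"] == pytest.approx(region.axis_major_length)
        assert fv["perimeter_max_p090"] == pytest.approx(region.perimeter)
        assert fv["eccentricity_max_p090"] == pytest.approx(region.eccentricity)
        assert fv["solidity_max_p090"] == pytest.approx(region.solidity)
        # single region -> higher moments zeroed
        assert fv["area_var_p090"] == 0 and fv["area_skew_p090"] == 0 and fv["area_kurt_p090"] == 0

    def test_thresholds_are_distinct(self):
        """A region between 0.5 and 0.9 appears only in the p=0.5 features."""
        prob = np.zeros((32, 32), dtype=np.float32)
        prob[5:10, 5:10] = 0.7
        fv = dict(zip(FEATURE_NAMES, extract_slide_features(_heatmap(prob), _tissue((32, 32)), 1.0)))
        assert fv["largest_area_p050"] == 25
        assert fv["n_regions_p090"] == 0
        assert fv["nonzero_count_p090"] == 0

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            extract_slide_features(_heatmap(np.zeros((16, 16))), _tissue((32, 32)), 1.0)


class TestBalancing:
    @staticmethod
    def _toy():
        rng = np.random.default_rng(0)
        Xa = rng.normal([0, 0], 0.3, (10, 2))
        Xb = rng.normal([5, 5], 0.3, (2, 2))
        return np.vstack([Xa, Xb]), np.array(["a"] * 10 + ["b"] * 2)

    def test_smote_reaches_parity_then_tomek_prunes(self):
        X, y = self._toy()
        Xs, ys = smote_oversample(X, y, seed=1)
        assert (ys == "a").sum() == 10 and (ys == "b").sum() == 10
        Xb, yb = balance_training_set(X, y, seed=1)
        assert (yb == "a").sum() <= 10 and (yb == "b").sum() <= 10

    def test_synthetic_points_interpolate_minority(self):
        X, y = self._toy()
        Xs, ys = smote_oversample(X, y, seed=1)
        new = Xs[len(X):]
        lo, hi = X[y == "b"].min(axis=0), X[y == "b"].max(axis=0)
        assert (new >= lo - 1e-9).all() and (new <= hi + 1e-9).all()

    def test_balanced_separated_data_unchanged(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal([0, 0], 0.2, (8, 2)), rng.normal([10, 10], 0.2, (8, 2))])
        y = np.array(["a"] * 8 + ["b"] * 8)
        Xb, yb = balance_training_set(X, y, seed=0)
        assert np.array_equal(np.sort(Xb, axis=0), np.sort(X, axis=0))

    def test_tomek_links_are_mutual_opposite_class_neighbors(self):
        X = np.array([[0.0, 0], [1.0, 0], [10.0, 0], [11.0, 0]])
        y = np.array(["a", "b", "a", "a"])
        linked = tomek_links(X, y)
        assert set(linked) == {0, 1}

    def test_deterministic_per_seed(self):
        X, y = self._toy()
        a = smote_oversample(X, y, seed=7)[0]
        b = smote_oversample(X, y, seed=7)[0]
        assert np.array_equal(a, b)

    def test_singleton_minority_rejected_by_name(self):
        X = np.zeros((5, 2))
        y = np.array(["a", "a", "a", "a", "rare"])
        with pytest.raises(ValueError, match="rare"):
            smote_oversample(X, y)


def _separable_features(n_per_class=12, seed=0):
    """Feature vectors whose size-linked entries separate the classes."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    scale = {"negative": 0.0, "itc": 30.0, "micro": 200.0, "macro": 700.0}
    for label, s in scale.items():
        for _ in range(n_per_class):
            fv = np.zeros(32)
            if s:
                fv[0] = fv[1] = s * rng.uniform(0.8, 1.2)
                fv[2] = fv[0] ** 2 * 0.6
                fv[4] = fv[2]
                fv[31] = 1
            X.append(fv)
            y.append(label)
    return np.array(X), np.array(y)


class TestRFEnsemble:
    def test_single_class_rejected(self):
        X = np.zeros((6, 32))
        with pytest.raises(ValueError):
            train_rf_ensemble(X, ["micro"] * 6)

    def test_holdout_accuracy_on_separable_features(self):
        X, y = _separable_features(n_per_class=14, seed=1)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(X))
        cut = int(0.75 * len(X))
        ens = train_rf_ensemble(X[idx[:cut]], y[idx[:cut]], seed=0, n_estimators=60)
        pred = ens.predict(X[idx[cut:]])
        acc = np.mean([p == t for p, t in zip(pred, y[idx[cut:]])])
        assert acc >= 0.9

    def test_seed_determinism(self):
        X, y = _separable_features(seed=2)
        a = train_rf_ensemble(X, y, seed=3, n_estimators=30).predict(X)
        b = train_rf_ensemble(X, y, seed=3, n_estimators=30).predict(X)
        assert a == b

    def test_majority_vote_and_tie_break(self):
        assert _majority_vote(["macro", "macro", "micro", "negative"]) == "macro"
        assert _majority_vote(["micro", "micro", "macro", "macro"]) == "macro"
        assert _majority_vote(["negative", "negative", "itc", "itc"]) == "itc"


class TestRuleTables:
    @pytest.mark.parametrize(
        "mm,cells,expected",
        [
            (0.0, None, "negative"),
            (0.1, 150, "itc"),
            (0.2, None, "itc"),          # boundary: exactly 0.2 mm
            (0.5, 150, "itc"),           # under 200 cells stays ITC
            (0.5, None, "micro"),
            (2.0, None, "micro"),        # boundary: exactly 2 mm
            (2.5, None, "macro"),
            (25.0, None, "macro"),
        ],
    )
    def test_size_bands(self, mm, cells, expected):
        assert metastasis_type_from_size(mm, cells) == expected

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError):
            metastasis_type_from_size(-0.1)

    @pytest.mark.parametrize(
        "labels,expected",
        [
            (["negative"] * 5, "pN0"),
            (["itc", "negative", "negative", "negative", "negative"], "pN0(i+)"),
            (["itc", "itc", "itc", "itc", "itc"], "pN0(i+)"),
            (["micro", "negative", "negative", "negative", "negative"], "pN1mi"),
            (["micro", "micro", "itc", "negative", "negative"], "pN1mi"),
            (["macro", "micro", "negative", "negative", "negative"], "pN1"),
            (["macro", "negative", "negative", "negative", "negative"], "pN1"),
            (["macro", "macro", "macro", "negative", "negative"], "pN1"),
            (["macro", "micro", "micro", "micro", "negative"], "pN2"),
            (["macro", "macro", "macro", "macro", "micro"], "pN2"),
            (["macro", "itc", "itc", "itc", "negative"], "pN1"),  # ITC nodes outside the tally
        ],
    )
    def test_pn_stage_rows(self, labels, expected):
        assert assign_pn_stage(labels) == expected

    def test_empty_patient_rejected(self):
        with pytest.raises(ValueError):
            assign_pn_stage([])

    def test_stage_monotonicity_under_label_upgrade(self):
        """Upgrading any slide's label never lowers the patient stage."""
        rng = np.random.default_rng(4)
        order = {s: i for i, s in enumerate(["pN0", "pN0(i+)", "pN1mi", "pN1", "pN2"])}
        for _ in range(200):
            labels = list(rng.choice(LABEL_ORDER, size=5))
            base = assign_pn_stage(labels)
            i = int(rng.integers(0, 5))
            rank = LABEL_ORDER.index(labels[i])
            if rank == len(LABEL_ORDER) - 1:
                continue
            labels[i] = LABEL_ORDER[rank + 1]
            assert order[assign_pn_stage(labels)] >= order[base]


class TestRuleBasedSlideTyping:
    def test_lesion_size_drives_label(self):
        prob = np.zeros((256, 256), dtype=np.float32)
        prob[100:104, 100:140] = 1.0  # 40 px major axis
        hm = _heatmap(prob)
        assert classify_slide_rule_based(hm, mpp_at_level=4.0) == "itc"  # 0.16 mm
        assert classify_slide_rule_based(hm, mpp_at_level=20.0) == "micro"  # 0.8 mm
        assert classify_slide_rule_based(hm, mpp_at_level=60.0) == "macro"  # 2.4 mm

    def test_empty_heatmap_is_negative(self):
        assert classify_slide_rule_based(_heatmap(np.zeros((32, 32))), 4.0) == "negative"
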
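"""Rule hierarchy, nearest-neighbour discrimination, accuracy assessment."""

import numpy as np
import pandas as pd
import pytest

from palmsust.classify import (
    ConfusionMatrix,
    RuleThresholds,
    accuracy_metrics,
    classify_segments,
    confusion_matrix,
    sample_validation_points,
    train_nn,
)
from palmsust.grid import GridGeometry, Raster
from palmsust.landcover import CLASS_IDS, CLASSES, LandCoverMap
from palmsust.segmentation import SegmentMap

FEATURES = ("mean_red", "mean_green", "mean_nir", "mean_texture", "mean_height")


def seg_map_from(features: pd.DataFrame) -> SegmentMap:
    k = len(features)
    geom = GridGeometry(0.0, 1.0, 1.0, 1, k)
    labels = Raster(geom, np.arange(k, dtype=np.int64).reshape(1, k), nodata=-1)
    return SegmentMap(labels, features)


def veg_training_frame():
    rows = []
    centres = {"oil_palm": 0.0, "crops": 40.0, "other_vegetation": 80.0}
    rng = np.random.default_rng(0)
    for label, c in centres.items():
        for _ in range(10):
            x = c + rng.normal(scale=0.5)
            rows.append(
                {
                    "mean_red": x,
                    "mean_green": x,
                    "mean_nir": x,
                    "mean_texture": x,
                    "mean_height": x,
                    "label": label,
                }
            )
    return pd.DataFrame(rows)


class TestRuleHierarchy:
    def make_features(self, **overrides):
        base = {
            "mean_red": 100.0,
            "mean_green": 100.0,
            "mean_nir": 100.0,
            "mean_texture": 1.0,
            "mean_height": 0.0,
            "rect_fit": 0.3,
        }
        base.update(overrides)
        return pd.DataFrame([base])

    def classify_one(self, feats, ndvi, ndwi, model=None):
        sm = seg_map_from(feats)
        lc = classify_segments(
            sm,
            ndvi_mean=pd.Series([ndvi]),
            ndwi_mean=pd.Series([ndwi]),
            nn_model=model,
        )
        return lc.legend[int(lc.classes.values[0, 0])]

    def test_high_ndvi_goes_to_vegetation_branch(self):
        model = train_nn(veg_training_frame(), FEATURES)
        feats = self.make_features(
            mean_red=40.0, mean_green=40.0, mean_nir=40.0,
            mean_texture=40.0, mean_height=40.0,
        )
        assert self.classify_one(feats, ndvi=0.7, ndwi=-0.5, model=model) == "crops"

    def test_low_ndvi_high_ndwi_is_water(self):
        assert self.classify_one(self.make_features(), ndvi=0.1, ndwi=0.4) == "water"

    def test_building_rule_conjunction(self):
        feats = self.make_features(rect_fit=0.92, mean_height=3.1, mean_red=180.0)
        assert self.classify_one(feats, ndvi=0.1, ndwi=-0.2) == "built_up"
        feats = self.make_features(rect_fit=0.5, mean_height=3.1, mean_red=180.0)
        assert self.classify_one(feats, ndvi=0.1, ndwi=-0.2) == "bare_soil"

    def test_vegetation_without_model_raises(self):
        with pytest.raises(ValueError, match="model"):
            self.classify_one(self.make_features(), ndvi=0.7, ndwi=-0.5, model=None)

    def test_every_segment_gets_exactly_one_class(self, rng):
        model = train_nn(veg_training_frame(), FEATURES)
        n = 40
        feats = pd.DataFrame(
            {
                "mean_red": rng.uniform(0, 255, n),
                "mean_green": rng.uniform(0, 255, n),
                "mean_nir": rng.uniform(0, 255, n),
                "mean_texture": rng.uniform(0, 30, n),
                "mean_height": rng.uniform(0, 10, n),
                "rect_fit": rng.uniform(0, 1, n),
            }
        )
        lc = classify_segments(
            seg_map_from(feats),
            ndvi_mean=pd.Series(rng.uniform(-1, 1, n)),
            ndwi_mean=pd.Series(rng.uniform(-1, 1, n)),
            nn_model=model,
        )
        assert set(np.unique(lc.classes.values)) <= set(CLASS_IDS.values())
        assert lc.valid().all()


class TestNearestNeighbour:
    def test_training_segment_recovers_its_own_label(self):
        df = veg_training_frame()
        model = train_nn(df, FEATURES)
        preds = model.predict(df)
        expected = df["label"].map(CLASS_IDS).to_numpy()
        np.testing.assert_array_equal(preds, expected)

    def test_exact_tie_prefers_lowest_legend_id(self):
        rows = []
        for label, x in (("oil_palm", 1.0), ("crops", -1.0), ("other_vegetation", 5.0)):
            rows.append(dict.fromkeys(FEATURES, x) | {"label": label})
        df = pd.DataFrame(rows)
        model = train_nn(df, FEATURES)
        query = pd.DataFrame([dict.fromkeys(FEATURES, 0.0)])  # equidistant palm/crops
        assert model.predict(query)[0] == CLASS_IDS["oil_palm"]

    def test_separated_clusters_full_heldout_recovery(self, rng):
        train_rows, test_rows, test_labels = [], [], []
        for label, c in (("oil_palm", 0.0), ("crops", 50.0), ("other_vegetation", 100.0)):
            for i in range(20):
                x = c + rng.normal(scale=1.0, size=5)
                row = dict(zip(FEATURES, x))
                if i < 10:
                    train_rows.append(row | {"label": label})
                else:
                    test_rows.append(row)
                    test_labels.append(CLASS_IDS[label])
        model = train_nn(pd.DataFrame(train_rows), FEATURES)
        preds = model.predict(pd.DataFrame(test_rows))
        np.testing.assert_array_equal(preds, test_labels)

    def test_empty_class_rejected(self):
        df = veg_training_frame()
        with pytest.raises(ValueError, match="crops"):
            train_nn(df[df["label"] != "crops"], FEATURES)


class TestValidationPoints:
    def make_map(self, n=20):
        geom = GridGeometry(0.0, float(n), 1.0, n, n)
        vals = np.full((n, n), CLASS_IDS["crops"], dtype=np.int64)
        return LandCoverMap(Raster(geom, vals, nodata=0))

    def test_default_draw_gives_45_distinct_points(self):
        pts = sample_validation_points(self.make_map(), n=45, seed=3)
        assert len(pts) == 45
        assert len(pts[["row", "col"]].drop_duplicates()) == 45

    def test_seeded_and_inside_extent(self):
        lc = self.make_map()
        a = sample_validation_points(lc, 45, seed=11)
        b = sample_validation_points(lc, 45, seed=11)
        assert a.equals(b)
        assert a["row"].between(0, 19).all() and a["col"].between(0, 19).all()

    def test_oversampling_raises(self):
        with pytest.raises(ValueError, match="available"):
            sample_validation_points(self.make_map(5), n=26, seed=0)


class TestAccuracyMetrics:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(np.diag([5, 7, 9, 1, 2, 3]))
        m = accuracy_metrics(cm)
        assert m["overall"] == 1.0 and m["kappa"] == 1.0
        assert all(v == 1.0 for v in m["producer"].values())
        assert all(v == 1.0 for v in m["user"].values())

    def test_two_class_hand_computation(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[0, 0], counts[0, 1] = 45, 5
        counts[1, 0], counts[1, 1] = 15, 35
        m = accuracy_metrics(ConfusionMatrix(counts))
        assert m["overall"] == pytest.approx(0.80)
        assert m["kappa"] == pytest.approx(0.60)
        assert m["producer"]["oil_palm"] == pytest.approx(0.90)
        assert m["user"]["oil_palm"] == pytest.approx(0.75)

    def test_single_class_prediction_on_balanced_truth_kappa_zero(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[0, 0] = 50  # all predictions class 1
        counts[1, 0] = 50
        m = accuracy_metrics(ConfusionMatrix(counts))
        assert m["kappa"] == pytest.approx(0.0)
        assert np.isnan(m["user"]["crops"])  # zero column marginal

    def test_kappa_one_iff_diagonal_and_permutation_invariant(self, rng):
        counts = rng.integers(0, 20, (6, 6))
        counts[np.diag_indices(6)] += 30
        m = accuracy_metrics(ConfusionMatrix(counts))
        perm = rng.permutation(6)
        m_perm = accuracy_metrics(ConfusionMatrix(counts[np.ix_(perm, perm)]))
        assert m["kappa"] == pytest.approx(m_perm["kappa"])
        off_diag = counts - np.diag(np.diag(counts))
        assert (m["kappa"] == 1.0) == (off_diag.sum() == 0)


def test_confusion_matrix_full_map_and_points_agree_on_uniform_maps():
    geom = GridGeometry(0.0, 10.0, 1.0, 10, 10)
    ref = LandCoverMap(Raster(geom, np.full((10, 10), 2, dtype=np.int64), nodata=0))
    pred = LandCoverMap(Raster(geom, np.full((10, 10), 4, dtype=np.int64), nodata=0))
    cm_full = confusion_matrix(ref, pred)
    assert cm_full.counts[1, 3] == 100
    pts = sample_validation_points(ref, 45, seed=0)
    cm_pts = confusion_matrix(ref, pred, points=pts)
    assert cm_pts.counts[1, 3] == 45 and cm_pts.total == 45
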
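"""Feature stack, balancing, training regimes and segmentation contracts."""

import numpy as np
import pandas as pd
import pytest

from psrquant.hsb import ClassCounts, NoTissueError
from psrquant.pixclf import (
    LabelledRegion,
    balance_classes,
    collect_training,
    compute_features,
    load_model,
    psr_positivity,
    retrain_with_divergent,
    save_model,
    segment_tile,
    select_divergent_cases,
    train,
)
from psrquant.synth import PixelClass, StainTransform, render


def naive_features(img, radii):
    """Brute-force per-pixel window statistics with replicate borders."""
    h, w, _ = img.shape
    planes, names = [], []
    for ch, ch_name in enumerate("RGB"):
        chan = img[..., ch].astype(np.float64)
        planes.append(chan)
        names.append(f"{ch_name}_raw")
        for r in radii:
            pad = np.pad(chan, r, mode="edge")
            stats = {s: np.zeros((h, w)) for s in ("mean", "min", "max", "median", "variance")}
            for y in range(h):
                for x in range(w):
                    win = pad[y : y + 2 * r + 1, x : x + 2 * r + 1]
                    stats["mean"][y, x] = win.mean()
                    stats["min"][y, x] = win.min()
                    stats["max"][y, x] = win.max()
                    stats["median"][y, x] = np.median(win)
                    stats["variance"][y, x] = win.var()
            for s in ("mean", "min", "max", "median", "variance"):
                planes.append(stats[s])
                names.append(f"{ch_name}_{s}_r{r}")
    return np.stack(planes, axis=-1), names


class TestFeatures:
    def test_constant_tile(self):
        img = np.full((16, 16, 3), 77, dtype=np.uint8)
        fs = compute_features(img, radii=(1, 2))
        for i, name in enumerate(fs.feature_names):
            if "variance" in name:
                assert (fs.data[..., i] == 0).all()
            else:
                assert (fs.data[..., i] == 77).all()

    def test_bright_pixel_max_propagates(self):
        img = np.zeros((9, 9, 3), dtype=np.uint8)
        img[4, 4] = 200
        fs = compute_features(img, radii=(1,))
        i = fs.feature_names.index("R_max_r1")
        region = fs.data[3:6, 3:6, i]
        assert (region == 200).all()

    @pytest.mark.parametrize("radii", [(2,), (1, 3)])
    def test_matches_naive_recomputation(self, radii):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        fs = compute_features(img, radii=radii, dtype=np.float64)
        expected, names = naive_features(img, radii)
        assert list(fs.feature_names) == names
        for i, name in enumerate(names):
            got = fs.data[..., i]
            if any(k in name for k in ("min", "max", "median", "raw")):
                assert np.array_equal(got, expected[..., i]), name
            else:
                assert np.allclose(got, expected[..., i], rtol=0, atol=1e-9), name

    def test_feature_count_invariant(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        fs = compute_features(img, radii=(1, 2, 4))
        assert fs.data.shape[-1] == 3 * (1 + 5 * 3)

    def test_empty_radii_rejected(self):
        with pytest.raises(ValueError):
            compute_features(np.zeros((8, 8, 3), dtype=np.uint8), radii=())


def _four_class_setup(small_gt, palette, noise=0.0, seed=0):
    img = render(small_gt, palette, StainTransform(noise_sd=noise), seed=seed)
    features = {"t0": compute_features(img, radii=(1, 2))}
    rng = np.random.default_rng(seed)
    regions = []
    for cls in PixelClass:
        idx = np.flatnonzero(small_gt.label_raster == int(cls))
        picks = rng.choice(idx, size=min(80, idx.size), replace=False)
        coords = np.column_stack(np.unravel_index(picks, small_gt.label_raster.shape))
        regions.append(
            LabelledRegion("t0", coords, cls, stain_set="E1", case_id="case01")
        )
    return img, features, regions


class TestCollectAndBalance:
    def test_row_cardinality(self):
        features = {
            "t0": compute_features(np.zeros((8, 8, 3), dtype=np.uint8), radii=(1,))
        }
        regions = [
            LabelledRegion("t0", np.array([[0, i] for i in range(8)] + [[1, i] for i in range(8)]), PixelClass.PSR),
            LabelledRegion("t0", np.array([[6, i] for i in range(8)] + [[7, i] for i in range(8)]), PixelClass.TISSUE),
        ]
        table = collect_training(regions, features)
        assert len(table) == 32

    def test_conflicting_overlap_rejected(self):
        features = {
            "t0": compute_features(np.zeros((8, 8, 3), dtype=np.uint8), radii=(1,))
        }
        c = np.array([[2, 2], [2, 3]])
        with pytest.raises(ValueError, match="conflict"):
            collect_training(
                [
                    LabelledRegion("t0", c, PixelClass.PSR),
                    LabelledRegion("t0", c, PixelClass.TISSUE),
                ],
                features,
            )

    def test_missing_tile_rejected(self):
        with pytest.raises(KeyError):
            collect_training(
                [LabelledRegion("ghost", np.array([[0, 0]]), PixelClass.PSR)], {}
            )

    def test_provenance_filter(self, small_gt, palette):
        _, features, regions = _four_class_setup(small_gt, palette)
        table = collect_training(regions, features)
        assert (table["stain_set"] == "E1").all()
        assert set(table["pixel_class"]) == {0, 1, 2, 3}

    def test_balance_upsamples_to_majority(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "f": rng.normal(size=310),
                "pixel_class": [2] * 10 + [3] * 100 + [1] * 100 + [0] * 100,
                "tile_id": "t",
                "stain_set": "E1",
                "case_id": "c",
            }
        )
        out = balance_classes(table, seed=1)
        assert out["pixel_class"].value_counts().eq(100).all()

    def test_balanced_input_unchanged(self):
        table = pd.DataFrame(
            {"f": range(20), "pixel_class": [0] * 10 + [2] * 10,
             "tile_id": "t", "stain_set": "E1", "case_id": "c"}
        )
        out = balance_classes(table, seed=3)
        pd.testing.assert_frame_equal(out, table)

    def test_balance_deterministic(self):
        table = pd.DataFrame(
            {"f": range(30), "pixel_class": [0] * 10 + [2] * 15 + [3] * 5,
             "tile_id": "t", "stain_set": "E1", "case_id": "c"}
        )
        a = balance_classes(table, seed=7)
        b = balance_classes(table, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_rejected(self):
        table = pd.DataFrame({"f": [1.0], "pixel_class": [2], "tile_id": "t",
                              "stain_set": "E1", "case_id": "c"})
        with pytest.raises(ValueError):
            balance_classes(table, seed=0)


class TestTrainAndSegment:
    def test_separable_palette_perfect_segmentation(self, small_gt, palette):
        img, features, regions = _four_class_setup(small_gt, palette)
        table = balance_classes(collect_training(regions, features), seed=0)
        clf = train(table, n_trees=30, seed=0, radii=(1, 2))
        pred, counts = segment_tile(clf, img, features["t0"])
        assert np.array_equal(pred, small_gt.label_raster)
        assert sum(counts.counts.values()) == small_gt.label_raster.size
        assert clf.holdout_accuracy > 0.99

    def test_permuted_labels_give_chance_accuracy(self, small_gt, palette):
        _, features, regions = _four_class_setup(small_gt, palette)
        table = balance_classes(collect_training(regions, features), seed=0)
        rng = np.random.default_rng(11)
        table = table.assign(
            pixel_class=rng.permutation(table["pixel_class"].to_numpy())
        )
        try:
            clf = train(table, n_trees=30, seed=1, radii=(1, 2))
        except ValueError:
            pytest.skip("permutation lost a class")
        assert abs(clf.holdout_accuracy - 0.25) < 0.06

    def test_deterministic_given_seed(self, small_gt, palette):
        img, features, regions = _four_class_setup(small_gt, palette, noise=4.0)
        table = balance_classes(collect_training(regions, features), seed=0)
        a = train(table, n_trees=20, seed=5, radii=(1, 2))
        b = train(table, n_trees=20, seed=5, radii=(1, 2))
        pa, _ = segment_tile(a, img, features["t0"])
        pb, _ = segment_tile(b, img, features["t0"])
        assert np.array_equal(pa, pb)

    def test_missing_class_rejected(self):
        table = pd.DataFrame(
            {"f": range(20), "pixel_class": [0] * 10 + [2] * 10,
             "tile_id": "t", "stain_set": "E1", "case_id": "c"}
        )
        with pytest.raises(ValueError, match="missing classes"):
            train(table, n_trees=5, seed=0)

    def test_feature_config_mismatch_rejected(self, small_gt, palette):
        img, features, regions = _four_class_setup(small_gt, palette)
        table = balance_classes(collect_training(regions, features), seed=0)
        clf = train(table, n_trees=5, seed=0, radii=(1, 2))
        other = compute_features(img, radii=(1,))
        with pytest.raises(ValueError, match="configuration"):
            segment_tile(clf, img, other)

    def test_serialisation_round_trip(self, small_gt, palette, tmp_path):
        img, features, regions = _four_class_setup(small_gt, palette, noise=4.0)
        table = balance_classes(collect_training(regions, features), seed=0)
        clf = train(table, n_trees=10, seed=2, radii=(1, 2))
        save_model(clf, tmp_path / "model.joblib")
        loaded = load_model(tmp_path / "model.joblib")
        pa, _ = segment_tile(clf, img, features["t0"])
        pb, _ = segment_tile(loaded, img, features["t0"])
        assert np.array_equal(pa, pb)
        assert loaded.regime == clf.regime and loaded.seed == clf.seed


class TestPsrPositivity:
    def test_quoted_formula(self):
        counts = ClassCounts({2: 100, 3: 800, 1: 100, 0: 500})
        assert psr_positivity(counts) == pytest.approx(10.0)

    def test_zero_scar(self):
        assert psr_positivity(ClassCounts({2: 0, 3: 10, 1: 0})) == 0.0

    def test_space_never_enters_denominator(self):
        a = ClassCounts({2: 50, 3: 100, 1: 10, 0: 0})
        b = ClassCounts({2: 50, 3: 100, 1: 10, 0: 9999})
        assert psr_positivity(a) == psr_positivity(b)

    def test_empty_denominator_is_error(self):
        with pytest.raises(NoTissueError):
            psr_positivity(ClassCounts({0: 100}))


class TestDivergence:
    def _scores(self, values):
        return pd.DataFrame(
            [
                {"case_id": case, "stain_set": s, "psr_percent": v}
                for case, by_set in values.items()
                for s, v in by_set.items()
            ]
        )

    def test_ratio_rule(self):
        scores = self._scores(
            {
                "c1": {"E1": 12.0, "N1": 30.0},  # ratio 2.5 -> divergent
                "c2": {"E1": 10.0, "N1": 15.0},  # ratio 1.5 -> not
                "c3": {"E1": 10.0, "N1": 20.0},  # exactly 2x, strict rule -> not
            }
        )
        assert select_divergent_cases(scores, [("E1", "N1")], 2.0) == ["c1"]

    def test_zero_handling(self):
        scores = self._scores({"c1": {"E1": 0.0, "N1": 5.0}, "c2": {"E1": 0.0, "N1": 0.0}})
        assert select_divergent_cases(scores, [("E1", "N1")], 2.0) == ["c1"]

    def test_missing_member_warns_and_skips(self):
        scores = self._scores({"c1": {"E1": 10.0}})
        with pytest.warns(UserWarning, match="incomplete"):
            assert select_divergent_cases(scores, [("E1", "N1")], 2.0) == []

    def test_factor_validation(self):
        with pytest.raises(ValueError):
            select_divergent_cases(self._scores({}), [("E1", "N1")], 1.0)


class TestRetraining:
    def test_provenance_and_regime(self, small_gt, palette):
        img, features, regions = _four_class_setup(small_gt, palette, noise=4.0)
        table = balance_classes(collect_training(regions, features), seed=0)
        base = train(table, n_trees=10, seed=0, regime="combined", radii=(1, 2))
        extra = [
            LabelledRegion("t0", r.coords[:10], r.pixel_class, case_id="case07")
            for r in regions
        ]
        clf2 = retrain_with_divergent(base, extra, features, seed=1)
        assert clf2.regime == "combined_retrained"
        assert clf2.provenance["added_cases"] == ["case07"]

    def test_duplicate_rows_keep_accuracy(self, small_gt, palette):
        img, features, regions = _four_class_setup(small_gt, palette, noise=4.0)
        table = balance_classes(collect_training(regions, features), seed=0)
        base = train(table, n_trees=30, seed=0, regime="combined", radii=(1, 2))
        dup = [
            LabelledRegion("t0", r.coords[:20], r.pixel_class, case_id="case01")
            for r in regions
        ]
        clf2 = retrain_with_divergent(base, dup, features, seed=0)
        assert abs(clf2.holdout_accuracy - base.holdout_accuracy) < 0.02

    def test_requires_combined_base_and_nonempty_extra(self, small_gt, palette):
        _, features, regions = _four_class_setup(small_gt, palette)
        table = balance_classes(collect_training(regions, features), seed=0)
        per_set = train(table, n_trees=5, seed=0, regime="per_set", radii=(1, 2))
        with pytest.raises(ValueError):
            retrain_with_divergent(per_set, regions, features, seed=0)
        combined = train(table, n_trees=5, seed=0, regime="combined", radii=(1, 2))
        with pytest.raises(ValueError, match="no-op"):
            retrain_with_divergent(combined, [], features, seed=0)
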
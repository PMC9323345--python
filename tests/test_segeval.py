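import numpy as np
import pandas as pd
import pytest

import histotex as ht
from histotex.segeval import (CLASS_NAMES, ConfusionMatrix, aggregate_runs,
                              class_metrics, confusion, eight_class_labels,
                              export_predictions, extract_uniform_patches,
                              fit_baseline_classifier, import_predictions,
                              macro_average, predict_labels, round2,
                              select_best_run, split_dataset, tiled_inference)
from histotex.synthetic import LabeledImage, LabelMask

# ---------------------------------------------------------------------------
# oracle: metrics from raw pixel loops
# ---------------------------------------------------------------------------


def oracle_metrics(target, predicted, cls):
    tp = tn = fp = fn = 0
    for t, p in zip(target.ravel(), predicted.ravel()):
        if t == 0 or p == 0:
            continue
        if t == cls and p == cls:
            tp += 1
        elif t == cls and p != cls:
            fn += 1
        elif t != cls and p == cls:
            fp += 1
        else:
            tn += 1
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else float("nan")
    iou = tp / (tp + fp + fn) if (tp + fp + fn) else float("nan")
    prec = tp / (tp + fp) if (tp + fp) else float("nan")
    rec = tp / (tp + fn) if (tp + fn) else float("nan")
    f1 = (2 * prec * rec / (prec + rec)) if (prec > 0 or rec > 0) else 0.0
    return acc, iou, prec, rec, f1


def random_label_pair(rng, shape=(12, 15)):
    target = rng.integers(0, 9, size=shape)
    predicted = rng.integers(1, 9, size=shape)
    return target, predicted


class TestEightClassLabels:
    def test_mapping(self):
        mask = np.array([[0, 1, 2], [3, 4, 1]], dtype=np.uint8)
        n = eight_class_labels(mask, "N")
        mn = eight_class_labels(mask, "MN")
        assert np.array_equal(n, [[0, 1, 2], [3, 4, 1]])
        assert np.array_equal(mn, [[0, 5, 6], [7, 8, 5]])

    def test_unknown_subtype(self):
        with pytest.raises(ValueError):
            eight_class_labels(np.zeros((2, 2), np.uint8), "Z")


class TestConfusion:
    def test_perfect_prediction_identity(self, rng):
        t = rng.integers(1, 9, size=(10, 10))
        cm = confusion(t, t)
        norm = cm.normalized
        present = np.unique(t) - 1
        for k in present:
            assert norm[k, k] == pytest.approx(1.0)

    def test_row_normalization(self):
        t = np.array([[1, 1, 1, 1]])
        p = np.array([[1, 1, 1, 2]])
        cm = confusion(t, p)
        assert cm.normalized[0, 0] == pytest.approx(0.75)
        assert cm.normalized[0, 1] == pytest.approx(0.25)

    def test_rows_sum_to_one(self, rng):
        t, p = random_label_pair(rng)
        cm = confusion(t, p)
        sums = cm.normalized.sum(axis=1)
        for k in range(8):
            if cm.counts[k].sum() > 0:
                assert sums[k] == pytest.approx(1.0, abs=1e-9)

    def test_code_zero_excluded(self):
        t = np.array([[0, 1], [0, 2]])
        p = np.array([[5, 1], [5, 2]])
        assert confusion(t, p).counts.sum() == 2

    def test_no_annotated_pixels(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2), int), np.ones((2, 2), int))

    def test_from_normalized_round_trip(self, rng):
        m = rng.random((8, 8))
        m /= m.sum(axis=1, keepdims=True)
        cm = ConfusionMatrix.from_normalized(m)
        assert np.allclose(cm.normalized, m)
        assert np.allclose(cm.diagonal(), np.diag(m))

    def test_query_by_name(self):
        m = np.eye(8) * 0.5
        m[2, 6] = 0.5
        cm = ConfusionMatrix.from_normalized(m)
        assert cm.query("PC-N", "PC-MN") == pytest.approx(0.5)
        counts = np.zeros((8, 8))
        counts[2, 2] = 3
        counts[2, 6] = 1
        assert ConfusionMatrix(counts).query("PC-N", "PC-MN") == \
            pytest.approx(0.25)


class TestClassMetrics:
    def test_direct_substitution_golden(self):
        # TP=1, FP=1, FN=1, TN=7 for class 1
        counts = np.zeros((8, 8))
        counts[0, 0] = 1
        counts[0, 1] = 1
        counts[1, 0] = 1
        counts[1, 1] = 7
        m = class_metrics(ConfusionMatrix(counts), 1)
        assert (m.tp, m.fp, m.fn, m.tn) == (1, 1, 1, 7)
        assert m.accuracy == pytest.approx(0.8)
        assert m.iou == pytest.approx(1 / 3)
        assert m.precision == pytest.approx(0.5)
        assert m.recall == pytest.approx(0.5)
        assert m.f1 == pytest.approx(0.5)

    def test_perfect_class(self):
        counts = np.zeros((8, 8))
        counts[0, 0] = 5
        counts[1, 1] = 5
        m = class_metrics(ConfusionMatrix(counts), "T-N")
        for v in (m.accuracy, m.iou, m.precision, m.recall, m.f1):
            assert v == pytest.approx(1.0)

    def test_absent_class_flagged(self):
        counts = np.zeros((8, 8))
        counts[1, 1] = 3
        m = class_metrics(ConfusionMatrix(counts), "T-N")
        assert m.undefined

    def test_pixel_loop_oracle(self, rng):
        for _ in range(25):
            t, p = random_label_pair(rng)
            if not ((t > 0) & (p > 0)).any():
                continue
            cm = confusion(t, p)
            for cls in range(1, 9):
                m = class_metrics(cm, cls)
                acc, iou, prec, rec, f1 = oracle_metrics(t, p, cls)
                for got, want in ((m.accuracy, acc), (m.iou, iou),
                                  (m.precision, prec), (m.recall, rec),
                                  (m.f1, f1)):
                    if np.isnan(want):
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(want, abs=1e-10)

    def test_f1_iou_identity(self, rng):
        for _ in range(25):
            t, p = random_label_pair(rng)
            cm = confusion(t, p)
            for cls in range(1, 9):
                m = class_metrics(cm, cls)
                if not np.isnan(m.iou):
                    assert m.f1 == pytest.approx(
                        2 * m.iou / (1 + m.iou), abs=1e-10)

    def test_recall_equals_normalized_diagonal(self, rng):
        t, p = random_label_pair(rng, shape=(30, 30))
        cm = confusion(t, p)
        diag = cm.diagonal()
        for cls in range(1, 9):
            m = class_metrics(cm, cls)
            if cm.counts[cls - 1].sum() > 0:
                assert m.recall == pytest.approx(diag[cls - 1])


class TestSplit:
    def test_paper_scale_sizes(self):
        split = split_dataset([f"i{k}" for k in range(417)], seed=0)
        assert len(split.train_ids) == 291
        assert len(split.val_ids) == 62
        assert len(split.test_ids) == 64

    def test_deterministic(self):
        ids = [f"i{k}" for k in range(20)]
        a = split_dataset(ids, seed=5)
        b = split_dataset(ids, seed=5)
        assert a == b

    def test_partition(self):
        ids = [f"i{k}" for k in range(23)]
        s = split_dataset(ids, seed=1)
        cells = [set(s.train_ids), set(s.val_ids), set(s.test_ids)]
        assert cells[0] | cells[1] | cells[2] == set(ids)
        assert not (cells[0] & cells[1] or cells[0] & cells[2]
                    or cells[1] & cells[2])

    def test_too_small(self):
        with pytest.raises(ValueError):
            split_dataset(["a", "b"], seed=0)


class TestAggregate:
    def _frame(self, accuracies, ious=None, f1s=None):
        ious = ious if ious is not None else accuracies
        f1s = f1s if f1s is not None else accuracies
        return pd.DataFrame({
            "class": list(CLASS_NAMES), "accuracy": accuracies, "iou": ious,
            "precision": accuracies, "recall": accuracies, "f1": f1s})

    def test_published_macro_averages(self):
        acc = [0.75, 0.79, 0.76, 0.85, 0.88, 0.83, 0.86, 0.94]
        iou = [0.70, 0.47, 0.61, 0.75, 0.81, 0.34, 0.59, 0.92]
        f1 = [0.56, 0.63, 0.76, 0.66, 0.64, 0.39, 0.54, 0.69]
        report = aggregate_runs([self._frame(acc, iou, f1)])
        assert round2(report.macro["accuracy"]) == 0.83
        assert round2(report.macro["iou"]) == 0.65
        assert round2(report.macro["f1"]) == 0.61

    def test_single_run_mean_and_zero_sd(self):
        report = aggregate_runs([self._frame([0.5] * 8)])
        assert np.allclose(report.mean["accuracy"], 0.5)
        assert np.allclose(report.sd["accuracy"], 0.0)

    def test_mean_sd_over_runs(self):
        r = aggregate_runs([self._frame([0.4] * 8), self._frame([0.6] * 8)])
        assert np.allclose(r.mean["iou"], 0.5)
        assert np.allclose(r.sd["iou"], 0.1)

    def test_inconsistent_class_sets_rejected(self):
        good = self._frame([0.5] * 8)
        bad = good.copy()
        bad.loc[0, "class"] = "bogus"
        with pytest.raises(ValueError):
            aggregate_runs([good, bad])

    def test_best_run_selection(self):
        runs = [self._frame([0.5] * 8), self._frame([0.7] * 8),
                self._frame([0.6] * 8)]
        report = aggregate_runs(runs)
        assert report.best_run == 1
        assert select_best_run(report) == 1

    def test_tie_goes_to_first(self):
        runs = [self._frame([0.7] * 8), self._frame([0.7] * 8)]
        assert aggregate_runs(runs).best_run == 0

    def test_display_table_layout(self):
        report = aggregate_runs([self._frame([0.5] * 8)])
        disp = report.display_table()
        assert list(disp["class"]) == list(CLASS_NAMES) + ["AVERAGE"]

    def test_round2_half_up(self):
        assert round2(0.60875) == 0.61
        assert round2(0.8325) == 0.83
        assert round2(0.645) == 0.65


class TestClassifier:
    @pytest.fixture(scope="class")
    def trained(self):
        spec = ht.SyntheticDatasetSpec.tiny(n_nodular=6, n_micronodular=6,
                                            seed=21)
        images = ht.generate_dataset(spec)
        clf = fit_baseline_classifier(images[:8] + images[-2:], window=9,
                                      seed=0, grid_stride=3)
        return images, clf

    def test_separable_two_class_sanity(self):
        rgb = np.zeros((60, 60, 3), np.uint8)
        rgb[:, :30] = (200, 60, 60)
        rgb[:, 30:] = (60, 60, 200)
        mask = np.zeros((60, 60), np.uint8)
        mask[:, :30] = 1
        mask[:, 30:] = 4
        rng = np.random.default_rng(0)
        noisy = np.clip(rgb.astype(int)
                        + rng.integers(-10, 10, rgb.shape), 1, 255
                        ).astype(np.uint8)
        im_n = LabeledImage(noisy, LabelMask(mask), "N", "a")
        clf = fit_baseline_classifier([im_n], window=5, seed=0,
                                      grid_stride=1,
                                      require_all_classes=False)
        pred = predict_labels(clf, im_n.pixels)
        target = eight_class_labels(mask, "N")
        acc = (pred == target).mean()
        assert acc > 0.95

    def test_deterministic(self, trained):
        images, clf = trained
        p1 = predict_labels(clf, images[0].pixels)
        p2 = predict_labels(clf, images[0].pixels)
        assert np.array_equal(p1, p2)

    def test_refit_identical(self, trained):
        images, clf = trained
        clf2 = fit_baseline_classifier(images[:8] + images[-2:], window=9,
                                       seed=0, grid_stride=3)
        assert np.array_equal(predict_labels(clf, images[0].pixels),
                              predict_labels(clf2, images[0].pixels))

    def test_output_shape(self, trained):
        images, clf = trained
        pred = predict_labels(clf, images[0].pixels)
        assert pred.shape == images[0].pixels.shape[:2]

    def test_missing_class_error(self):
        spec = ht.SyntheticDatasetSpec.tiny(n_nodular=2, n_micronodular=2,
                                            seed=5)
        images = ht.generate_dataset(spec)
        n_only = [im for im in images if im.subtype == "N"]
        with pytest.raises(ValueError, match="T-MN"):
            fit_baseline_classifier(n_only, window=9, seed=0)


class TestImportExport:
    def test_round_trip(self, tmp_path, rng):
        labels = rng.integers(0, 9, size=(20, 30)).astype(np.uint8)
        path = tmp_path / "pred.png"
        export_predictions(labels, path)
        back = import_predictions(path, expected_shape=(20, 30))
        assert np.array_equal(labels, back)

    def test_unknown_codes_rejected(self, tmp_path):
        labels = np.full((5, 5), 17, np.uint8)
        path = tmp_path / "bad.png"
        export_predictions(labels, path)
        with pytest.raises(ValueError, match="17"):
            import_predictions(path)

    def test_shape_mismatch(self, tmp_path):
        path = tmp_path / "p.png"
        export_predictions(np.zeros((4, 4), np.uint8), path)
        with pytest.raises(ValueError, match="shape"):
            import_predictions(path, expected_shape=(5, 5))


class TestPatches:
    def test_uniform_image_tiling(self):
        img = np.zeros((300, 300, 3), np.uint8)
        t = np.full((300, 300), 3, np.uint8)
        patches = extract_uniform_patches(img, t, t, size=100)
        assert len(patches) == 9
        assert all(p["class_code"] == 3 for p in patches)
        assert patches[0]["pixels"].shape == (100, 100, 3)

    def test_boundary_tile_excluded(self):
        img = np.zeros((100, 200, 3), np.uint8)
        t = np.full((100, 200), 2, np.uint8)
        p = t.copy()
        p[:, 150:] = 3  # second tile not uniform
        patches = extract_uniform_patches(img, t, p, size=100)
        assert len(patches) == 1
        assert patches[0]["col"] == 0

    def test_wrong_prediction_excluded(self):
        img = np.zeros((100, 100, 3), np.uint8)
        t = np.full((100, 100), 2, np.uint8)
        p = np.full((100, 100), 3, np.uint8)  # uniform but wrong
        assert extract_uniform_patches(img, t, p, size=100) == []

    def test_image_smaller_than_patch(self):
        img = np.zeros((50, 50, 3), np.uint8)
        t = np.full((50, 50), 1, np.uint8)
        assert extract_uniform_patches(img, t, t, size=100) == []


class TestTiledInference:
    @pytest.fixture(scope="class")
    def clf(self):
        spec = ht.SyntheticDatasetSpec.tiny(n_nodular=5, n_micronodular=5,
                                            seed=31)
        images = ht.generate_dataset(spec)
        return fit_baseline_classifier(images, window=9, seed=0,
                                       grid_stride=3)

    def test_output_shape(self, clf):
        spec = ht.SyntheticDatasetSpec.tiny(seed=32)
        im = ht.render_subtype_image("N", spec, np.random.default_rng(2))
        out = tiled_inference(clf, im.pixels, tile=64, overlap=8)
        assert out.shape == im.pixels.shape[:2]

    def test_tile_larger_than_image(self, clf):
        spec = ht.SyntheticDatasetSpec.tiny(seed=33)
        im = ht.render_subtype_image("MN", spec, np.random.default_rng(3))
        out = tiled_inference(clf, im.pixels, tile=4096, overlap=0)
        assert np.array_equal(out, predict_labels(clf, im.pixels))

    def test_uniform_texture_consistency(self, clf):
        rng = np.random.default_rng(4)
        img = np.clip(rng.normal(185, 16, size=(120, 160, 3)), 1, 255
                      ).astype(np.uint8)
        whole = predict_labels(clf, img)
        tiled = tiled_inference(clf, img, tile=80, overlap=16)
        assert (whole == tiled).mean() >= 0.99

    def test_bad_overlap(self, clf):
        with pytest.raises(ValueError):
            tiled_inference(clf, np.zeros((10, 10, 3), np.uint8),
                            tile=8, overlap=8)


def test_macro_average_is_plain_mean():
    assert macro_average([0.0, 1.0]) == pytest.approx(0.5)
    vals = [0.70, 0.47, 0.61, 0.75, 0.81, 0.34, 0.59, 0.92]
    assert macro_average(vals) == pytest.approx(np.mean(vals))
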
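"""Eight-class pixel segmentation evaluation calculus.

Classes are component x subtype::

    1 T-N   2 TT-N   3 PC-N   4 S-N   5 T-MN   6 TT-MN   7 PC-MN   8 S-MN

with code 0 reserved for unannotated pixels (excluded from training,
confusion counting and metrics).

The evaluation stack (confusion matrices, one-vs-rest accuracy / IoU /
precision / recall / F1, repeated 70/15/15 resampling with mean +- SD and
macro averages, best-run selection, uniform-patch mining and tiled
inference) wraps a pluggable pixel-classifier contract.  The bundled
baseline is a desk-scale random-forest over local window statistics; any
externally produced label map can be evaluated via import_predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .components import LUMA_WEIGHTS
from .synthetic import COMPONENT_CODES, COMPONENTS, LabeledImage

__all__ = [
    "CLASS_NAMES", "eight_class_labels", "ConfusionMatrix", "ClassMetrics",
    "DatasetSplit", "RunReport", "PixelClassifier", "split_dataset",
    "fit_baseline_classifier", "predict_labels", "import_predictions",
    "export_predictions", "confusion", "class_metrics", "macro_average",
    "round2", "aggregate_runs", "select_best_run", "extract_uniform_patches",
    "tiled_inference", "run_protocol",
]

CLASS_NAMES = ("T-N", "TT-N", "PC-N", "S-N", "T-MN", "TT-MN", "PC-MN", "S-MN")
_N_CLASSES = 8
METRIC_NAMES = ("accuracy", "iou", "precision", "recall", "f1")


def eight_class_labels(mask_labels: np.ndarray, subtype: str) -> np.ndarray:
    """Map component codes {0..4} + image subtype to 8-class codes."""
    labels = np.asarray(mask_labels)
    out = labels.astype(np.uint8).copy()
    if subtype == "MN":
        out[labels > 0] += 4
    elif subtype != "N":
        raise ValueError(f"unknown subtype {subtype!r}")
    return out


def class_name_to_code(name: str) -> int:
    return CLASS_NAMES.index(name) + 1


# ---------------------------------------------------------------------------
# confusion matrix and per-class metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """8x8 target-by-predicted counts with a row-normalized view."""

    counts: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES
    prenormalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (len(self.class_names),) * 2:
            raise ValueError("confusion matrix shape mismatch")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_normalized(cls, matrix, class_names: tuple[str, ...] = CLASS_NAMES
                        ) -> "ConfusionMatrix":
        """Wrap a matrix that already is the row-normalized view.

        Entries are taken verbatim (printed tables may carry rounded rows
        that do not sum to exactly 1; they are not re-normalized).
        """
        return cls(counts=np.asarray(matrix, dtype=np.float64),
                   class_names=class_names, prenormalized=True)

    @property
    def normalized(self) -> np.ndarray:
        if self.prenormalized:
            return self.counts
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(sums > 0, self.counts / sums, 0.0)
        return norm

    def diagonal(self) -> np.ndarray:
        """Per-class recall (the diagonal of the normalized view)."""
        return np.diag(self.normalized)

    def query(self, target: str, predicted: str) -> float:
        """Normalized confusion rate for (target class, predicted class)."""
        return float(self.normalized[self.class_names.index(target),
                                     self.class_names.index(predicted)])

    def to_frame(self, normalized: bool = True) -> pd.DataFrame:
        data = self.normalized if normalized else self.counts
        return pd.DataFrame(data, index=list(self.class_names),
                            columns=list(self.class_names))


def confusion(target: np.ndarray, predicted: np.ndarray) -> ConfusionMatrix:
    """Pixel-level confusion counts; code-0 target pixels are excluded."""
    target = np.asarray(target)
    predicted = np.asarray(predicted)
    if target.shape != predicted.shape:
        raise ValueError("target and predicted shapes differ")
    keep = (target > 0) & (predicted > 0)
    t = target[keep].astype(np.int64) - 1
    p = predicted[keep].astype(np.int64) - 1
    if t.size == 0:
        raise ValueError("no annotated pixels to score")
    if t.max() >= _N_CLASSES or p.max() >= _N_CLASSES:
        raise ValueError("label codes outside 1..8")
    counts = np.bincount(t * _N_CLASSES + p,
                         minlength=_N_CLASSES * _N_CLASSES)
    return ConfusionMatrix(counts.reshape(_N_CLASSES, _N_CLASSES))


@dataclass
class ClassMetrics:
    tp: float
    tn: float
    fp: float
    fn: float
    accuracy: float
    iou: float
    precision: float
    recall: float
    f1: float
    undefined: bool = False


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def class_metrics(cm: ConfusionMatrix, cls: int | str) -> ClassMetrics:
    """One-vs-rest counts and direct-substitution metrics for one class.

    ``cls`` is a class name or 1-based code.  If the class is absent from
    both target and prediction the result is flagged undefined.
    """
    k = (cm.class_names.index(cls) if isinstance(cls, str)
         else int(cls) - 1)
    c = cm.counts
    total = c.sum()
    tp = c[k, k]
    fn = c[k, :].sum() - tp
    fp = c[:, k].sum() - tp
    tn = total - tp - fn - fp
    undefined = (tp + fn + fp) == 0
    accuracy = _safe_div(tp + tn, total)
    iou = _safe_div(tp, tp + fp + fn)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    if precision > 0 or recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1 = float("nan") if undefined else 0.0
    return ClassMetrics(tp=float(tp), tn=float(tn), fp=float(fp),
                        fn=float(fn), accuracy=accuracy, iou=iou,
                        precision=precision, recall=recall, f1=f1,
                        undefined=bool(undefined))


def macro_average(values: Iterable[float]) -> float:
    """Unweighted mean over per-class values (NaNs propagate)."""
    arr = np.asarray(list(values), dtype=np.float64)
    return float(arr.mean())


def round2(x: float) -> float:
    """Display rounding to 2 decimals, half away from zero."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# dataset splitting and the run protocol
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fractions: tuple[float, float, float]
    seed: int


def split_dataset(ids: Sequence[str],
                  fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                  seed: int = 0) -> DatasetSplit:
    """Uniform random partition: floor(train), floor(val), remainder."""
    ids = list(ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 ids to split")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    n_train = int(math.floor(fractions[0] * n))
    n_val = int(math.floor(fractions[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("a partition cell is empty at this dataset size")
    perm = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in perm]
    return DatasetSplit(
        train_ids=tuple(shuffled[:n_train]),
        val_ids=tuple(shuffled[n_train:n_train + n_val]),
        test_ids=tuple(shuffled[n_train + n_val:]),
        fractions=tuple(fractions), seed=seed)


# ---------------------------------------------------------------------------
# baseline pixel classifier
# ---------------------------------------------------------------------------

@dataclass
class PixelClassifier:
    """Fitted per-pixel classifier over local window statistics."""

    model: RandomForestClassifier
    window: int
    training_ids: tuple[str, ...]
    seed: int

    @property
    def n_features(self) -> int:
        return 6


def _window_features(pixels: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel feature maps: window means of R/G/B and gray, window
    gray std, and window mean absolute horizontal gradient."""
    rgb = pixels.astype(np.float64)
    gray = rgb @ np.asarray(LUMA_WEIGHTS)
    size = (window, window)
    feats = [ndimage.uniform_filter(rgb[:, :, c], size) for c in range(3)]
    gmean = ndimage.uniform_filter(gray, size)
    gsq = ndimage.uniform_filter(gray * gray, size)
    gstd = np.sqrt(np.maximum(gsq - gmean * gmean, 0.0))
    grad = np.abs(np.diff(gray, axis=1, prepend=gray[:, :1]))
    feats += [gmean, gstd, ndimage.uniform_filter(grad, size)]
    return np.stack(feats, axis=-1)


def fit_baseline_classifier(train: Sequence[LabeledImage], window: int = 15,
                            seed: int = 0, grid_stride: int = 5,
                            max_samples: int = 120_000,
                            require_all_classes: bool = True
                            ) -> PixelClassifier:
    """Fit the desk-scale baseline on grid-sampled annotated pixels.

    ``require_all_classes=False`` permits reduced-class sanity fits.
    """
    xs, ys = [], []
    for im in train:
        fm = _window_features(im.pixels, window)
        labels = eight_class_labels(im.mask.labels, im.subtype)
        sl = (slice(None, None, grid_stride),) * 2
        lab = labels[sl]
        keep = lab > 0
        xs.append(fm[sl][keep])
        ys.append(lab[keep])
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    present = set(np.unique(y).tolist())
    missing = [CLASS_NAMES[c - 1] for c in range(1, 9) if c not in present]
    if missing and require_all_classes:
        raise ValueError(
            "classes absent from training pixels: " + ", ".join(missing))
    if X.shape[0] > max_samples:
        sel = np.random.default_rng(seed).choice(
            X.shape[0], size=max_samples, replace=False)
        X, y = X[sel], y[sel]
    model = RandomForestClassifier(
        n_estimators=16, max_depth=14, min_samples_leaf=5,
        random_state=seed, n_jobs=1)
    model.fit(X, y)
    return PixelClassifier(model=model, window=window,
                           training_ids=tuple(im.image_id for im in train),
                           seed=seed)


def predict_labels(clf: PixelClassifier, image: np.ndarray) -> np.ndarray:
    """Predict an 8-class label raster with the same shape as the input."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    fm = _window_features(image, clf.window)
    H, W = image.shape[:2]
    pred = clf.model.predict(fm.reshape(-1, fm.shape[-1]))
    return pred.reshape(H, W).astype(np.uint8)


def export_predictions(labels: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(labels, dtype=np.uint8), mode="L").save(path)


def import_predictions(path: str | Path,
                       expected_shape: tuple[int, int] | None = None
                       ) -> np.ndarray:
    """Load a single-channel PNG label map and validate its codes."""
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError("prediction PNG must be single-channel")
    bad = np.setdiff1d(np.unique(arr), np.arange(_N_CLASSES + 1))
    if bad.size:
        raise ValueError(
            f"unknown label codes in {path}: {bad.tolist()}")
    if expected_shape is not None and arr.shape != tuple(expected_shape):
        raise ValueError(
            f"prediction shape {arr.shape} != expected {expected_shape}")
    return arr


# ---------------------------------------------------------------------------
# run aggregation
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    per_run: pd.DataFrame      # columns: run, class + METRIC_NAMES
    mean: pd.DataFrame         # index class, columns METRIC_NAMES
    sd: pd.DataFrame
    macro: dict[str, float]    # unweighted over the 8 per-class means
    best_run: int
    confusions: list[ConfusionMatrix] = field(default_factory=list)
    run_seeds: tuple[int, ...] = ()

    def display_table(self) -> pd.DataFrame:
        """2-decimal mean +- SD layout with a MACRO row."""
        rows = []
        for cls in CLASS_NAMES:
            row = {"class": cls}
            for m in METRIC_NAMES:
                row[m] = round2(self.mean.loc[cls, m])
                row[m + "_sd"] = round2(self.sd.loc[cls, m])
            rows.append(row)
        macro_row = {"class": "AVERAGE"}
        for m in METRIC_NAMES:
            macro_row[m] = round2(self.macro[m])
            macro_row[m + "_sd"] = float("nan")
        rows.append(macro_row)
        return pd.DataFrame(rows)


def aggregate_runs(reports: Sequence[pd.DataFrame] | pd.DataFrame
                   ) -> RunReport:
    """Aggregate per-run per-class metrics into mean/SD + macro averages.

    ``reports`` is either a list of per-run frames (one row per class,
    columns METRIC_NAMES, indexed or keyed by 'class') or a single long
    frame with a 'run' column.
    """
    if isinstance(reports, pd.DataFrame):
        long = reports.copy()
    else:
        if len(reports) == 0:
            raise ValueError("need at least one run")
        frames = []
        for r, df in enumerate(reports):
            df = df.copy()
            df["run"] = r
            frames.append(df)
        long = pd.concat(frames, ignore_index=True)
    classes = set(long["class"])
    for r, grp in long.groupby("run"):
        if set(grp["class"]) != classes:
            raise ValueError("inconsistent class sets across runs")
    if classes != set(CLASS_NAMES):
        raise ValueError("expected exactly the 8 segmentation classes")
    mean = (long.groupby("class")[list(METRIC_NAMES)].mean()
            .reindex(list(CLASS_NAMES)))
    sd = (long.groupby("class")[list(METRIC_NAMES)].std(ddof=0)
          .reindex(list(CLASS_NAMES)))
    macro = {m: macro_average(mean[m].to_numpy()) for m in METRIC_NAMES}
    per_run_macro_iou = long.groupby("run")["iou"].mean()
    best_run = int(per_run_macro_iou.to_numpy().argmax())
    return RunReport(per_run=long, mean=mean, sd=sd, macro=macro,
                     best_run=best_run)


def select_best_run(report: RunReport, criterion: str = "iou") -> int:
    """Argmax of the per-run macro metric; ties go to the lower index."""
    per_run = report.per_run.groupby("run")[criterion].mean()
    return int(per_run.to_numpy().argmax())


# ---------------------------------------------------------------------------
# patch mining and tiled inference
# ---------------------------------------------------------------------------

def extract_uniform_patches(image: np.ndarray, target: np.ndarray,
                            predicted: np.ndarray, size: int = 100
                            ) -> list[dict]:
    """Non-overlapping size x size tiles that are uniformly and correctly
    predicted (one predicted class everywhere, equal to the target)."""
    image = np.asarray(image)
    target = np.asarray(target)
    predicted = np.asarray(predicted)
    if target.shape != predicted.shape or image.shape[:2] != target.shape:
        raise ValueError("rasters are not aligned")
    H, W = target.shape
    patches = []
    for r in range(0, H - size + 1, size):
        for c in range(0, W - size + 1, size):
            tp = predicted[r:r + size, c:c + size]
            first = tp.flat[0]
            if first == 0 or not np.all(tp == first):
                continue
            if not np.all(target[r:r + size, c:c + size] == first):
                continue
            patches.append({"row": r, "col": c, "class_code": int(first),
                            "class_name": CLASS_NAMES[int(first) - 1],
                            "pixels": image[r:r + size, c:c + size].copy()})
    return patches


def tiled_inference(clf: PixelClassifier, image: np.ndarray, tile: int,
                    overlap: int = 0) -> np.ndarray:
    """Tile-wise prediction; overlaps resolved by the nearest tile center."""
    if overlap < 0 or tile <= overlap:
        raise ValueError("need tile > overlap >= 0")
    image = np.asarray(image)
    H, W = image.shape[:2]
    if tile >= H and tile >= W:
        return predict_labels(clf, image)
    stride = tile - overlap

    def starts(dim: int) -> list[int]:
        if tile >= dim:
            return [0]
        s = list(range(0, dim - tile, stride))
        s.append(dim - tile)
        return s

    out = np.zeros((H, W), dtype=np.uint8)
    best = np.full((H, W), np.inf)
    for r0 in starts(H):
        for c0 in starts(W):
            r1, c1 = min(r0 + tile, H), min(c0 + tile, W)
            pred = predict_labels(clf, image[r0:r1, c0:c1])
            cy, cx = (r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0
            yy, xx = np.mgrid[r0:r1, c0:c1]
            dist = (yy - cy) ** 2 + (xx - cx) ** 2
            sel = dist < best[r0:r1, c0:c1]
            out[r0:r1, c0:c1][sel] = pred[sel]
            best[r0:r1, c0:c1][sel] = dist[sel]
    return out


# ---------------------------------------------------------------------------
# the end-to-end resampling protocol
# ---------------------------------------------------------------------------

def _metrics_frame(cm: ConfusionMatrix) -> pd.DataFrame:
    rows = []
    for cls in CLASS_NAMES:
        m = class_metrics(cm, cls)
        rows.append({"class": cls, "accuracy": m.accuracy, "iou": m.iou,
                     "precision": m.precision, "recall": m.recall,
                     "f1": m.f1})
    return pd.DataFrame(rows)


def run_protocol(dataset: Sequence[LabeledImage], runs: int = 10,
                 fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                 window: int = 15, seed: int = 0) -> RunReport:
    """Repeat split -> fit -> evaluate-on-test ``runs`` times.

    Each run draws a fresh 70/15/15 split (validation images are held out
    but unused by the baseline), fits the baseline classifier on the
    training images and scores the pooled confusion matrix over the test
    images.  Deterministic in ``seed``.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    by_id = {im.image_id: im for im in dataset}
    ids = list(by_id)
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(runs)]
    frames = []
    confusions = []
    for r in range(runs):
        split = split_dataset(ids, fractions, seed=run_seeds[r])
        clf = fit_baseline_classifier(
            [by_id[i] for i in split.train_ids], window=window,
            seed=run_seeds[r])
        total = np.zeros((_N_CLASSES, _N_CLASSES))
        for i in split.test_ids:
            im = by_id[i]
            pred = predict_labels(clf, im.pixels)
            cm = confusion(eight_class_labels(im.mask.labels, im.subtype),
                           pred)
            total += cm.counts
        cm = ConfusionMatrix(total)
        confusions.append(cm)
        frames.append(_metrics_frame(cm))
    report = aggregate_runs(frames)
    report.confusions = confusions
    report.run_seeds = tuple(run_seeds)
    return report
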
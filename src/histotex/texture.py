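"""Trimmed-GLCM Haralick texture features and literal central moments.

Pipeline per component image::

    gray (8-bit) --quantize--> levels {1..9} --glcm--> 9x9 counts
        --trim_and_normalize--> 8x8 probabilities --haralick_features--> f1..f14

Quantization uses the fixed range [0, 255]; level 1 therefore contains
every background (black) pixel, and dropping the first row and column of
the 9x9 co-occurrence matrix purges all pixel pairs that touch the
background.  This conflates genuinely dark tissue (gray 1..28) with
background; that is the documented behavior, the synthetic generator
keeps tissue well above that range.

Conventions (uniform across features, chosen for internal comparability):

* natural logarithms everywhere; ``0 * log 0 == 0``;
* the information measures of correlation use ``log(q + 1e-12)`` inside
  entropy terms built from products of marginals;
* the "variance" feature f4 is centered on the row-marginal mean;
* f7 (sum variance) is centered on the sum average f6;
* degenerate inputs (single occupied level) yield 0 for correlation-type
  features (f3, f12, f13, f14).

The histogram moments implement the unstandardized central-moment formula
``m_k = sum((x - m)^k) / n`` literally for k = 2, 3, 4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .components import ComponentImage, GrayImage, to_grayscale
from .synthetic import COMPONENTS, LabeledImage

__all__ = [
    "LevelImage", "GLCMatrix", "TrimmedGLCM", "HaralickVector",
    "MomentVector", "HARALICK_NAMES", "MOMENT_NAMES", "FEATURE_COLUMNS",
    "quantize", "glcm", "trim_and_normalize", "haralick_features",
    "histogram_moments", "build_feature_table",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12

HARALICK_NAMES = (
    "energy",                    # f1  angular second moment
    "contrast",                  # f2
    "correlation",               # f3
    "variance",                  # f4
    "homogeneity",               # f5  inverse difference moment
    "sum_average",               # f6
    "sum_variance",              # f7
    "sum_entropy",               # f8
    "entropy",                   # f9
    "difference_variance",       # f10
    "difference_entropy",        # f11
    "imc1",                      # f12 information measure of correlation I
    "imc2",                      # f13 information measure of correlation II
    "max_correlation_coeff",     # f14
)
MOMENT_NAMES = ("variance_eq1", "skewness_eq1", "kurtosis_eq1")
#: the 17 feature columns of a FeatureTable (14 Haralick + 3 moments)
FEATURE_COLUMNS = HARALICK_NAMES + MOMENT_NAMES


@dataclass
class LevelImage:
    levels: np.ndarray  # int raster, values in {1..n_levels}
    n_levels: int = 9


@dataclass
class GLCMatrix:
    counts: np.ndarray                      # (L, L) ints
    offset: tuple[int, int] = (0, 1)
    symmetric: bool = False


@dataclass
class TrimmedGLCM:
    """Background-purged co-occurrence probabilities (8x8 by default)."""

    p: np.ndarray
    n_pairs: int

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0

    @property
    def px(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def py(self) -> np.ndarray:
        return self.p.sum(axis=0)

    @property
    def p_sum(self) -> np.ndarray:
        """p_{x+y}(k) for k = 2..2L, returned as array indexed k-2."""
        L = self.p.shape[0]
        out = np.zeros(2 * L - 1)
        for i in range(L):
            for j in range(L):
                out[i + j] += self.p[i, j]
        return out

    @property
    def p_diff(self) -> np.ndarray:
        """p_{|x-y|}(k) for k = 0..L-1."""
        L = self.p.shape[0]
        out = np.zeros(L)
        for i in range(L):
            for j in range(L):
                out[abs(i - j)] += self.p[i, j]
        return out


@dataclass
class HaralickVector:
    values: dict[str, float]
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        missing = set(HARALICK_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")

    def __len__(self) -> int:
        return len(HARALICK_NAMES)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in HARALICK_NAMES])


@dataclass
class MomentVector:
    mean: float
    m2: float
    m3: float
    m4: float
    n: int


def quantize(gray: GrayImage | np.ndarray, levels: int = 9) -> LevelImage:
    """Uniform quantization of 8-bit gray over the fixed range [0, 255].

    ``level(g) = floor(g * levels / 256) + 1`` so g=0 -> 1, g=255 -> levels.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    g = gray.pixels if isinstance(gray, GrayImage) else np.asarray(gray)
    if g.dtype != np.uint8:
        if np.any((g < 0) | (g > 255)):
            raise ValueError("gray values must lie in [0, 255]")
        g = g.astype(np.uint8)
    lv = (g.astype(np.int64) * levels) // 256 + 1
    return LevelImage(levels=lv, n_levels=levels)


def glcm(levels: LevelImage) -> GLCMatrix:
    """Horizontal offset-1 co-occurrence counts, no symmetrization."""
    lv = levels.levels
    L = levels.n_levels
    if lv.shape[1] < 2:
        raise ValueError("image must have at least 2 columns")
    left = lv[:, :-1].ravel() - 1
    right = lv[:, 1:].ravel() - 1
    counts = np.bincount(left * L + right, minlength=L * L).reshape(L, L)
    return GLCMatrix(counts=counts)


def trim_and_normalize(g: GLCMatrix) -> TrimmedGLCM:
    """Drop the first row and column (background level) and normalize."""
    counts = np.asarray(g.counts)
    if counts.shape[0] != counts.shape[1] or counts.shape[0] < 2:
        raise ValueError("expected a square count matrix of size >= 2")
    trimmed = counts[1:, 1:].astype(np.float64)
    n_pairs = int(trimmed.sum())
    if n_pairs == 0:
        return TrimmedGLCM(p=np.zeros_like(trimmed), n_pairs=0)
    return TrimmedGLCM(p=trimmed / n_pairs, n_pairs=n_pairs)


def _entropy(q: np.ndarray) -> float:
    q = q[q > 0]
    return float(-(q * np.log(q)).sum())


def haralick_features(t: TrimmedGLCM) -> HaralickVector:
    """The 14 Haralick (1973) features of a trimmed, normalized GLCM."""
    if t.empty:
        raise ValueError("empty TrimmedGLCM: features are missing, not zero")
    p = t.p
    L = p.shape[0]
    idx = np.arange(1, L + 1, dtype=np.float64)  # levels relabeled 1..L
    i = idx[:, None]
    j = idx[None, :]
    px = t.px
    py = t.py
    psum = t.p_sum          # k = 2..2L
    pdiff = t.p_diff        # k = 0..L-1
    ksum = np.arange(2, 2 * L + 1, dtype=np.float64)
    kdiff = np.arange(0, L, dtype=np.float64)
    flags: list[str] = []

    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    sd_x = float(np.sqrt(((idx - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((idx - mu_y) ** 2 * py).sum()))

    f1 = float((p ** 2).sum())
    f2 = float((kdiff ** 2 * pdiff).sum())
    if sd_x > 0 and sd_y > 0:
        f3 = float(((i * j * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        f3 = 0.0
        flags.append("degenerate_correlation")
    f4 = float(((i - mu_x) ** 2 * p).sum())
    f5 = float((p / (1.0 + (i - j) ** 2)).sum())
    f6 = float((ksum * psum).sum())
    f7 = float(((ksum - f6) ** 2 * psum).sum())
    f8 = _entropy(psum)
    f9 = _entropy(p.ravel())
    mu_d = float((kdiff * pdiff).sum())
    f10 = float(((kdiff - mu_d) ** 2 * pdiff).sum())
    f11 = _entropy(pdiff)

    hx = _entropy(px)
    hy = _entropy(py)
    pxy = px[:, None] * py[None, :]
    hxy1 = float(-(p * np.log(pxy + _EPS)).sum())
    hxy2 = float(-(pxy * np.log(pxy + _EPS)).sum())
    denom = max(hx, hy)
    if denom > 0:
        f12 = (f9 - hxy1) / denom
    else:
        f12 = 0.0
        flags.append("degenerate_imc1")
    f13 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - f9)))))

    # f14: sqrt of the second-largest eigenvalue of
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)).
    # Q = D1^-1 P D2^-1 P^T is similar to M M^T with
    # M = D1^-1/2 P D2^-1/2, so eigenvalues are the squared singular
    # values of M: real, non-negative, largest exactly 1.
    keep_i = px > 0
    keep_k = py > 0
    if keep_i.sum() >= 2 and keep_k.sum() >= 2:
        P = p[np.ix_(keep_i, keep_k)]
        M = P / np.sqrt(px[keep_i])[:, None] / np.sqrt(py[keep_k])[None, :]
        sv = np.linalg.svd(M, compute_uv=False)
        f14 = float(min(sv[1], 1.0)) if sv.size >= 2 else 0.0
    else:
        f14 = 0.0
        flags.append("degenerate_mcc")

    values = dict(zip(HARALICK_NAMES,
                      (f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11,
                       f12, f13, f14)))
    return HaralickVector(values=values, flags=tuple(flags))


def histogram_moments(img: ComponentImage) -> MomentVector:
    """Literal central moments m_k = sum((x - m)^k) / n of foreground gray."""
    if img.empty:
        raise ValueError("empty component: moments are missing, not zero")
    gray = to_grayscale(img).pixels
    if img.foreground is not None:
        x = gray[img.foreground].astype(np.float64)
    else:
        x = gray[img.pixels.any(axis=-1)].astype(np.float64)
    m = float(x.mean())
    d = x - m
    return MomentVector(mean=m,
                        m2=float((d ** 2).mean()),
                        m3=float((d ** 3).mean()),
                        m4=float((d ** 4).mean()),
                        n=int(x.size))


def _image_features(image: LabeledImage) -> list[dict]:
    from .components import extract_component
    rows = []
    for comp in COMPONENTS:
        ci = extract_component(image.pixels, image.mask, comp,
                               parent_id=image.image_id,
                               subtype=image.subtype)
        row: dict = {"image_id": image.image_id, "subtype": image.subtype,
                     "component": comp,
                     "n_foreground": ci.foreground_count}
        if ci.empty:
            row.update({name: np.nan for name in FEATURE_COLUMNS})
            rows.append(row)
            continue
        t = trim_and_normalize(glcm(quantize(to_grayscale(ci))))
        if t.empty:
            row.update({name: np.nan for name in HARALICK_NAMES})
        else:
            row.update(haralick_features(t).values)
        mv = histogram_moments(ci)
        row["variance_eq1"] = mv.m2
        row["skewness_eq1"] = mv.m3
        row["kurtosis_eq1"] = mv.m4
        rows.append(row)
    return rows


def build_feature_table(dataset: Sequence[LabeledImage] | Iterable[LabeledImage]
                        ) -> pd.DataFrame:
    """One row per (image, component): 17 feature columns + bookkeeping.

    Empty components carry NaN markers, never silent zeros.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset is empty")
    rows: list[dict] = []
    for image in dataset:
        try:
            rows.extend(_image_features(image))
        except Exception:
            logger.exception("feature extraction failed for %s",
                             image.image_id)
    cols = (["image_id", "subtype", "component", "n_foreground"]
            + list(FEATURE_COLUMNS))
    return pd.DataFrame(rows, columns=cols)
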
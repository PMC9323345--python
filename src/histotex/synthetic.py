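"""Seeded generator of labeled two-subtype synthetic "histology" images.

Every generated image carries an exact four-component ground-truth mask:

====  ====  =========================================================
code  name  geometry
====  ====  =========================================================
0     --    unannotated border pixels (excluded everywhere downstream)
1     T     nodule core (nodule eroded by ``rim_width_px``)
2     TT    palisade rim (nodule minus core)
3     PC    cleft annulus of width ``cleft_width_px`` outside a nodule
4     S     stroma (everything else annotated)
====  ====  =========================================================

The two subtypes differ in nodule geometry (few large nodules for ``N``,
many small ones for ``MN``, split at a physical diameter bound) and in
per-component texture statistics.  The strength of the nodular vs.
micronodular texture difference is controlled per component by the
``texture_divergence`` map: 0 means the two subtypes draw their texture
parameters from identical distributions, 1 means maximally different.

In addition to the grayscale-visible divergence, the stroma and nodule
core receive a fixed *luma-neutral* stain-tone shift between subtypes
(red up / green down with zero net effect on the 8-bit grayscale).  This
gives a pixel-level classifier the subtype context that a whole-image
model would get from global appearance, without perturbing any of the
grayscale texture statistics computed downstream.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "COMPONENTS",
    "COMPONENT_CODES",
    "SUBTYPES",
    "SyntheticDatasetSpec",
    "LabelMask",
    "LabeledImage",
    "generate_dataset",
    "render_subtype_image",
    "write_dataset",
    "read_dataset",
]

COMPONENTS = ("T", "TT", "PC", "S")
COMPONENT_CODES: Mapping[str, int] = {"T": 1, "TT": 2, "PC": 3, "S": 4}
CODE_COMPONENTS: Mapping[int, str] = {v: k for k, v in COMPONENT_CODES.items()}
SUBTYPES = ("N", "MN")

#: ITU-R BT.601 luma weights; kept consistent with components.to_grayscale.
_LUMA = (0.2989, 0.5870, 0.1140)


def _default_divergence() -> dict[str, float]:
    return {"T": 0.6, "TT": 0.0, "PC": 1.0, "S": 0.15}


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters of a synthetic dataset; a pure value object.

    The full-scale defaults mirror the acquisition geometry of the study
    setting this generator emulates: 1920x1017 px frames at a pixel area
    of 0.038 um^2 (i.e. ~0.195 um/px), 216 nodular and 201 micronodular
    images, and a micronodule diameter bound of 150 um (0.15 mm).
    """

    n_nodular: int = 216
    n_micronodular: int = 201
    image_height_px: int = 1017
    image_width_px: int = 1920
    microns_per_pixel: float = 0.038**0.5
    micronodule_max_diameter_um: float = 150.0
    rim_width_px: int = 24
    cleft_width_px: int = 16
    texture_divergence: Mapping[str, float] = field(default_factory=_default_divergence)
    cleft_presence_prob: float = 0.95
    seed: int = 0
    border_px: int = 2

    # -- presets ---------------------------------------------------------
    @classmethod
    def default(cls) -> "SyntheticDatasetSpec":
        """Full-scale preset (1920x1017 px, 216 + 201 images)."""
        return cls()

    @classmethod
    def desk_scale(cls, n_nodular: int = 40, n_micronodular: int = 40,
                   seed: int = 0, **overrides) -> "SyntheticDatasetSpec":
        """Desk-scale preset: 512x384 px at 4x coarser sampling."""
        kw = dict(
            n_nodular=n_nodular,
            n_micronodular=n_micronodular,
            image_height_px=384,
            image_width_px=512,
            microns_per_pixel=4 * 0.038**0.5,
            rim_width_px=6,
            cleft_width_px=4,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def tiny(cls, n_nodular: int = 5, n_micronodular: int = 5,
             seed: int = 0, **overrides) -> "SyntheticDatasetSpec":
        """Very small preset for fast unit tests (128x96 px)."""
        kw = dict(
            n_nodular=n_nodular,
            n_micronodular=n_micronodular,
            image_height_px=96,
            image_width_px=128,
            microns_per_pixel=16 * 0.038**0.5,
            rim_width_px=3,
            cleft_width_px=2,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    # -- derived ---------------------------------------------------------
    @property
    def micronodule_max_diameter_px(self) -> float:
        return self.micronodule_max_diameter_um / self.microns_per_pixel

    @property
    def pixel_area_um2(self) -> float:
        return self.microns_per_pixel**2

    def replace(self, **changes) -> "SyntheticDatasetSpec":
        return dataclasses.replace(self, **changes)

    def validate(self) -> None:
        if self.n_nodular <= 0 or self.n_micronodular <= 0:
            raise ValueError("image counts must be positive")
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.micronodule_max_diameter_um <= 0:
            raise ValueError("micronodule_max_diameter_um must be positive")
        if self.rim_width_px < 1 or self.cleft_width_px < 1:
            raise ValueError("rim and cleft widths must be >= 1 px")
        if not 0.0 <= self.cleft_presence_prob <= 1.0:
            raise ValueError("cleft_presence_prob must be in [0, 1]")
        for comp in COMPONENTS:
            d = float(self.texture_divergence.get(comp, 0.0))
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"texture_divergence[{comp}] must be in [0, 1]")
        bound = self.micronodule_max_diameter_px
        margin = self.border_px + self.cleft_width_px + 2
        usable = min(self.image_height_px, self.image_width_px) - 2 * margin
        if 1.05 * bound >= 0.95 * usable:
            raise ValueError(
                "a nodular-subtype nodule (diameter > "
                f"{bound:.0f} px at {self.microns_per_pixel:.3f} um/px) "
                "cannot fit in the image; enlarge the image or coarsen "
                "microns_per_pixel"
            )
        mn_lo = max(0.22 * bound, 2.0 * (self.rim_width_px + 3))
        if mn_lo >= 0.5 * bound:
            raise ValueError(
                "rim_width_px too large for micronodules at this scale"
            )


@dataclass
class LabelMask:
    """Integer raster of component codes {0..4}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2-D")
        bad = np.setdiff1d(np.unique(self.labels), np.arange(5))
        if bad.size:
            raise ValueError(f"mask contains codes outside 0..4: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def component_count(self, component: str) -> int:
        return int(np.count_nonzero(self.labels == COMPONENT_CODES[component]))


@dataclass
class LabeledImage:
    pixels: np.ndarray  # (H, W, 3) uint8
    mask: LabelMask
    subtype: str
    image_id: str
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != self.mask.shape:
            raise ValueError("pixels and mask shapes differ")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")


# ---------------------------------------------------------------------------
# texture parameterization
# ---------------------------------------------------------------------------
# Base (nodular) appearance per component and the delta applied for the
# micronodular subtype, scaled by texture_divergence[component].  "rgb" is
# the mean tissue color, "amp" the gray-noise amplitude, "sigma" the noise
# correlation length (y, x).
_BASE = {
    "T": {"rgb": (152.0, 120.0, 170.0), "amp": 24.0, "sigma": (1.2, 1.2)},
    "TT": {"rgb": (146.0, 114.0, 165.0), "amp": 20.0, "sigma": (1.0, 1.0)},
    "PC": {"rgb": (228.0, 221.0, 232.0), "amp": 9.0, "sigma": (1.5, 1.5)},
    "S": {"rgb": (205.0, 165.0, 182.0), "amp": 16.0, "sigma": (0.7, 2.6)},
}
_MN_DELTA = {
    "T": {"rgb": (-5.0, -6.0, -2.0), "amp": 0.0, "sigma_scale": 0.3},
    "TT": {"rgb": (0.0, 0.0, 0.0), "amp": 0.0, "sigma_scale": 0.0},
    "PC": {"rgb": (-40.0, -28.0, -22.0), "amp": 14.0, "sigma_scale": 0.8},
    "S": {"rgb": (-2.4, -2.3, -2.0), "amp": 14.0, "sigma_scale": 0.0},
}
# Luma-neutral stain-tone shift applied to MN at full strength (never
# scaled by divergence; invisible to grayscale statistics).
_MN_TONE = {
    "T": (26.0, -13.238, 0.0),
    "TT": (0.0, 0.0, 0.0),
    "PC": (0.0, 0.0, 0.0),
    "S": (-20.0, 10.183, 0.0),
}
# Per-image jitter: (shared-luma offset sd, per-channel offset sd, amp sd,
# log-sigma sd).  The independent log-sigma jitter decorrelates the
# contrast-family features from the shared amplitude draw.
_JITTER = {
    "T": (5.0, 2.0, 1.5, 0.05),
    "TT": (4.0, 2.0, 1.5, 0.06),
    "PC": (5.0, 2.0, 1.5, 0.05),
    "S": (3.0, 1.5, 1.5, 0.02),
}
# Stamped nuclei inside the nodule core: elongated and co-oriented for N,
# interpolated toward round-and-dense for MN.
_T_PARTICLES_N = {"sigma_minor": 0.8, "sigma_major": 3.0, "density": 0.30,
                  "contrast": 42.0}
_T_PARTICLES_MN = {"sigma_minor": 1.05, "sigma_major": 1.05, "density": 0.34,
                   "contrast": 48.0}
# Palisade nuclei in the rim: identical for both subtypes (TT is the
# null component) and deliberately close to the core texture.
_TT_PARTICLES = {"sigma_minor": 0.9, "sigma_major": 1.6, "density": 0.40,
                 "contrast": 38.0}


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: tuple[float, float]) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    f -= f.mean()
    s = f.std()
    return f / s if s > 0 else f


def _paint_ellipse(canvas: np.ndarray, cy: float, cx: float, a: float,
                   b: float, theta: float) -> None:
    """Set canvas pixels inside the rotated ellipse (bbox-local work)."""
    H, W = canvas.shape
    r = int(math.ceil(a)) + 1
    y0, y1 = max(0, int(cy) - r), min(H, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(W, int(cx) + r + 1)
    yy, xx = np.ogrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    canvas[y0:y1, x0:x1] |= (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_nodules(rng: np.random.Generator, spec: SyntheticDatasetSpec,
                   subtype: str) -> np.ndarray:
    """Return a boolean nodule union mask honoring the subtype geometry."""
    H, W = spec.image_height_px, spec.image_width_px
    bound = spec.micronodule_max_diameter_px
    margin = spec.border_px + spec.cleft_width_px + 2
    usable = min(H, W) - 2 * margin
    if subtype == "N":
        k = int(rng.integers(1, 4))
        d_lo, d_hi = 1.05 * bound, min(1.8 * bound, 0.95 * usable)
        k_min = 1
    else:
        k = int(rng.integers(10, 14))
        d_lo = max(0.20 * bound, 2.0 * (spec.rim_width_px + 3))
        d_hi = 0.33 * bound
        if d_hi <= d_lo:  # very coarse presets: narrow but valid range
            d_hi = 0.5 * bound
        k_min = 10

    gap = 2.0 * (spec.cleft_width_px + 2)
    for _attempt_layout in range(8):
        placed: list[tuple[float, float, float, float, float]] = []
        tries = 0
        while len(placed) < k and tries < 600:
            tries += 1
            d = float(rng.uniform(d_lo, d_hi))
            asp_cap = max(1.0, min(1.7, (usable / d) ** 2))
            asp = float(rng.uniform(1.0, asp_cap))
            a = (d / 2.0) * math.sqrt(asp)
            b = (d / 2.0) / math.sqrt(asp)
            if b < spec.rim_width_px + 2:
                continue
            theta = float(rng.uniform(0.0, math.pi))
            r = a + spec.cleft_width_px + 1
            if 2 * r >= min(H, W) - 2 * spec.border_px:
                continue
            cy = float(rng.uniform(spec.border_px + r, H - spec.border_px - r))
            cx = float(rng.uniform(spec.border_px + r, W - spec.border_px - r))
            # conservative bounding-circle separation keeps cleft rings apart
            if any(math.hypot(cy - oy, cx - ox) < a + oa + gap
                   for oy, ox, oa, _, _ in placed):
                continue
            placed.append((cy, cx, a, b, theta))
        if len(placed) >= k_min and (subtype == "N" or len(placed) >= 10):
            union = np.zeros((H, W), dtype=bool)
            for cy, cx, a, b, theta in placed:
                _paint_ellipse(union, cy, cx, a, b, theta)
            return union
    raise RuntimeError(
        f"could not place nodules for subtype {subtype}; spec too crowded")


def _lerp(a: float, b: float, t: float) -> float:
    return a + t * (b - a)


def render_subtype_image(subtype: str, spec: SyntheticDatasetSpec,
                         rng: np.random.Generator,
                         image_id: str = "img") -> LabeledImage:
    """Render one labeled image of the requested subtype.

    Geometry first (nodules -> T/TT/PC/S mask), then per-component texture
    synthesis with subtype- and divergence-dependent parameters.
    """
    if subtype not in SUBTYPES:
        raise ValueError(f"subtype must be one of {SUBTYPES}")
    spec.validate()
    H, W = spec.image_height_px, spec.image_width_px
    nodules = _place_nodules(rng, spec, subtype)

    # --- mask construction via distance transforms ---------------------
    lab, nlab = ndimage.label(nodules)
    edt_in = ndimage.distance_transform_edt(nodules)
    core = edt_in > spec.rim_width_px
    edt_out, (iy, ix) = ndimage.distance_transform_edt(
        ~nodules, return_indices=True)
    ring = (edt_out > 0) & (edt_out <= spec.cleft_width_px)
    cleft_present = rng.random(nlab + 1) < spec.cleft_presence_prob
    cleft_present[0] = False
    ring &= cleft_present[lab[iy, ix]]

    mask = np.full((H, W), COMPONENT_CODES["S"], dtype=np.uint8)
    mask[ring] = COMPONENT_CODES["PC"]
    mask[nodules] = COMPONENT_CODES["TT"]
    mask[core] = COMPONENT_CODES["T"]
    bp = spec.border_px
    if bp > 0:
        mask[:bp, :] = 0
        mask[-bp:, :] = 0
        mask[:, :bp] = 0
        mask[:, -bp:] = 0

    flags: list[str] = []
    if not np.any(mask == COMPONENT_CODES["PC"]):
        flags.append("no_pc")

    # --- texture synthesis ---------------------------------------------
    img = np.zeros((H, W, 3), dtype=np.float64)
    mn = 1.0 if subtype == "MN" else 0.0
    for comp in COMPONENTS:
        code = COMPONENT_CODES[comp]
        region = mask == code
        if not region.any() and comp != "S":
            continue
        div = float(spec.texture_divergence.get(comp, 0.0))
        base = _BASE[comp]
        delta = _MN_DELTA[comp]
        tone = _MN_TONE[comp]
        luma_sd, chan_sd, amp_sd, logsigma_sd = _JITTER[comp]
        luma_off = rng.normal(0.0, luma_sd)
        chan_off = rng.normal(0.0, chan_sd, size=3)
        rgb = np.array(base["rgb"], dtype=float)
        rgb += mn * div * np.array(delta["rgb"])
        rgb += mn * np.array(tone)
        rgb += luma_off + chan_off
        amp = max(1.0, base["amp"] + mn * div * delta["amp"]
                  + rng.normal(0.0, amp_sd))
        sscale = (1.0 + mn * div * delta["sigma_scale"]) \
            * math.exp(rng.normal(0.0, logsigma_sd))
        sigma = tuple(s * sscale for s in base["sigma"])
        noise = _smooth_noise(rng, (H, W), sigma)
        tex = rgb[None, None, :] + amp * noise[:, :, None]

        if comp in ("T", "TT"):
            if comp == "T":
                pN, pM = _T_PARTICLES_N, _T_PARTICLES_MN
                t = mn * div
                pp = {k: _lerp(pN[k], pM[k], t) for k in pN}
            else:
                pp = dict(_TT_PARTICLES)
            f = ndimage.gaussian_filter(
                rng.standard_normal((H, W)),
                (pp["sigma_minor"], pp["sigma_major"]))
            angle = float(rng.uniform(0.0, 180.0))
            f = ndimage.rotate(f, angle, reshape=False, order=1,
                               mode="reflect")
            thr = np.quantile(f, 1.0 - pp["density"])
            blobs = f > thr
            tex = tex - pp["contrast"] * blobs[:, :, None] * np.array(
                [0.9, 1.0, 0.75])[None, None, :]

        img[region] = tex[region]

    out = np.clip(np.rint(img), 1, 255).astype(np.uint8)
    out[mask == 0] = 0
    return LabeledImage(pixels=out, mask=LabelMask(mask), subtype=subtype,
                        image_id=image_id, flags=tuple(flags))


def generate_dataset(spec: SyntheticDatasetSpec) -> list[LabeledImage]:
    """Generate the full dataset described by ``spec``.

    Deterministic: same spec (including seed) gives bit-identical rasters.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_nodular + spec.n_micronodular)
    images: list[LabeledImage] = []
    for i in range(spec.n_nodular):
        rng = np.random.default_rng(children[i])
        images.append(render_subtype_image(
            "N", spec, rng, image_id=f"N_{i:04d}"))
    for j in range(spec.n_micronodular):
        rng = np.random.default_rng(children[spec.n_nodular + j])
        images.append(render_subtype_image(
            "MN", spec, rng, image_id=f"MN_{j:04d}"))
    return images


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def write_dataset(images: Iterable[LabeledImage], directory: str | Path
                  ) -> pd.DataFrame:
    """Write PNG images + PNG masks + a CSV manifest; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in images:
        img_path = directory / f"{im.image_id}_image.png"
        mask_path = directory / f"{im.image_id}_mask.png"
        Image.fromarray(im.pixels, mode="RGB").save(img_path)
        Image.fromarray(im.mask.labels.astype(np.uint8), mode="L").save(
            mask_path)
        rows.append({
            "image_id": im.image_id,
            "subtype": im.subtype,
            "image_path": img_path.name,
            "mask_path": mask_path.name,
            "flags": ";".join(im.flags),
        })
    manifest = pd.DataFrame(rows)
    if len(manifest) != len(rows):
        raise IOError("manifest/file count mismatch")
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def read_dataset(directory: str | Path) -> list[LabeledImage]:
    """Read back the layout written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.csv in {directory}")
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    missing = [
        str(directory / row[col])
        for _, row in manifest.iterrows()
        for col in ("image_path", "mask_path")
        if not (directory / row[col]).exists()
    ]
    if missing:
        raise FileNotFoundError(
            "missing dataset files: " + ", ".join(missing))
    images = []
    for _, row in manifest.iterrows():
        pixels = np.asarray(
            Image.open(directory / row["image_path"]).convert("RGB"))
        labels = np.asarray(Image.open(directory / row["mask_path"]))
        flags = tuple(f for f in str(row.get("flags", "")).split(";") if f)
        images.append(LabeledImage(
            pixels=pixels, mask=LabelMask(labels),
            subtype=row["subtype"], image_id=row["image_id"], flags=flags))
    return images
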
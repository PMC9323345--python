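"""Per-component image extraction and 8-bit grayscale conversion.

An annotated (image, mask) pair is split into four component images, one
per mask code, with all non-component pixels set to exact black.  The
grayscale step uses the ITU-R BT.601 luma weights so that downstream
quantization is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import COMPONENT_CODES, COMPONENTS, LabelMask

__all__ = ["ComponentImage", "GrayImage", "extract_component", "to_grayscale",
           "LUMA_WEIGHTS"]

logger = logging.getLogger(__name__)

LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)


@dataclass
class ComponentImage:
    """RGB raster restricted to one component; black elsewhere."""

    pixels: np.ndarray          # (H, W, 3) uint8, zeros outside component
    component: str
    parent_id: str
    subtype: str
    foreground_count: int
    foreground: np.ndarray = None  # (H, W) bool, exact component support

    @property
    def empty(self) -> bool:
        return self.foreground_count == 0


@dataclass
class GrayImage:
    pixels: np.ndarray  # (H, W) uint8
    provenance: str


def extract_component(image: np.ndarray, mask: LabelMask | np.ndarray,
                      component: str, parent_id: str = "",
                      subtype: str = "N") -> ComponentImage:
    """Black out everything except ``component``'s pixels.

    Absent components yield an empty-flagged result rather than an error.
    """
    if component not in COMPONENTS:
        raise ValueError(f"component must be one of {COMPONENTS}")
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    image = np.asarray(image)
    if image.shape[:2] != labels.shape:
        raise ValueError(
            f"image shape {image.shape[:2]} != mask shape {labels.shape}")
    bad = np.setdiff1d(np.unique(labels), np.arange(5))
    if bad.size:
        raise ValueError(f"mask codes outside 0..4: {bad.tolist()}")
    fg = labels == COMPONENT_CODES[component]
    out = np.zeros_like(image)
    out[fg] = image[fg]
    count = int(np.count_nonzero(fg))
    if count and not np.all(image[fg].any(axis=-1)):
        # true-black tissue pixels conflate with background downstream
        logger.warning(
            "component %s of %s contains pure-black tissue pixels",
            component, parent_id or "<image>")
    return ComponentImage(pixels=out, component=component,
                          parent_id=parent_id, subtype=subtype,
                          foreground_count=count, foreground=fg)


def to_grayscale(image: ComponentImage | np.ndarray) -> GrayImage:
    """BT.601 luma: round(0.2989 R + 0.5870 G + 0.1140 B), in [0, 255]."""
    if isinstance(image, ComponentImage):
        rgb = image.pixels
        provenance = image.parent_id + ":" + image.component
    else:
        rgb = np.asarray(image)
        provenance = ""
    w = np.asarray(LUMA_WEIGHTS)
    gray = np.clip(np.rint(rgb.astype(np.float64) @ w), 0, 255).astype(np.uint8)
    return GrayImage(pixels=gray, provenance=provenance)
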
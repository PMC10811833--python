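"""Patient body outline (PBO) methods.

Three pieces: extracting the body outline from a slice (threshold +
morphological closing + hole filling + largest connected component), the
PBO-only completion that fills missing in-body pixels with water density,
and the hybrid fusion that fine-tunes a network completion with the
outline — generated tissue outside the outline is eliminated (set to air),
remaining gaps inside the outline are replaced with water, and generated
tissue inside the outline is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .image import CTSlice
from .network import CompletionOutput
from .preprocess import TruncationMask

__all__ = ["BodyOutline", "FillConstants", "extract_outline", "pbo_fill",
           "hybrid_fuse", "save_outline_png", "load_outline_png"]


@dataclass
class BodyOutline:
    """inside == 1 for pixels within the body surface; a single filled
    connected component."""

    inside: np.ndarray
    source: str = "thresholded"  # ground_truth | thresholded | external

    def __post_init__(self):
        self.inside = np.asarray(self.inside, dtype=bool)


@dataclass
class FillConstants:
    """water_gray: 8-bit code of water density under the active intensity
    mapping (the phantom scale puts soft tissue/water at 100);
    tissue_threshold: generated intensity above which a pixel counts as
    tissue (default: midpoint of air and lung gray, so lung parenchyma is
    kept, not overwritten by water)."""

    water_gray: int = 100
    air_gray: int = 0
    tissue_threshold: int = 15

    def validate(self) -> None:
        if not (self.air_gray < self.tissue_threshold <= self.water_gray <= 255):
            raise ValueError(
                "constants must satisfy air_gray < tissue_threshold <= water_gray <= 255"
            )


def extract_outline(slice_: CTSlice, consts: FillConstants = FillConstants(),
                    closing_radius: int = 2) -> BodyOutline:
    """Body outline from a gray8 slice: threshold at tissue_threshold,
    close with a small disk, fill interior holes, keep the largest
    connected component."""
    consts.validate()
    if slice_.unit != "gray8":
        raise ValueError("extract_outline expects a gray8 slice")
    fg = slice_.pixels >= consts.tissue_threshold
    if not fg.any():
        raise ValueError("no pixel above tissue_threshold: empty outline")
    fg = morphology.closing(fg, morphology.disk(closing_radius))
    fg = ndimage.binary_fill_holes(fg)
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = labels == int(np.argmax(counts))
    return BodyOutline(inside=keep, source="thresholded")


def pbo_fill(masked: CTSlice, mask: TruncationMask, outline: BodyOutline,
             consts: FillConstants = FillConstants()) -> CTSlice:
    """Water-density fill: missing pixels inside the outline become
    water_gray, missing pixels outside become air_gray; known pixels are
    untouched."""
    consts.validate()
    if masked.pixels.shape != mask.known.shape or masked.pixels.shape != outline.inside.shape:
        raise ValueError("slice, mask and outline shapes must agree")
    out = masked.to_gray8().pixels.copy()
    missing = mask.missing
    out[missing & outline.inside] = consts.water_gray
    out[missing & ~outline.inside] = consts.air_gray
    return CTSlice(out, masked.spacing, "gray8")


def hybrid_fuse(dl: CompletionOutput | CTSlice, mask: TruncationMask,
                outline: BodyOutline, consts: FillConstants = FillConstants(),
                spacing: float = 1.0) -> CTSlice:
    """Fine-tune a network completion with the body outline.

    On the missing region: generated tissue outside the outline is
    eliminated (air_gray); pixels inside the outline where the network
    produced sub-threshold (air-like) values are replaced with water_gray;
    generated tissue inside the outline is kept. Known pixels pass through
    unchanged.
    """
    consts.validate()
    if isinstance(dl, CompletionOutput):
        pixels = np.round(np.asarray(dl.composited) * 255.0).astype(np.uint8)
    else:
        if dl.unit != "gray8":
            raise ValueError("hybrid_fuse expects a gray8 composited slice")
        pixels = dl.pixels.copy()
        spacing = dl.spacing
    if pixels.shape != mask.known.shape or pixels.shape != outline.inside.shape:
        raise ValueError("slice, mask and outline shapes must agree")
    out = pixels.copy()
    missing = mask.missing
    inside = outline.inside
    out[missing & ~inside] = consts.air_gray
    replace = missing & inside & (pixels < consts.tissue_threshold)
    out[replace] = consts.water_gray
    return CTSlice(out, spacing, "gray8")


def save_outline_png(path, outline: BodyOutline) -> None:
    from PIL import Image

    Image.fromarray((outline.inside.astype(np.uint8)) * 255, mode="L").save(path)


def load_outline_png(path) -> BodyOutline:
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("L")) > 127
    return BodyOutline(inside=arr, source="external")
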
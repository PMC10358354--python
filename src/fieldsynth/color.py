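"""Mean-matching color corrections.

Two corrections keep synthetic tiles consistent:

* **Plant color correction** (CIELAB8): indoor lighting leaves lab-grown
  foliage darker than field plants, so each CIELAB8 channel of the masked
  plant region is shifted by (target mean - current masked mean). The default
  targets (L=170, a=100, b=160) give the enhanced lightness, greenness and
  yellowness of field foliage. Unmasked pixels are untouched.

* **Background offset correction** (RGB): after domain translation the soil
  inside a tile drifts from the surrounding field. A per-channel offset — the
  mean difference between the pre-translation composite and the translated
  tile over a region outside the plant box — is added uniformly to the
  translated tile.

Simple mean matching is used deliberately: the translator is expected to
adjust color distributions itself, so a full histogram match would fight it.
All arithmetic is floating point; outputs are rounded half-even then clamped
to [0, 255]. Everything in this module is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import BBox
from .colorspace import quantize

#: Default CIELAB8 plant-color targets (L, a, b).
DEFAULT_COLOR_TARGETS = (170, 100, 160)


@dataclass(frozen=True)
class ColorTargets:
    """Desired CIELAB8 channel means for the corrected plant region."""

    L: float = 170.0
    A: float = 100.0
    B: float = 160.0

    def __post_init__(self) -> None:
        for name, v in (("L", self.L), ("A", self.A), ("B", self.B)):
            if not (0.0 <= v <= 255.0):
                raise ValueError(f"target {name}={v} outside [0, 255]")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.A, self.B], dtype=np.float64)


def _check_pair(image: np.ndarray, mask: np.ndarray) -> None:
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got {image.shape}")
    if mask.dtype != bool or mask.shape != image.shape[:2]:
        raise ValueError("mask must be boolean and aligned with the image")


def masked_channel_mean(image: np.ndarray, mask: np.ndarray, k: int) -> float:
    """Mean of channel ``k`` over true-mask pixels (mask-weighted average)."""
    _check_pair(image, mask)
    if not mask.any():
        raise ValueError("mask has no true pixels")
    return float(image[..., k][mask].mean(dtype=np.float64))


def masked_means(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """All three masked channel means at once."""
    _check_pair(image, mask)
    if not mask.any():
        raise ValueError("mask has no true pixels")
    return image[mask].mean(axis=0, dtype=np.float64)


def correct_plant_color(
    image: np.ndarray, mask: np.ndarray, targets: ColorTargets = ColorTargets()
) -> np.ndarray:
    """Shift masked CIELAB8 pixels so channel means hit the targets.

    Each channel moves by (target - masked mean), then rounds and clamps;
    unmasked pixels are bit-identical to the input. With no clamping the
    corrected masked means land within rounding (0.5) of the targets; with
    clamping they move monotonically toward them.
    """
    _check_pair(image, mask)
    if not mask.any():
        raise ValueError("mask has no true pixels")
    offsets = targets.as_array() - masked_means(image, mask)
    out = image.copy()
    out[mask] = quantize(image[mask].astype(np.float64) + offsets)
    return out


def exterior_mask(shape: tuple[int, int], bbox: BBox) -> np.ndarray:
    """Mask that is False inside ``bbox`` and True everywhere else."""
    h, w = shape
    if not (0 <= bbox.x0 < bbox.x1 <= w and 0 <= bbox.y0 < bbox.y1 <= h):
        raise ValueError(f"bbox {bbox} outside {h}x{w} grid")
    mask = np.ones((h, w), dtype=bool)
    mask[bbox.y0 : bbox.y1, bbox.x0 : bbox.x1] = False
    return mask


def exterior_band_mask(shape: tuple[int, int], bbox: BBox, band: int) -> np.ndarray:
    """Exterior restricted to a band of ``band`` px around the box.

    The "small region outside the plant bounding box" variant; ``band <= 0``
    falls back to the full exterior.
    """
    outside = exterior_mask(shape, bbox)
    if band <= 0:
        return outside
    h, w = shape
    grown = BBox(bbox.x0 - band, bbox.y0 - band, bbox.x1 + band, bbox.y1 + band).clip(h, w)
    inside_band = np.zeros((h, w), dtype=bool)
    inside_band[grown.y0 : grown.y1, grown.x0 : grown.x1] = True
    return outside & inside_band


def background_offsets(
    composite: np.ndarray, translated: np.ndarray, region: np.ndarray
) -> np.ndarray:
    """Per-channel mean of (composite - translated) over the region."""
    if composite.shape != translated.shape:
        raise ValueError("composite/translated shapes differ")
    _check_pair(composite, region)
    if not region.any():
        raise ValueError("region has no true pixels")
    diff = composite.astype(np.float64) - translated.astype(np.float64)
    return diff[region].mean(axis=0)


def correct_background(translated: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Add the per-channel offsets to every pixel, round and clamp."""
    offsets = np.asarray(offsets, dtype=np.float64)
    if offsets.shape != (3,) or not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be 3 finite reals")
    return quantize(translated.astype(np.float64) + offsets)
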
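"""Single-plant composite tiles: a rescaled cutout pasted onto soil.

A composite tile is the unit the domain translator consumes: a square RGB
image (default 256 px, the generator's input size) holding one plant on a
soil background. The plant's scale is defined as its longest side divided by
the tile side, drawn uniformly from a configured range (default 0.50-0.85);
random padding inside the tile gives the effect of random placement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .boxes import BBox
from .masking import PlantCutout, tight_bbox

DEFAULT_TILE_SIDE = 256


@dataclass(frozen=True)
class ScaleRange:
    """Plant scale bounds relative to the tile side."""

    s_min: float = 0.50
    s_max: float = 0.85

    def __post_init__(self) -> None:
        if not (0.0 < self.s_min <= self.s_max <= 1.0):
            raise ValueError(f"require 0 < s_min <= s_max <= 1, got {self}")


@dataclass(frozen=True)
class CompositeTile:
    """Plant-on-soil tile with its mask, plant box, scale and provenance."""

    image: np.ndarray
    mask: np.ndarray
    plant_bbox: BBox
    scale: float
    background_id: str = ""
    paste_box: BBox | None = None  # extent of the pasted (rescaled) cutout

    @property
    def side(self) -> int:
        return int(self.image.shape[0])


def compute_scale(plant_h: int, plant_w: int, out_side: int) -> float:
    """Plant scale: longest side of the plant image over the tile side."""
    if plant_h <= 0 or plant_w <= 0 or out_side <= 0:
        raise ValueError("dimensions must be positive")
    return max(plant_h, plant_w) / out_side


def _round_half_even(x: float) -> int:
    return int(round(x))


def rescale_cutout(cutout: PlantCutout, target_scale: float, out_side: int) -> PlantCutout:
    """Resize a cutout so its longest side is ``round(target_scale * out_side)``.

    Aspect ratio is preserved to within the 1 px rounding of each side. The
    image is resampled bilinearly; the mask with nearest-neighbor so it stays
    boolean.
    """
    if not (0.0 < target_scale <= 1.0):
        raise ValueError(f"target_scale must be in (0, 1], got {target_scale}")
    h, w = cutout.height, cutout.width
    long_side = max(h, w)
    new_long = _round_half_even(target_scale * out_side)
    if new_long < 1:
        raise ValueError("rescale collapses the cutout below 1 px")
    ratio = new_long / long_side
    new_h = new_long if h >= w else max(_round_half_even(h * ratio), 1)
    new_w = new_long if w > h else max(_round_half_even(w * ratio), 1)
    if (new_h, new_w) == (h, w):
        return cutout
    image = _sk_resize(
        cutout.image, (new_h, new_w), order=1, preserve_range=True, anti_aliasing=ratio < 1
    )
    mask = _sk_resize(
        cutout.mask.astype(np.float64), (new_h, new_w), order=0, anti_aliasing=False
    ) > 0.5
    if not mask.any():
        raise ValueError("rescaled mask lost all plant pixels")
    return PlantCutout(
        np.clip(np.rint(image), 0, 255).astype(np.uint8),
        mask,
        species=cutout.species,
        source_id=cutout.source_id,
    )


def pad_to_tile(
    cutout: PlantCutout, out_side: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, BBox]:
    """Place a cutout at a uniformly random offset inside a black tile.

    Returns the padded image, padded mask, and the pasted cutout's extent.
    Deterministic given the generator state.
    """
    h, w = cutout.height, cutout.width
    if h > out_side or w > out_side:
        raise ValueError(f"cutout {h}x{w} does not fit in a {out_side} px tile")
    x0 = int(rng.integers(0, out_side - w + 1))
    y0 = int(rng.integers(0, out_side - h + 1))
    image = np.zeros((out_side, out_side, 3), dtype=np.uint8)
    mask = np.zeros((out_side, out_side), dtype=bool)
    image[y0 : y0 + h, x0 : x0 + w] = cutout.image
    mask[y0 : y0 + h, x0 : x0 + w] = cutout.mask
    return image, mask, BBox(x0, y0, x0 + w, y0 + h)


def prepare_background(
    background: np.ndarray, out_side: int, rng: np.random.Generator
) -> np.ndarray:
    """Crop a tile-sized window from a soil image (random when larger).

    Random cropping rather than resizing preserves the soil texture scale.
    """
    h, w = background.shape[:2]
    if h < out_side or w < out_side:
        raise ValueError(f"background {h}x{w} smaller than tile side {out_side}")
    y0 = int(rng.integers(0, h - out_side + 1))
    x0 = int(rng.integers(0, w - out_side + 1))
    return np.ascontiguousarray(background[y0 : y0 + out_side, x0 : x0 + out_side])


def make_composite(
    cutout: PlantCutout,
    background: np.ndarray,
    scale_range: ScaleRange,
    out_side: int = DEFAULT_TILE_SIDE,
    rng: np.random.Generator | None = None,
    background_id: str = "",
) -> CompositeTile:
    """Draw a scale, rescale the cutout, and paste it on a soil tile.

    Plant pixels come bit-exactly from the cutout and all others from the
    background; the drawn scale and resulting plant box are recorded.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    tile_bg = prepare_background(background, out_side, rng)
    scale = float(rng.uniform(scale_range.s_min, scale_range.s_max))
    scaled = rescale_cutout(cutout, scale, out_side)
    plant_img, plant_mask, paste_box = pad_to_tile(scaled, out_side, rng)
    image = tile_bg.copy()
    image[plant_mask] = plant_img[plant_mask]
    return CompositeTile(
        image=image,
        mask=plant_mask,
        plant_bbox=tight_bbox(plant_mask, 0),
        scale=scale,
        background_id=background_id,
        paste_box=paste_box,
    )


def write_tile_sidecar(path: str | Path, tile: CompositeTile) -> None:
    """Write the tile's metadata (scale, boxes, provenance) as JSON."""
    box = tile.plant_bbox
    meta = {
        "scale": tile.scale,
        "plant_bbox": [box.x0, box.y0, box.x1, box.y1],
        "paste_box": list(tile.paste_box) if tile.paste_box else None,
        "background_id": tile.background_id,
        "side": tile.side,
    }
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")
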
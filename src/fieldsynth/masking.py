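"""Chroma-key plant extraction from blue-screen photographs.

Indoor plant images are captured against blue keying fabric, which makes
foreground separation a thresholding problem: a pixel belongs to the backdrop
when its blue channel dominates both red and green by at least a configurable
margin. The default margin of 30 intensity levels separates healthy green
foliage from typical keying blue with a wide gap; it is configurable because
the tone of real fabric varies with lighting.

Images are plain ``uint8`` H x W x 3 RGB arrays and masks are boolean H x W
arrays, aligned pixel-for-pixel with their image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import morphology

from .boxes import BBox

#: Default blue-dominance margin (intensity levels) above which a pixel is
#: classified as blue-screen background.
DEFAULT_CHROMA_THRESHOLD = 30

#: Reference keying-fabric color used by fixtures and by mask-fill operations.
REFERENCE_BLUE = (40, 60, 200)

#: Connected components smaller than this (pixels) are treated as speckle
#: when morphological cleanup is enabled.
DEFAULT_MIN_COMPONENT_AREA = 16


@dataclass(frozen=True)
class PlantCutout:
    """A masked single-plant image with provenance.

    ``image`` is RGB; ``mask`` is True on plant pixels. The mask must contain
    at least one true pixel — an empty cutout has no plant to composite.
    """

    image: np.ndarray
    mask: np.ndarray
    species: str = "plant"
    source_id: str = ""

    def __post_init__(self) -> None:
        _check_rgb(self.image)
        _check_mask_shape(self.image, self.mask)
        if not self.mask.any():
            raise ValueError("cutout mask has no true pixels")

    @property
    def height(self) -> int:
        return int(self.image.shape[0])

    @property
    def width(self) -> int:
        return int(self.image.shape[1])


def _check_rgb(image: np.ndarray) -> None:
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError(
            f"expected uint8 HxWx3 RGB image, got shape {image.shape} dtype {image.dtype}"
        )


def _check_mask_shape(image: np.ndarray, mask: np.ndarray) -> None:
    if mask.dtype != bool or mask.shape != image.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape}/{mask.dtype} does not match image {image.shape[:2]}"
        )


def segment_bluescreen(
    image: np.ndarray,
    threshold: int = DEFAULT_CHROMA_THRESHOLD,
    min_component_area: int = 0,
) -> np.ndarray:
    """Classify plant (non-blue) pixels on a blue-screen image.

    A pixel is background when ``B - max(R, G) >= threshold``; the returned
    mask is True on plant pixels. With ``min_component_area > 0``, connected
    plant components smaller than that area are removed as speckle.

    Deterministic for a fixed rule; raises on non-RGB input.
    """
    _check_rgb(image)
    channels = image.astype(np.int16)
    blue_dominance = channels[..., 2] - np.maximum(channels[..., 0], channels[..., 1])
    mask = blue_dominance < threshold
    if min_component_area > 0:
        # drop components strictly smaller than min_component_area
        mask = morphology.remove_small_objects(mask, max_size=min_component_area - 1)
    return mask


def tight_bbox(mask: np.ndarray, margin: int = 0) -> BBox:
    """Smallest half-open box containing all true pixels, padded by ``margin``
    and clipped to the grid.

    Raises ``ValueError`` on an all-false mask.
    """
    if mask.dtype != bool or mask.ndim != 2:
        raise ValueError("expected 2-D boolean mask")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("cannot take bbox of an all-false mask")
    h, w = mask.shape
    return BBox(
        max(int(cols[0]) - margin, 0),
        max(int(rows[0]) - margin, 0),
        min(int(cols[-1]) + 1 + margin, w),
        min(int(rows[-1]) + 1 + margin, h),
    ).validate()


def apply_mask(
    image: np.ndarray,
    mask: np.ndarray,
    fill: tuple[int, int, int] = (0, 0, 0),
) -> np.ndarray:
    """Keep ``image`` where the mask is true, replace with ``fill`` elsewhere."""
    _check_rgb(image)
    _check_mask_shape(image, mask)
    out = np.empty_like(image)
    out[:] = np.asarray(fill, dtype=np.uint8)
    out[mask] = image[mask]
    return out


def extract_cutout(
    image: np.ndarray,
    threshold: int = DEFAULT_CHROMA_THRESHOLD,
    margin: int = 0,
    min_component_area: int = 0,
    species: str = "plant",
    source_id: str = "",
) -> tuple[PlantCutout, BBox]:
    """Segment a blue-screen image and crop it to the plant's tight box."""
    mask = segment_bluescreen(image, threshold, min_component_area)
    box = tight_bbox(mask, margin)
    crop = image[box.y0 : box.y1, box.x0 : box.x1]
    crop_mask = mask[box.y0 : box.y1, box.x0 : box.x1]
    return PlantCutout(crop, crop_mask, species=species, source_id=source_id), box


# ---------------------------------------------------------------------------
# PNG/JPEG I/O


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file as uint8 RGB (alpha dropped, grayscale expanded)."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    return np.ascontiguousarray(arr.astype(np.uint8))


def save_image(path: str | Path, image: np.ndarray) -> None:
    _check_rgb(image)
    iio.imwrite(path, image)


def load_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Persist a boolean mask as single-channel 0/255 PNG."""
    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def save_bbox_sidecar(path: str | Path, box: BBox) -> None:
    Path(path).write_text(
        json.dumps({"x0": box.x0, "y0": box.y0, "x1": box.x1, "y1": box.y1}) + "\n"
    )
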
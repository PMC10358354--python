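"""8-bit CIELAB encoding and conversions to/from 8-bit RGB.

The plant-color targets used by the compositing pipeline (L=170, a=100,
b=160) only make sense in the common 8-bit CIELAB convention where all three
channels occupy [0, 255]: L* in [0, 100] is scaled by 255/100, and the
opponent channels a*, b* are offset by +128. In this encoding "greener than
neutral" means a < 128 and "yellower" means b > 128, so the default targets
describe a bright, green-yellow leaf color. We call this space CIELAB8.

Conversions use scikit-image's D65 sRGB <-> CIELAB transform. The round trip
RGB -> CIELAB8 -> RGB is not exact (quantization plus gamut clipping); tests
bound it at <= 2 intensity levels per channel for in-gamut colors.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

RGB = "RGB"
CIELAB8 = "CIELAB8"


def _as_uint8_image(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"expected uint8 pixels, got {arr.dtype}")
    return arr


def quantize(values: np.ndarray) -> np.ndarray:
    """Round half-even and clamp to the 8-bit range."""
    return np.clip(np.rint(values), 0, 255).astype(np.uint8)


def rgb_to_lab8(rgb: np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB to the 8-bit CIELAB encoding (uint8, D65)."""
    arr = _as_uint8_image(rgb)
    lab = _skcolor.rgb2lab(arr.astype(np.float64) / 255.0)
    lab8 = np.empty_like(lab)
    lab8[..., 0] = lab[..., 0] * 255.0 / 100.0
    lab8[..., 1] = lab[..., 1] + 128.0
    lab8[..., 2] = lab[..., 2] + 128.0
    return quantize(lab8)


def lab8_to_rgb(lab8: np.ndarray) -> np.ndarray:
    """Convert 8-bit CIELAB back to 8-bit RGB (out-of-gamut values clip)."""
    arr = _as_uint8_image(lab8).astype(np.float64)
    lab = np.empty_like(arr)
    lab[..., 0] = arr[..., 0] * 100.0 / 255.0
    lab[..., 1] = arr[..., 1] - 128.0
    lab[..., 2] = arr[..., 2] - 128.0
    rgb = _skcolor.lab2rgb(lab)
    return quantize(rgb * 255.0)
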
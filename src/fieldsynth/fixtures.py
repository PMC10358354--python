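"""Procedural fixtures: blue-screen plants, soil textures, detection scenarios.

Real inputs to the pipeline are photographs — indoor plants on blue keying
fabric and field soil. These generators emulate the properties the pipeline
actually relies on, with known ground truth and no downloads:

* plants are rosettes of elliptical "leaves" in field-plausible greens on a
  uniform reference blue, with the exact painted-pixel mask returned alongside
  — perfectly chroma-separable at the default rule, so mask recovery is exact;
* soil is correlated low-frequency noise around a base brown with optional
  bright speckles, guaranteed never blue-dominant;
* detection scenarios are ground-truth boxes plus predictions derived by
  corner jitter, box dropping (false negatives) and spurious boxes (false
  positives), with confidences that fall with jitter magnitude.

Everything is bit-reproducible from its style and seed. A ``pixel_noise``
knob exists on plants for robustness experiments; exact mask recovery is only
guaranteed at noise 0 (the default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _ellipse

from .boxes import BBox
from .colorspace import lab8_to_rgb, quantize
from .masking import DEFAULT_CHROMA_THRESHOLD, REFERENCE_BLUE, PlantCutout
from .metrics import Detection

#: Leaf base color in CIELAB8, chosen darker/greener than the field targets
#: (170, 100, 160) so that plant color correction produces a visible,
#: testable lightening and yellowing shift.
DEFAULT_LEAF_LAB8 = (120, 110, 150)

DEFAULT_SOIL_BROWN = (120, 85, 55)


@dataclass(frozen=True)
class PlantStyle:
    """Parameters of one synthetic blue-screen plant."""

    n_leaves: int = 5
    leaf_eccentricity: float = 0.55  # 0 = circular leaves, ->1 = needle-like
    base_green: tuple[int, int, int] = DEFAULT_LEAF_LAB8  # CIELAB8
    hue_jitter: float = 6.0  # per-leaf CIELAB8 channel jitter (std)
    size_px: int = 192
    pixel_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.size_px < 16:
            raise ValueError("size_px must be >= 16")
        if not (0.0 <= self.leaf_eccentricity < 1.0):
            raise ValueError("leaf_eccentricity must be in [0, 1)")


@dataclass(frozen=True)
class SoilStyle:
    """Parameters of a synthetic soil texture."""

    base_brown: tuple[int, int, int] = DEFAULT_SOIL_BROWN  # RGB
    roughness: float = 0.5
    speckle_density: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.roughness <= 1.0 and 0.0 <= self.speckle_density <= 1.0):
            raise ValueError("roughness and speckle_density must be in [0, 1]")


def _safe_leaf_rgb(lab8: np.ndarray) -> np.ndarray:
    """Convert a CIELAB8 leaf color to RGB, kept clear of blue dominance."""
    # keep b (yellow-blue) comfortably on the yellow side before converting
    lab8 = lab8.copy()
    lab8[2] = max(lab8[2], 138.0)
    rgb = lab8_to_rgb(quantize(lab8).reshape(1, 1, 3)).reshape(3).astype(np.int16)
    # belt and braces: clamp B below the chroma rule with a wide margin
    limit = max(rgb[0], rgb[1]) + DEFAULT_CHROMA_THRESHOLD - 20
    rgb[2] = min(rgb[2], max(limit, 0))
    return rgb.astype(np.uint8)


def gen_plant(style: PlantStyle = PlantStyle()) -> tuple[np.ndarray, np.ndarray]:
    """Draw a leaf rosette on reference blue; return (image, ground-truth mask).

    A single leaf with zero jitter is one centered ellipse whose pixel area
    matches pi*a*b to rasterization accuracy. Deterministic given the style.
    """
    rng = np.random.default_rng(style.seed)
    s = style.size_px
    image = np.empty((s, s, 3), dtype=np.uint8)
    image[:] = np.asarray(REFERENCE_BLUE, dtype=np.uint8)
    mask = np.zeros((s, s), dtype=bool)

    center = (s - 1) / 2.0
    a = 0.26 * s  # leaf semi-major axis
    b = a * (1.0 - style.leaf_eccentricity)
    offset = 0.0 if style.n_leaves == 1 else 0.18 * s
    base = np.asarray(style.base_green, dtype=np.float64)

    for leaf in range(style.n_leaves):
        angle = 2.0 * np.pi * leaf / style.n_leaves + (
            rng.uniform(-0.2, 0.2) if style.hue_jitter > 0 else 0.0
        )
        cy = center + offset * np.sin(angle)
        cx = center + offset * np.cos(angle)
        rr, cc = _ellipse(cy, cx, b, a, shape=(s, s), rotation=angle)
        lab = base + rng.normal(0.0, style.hue_jitter, size=3)
        color = _safe_leaf_rgb(lab)
        image[rr, cc] = color
        mask[rr, cc] = True

    if style.pixel_noise > 0:
        noisy = image.astype(np.float64) + rng.normal(0, style.pixel_noise, image.shape)
        image = quantize(noisy)
    return image, mask


def gen_plant_cutout(style: PlantStyle = PlantStyle(), species: str = "plant") -> PlantCutout:
    """Plant fixture cropped to its tight box, as a compositing-ready cutout."""
    from .masking import tight_bbox  # local to avoid cycle at import time

    image, mask = gen_plant(style)
    box = tight_bbox(mask, 0)
    return PlantCutout(
        np.ascontiguousarray(image[box.y0 : box.y1, box.x0 : box.x1]),
        np.ascontiguousarray(mask[box.y0 : box.y1, box.x0 : box.x1]),
        species=species,
        source_id=f"fixture-plant-{style.seed}",
    )


def gen_soil(style: SoilStyle, h: int, w: int) -> np.ndarray:
    """Correlated brown-noise soil texture, never blue-dominant.

    roughness scales a smoothed (sigma 6 px) noise field applied with
    per-channel gains so the texture stays brown; speckle_density controls
    the fraction of bright sand-grain pixels. Zero roughness and speckle give
    the uniform base color.
    """
    if h < 1 or w < 1:
        raise ValueError("soil dimensions must be positive")
    rng = np.random.default_rng(style.seed)
    base = np.asarray(style.base_brown, dtype=np.float64)
    image = np.broadcast_to(base, (h, w, 3)).copy()
    if style.roughness > 0:
        noise = rng.normal(0.0, 1.0, size=(h, w))
        noise = gaussian_filter(noise, sigma=6.0, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
        gains = np.array([1.0, 0.85, 0.6]) * 35.0 * style.roughness
        image = image + noise[..., None] * gains
    if style.speckle_density > 0:
        speckle = rng.random((h, w)) < 0.02 * style.speckle_density
        image[speckle] = image[speckle] + np.array([45.0, 40.0, 25.0])
    out = quantize(image).astype(np.int16)
    # hard guarantee: keep blue below the chroma rule everywhere
    limit = np.maximum(out[..., 0], out[..., 1]) + DEFAULT_CHROMA_THRESHOLD - 10
    out[..., 2] = np.minimum(out[..., 2], np.maximum(limit, 0))
    return out.astype(np.uint8)


def gen_soil_pool(
    n: int, h: int, w: int, seed: int = 0, style: SoilStyle | None = None
) -> list[tuple[str, np.ndarray]]:
    """A pool of (id, image) soil textures with per-item derived seeds."""
    pool = []
    for i in range(n):
        s = SoilStyle(
            base_brown=(style or SoilStyle()).base_brown,
            roughness=(style or SoilStyle()).roughness,
            speckle_density=(style or SoilStyle()).speckle_density,
            seed=seed * 10_007 + i,
        )
        pool.append((f"fixture-soil-{s.seed}", gen_soil(s, h, w)))
    return pool


def gen_detection_scenario(
    n_gt: int,
    jitter: float = 0.0,
    drop_rate: float = 0.0,
    spurious_rate: float = 0.0,
    canvas: tuple[int, int] = (512, 512),
    seed: int = 0,
) -> tuple[list[BBox], list[Detection]]:
    """Ground-truth boxes plus degraded predictions for metric testing.

    Predictions jitter each kept box's corners (sigma ``jitter`` px), drop
    boxes independently at ``drop_rate`` (false negatives) and add spurious
    low-confidence boxes at ``spurious_rate`` per ground truth (false
    positives). Confidence decreases with the realized jitter. With all rates
    at zero the predictions equal the ground truth at confidence 1.
    """
    if n_gt < 0:
        raise ValueError("n_gt must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = canvas
    gts: list[BBox] = []
    for _ in range(n_gt):
        bw = int(rng.integers(30, 81))
        bh = int(rng.integers(30, 81))
        x0 = int(rng.integers(0, max(w - bw, 1)))
        y0 = int(rng.integers(0, max(h - bh, 1)))
        gts.append(BBox(x0, y0, x0 + bw, y0 + bh))

    preds: list[Detection] = []
    for box in gts:
        if drop_rate > 0 and rng.random() < drop_rate:
            continue
        if jitter > 0:
            d = rng.normal(0.0, jitter, size=4)
            x0 = int(np.clip(round(box.x0 + d[0]), 0, w - 2))
            y0 = int(np.clip(round(box.y0 + d[1]), 0, h - 2))
            x1 = int(np.clip(round(box.x1 + d[2]), x0 + 1, w))
            y1 = int(np.clip(round(box.y1 + d[3]), y0 + 1, h))
            pbox = BBox(x0, y0, x1, y1)
            conf = float(np.clip(1.0 - np.abs(d).mean() / 25.0, 0.05, 1.0))
        else:
            pbox, conf = box, 1.0
        preds.append(Detection(pbox, conf))
    if spurious_rate > 0:
        n_spur = int(rng.binomial(max(n_gt, 1), spurious_rate))
        for _ in range(n_spur):
            bw = int(rng.integers(20, 61))
            bh = int(rng.integers(20, 61))
            x0 = int(rng.integers(0, max(w - bw, 1)))
            y0 = int(rng.integers(0, max(h - bh, 1)))
            conf = float(rng.uniform(0.05, 0.4))
            preds.append(Detection(BBox(x0, y0, x0 + bw, y0 + bh), conf))
    return gts, preds
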
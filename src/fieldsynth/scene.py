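"""Multi-plant scene assembly with automatic labels, label export, splits.

A scene starts from a full-scale soil image. For each plant, a tile-sized
window of the soil is chosen (randomly without overlap, or on a row grid), a
single-plant composite is formed in that window, optionally plant-color
corrected, passed through the domain translator, background-offset corrected,
and the window is replaced by the result. Because the plant's position inside
the tile and the tile's position in the scene are both known, every plant's
bounding box is known exactly — the scene is born labeled.

Scene construction is a pure function of (spec, pools, translator): one
master seed, with per-plant generators derived by a counter-based spawn so
that adding a plant never perturbs the ones already placed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
from xml.etree import ElementTree as ET

import numpy as np

from .boxes import BBox, intersection_area
from .color import (
    ColorTargets,
    background_offsets,
    correct_background,
    correct_plant_color,
    exterior_band_mask,
    exterior_mask,
)
from .colorspace import lab8_to_rgb, rgb_to_lab8
from .compositing import CompositeTile, ScaleRange, make_composite
from .masking import PlantCutout, save_image
from .translate import Translator


class PlacementError(RuntimeError):
    """No non-overlapping site found within the attempt budget."""


@dataclass(frozen=True)
class SceneSpec:
    """Everything that determines one synthetic scene."""

    n_plants: int = 4
    placement: str = "random"  # "random" | "rows"
    rows: int = 2
    scale_range: ScaleRange = field(default_factory=ScaleRange)
    tile_side: int = 256
    soil_id: str | None = None
    species_filter: frozenset[str] | None = None
    color_correct: bool = True
    color_targets: ColorTargets = field(default_factory=ColorTargets)
    correction_band: int = 0  # 0 = full bbox exterior for background offsets
    row_jitter: int = 0
    max_attempts: int = 100
    class_mode: str = "single"  # "single" | "species"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if self.placement not in ("random", "rows"):
            raise ValueError(f"unknown placement '{self.placement}'")
        if self.placement == "rows" and self.rows < 1:
            raise ValueError("rows must be >= 1")
        if self.class_mode not in ("single", "species"):
            raise ValueError(f"unknown class_mode '{self.class_mode}'")


@dataclass
class PlantRecord:
    """Provenance of one placed plant (mask kept in memory, not serialized)."""

    source_id: str
    species: str
    tile_box: BBox
    plant_box: BBox  # in scene coordinates
    scale: float
    mask: np.ndarray | None = None  # tile-local plant mask


@dataclass
class LabeledScene:
    """A synthetic field image plus its ground-truth boxes."""

    image: np.ndarray
    labels: list[tuple[BBox, str]]
    provenance: list[PlantRecord] = field(default_factory=list)
    soil_id: str = ""
    seed: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test proportions (must sum to 1)."""

    train: float = 0.8
    val: float = 0.1
    test: float = 0.1

    def __post_init__(self) -> None:
        if min(self.train, self.val, self.test) <= 0:
            raise ValueError("split proportions must be positive")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split proportions must sum to 1")


def _rng_for(seed: int, counter: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(counter,)))


def sample_background_window(
    soil: np.ndarray, side: int, rng: np.random.Generator
) -> tuple[np.ndarray, BBox]:
    """Uniformly random side x side window of a soil image, with its location."""
    h, w = soil.shape[:2]
    if h < side or w < side:
        raise ValueError(f"soil {h}x{w} smaller than window side {side}")
    y0 = int(rng.integers(0, h - side + 1))
    x0 = int(rng.integers(0, w - side + 1))
    box = BBox(x0, y0, x0 + side, y0 + side)
    return np.ascontiguousarray(soil[y0 : y0 + side, x0 : x0 + side]), box


def place_nonoverlap(
    existing: Sequence[BBox],
    tile_side: int,
    canvas_hw: tuple[int, int],
    rng: np.random.Generator,
    max_attempts: int = 100,
) -> BBox:
    """Rejection-sample a tile site that does not intersect any existing box."""
    h, w = canvas_hw
    if tile_side > h or tile_side > w:
        raise ValueError(f"tile {tile_side} does not fit canvas {h}x{w}")
    for _ in range(max_attempts):
        x0 = int(rng.integers(0, w - tile_side + 1))
        y0 = int(rng.integers(0, h - tile_side + 1))
        box = BBox(x0, y0, x0 + tile_side, y0 + tile_side)
        if all(intersection_area(box, other) == 0 for other in existing):
            return box
    raise PlacementError(
        f"no free {tile_side} px site after {max_attempts} attempts "
        f"({len(existing)} plants already placed)"
    )


def place_rows(
    n_plants: int,
    rows: int,
    tile_side: int,
    canvas_hw: tuple[int, int],
    jitter: int = 0,
    rng: np.random.Generator | None = None,
) -> list[BBox]:
    """Evenly spaced row/column grid of tile sites with optional jitter.

    Sites are centered in a rows x ceil(n/rows) grid of cells; jitter below
    the inter-site gap keeps the layout non-overlapping.
    """
    h, w = canvas_hw
    cols = math.ceil(n_plants / rows)
    if rows * tile_side > h or cols * tile_side > w:
        raise ValueError(f"{rows}x{cols} grid of {tile_side} px tiles exceeds canvas {h}x{w}")
    rng = np.random.default_rng(0) if rng is None else rng
    boxes: list[BBox] = []
    for i in range(n_plants):
        r, c = divmod(i, cols)
        cy = (r + 0.5) * h / rows
        cx = (c + 0.5) * w / cols
        x0 = int(round(cx - tile_side / 2))
        y0 = int(round(cy - tile_side / 2))
        if jitter > 0:
            x0 += int(rng.integers(-jitter, jitter + 1))
            y0 += int(rng.integers(-jitter, jitter + 1))
        x0 = min(max(x0, 0), w - tile_side)
        y0 = min(max(y0, 0), h - tile_side)
        boxes.append(BBox(x0, y0, x0 + tile_side, y0 + tile_side))
    return boxes


def _translate_tile(
    tile: CompositeTile,
    translator: Translator,
    spec: SceneSpec,
) -> np.ndarray:
    """Color-correct, translate, and background-correct one composite tile."""
    image = tile.image
    if spec.color_correct:
        lab = rgb_to_lab8(image)
        lab = correct_plant_color(lab, tile.mask, spec.color_targets)
        rgb_plant = lab8_to_rgb(lab)
        image = image.copy()
        image[tile.mask] = rgb_plant[tile.mask]  # background stays bit-exact
    translated = translator(image)
    shape = image.shape[:2]
    if spec.correction_band > 0:
        region = exterior_band_mask(shape, tile.plant_bbox, spec.correction_band)
    else:
        region = exterior_mask(shape, tile.plant_bbox)
    offsets = background_offsets(image, translated, region)
    return correct_background(translated, offsets)


def build_scene(
    spec: SceneSpec,
    cutout_pool: Sequence[PlantCutout],
    soil_pool: Sequence[tuple[str, np.ndarray]],
    translator: Translator,
) -> LabeledScene:
    """Assemble one labeled multi-plant scene.

    Per plant: pick a cutout, pick a tile site, composite onto the soil
    window, optionally color-correct the plant, translate, correct the
    background offset, and paste the window back. Deterministic in spec.seed.
    """
    if not cutout_pool or not soil_pool:
        raise ValueError("cutout and soil pools must be non-empty")
    pool = list(cutout_pool)
    if spec.species_filter is not None:
        pool = [c for c in pool if c.species in spec.species_filter]
        if not pool:
            raise ValueError(f"no cutouts match species filter {set(spec.species_filter)}")

    scene_rng = _rng_for(spec.seed, 0)
    if spec.soil_id is not None:
        candidates = [(sid, img) for sid, img in soil_pool if sid == spec.soil_id]
        if not candidates:
            raise ValueError(f"soil id '{spec.soil_id}' not in pool")
        soil_id, soil = candidates[0]
    else:
        idx = int(scene_rng.integers(0, len(soil_pool)))
        soil_id, soil = soil_pool[idx]
    canvas = soil.copy()
    canvas_hw = canvas.shape[:2]

    row_sites = None
    if spec.placement == "rows":
        row_sites = place_rows(
            spec.n_plants, spec.rows, spec.tile_side, canvas_hw, spec.row_jitter, scene_rng
        )

    labels: list[tuple[BBox, str]] = []
    records: list[PlantRecord] = []
    placed: list[BBox] = []
    for i in range(spec.n_plants):
        prng = _rng_for(spec.seed, i + 1)
        cutout = pool[int(prng.integers(0, len(pool)))]
        if row_sites is not None:
            site = row_sites[i]
        else:
            site = place_nonoverlap(
                placed, spec.tile_side, canvas_hw, prng, spec.max_attempts
            )
        window = np.ascontiguousarray(canvas[site.y0 : site.y1, site.x0 : site.x1])
        tile = make_composite(
            cutout,
            window,
            spec.scale_range,
            spec.tile_side,
            prng,
            background_id=soil_id,
        )
        corrected = _translate_tile(tile, translator, spec)
        canvas[site.y0 : site.y1, site.x0 : site.x1] = corrected
        placed.append(site)
        plant_box = tile.plant_bbox.shift(site.x0, site.y0)
        label = "plant" if spec.class_mode == "single" else cutout.species
        labels.append((plant_box, label))
        records.append(
            PlantRecord(
                source_id=cutout.source_id,
                species=cutout.species,
                tile_box=site,
                plant_box=plant_box,
                scale=tile.scale,
                mask=tile.mask,
            )
        )
    return LabeledScene(
        image=canvas, labels=labels, provenance=records, soil_id=soil_id, seed=spec.seed
    )


# ---------------------------------------------------------------------------
# Label export / import


def export_labels(
    scene_shape: tuple[int, int],
    labels: Sequence[tuple[BBox, str]],
    dialect: str = "yolo",
    classes: Sequence[str] = ("plant",),
) -> str:
    """Serialize ground-truth boxes in a detection-label dialect.

    yolo: "class cx cy w h" normalized to [0,1], 6 decimals. voc-xml: corner
    coordinates, 1-based inclusive. csv: 0-based half-open corners.
    """
    h, w = scene_shape
    if dialect == "yolo":
        lines = []
        for box, label in labels:
            ci = list(classes).index(label)
            cx = (box.x0 + box.x1) / 2 / w
            cy = (box.y0 + box.y1) / 2 / h
            bw = box.width / w
            bh = box.height / h
            lines.append(f"{ci} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
        return "\n".join(lines) + ("\n" if lines else "")
    if dialect == "csv":
        lines = [f"{label},{b.x0},{b.y0},{b.x1},{b.y1}" for b, label in labels]
        return "\n".join(lines) + ("\n" if lines else "")
    if dialect == "voc-xml":
        root = ET.Element("annotation")
        size = ET.SubElement(root, "size")
        ET.SubElement(size, "width").text = str(w)
        ET.SubElement(size, "height").text = str(h)
        ET.SubElement(size, "depth").text = "3"
        for box, label in labels:
            obj = ET.SubElement(root, "object")
            ET.SubElement(obj, "name").text = label
            bnd = ET.SubElement(obj, "bndbox")
            # VOC corners are 1-based inclusive
            ET.SubElement(bnd, "xmin").text = str(box.x0 + 1)
            ET.SubElement(bnd, "ymin").text = str(box.y0 + 1)
            ET.SubElement(bnd, "xmax").text = str(box.x1)
            ET.SubElement(bnd, "ymax").text = str(box.y1)
        return ET.tostring(root, encoding="unicode")
    raise ValueError(f"unknown label dialect '{dialect}'")


def import_yolo_labels(
    text: str, scene_shape: tuple[int, int], classes: Sequence[str] = ("plant",)
) -> list[tuple[BBox, str]]:
    """Parse yolo-dialect labels back to half-open integer boxes."""
    h, w = scene_shape
    out: list[tuple[BBox, str]] = []
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        ci = int(parts[0])
        cx, cy, bw, bh = map(float, parts[1:5])
        x0 = int(round((cx - bw / 2) * w))
        y0 = int(round((cy - bh / 2) * h))
        x1 = int(round((cx + bw / 2) * w))
        y1 = int(round((cy + bh / 2) * h))
        out.append((BBox(x0, y0, x1, y1), list(classes)[ci]))
    return out


def split_dataset(
    n_items: int, spec: SplitSpec = SplitSpec(), rng: np.random.Generator | None = None
) -> tuple[list[int], list[int], list[int]]:
    """Deterministic shuffled partition into train/val/test index lists.

    Validation and test sizes are round(n * p); the remainder goes to train.
    """
    if n_items < 3:
        raise ValueError("need at least 3 items to split")
    n_val = round(n_items * spec.val)
    n_test = round(n_items * spec.test)
    n_train = n_items - n_val - n_test
    if n_train < 1:
        raise ValueError("degenerate proportions: empty training split")
    rng = np.random.default_rng(0) if rng is None else rng
    perm = rng.permutation(n_items)
    return (
        [int(i) for i in perm[:n_train]],
        [int(i) for i in perm[n_train : n_train + n_val]],
        [int(i) for i in perm[n_train + n_val :]],
    )


# ---------------------------------------------------------------------------
# Dataset builder (images/{split}/*.png + labels/{split}/*.txt + manifest)


def write_dataset(
    out_dir: str | Path,
    scenes: Sequence[LabeledScene],
    split: SplitSpec,
    classes: Sequence[str],
    master_seed: int,
    config_snapshot: dict | None = None,
) -> dict:
    """Write scenes in the standard layout and return the manifest dict."""
    out = Path(out_dir)
    train, val, test = split_dataset(
        len(scenes), split, _rng_for(master_seed, 10_000)
    )
    assignment = {}
    for name, idxs in (("train", train), ("val", val), ("test", test)):
        for i in idxs:
            assignment[i] = name
    manifest: dict = {
        "master_seed": master_seed,
        "classes": list(classes),
        "split": {"train": split.train, "val": split.val, "test": split.test},
        "config": config_snapshot or {},
        "scenes": [],
    }
    for sub in ("images", "labels"):
        for name in ("train", "val", "test"):
            (out / sub / name).mkdir(parents=True, exist_ok=True)
    for i, scene in enumerate(scenes):
        part = assignment[i]
        stem = f"scene_{i:05d}"
        save_image(out / "images" / part / f"{stem}.png", scene.image)
        (out / "labels" / part / f"{stem}.txt").write_text(
            export_labels(scene.shape, scene.labels, "yolo", classes)
        )
        manifest["scenes"].append(
            {
                "stem": stem,
                "split": part,
                "seed": scene.seed,
                "soil_id": scene.soil_id,
                "plants": [
                    {
                        "source_id": r.source_id,
                        "species": r.species,
                        "tile_box": list(r.tile_box),
                        "plant_box": list(r.plant_box),
                        "scale": r.scale,
                    }
                    for r in scene.provenance
                ],
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
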
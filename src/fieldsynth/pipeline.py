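"""Config-driven dataset production: pools -> scenes -> on-disk dataset.

Ties the modules together behind one entry point so a dataset is a pure
function of its configuration. The manifest written next to the images holds
the full config snapshot and every derived seed; re-running the builder from
a manifest reproduces the dataset byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import PipelineConfig
from .fixtures import PlantStyle, gen_plant_cutout, gen_soil_pool
from .masking import PlantCutout, extract_cutout, load_image
from .scene import LabeledScene, SceneSpec, build_scene, write_dataset
from .translate import Translator, get_translator

log = logging.getLogger("fieldsynth")

_FIXTURE_SPECIES = ("canola", "oat", "soybean", "wheat")


def scene_seed(master_seed: int, index: int) -> int:
    """Counter-based per-scene seed; independent of how many scenes exist."""
    return int((master_seed * 1_000_003 + index) % 2**31)


def fixture_cutout_pool(cfg: PipelineConfig) -> list[PlantCutout]:
    """Procedural blue-screen plants cycled over the four crop species."""
    pool = []
    for i in range(cfg.fixture_plants):
        style = PlantStyle(seed=cfg.seed * 7_919 + i)
        species = _FIXTURE_SPECIES[i % len(_FIXTURE_SPECIES)]
        pool.append(gen_plant_cutout(style, species=species))
    return pool


def fixture_soil_pool(cfg: PipelineConfig) -> list[tuple[str, np.ndarray]]:
    h, w = cfg.soil_hw
    return gen_soil_pool(cfg.fixture_soils, h, w, seed=cfg.seed)


def load_cutout_pool(cfg: PipelineConfig, directory: str | Path) -> list[PlantCutout]:
    """Segment every readable image in a directory into a cutout."""
    pool = []
    for path in sorted(Path(directory).glob("*")):
        if path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        try:
            image = load_image(path)
            cutout, _ = extract_cutout(
                image,
                threshold=cfg.chroma_threshold,
                min_component_area=cfg.min_component_area,
                species=path.stem.split("_")[0],
                source_id=path.name,
            )
        except Exception as exc:  # unreadable or plant-free file: log and skip
            log.warning("skipping %s: %s", path.name, exc)
            continue
        pool.append(cutout)
    return pool


def load_soil_pool(directory: str | Path) -> list[tuple[str, np.ndarray]]:
    pool = []
    for path in sorted(Path(directory).glob("*")):
        if path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        pool.append((path.name, load_image(path)))
    return pool


def scene_spec_for(cfg: PipelineConfig, index: int) -> SceneSpec:
    return SceneSpec(
        n_plants=cfg.n_plants,
        placement=cfg.placement,
        rows=cfg.rows,
        scale_range=cfg.scale_range(),
        tile_side=cfg.tile_side,
        color_correct=cfg.color_correct,
        color_targets=cfg.targets(),
        correction_band=cfg.correction_band,
        row_jitter=cfg.row_jitter,
        max_attempts=cfg.max_attempts,
        class_mode=cfg.class_mode,
        seed=scene_seed(cfg.seed, index),
    )


def build_scenes(
    cfg: PipelineConfig,
    n_scenes: int,
    cutout_pool: Sequence[PlantCutout] | None = None,
    soil_pool: Sequence[tuple[str, np.ndarray]] | None = None,
    translator: Translator | None = None,
) -> list[LabeledScene]:
    """Build ``n_scenes`` labeled scenes; fixture pools are used by default."""
    cutouts = list(cutout_pool) if cutout_pool is not None else fixture_cutout_pool(cfg)
    soils = list(soil_pool) if soil_pool is not None else fixture_soil_pool(cfg)
    trans = translator or get_translator(cfg.translator, **cfg.translator_options)
    scenes = []
    for i in range(n_scenes):
        scenes.append(build_scene(scene_spec_for(cfg, i), cutouts, soils, trans))
        log.info("scene %d/%d built (%d plants)", i + 1, n_scenes, cfg.n_plants)
    return scenes


def classes_for(cfg: PipelineConfig) -> tuple[str, ...]:
    if cfg.class_mode == "single":
        return ("plant",)
    return tuple(cfg.classes) if cfg.classes != ("plant",) else _FIXTURE_SPECIES


def build_dataset(
    cfg: PipelineConfig,
    n_scenes: int,
    out_dir: str | Path,
    cutout_dir: str | Path | None = None,
    soil_dir: str | Path | None = None,
) -> dict:
    """Build and write a labeled dataset; returns the manifest dict."""
    cutouts = load_cutout_pool(cfg, cutout_dir) if cutout_dir else None
    soils = load_soil_pool(soil_dir) if soil_dir else None
    if cutout_dir and not cutouts:
        raise ValueError(f"no usable cutout images in {cutout_dir}")
    if soil_dir and not soils:
        raise ValueError(f"no usable soil images in {soil_dir}")
    scenes = build_scenes(cfg, n_scenes, cutouts, soils)
    snapshot = cfg.to_dict()
    snapshot["_n_scenes"] = n_scenes
    snapshot["_cutout_dir"] = str(cutout_dir) if cutout_dir else None
    snapshot["_soil_dir"] = str(soil_dir) if soil_dir else None
    return write_dataset(
        out_dir, scenes, cfg.split_spec(), classes_for(cfg), cfg.seed, snapshot
    )


def rebuild_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> dict:
    """Re-run the builder from a dataset manifest (byte-identical output)."""
    manifest = json.loads(Path(manifest_path).read_text())
    snapshot = dict(manifest["config"])
    n_scenes = snapshot.pop("_n_scenes")
    cutout_dir = snapshot.pop("_cutout_dir", None)
    soil_dir = snapshot.pop("_soil_dir", None)
    cfg = PipelineConfig.from_dict(snapshot)
    return build_dataset(cfg, n_scenes, out_dir, cutout_dir, soil_dir)
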
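"""Pipeline configuration: one YAML file holding every tunable default.

Field defaults mirror the study conditions of the pipeline: 256 px tiles,
plant scales 0.50-0.85, CIELAB8 plant targets (170, 100, 160), chroma
threshold 30, 80/10/10 dataset split. Validation happens eagerly at load time
and error messages name the offending field.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .color import ColorTargets
from .compositing import ScaleRange
from .scene import SplitSpec


@dataclass
class PipelineConfig:
    tile_side: int = 256
    scale_min: float = 0.50
    scale_max: float = 0.85
    color_targets: tuple[float, float, float] = (170.0, 100.0, 160.0)
    color_correct: bool = True
    chroma_threshold: int = 30
    min_component_area: int = 0
    correction_band: int = 0
    translator: str = "identity"
    translator_options: dict = field(default_factory=dict)
    placement: str = "random"
    n_plants: int = 4
    rows: int = 2
    row_jitter: int = 0
    max_attempts: int = 100
    class_mode: str = "single"
    classes: tuple[str, ...] = ("plant",)
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    soil_hw: tuple[int, int] = (768, 768)
    fixture_plants: int = 8
    fixture_soils: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived module objects -------------------------------------------
    def scale_range(self) -> ScaleRange:
        return ScaleRange(self.scale_min, self.scale_max)

    def targets(self) -> ColorTargets:
        return ColorTargets(*self.color_targets)

    def split_spec(self) -> SplitSpec:
        return SplitSpec(*self.split)

    def validate(self) -> None:
        def _fail(fieldname: str, why: str) -> None:
            raise ValueError(f"config field '{fieldname}': {why}")

        if self.tile_side < 16:
            _fail("tile_side", "must be >= 16 px")
        try:
            ScaleRange(self.scale_min, self.scale_max)
        except ValueError as e:
            _fail("scale_min/scale_max", str(e))
        try:
            ColorTargets(*self.color_targets)
        except (TypeError, ValueError) as e:
            _fail("color_targets", str(e))
        if not (0 < self.chroma_threshold < 256):
            _fail("chroma_threshold", "must be in (0, 255)")
        if self.min_component_area < 0:
            _fail("min_component_area", "must be >= 0")
        if self.correction_band < 0:
            _fail("correction_band", "must be >= 0")
        if self.placement not in ("random", "rows"):
            _fail("placement", f"unknown placement '{self.placement}'")
        if self.n_plants < 1:
            _fail("n_plants", "must be >= 1")
        if self.rows < 1:
            _fail("rows", "must be >= 1")
        if self.class_mode not in ("single", "species"):
            _fail("class_mode", f"unknown mode '{self.class_mode}'")
        try:
            SplitSpec(*self.split)
        except (TypeError, ValueError) as e:
            _fail("split", str(e))
        if min(self.soil_hw) < self.tile_side:
            _fail("soil_hw", "soil canvas must be at least tile_side in each dimension")
        if self.fixture_plants < 1 or self.fixture_soils < 1:
            _fail("fixture_plants/fixture_soils", "must be >= 1")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("color_targets", "classes", "split", "soil_hw"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        coerced = dict(data)
        for key in ("color_targets", "classes", "split", "soil_hw"):
            if key in coerced:
                coerced[key] = tuple(coerced[key])
        return cls(**coerced)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
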
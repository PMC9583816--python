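"""Pipeline configuration: one dataclass, YAML round-trip, instrument defaults.

Every instrument constant lives here as a default rather than hard-coded in
stage logic: voxel size 0.32 × 0.32 × 2 μm³, 576 μm FOV with 5 μm mosaic
overlap, 288 μm planning margin (half a FOV), 1.68 μm/px contour-recognition
resolution, 1 μm co-location threshold, 342.5 ms per-mosaic dwell.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    voxel_size_um: tuple[float, float, float] = (0.32, 0.32, 2.0)
    fov_side_um: float = 576.0
    overlap_um: float = 5.0
    margin_um: float = 288.0
    recognition_pixel_size_um: float = 1.68
    coloc_threshold_um: float = 1.0
    per_mosaic_time_ms: float = 342.5
    channel_modes: dict = field(default_factory=lambda: {"blue": "WF", "green": "SIM", "red": "SIM"})
    axial_chromatic_separation_um: float = 10.0
    crosstalk_free_depth_um: float = 4.0
    tile_shape: tuple[int, int] = (1800, 1800)
    bit_depth: int = 16
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self):
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ConfigError("voxel_size_um must be three positive values")
        if not (0 <= self.overlap_um < self.fov_side_um):
            raise ConfigError("need 0 <= overlap < fov_side")
        if self.margin_um < 0 or self.coloc_threshold_um <= 0:
            raise ConfigError("margin must be >= 0 and coloc threshold > 0")
        for ch, mode in self.channel_modes.items():
            if mode not in ("SIM", "WF"):
                raise ConfigError(f"channel {ch!r}: unknown mode {mode!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["voxel_size_um"] = list(self.voxel_size_um)
        d["tile_shape"] = list(self.tile_shape)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            d = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML: {exc}") from exc
        if not isinstance(d, dict):
            raise ConfigError("config file must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "voxel_size_um" in d:
            d["voxel_size_um"] = tuple(d["voxel_size_um"])
        if "tile_shape" in d:
            d["tile_shape"] = tuple(d["tile_shape"])
        return cls(**d)
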
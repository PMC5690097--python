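"""Run configuration: YAML schema, defaults, resolved-config provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .calibration import TABLE_SLAB_THICKNESS_MM

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # protocol
    kvps: list[float] = field(default_factory=lambda: [80.0, 90.0, 100.0])
    projections: int = 106
    angular_spacing_deg: float = 2.0
    start_angle_deg: float = 106.0
    tube_current_ma: float = 250.0
    exposure_time_ms: float = 6.3
    source_isocenter_cm: float = 70.0
    source_imager_cm: float = 110.0
    fov_cm: list[float] = field(default_factory=lambda: [20.0, 20.0])
    # phantom
    phantom_path: str | None = None   # read instead of generating when set
    voxel_mm: float = 2.5
    seed: int = 0
    jitter_frac: float = 0.0
    # sweep grid
    thicknesses_mm: list[float] = field(
        default_factory=lambda: [0.0, 0.102, 0.204, 0.306, 0.408]
    )
    apertures: list[float | None] = field(default_factory=lambda: [0.2, 0.4, None])
    isocenter_zs_mm: list[float] = field(default_factory=lambda: [1580.0, 1550.0])
    isocenter_xy_mm: list[float] = field(default_factory=lambda: [265.0, 90.0])
    table: list[bool] = field(default_factory=lambda: [False, True])
    table_density: float = 0.484
    table_thickness_mm: float = TABLE_SLAB_THICKNESS_MM
    # engine
    engine: str = "primary_kerma"
    histories: int = 1_000_000
    energy_rebin_kev: float = 2.0
    quick: bool = False

    def __post_init__(self) -> None:
        if self.engine not in ("primary_kerma", "mc"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.projections < 1 or self.histories < 1:
            raise ValueError("projections and histories must be positive")
        if not (1.0 <= self.voxel_mm <= 5.0):
            raise ValueError("voxel size must lie in [1, 5] mm")
        if self.quick:
            # coarse, fast settings for smoke runs
            self.voxel_mm = max(self.voxel_mm, 5.0)
            self.projections = min(self.projections, 12)
            self.histories = min(self.histories, 50_000)
            self.energy_rebin_kev = max(self.energy_rebin_kev, 5.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        out = asdict(self)
        out["config_hash"] = hashlib.sha256(
            json.dumps(out, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return out

    def dump_resolved(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.resolved(), indent=1))
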
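"""Job configuration: the print parameters and analysis settings of one run."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .gcode_model import CalibrationTable, GCodeDialect, GridSpec

__all__ = ["JobConfig"]


@dataclass
class JobConfig:
    """Everything a pipeline run needs besides the GCode and the scans.

    Nozzle diameter and layer thickness double as the default filament
    width/height when no calibration table is supplied; pressure is a per-job
    constant because it is not a GCode word. ``tolerance_mm`` is the +/-
    thickness band of normal printing; ``dz_mm`` the axial OCT resolution.
    """

    nozzle_diameter_mm: float = 0.41
    pressure_mpa: float = 0.18
    layer_thickness_mm: float = 0.25
    speed_mm_s: float = 10.0
    tolerance_mm: float = 0.05
    dz_mm: float = 0.01
    grid_nx: int = 1024
    grid_ny: int = 1024
    wide_field: bool = False
    x_extent_mm: tuple[float, float] | None = None
    y_extent_mm: tuple[float, float] | None = None
    stringing_dilation_px: int | None = None  # None -> filament half-width
    ssim_window_px: int | None = None  # None -> filament diameter in px
    min_repair_length_mm: float = 1.5
    repair_classes: tuple[str, ...] = ("filament_breakage",)
    extrusion_from_e: bool = True
    extrusion_on_codes: tuple[str, ...] = ()
    extrusion_off_codes: tuple[str, ...] = ()
    calibration_entries: list | None = None  # [[speed, pressure, width, height], ...]
    calibration_mode: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nozzle_diameter_mm", "pressure_mpa", "layer_thickness_mm",
                     "speed_mm_s", "dz_mm", "min_repair_length_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tolerance_mm < 0:
            raise ValueError("tolerance_mm must be non-negative")

    def grid(self) -> GridSpec:
        kwargs: dict = dict(nx=self.grid_nx, ny=self.grid_ny, wide_field=self.wide_field)
        if self.x_extent_mm is not None:
            kwargs["x_extent_mm"] = tuple(self.x_extent_mm)
        if self.y_extent_mm is not None:
            kwargs["y_extent_mm"] = tuple(self.y_extent_mm)
        return GridSpec(**kwargs)

    def dialect(self) -> GCodeDialect:
        return GCodeDialect(
            extrusion_from_e=self.extrusion_from_e,
            extrusion_on_codes=tuple(self.extrusion_on_codes),
            extrusion_off_codes=tuple(self.extrusion_off_codes),
        )

    def calibration(self) -> CalibrationTable:
        if self.calibration_entries:
            entries = [
                ((float(s), float(p)), (float(w), float(h)))
                for s, p, w, h in self.calibration_entries
            ]
            return CalibrationTable(entries=entries, mode=self.calibration_mode)
        return CalibrationTable.constant(self.nozzle_diameter_mm, self.layer_thickness_mm)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "JobConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("repair_classes", "extrusion_on_codes", "extrusion_off_codes"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        for key in ("repair_classes", "extrusion_on_codes", "extrusion_off_codes"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
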
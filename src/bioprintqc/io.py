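"""File-format adapters.

Millimetre-valued fields travel as 32-bit float TIFF (bit-exact); renderings
as 8-bit PNG; tables as CSV; metadata as JSON. Volumes are multi-page TIFF
stacks (pages along depth) with a JSON sidecar carrying dz_mm, lateral
pitch, orientation and the acquisition geometry.

Coordinate convention in every writer: x right, y up, millimetres, origin at
the grid center (the GCode frame); array index (row, col) maps to (y, x)
with row 0 at the y minimum.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .defect_map import DefectRun
from .oct_reconstruction import AcquisitionMeta, OCTVolume

__all__ = [
    "write_field_tiff", "read_field_tiff", "write_png", "write_json",
    "read_json", "write_volume", "read_volume", "runs_to_csv", "runs_from_csv",
]


def write_field_tiff(path: str | Path, field: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(field, np.float32))


def read_field_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_png(path: str | Path, image: np.ndarray) -> None:
    """Write a rendering; float images in [0, 1] are scaled to 8 bit."""
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = (np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)
    iio.imwrite(str(path), img)


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_volume(path: str | Path, volume: OCTVolume, meta: AcquisitionMeta) -> None:
    """Multi-page TIFF (pages along depth) + JSON sidecar ``<path>.json``."""
    pages = np.moveaxis(volume.intensity, 2, 0).astype(np.float32)
    tifffile.imwrite(str(path), pages)
    sidecar = {
        "dz_mm": volume.dz_mm,
        "lateral_pitch_mm": volume.lateral_pitch_mm,
        "z_down": volume.z_down,
        "round_index": meta.round_index,
        "z_set_height_px": meta.z_set_height_px,
        "device_xy_mm": list(meta.device_xy_mm),
    }
    write_json(str(path) + ".json", sidecar)


def read_volume(path: str | Path) -> tuple[OCTVolume, AcquisitionMeta]:
    pages = tifffile.imread(str(path))
    side = read_json(str(path) + ".json")
    vol = OCTVolume(
        intensity=np.moveaxis(pages, 0, 2),
        dz_mm=side["dz_mm"],
        lateral_pitch_mm=side["lateral_pitch_mm"],
        z_down=side.get("z_down", True),
    )
    meta = AcquisitionMeta(
        round_index=side.get("round_index", 1),
        z_set_height_px=side.get("z_set_height_px", 0.0),
        device_xy_mm=tuple(side.get("device_xy_mm", (0.0, 0.0))),
    )
    return vol, meta


def runs_to_csv(path: str | Path, runs: list[DefectRun]) -> None:
    df = pd.DataFrame(
        {
            "class": [r.defect_class.name.lower() for r in runs],
            "z_mm": [r.z_mm for r in runs],
            "x0_mm": [r.start_mm[0] for r in runs],
            "y0_mm": [r.start_mm[1] for r in runs],
            "x1_mm": [r.end_mm[0] for r in runs],
            "y1_mm": [r.end_mm[1] for r in runs],
            "length_mm": [r.length_mm for r in runs],
        }
    )
    df.to_csv(path, index=False)


def runs_from_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
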
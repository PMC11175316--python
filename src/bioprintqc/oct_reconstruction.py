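"""Printed-thickness reconstruction from OCT-style intensity volumes.

An in-situ OCT probe images the print bed between printing rounds. Each
lateral (x, y) column of the volume is scanned along depth for its first
bright voxel — the material surface. Printed thickness then follows from the
surface index of the current round, the surface index of the bare base
platform, and the platform descent between the two acquisitions:

    thickness = (z_base + z_descent - z_surface) * dz

with dz the axial pixel resolution in mm/px. Referencing every round to the
same base acquisition cancels base-platform unevenness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .gcode_model import GridSpec, bresenham_points

__all__ = [
    "OCTVolume",
    "AcquisitionMeta",
    "SurfaceMap",
    "ReconstructedModelMap",
    "detect_surface",
    "compute_thickness",
    "accumulate_rounds",
    "extract_cross_section",
]


@dataclass
class OCTVolume:
    """Intensity volume with axes (y, x, z); z is the depth axis.

    ``z_down`` states whether the z index increases with physical depth
    (True for the native orientation; volumes stored upside-down set False
    and are flipped on load).
    """

    intensity: np.ndarray  # (ny, nx, nz), non-negative
    dz_mm: float
    lateral_pitch_mm: float
    z_down: bool = True

    def __post_init__(self) -> None:
        if self.intensity.ndim != 3 or self.intensity.shape[2] < 2:
            raise ValueError("volume must be (ny, nx, nz) with nz >= 2")
        if self.dz_mm <= 0:
            raise ValueError("dz_mm must be positive")


@dataclass
class AcquisitionMeta:
    """Geometry of one print-imaging round.

    ``z_set_height_px`` is the number of pixels the platform has descended
    since the base acquisition; the lateral device coordinates must match the
    base acquisition so surface maps are pixel-aligned.
    """

    round_index: int = 1
    z_set_height_px: float = 0.0
    device_xy_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.z_set_height_px < 0:
            raise ValueError("platform descent cannot be negative")


@dataclass
class SurfaceMap:
    """First-surface axial index per lateral column, with validity mask."""

    surface_z_px: np.ndarray  # (ny, nx) float
    valid: np.ndarray  # (ny, nx) bool


@dataclass
class ReconstructedModelMap:
    """Measured printed thickness (mm) of one round on the model grid."""

    thickness_mm: np.ndarray
    grid: GridSpec
    round_index: int = 1
    valid: np.ndarray | None = None
    n_clipped_negative: int = 0

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.thickness_mm.shape, bool)


def detect_surface(
    volume: OCTVolume,
    threshold: float | None = None,
    *,
    smooth_window_px: int = 1,
    method: str = "otsu",
    threshold_k: float = 1.0,
) -> SurfaceMap:
    """Find the shallowest axial index exceeding ``threshold`` per column.

    Columns are optionally smoothed along depth with a uniform window before
    thresholding. With ``threshold=None`` the detection level is chosen by
    ``method``: "otsu" (default; separates the bright material phase from
    the dim background regardless of their volume fractions) or "mean_std"
    (mean + threshold_k * std of the whole volume, which assumes the bright
    phase fills well under half the volume). Columns that never exceed
    the threshold are marked invalid (an all-invalid result is allowed).
    """
    inten = np.asarray(volume.intensity, float)
    if not np.all(np.isfinite(inten)):
        raise ValueError("volume intensities must be finite")
    if not volume.z_down:
        inten = inten[:, :, ::-1]
    if smooth_window_px > 1:
        inten = uniform_filter1d(inten, smooth_window_px, axis=2, mode="nearest")
    if threshold is None:
        if method == "otsu":
            from skimage.filters import threshold_otsu

            lo, hi = float(inten.min()), float(inten.max())
            if hi - lo < 1e-12:  # constant volume: no bright phase
                threshold = hi
            else:
                threshold = float(threshold_otsu(inten))
        elif method == "mean_std":
            threshold = float(inten.mean() + threshold_k * inten.std())
        else:
            raise ValueError(f"unknown threshold method {method!r}")
    # indices are always reported in the depth-downward frame (a taller
    # deposit has a smaller surface index); flipped volumes were reoriented
    above = inten > threshold
    valid = above.any(axis=2)
    surface = np.argmax(above, axis=2).astype(float)
    surface[~valid] = np.nan
    return SurfaceMap(surface_z_px=surface, valid=valid)


def compute_thickness(
    print_surface: SurfaceMap,
    base: SurfaceMap,
    meta: AcquisitionMeta,
    dz_mm: float,
    *,
    grid: GridSpec | None = None,
) -> ReconstructedModelMap:
    """Convert surface indices to printed thickness in mm.

    thickness = (base + descent - print_surface) * dz per pixel. Columns
    invalid in either surface map propagate as invalid; negative thicknesses
    (surface apparently below the descended base — a registration error) are
    clipped to 0 and counted.
    """
    if print_surface.surface_z_px.shape != base.surface_z_px.shape:
        raise ValueError("print and base surface maps must share lateral shape")
    valid = print_surface.valid & base.valid
    thickness = (
        base.surface_z_px + meta.z_set_height_px - print_surface.surface_z_px
    ) * dz_mm
    negative = valid & (thickness < 0)
    thickness = np.where(negative, 0.0, thickness)
    thickness = np.where(valid, thickness, np.nan)
    if grid is None:
        ny, nx = thickness.shape
        grid = GridSpec(nx=nx, ny=ny)
    return ReconstructedModelMap(
        thickness_mm=thickness,
        grid=grid,
        round_index=meta.round_index,
        valid=valid,
        n_clipped_negative=int(negative.sum()),
    )


def accumulate_rounds(maps: list[ReconstructedModelMap]) -> np.ndarray:
    """Per-pixel cumulative printed height over successive rounds (mm).

    Invalid pixels contribute 0 to the sum; per-round maps are left intact
    for per-layer analysis.
    """
    if not maps:
        raise ValueError("no rounds to accumulate")
    shape = maps[0].thickness_mm.shape
    idx = [m.round_index for m in maps]
    if any(j <= i for i, j in zip(idx, idx[1:])):
        raise ValueError("round indices must be strictly increasing")
    total = np.zeros(shape, float)
    for m in maps:
        if m.thickness_mm.shape != shape:
            raise ValueError("rounds must share grid shape")
        total += np.nan_to_num(m.thickness_mm, nan=0.0)
    return total


def extract_cross_section(
    data: np.ndarray,
    *,
    row: int | None = None,
    col: int | None = None,
    polyline_px: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Sample a 1D profile from a 2D field (or a 2D slice from a volume).

    Exactly one of ``row``, ``col``, ``polyline_px`` selects the line; a
    polyline is rasterized point-to-point with Bresenham.
    """
    given = sum(x is not None for x in (row, col, polyline_px))
    if given != 1:
        raise ValueError("specify exactly one of row, col, polyline_px")
    if row is not None:
        return np.asarray(data[row])
    if col is not None:
        return np.asarray(data[:, col])
    pts: list[tuple[int, int]] = []
    for p0, p1 in zip(polyline_px, polyline_px[1:]):
        seg = bresenham_points(p0, p1, shape=data.shape[:2])
        pts.extend(seg if not pts else seg[1:])
    if len(polyline_px) == 1:
        pts = [tuple(polyline_px[0])]
    rows, cols = zip(*pts)
    return np.asarray(data[list(rows), list(cols)])
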
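"""Spatially resolved defect characterization.

The measured thickness map is compared against the target map pixel by
pixel. Along the target centerline, each point is classified by the printed
thickness t relative to the target T with tolerance band delta (0.05 mm by
default):

    normal            T - delta <= t <= T + delta   (band edges inclusive)
    under-extrusion   eps <= t < T - delta
    over-extrusion    t > T + delta
    filament breakage t < eps  (and T != 0)

where eps is a small zero-thickness threshold (exact float zero is fragile;
half an axial pixel by default). Centerline labels are then propagated
laterally across the local filament width (each in-path pixel takes the
label of its nearest centerline pixel). Outside the path, stringing is
detected morphologically: binarize the reconstruction, skeletonize, dilate,
intersect with the inverted path mask, and clean with a morphological
opening. The six states render with the fixed legend: background black,
normal green, under-extrusion cyan, over-extrusion yellow, breakage dark
blue, stringing red.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.morphology import dilation, disk, opening, skeletonize

from .gcode_model import GridSpec, TargetModelMap
from .oct_reconstruction import ReconstructedModelMap

__all__ = [
    "DefectClass",
    "DEFECT_COLORS",
    "DefectMap",
    "DefectRun",
    "mask_recon_in_path",
    "classify_in_path",
    "detect_stringing",
    "compose_defect_map",
    "measure_defect_runs",
    "render_defect_map",
]


class DefectClass(IntEnum):
    BACKGROUND = 0
    NORMAL = 1
    UNDER_EXTRUSION = 2
    OVER_EXTRUSION = 3
    FILAMENT_BREAKAGE = 4
    STRINGING = 5


DEFECT_COLORS: dict[DefectClass, tuple[float, float, float]] = {
    DefectClass.BACKGROUND: (0.0, 0.0, 0.0),  # black
    DefectClass.NORMAL: (0.0, 0.8, 0.0),  # green
    DefectClass.UNDER_EXTRUSION: (0.0, 0.85, 0.85),  # cyan
    DefectClass.OVER_EXTRUSION: (0.9, 0.9, 0.0),  # yellow
    DefectClass.FILAMENT_BREAKAGE: (0.0, 0.0, 0.55),  # dark blue
    DefectClass.STRINGING: (0.9, 0.0, 0.0),  # red
}


@dataclass
class DefectMap:
    """Per-pixel six-state label field for one layer/round."""

    labels: np.ndarray  # (ny, nx) uint8 of DefectClass values
    grid: GridSpec
    tolerance_mm: float = 0.05
    z_mm: float = 0.0
    round_index: int = 1

    def class_counts(self) -> dict[str, int]:
        return {
            cls.name.lower(): int((self.labels == cls).sum()) for cls in DefectClass
        }

    def class_areas_mm2(self) -> dict[str, float]:
        px_area = self.grid.pitch_x * self.grid.pitch_y
        return {k: v * px_area for k, v in self.class_counts().items()}


@dataclass
class DefectRun:
    """A maximal same-class run along the ordered centerline."""

    defect_class: DefectClass
    pixels: list[tuple[int, int]]  # ordered (row, col)
    start_mm: tuple[float, float]
    end_mm: tuple[float, float]
    length_mm: float
    z_mm: float = 0.0


def mask_recon_in_path(
    recon: ReconstructedModelMap, target: TargetModelMap
) -> np.ndarray:
    """Restrict the reconstruction to the target path (pointwise product
    with the path mask); invalid columns count as thickness 0."""
    if recon.grid.shape != target.grid.shape:
        raise ValueError("reconstruction and target grids differ")
    t = np.nan_to_num(recon.thickness_mm, nan=0.0)
    return np.where(target.path_mask, t, 0.0)


def _classify_values(
    t: np.ndarray, target_t: np.ndarray, tolerance_mm: float, zero_eps_mm: float
) -> np.ndarray:
    labels = np.full(t.shape, DefectClass.BACKGROUND, np.uint8)
    on = target_t > 0
    breakage = on & (t < zero_eps_mm)
    normal = on & (t >= target_t - tolerance_mm) & (t <= target_t + tolerance_mm)
    over = on & (t > target_t + tolerance_mm)
    under = on & ~breakage & ~normal & ~over
    labels[normal] = DefectClass.NORMAL
    labels[under] = DefectClass.UNDER_EXTRUSION
    labels[over] = DefectClass.OVER_EXTRUSION
    labels[breakage] = DefectClass.FILAMENT_BREAKAGE
    return labels


def classify_thickness(
    t: float, target_t: float, tolerance_mm: float = 0.05, zero_eps_mm: float = 1e-6
) -> DefectClass:
    """Classify a single (printed, target) thickness pair (mm)."""
    return DefectClass(
        int(
            _classify_values(
                np.array([t]), np.array([target_t]), tolerance_mm, zero_eps_mm
            )[0]
        )
    )


def classify_in_path(
    recon_in_path: np.ndarray,
    target: TargetModelMap,
    tolerance_mm: float = 0.05,
    *,
    zero_eps_mm: float = 1e-6,
) -> np.ndarray:
    """In-path label field: classify along the centerline, then propagate
    each centerline label across the local filament width.

    Propagation assigns every path pixel the label of its nearest centerline
    pixel (Euclidean), which realizes the lateral spread over the filament
    half-width for display. Breakage pixels whose centerline label is normal
    but which themselves have no centerline nearby keep the nearest label —
    classification authority is the centerline, as the map is a display of
    the per-point print status.
    """
    if tolerance_mm < 0:
        raise ValueError("tolerance must be non-negative")
    if recon_in_path.shape != target.grid.shape:
        raise ValueError("field shape does not match target grid")
    labels = np.full(recon_in_path.shape, DefectClass.BACKGROUND, np.uint8)
    if not target.centerline.any():
        return labels
    center_labels = _classify_values(
        recon_in_path, target.target_thickness, tolerance_mm, zero_eps_mm
    )
    # nearest-centerline propagation across the filament width
    _, (ir, ic) = distance_transform_edt(~target.centerline, return_indices=True)
    propagated = center_labels[ir, ic]
    labels[target.path_mask] = propagated[target.path_mask]
    return labels


def detect_stringing(
    recon: ReconstructedModelMap,
    target: TargetModelMap,
    *,
    dilation_radius_px: int | None = None,
    opening_footprint: np.ndarray | None = None,
    zero_eps_mm: float = 1e-6,
) -> np.ndarray:
    """Out-of-path material mask.

    Pipeline: binarize the reconstruction (t > eps); skeletonize; dilate the
    skeleton with a disc (radius defaults to the filament half-width in
    pixels); AND with the inverted path mask; clean with a morphological
    opening (3x3 square by default). Surviving pixels are stringing.
    """
    if recon.grid.shape != target.grid.shape:
        raise ValueError("reconstruction and target grids differ")
    if dilation_radius_px is None:
        widths = target.target_width[target.path_mask]
        w = float(widths.mean()) if widths.size else 0.41
        dilation_radius_px = max(1, int(round(w / (2.0 * target.grid.pitch))))
    if opening_footprint is None:
        opening_footprint = np.ones((3, 3), bool)
    binary = np.nan_to_num(recon.thickness_mm, nan=0.0) > zero_eps_mm
    skel = skeletonize(binary)
    expanded = dilation(skel, disk(dilation_radius_px))
    outside = expanded & ~target.path_mask
    return opening(outside, opening_footprint).astype(bool)


def compose_defect_map(
    in_path_labels: np.ndarray,
    stringing_mask: np.ndarray,
    grid: GridSpec,
    *,
    tolerance_mm: float = 0.05,
    z_mm: float = 0.0,
    round_index: int = 1,
) -> DefectMap:
    """Merge in-path labels with the stringing mask into one DefectMap."""
    if in_path_labels.shape != stringing_mask.shape:
        raise ValueError("label field and stringing mask shapes differ")
    overlap = stringing_mask & (in_path_labels != DefectClass.BACKGROUND)
    if overlap.any():
        raise RuntimeError(
            "stringing overlaps in-path labels — construction violated "
            f"({int(overlap.sum())} pixels)"
        )
    labels = in_path_labels.copy()
    labels[stringing_mask] = DefectClass.STRINGING
    return DefectMap(
        labels=labels,
        grid=grid,
        tolerance_mm=tolerance_mm,
        z_mm=z_mm,
        round_index=round_index,
    )


def render_defect_map(dmap: DefectMap) -> np.ndarray:
    """RGB rendering with the fixed color legend."""
    rgb = np.zeros(dmap.labels.shape + (3,), float)
    for cls, color in DEFECT_COLORS.items():
        rgb[dmap.labels == cls] = color
    return rgb


_MAX_STEP_PX = 1.5  # steps longer than sqrt(2) px break a centerline run


def measure_defect_runs(
    dmap: DefectMap,
    target: TargetModelMap,
    classes: tuple[DefectClass, ...] = (
        DefectClass.UNDER_EXTRUSION,
        DefectClass.OVER_EXTRUSION,
        DefectClass.FILAMENT_BREAKAGE,
    ),
) -> list[DefectRun]:
    """Maximal same-class runs along the ordered centerline, with arc length.

    Step lengths are pitch for axis-aligned steps and pitch*sqrt(2) for
    diagonal ones; a jump between non-adjacent centerline points (e.g.
    across a travel move) terminates the current run.
    """
    pts = target.centerline_points
    if not pts:
        return []
    grid = target.grid
    runs: list[DefectRun] = []
    cur_cls: DefectClass | None = None
    cur_pts: list[tuple[int, int]] = []
    cur_len = 0.0

    def flush() -> None:
        nonlocal cur_cls, cur_pts, cur_len
        if cur_cls is not None and cur_cls in classes and cur_pts:
            x0, y0 = grid.pixel_to_mm(cur_pts[0][1], cur_pts[0][0])
            x1, y1 = grid.pixel_to_mm(cur_pts[-1][1], cur_pts[-1][0])
            runs.append(
                DefectRun(
                    defect_class=cur_cls,
                    pixels=list(cur_pts),
                    start_mm=(float(x0), float(y0)),
                    end_mm=(float(x1), float(y1)),
                    length_mm=cur_len,
                    z_mm=dmap.z_mm,
                )
            )
        cur_cls, cur_pts, cur_len = None, [], 0.0

    prev: tuple[int, int] | None = None
    for p in pts:
        cls = DefectClass(int(dmap.labels[p]))
        step = 0.0
        contiguous = True
        if prev is not None:
            dr, dc = p[0] - prev[0], p[1] - prev[1]
            d = float(np.hypot(dr, dc))
            contiguous = d <= _MAX_STEP_PX
            step = d * grid.pitch
        if cls is not cur_cls or not contiguous:
            flush()
            cur_cls = cls
            cur_pts = [p]
        else:
            cur_pts.append(p)
            cur_len += step
        prev = p
    flush()
    return runs
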
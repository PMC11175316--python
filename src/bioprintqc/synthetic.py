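"""Synthetic printed-surface generator with ground-truth annotations.

Real acquisitions of printed scaffolds are instrument-bound; this module
emulates them. Starting from a rasterized target map, it renders an ideal
print (the target footprint at target height, a flat-topped filament
cross-section), then injects the defect taxonomy the pipeline must detect:

* breakage gaps — arc-length intervals of the toolpath zeroed out;
* under-/over-extrusion stretches — intervals scaled by a height factor;
* accumulation blobs — radially tapered bumps, typically at turnarounds;
* stringing threads — thin material polylines outside the path.

Height maps can further be rendered into OCT-style intensity volumes (bright
material below the surface, dim background above, optional multiplicative
speckle, optionally uneven/tilted base) so that surface detection and the
thickness formula are exercised end to end. All randomness is seeded;
identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .config import JobConfig
from .defect_map import DefectClass, _classify_values
from .gcode_model import GridSpec, TargetModelMap, bresenham_points
from .oct_reconstruction import AcquisitionMeta, OCTVolume

__all__ = [
    "DefectSpec",
    "GroundTruth",
    "ScenarioBundle",
    "render_heightmap",
    "render_volume",
    "scenario_fixtures",
    "SCENARIO_NAMES",
    "arc_length_map",
]


@dataclass
class DefectSpec:
    """Defects to inject, positioned by arc length along the toolpath (mm).

    ``breakage_mm`` and the under/over entries are (start_s, end_s) arc
    intervals; scale factors multiply the local target height. Blobs are
    (center_xy_mm, radius_mm, extra_height_mm); threads are (polyline_mm,
    height_mm) placed off-path.
    """

    breakage_mm: list[tuple[float, float]] = field(default_factory=list)
    scaled_mm: list[tuple[float, float, float]] = field(default_factory=list)  # (s0, s1, scale)
    blobs: list[tuple[tuple[float, float], float, float]] = field(default_factory=list)
    threads: list[tuple[list[tuple[float, float]], float]] = field(default_factory=list)
    seed: int = 0

    def validate(self, total_arc_mm: float) -> None:
        for s0, s1 in self.breakage_mm:
            if not (0 <= s0 < s1 <= total_arc_mm):
                raise ValueError(f"breakage interval ({s0}, {s1}) outside arc length {total_arc_mm:.3f}")
        for s0, s1, scale in self.scaled_mm:
            if not (0 <= s0 < s1 <= total_arc_mm):
                raise ValueError(f"scaled interval ({s0}, {s1}) outside arc length {total_arc_mm:.3f}")
            if scale <= 0:
                raise ValueError("scale factors must be positive")


@dataclass
class GroundTruth:
    """What was actually injected, for verifying the pipeline."""

    height_mm: np.ndarray
    labels: np.ndarray  # DefectClass values per pixel
    runs: list[dict]  # class, s-interval, length, endpoints (mm)
    total_arc_mm: float


@dataclass
class ScenarioBundle:
    name: str
    gcode: str
    config: JobConfig
    defect_spec: DefectSpec


def arc_length_map(target: TargetModelMap) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative arc length (mm) at each ordered centerline point, and a
    per-pixel field mapping every grid pixel to the arc position of its
    nearest centerline pixel."""
    pts = target.centerline_points
    if not pts:
        raise ValueError("target has no centerline")
    pitch = target.grid.pitch
    s = np.zeros(len(pts))
    for i in range(1, len(pts)):
        dr = pts[i][0] - pts[i - 1][0]
        dc = pts[i][1] - pts[i - 1][1]
        s[i] = s[i - 1] + np.hypot(dr, dc) * pitch
    s_img = np.full(target.grid.shape, np.nan)
    for i, (r, c) in enumerate(pts):
        if np.isnan(s_img[r, c]):
            s_img[r, c] = s[i]
    _, (ir, ic) = distance_transform_edt(~target.centerline, return_indices=True)
    return s, s_img[ir, ic]


def render_heightmap(
    target: TargetModelMap, spec: DefectSpec, *, tolerance_mm: float = 0.05
) -> tuple[np.ndarray, GroundTruth]:
    """Render the true surface-height field for a target plus injected defects."""
    s_points, s_pix = arc_length_map(target)
    total = float(s_points[-1])
    spec.validate(total)
    grid = target.grid
    height = target.target_thickness.copy()
    runs: list[dict] = []

    # widen each interval by half a pitch so the rendered arc matches the
    # requested length to within one pixel pitch despite grid quantization
    half = target.grid.pitch / 2.0

    def interval_mask(s0: float, s1: float) -> np.ndarray:
        return target.path_mask & (s_pix >= s0 - half) & (s_pix < s1 + half)

    def endpoints(s0: float, s1: float) -> tuple[tuple[float, float], tuple[float, float]]:
        i0 = int(np.searchsorted(s_points, s0 - half, side="left"))
        i1 = max(i0, int(np.searchsorted(s_points, s1 + half, side="left")) - 1)
        p0, p1 = target.centerline_points[i0], target.centerline_points[i1]
        x0, y0 = grid.pixel_to_mm(p0[1], p0[0])
        x1, y1 = grid.pixel_to_mm(p1[1], p1[0])
        return (float(x0), float(y0)), (float(x1), float(y1))

    for s0, s1, scale in spec.scaled_mm:
        m = interval_mask(s0, s1)
        height[m] *= scale
        cls = (
            DefectClass.UNDER_EXTRUSION if scale < 1 else DefectClass.OVER_EXTRUSION
        )
        e0, e1 = endpoints(s0, s1)
        runs.append(
            {"class": cls, "s0": s0, "s1": s1, "length_mm": s1 - s0,
             "start_mm": e0, "end_mm": e1}
        )
    for s0, s1 in spec.breakage_mm:
        height[interval_mask(s0, s1)] = 0.0
        e0, e1 = endpoints(s0, s1)
        runs.append(
            {"class": DefectClass.FILAMENT_BREAKAGE, "s0": s0, "s1": s1,
             "length_mm": s1 - s0, "start_mm": e0, "end_mm": e1}
        )

    yy, xx = np.meshgrid(
        np.arange(grid.ny), np.arange(grid.nx), indexing="ij"
    )
    xs, ys = grid.pixel_to_mm(xx, yy)
    for (cx, cy), radius, extra in spec.blobs:
        d = np.hypot(xs - cx, ys - cy)
        bump = np.clip(1.0 - d / radius, 0.0, None) * extra
        height += bump

    thread_mask = np.zeros(grid.shape, bool)
    for polyline, h in spec.threads:
        pts: list[tuple[int, int]] = []
        px = [grid.mm_to_pixel(x, y) for x, y in polyline]
        for (c0, r0), (c1, r1) in zip(px, px[1:]):
            seg = bresenham_points((int(r0), int(c0)), (int(r1), int(c1)), shape=grid.shape)
            pts.extend(seg if not pts else seg[1:])
        for r, c in pts:
            if not target.path_mask[r, c]:
                height[r, c] = max(height[r, c], h)
                thread_mask[r, c] = True

    # ground-truth labels: thresholds applied to the *true* heights
    labels = np.full(grid.shape, DefectClass.BACKGROUND, np.uint8)
    on = target.path_mask
    labels[on] = _classify_values(
        height, target.target_thickness, tolerance_mm, zero_eps_mm=1e-9
    )[on]
    labels[thread_mask] = DefectClass.STRINGING
    gt = GroundTruth(height_mm=height.copy(), labels=labels, runs=runs, total_arc_mm=total)
    return height, gt


def render_volume(
    height_mm: np.ndarray,
    *,
    dz_mm: float = 0.01,
    nz: int = 128,
    base_index_px: float | np.ndarray | None = None,
    z_set_height_px: float = 0.0,
    speckle_contrast: float = 0.0,
    seed: int = 0,
    round_index: int = 1,
    lateral_pitch_mm: float = 0.0390625,
    signal: float = 1.0,
    background: float = 0.02,
) -> tuple[OCTVolume, AcquisitionMeta]:
    """Render a height field into an OCT-style intensity volume.

    Columns are bright from the surface index downward and dim above it; the
    surface index is base + descent - height/dz (the inverse of the
    thickness formula). ``base_index_px`` may be a field to emulate an
    uneven or tilted base. Multiplicative gamma speckle of the requested
    contrast is applied when ``speckle_contrast`` > 0; generation is
    deterministic for a fixed seed.
    """
    ny, nx = height_mm.shape
    if base_index_px is None:
        base_index_px = int(0.75 * nz)
    base = np.broadcast_to(np.asarray(base_index_px, float), (ny, nx))
    surf = np.round(base + z_set_height_px - height_mm / dz_mm)
    if np.any(surf < 0) or np.any(base + z_set_height_px > nz - 1):
        raise ValueError("height or base depth exceeds the volume's axial range")
    z_idx = np.arange(nz)[None, None, :]
    vol = np.where(z_idx >= surf[:, :, None], signal, background)
    if speckle_contrast > 0:
        rng = np.random.default_rng(seed)
        shape = 1.0 / speckle_contrast**2
        vol = vol * rng.gamma(shape, 1.0 / shape, size=vol.shape)
    meta = AcquisitionMeta(round_index=round_index, z_set_height_px=z_set_height_px)
    return (
        OCTVolume(
            intensity=vol.astype(np.float32),
            dz_mm=dz_mm,
            lateral_pitch_mm=lateral_pitch_mm,
        ),
        meta,
    )


def _program(
    polylines: list[list[tuple[float, float]]],
    z_mm: float,
    speed_mm_s: float,
) -> str:
    """Emit a single-layer GCode program: G0 travel to each polyline start,
    extruding G1 moves along it."""
    lines = []
    e = 0.0
    f_word = speed_mm_s * 60.0
    first = True
    for poly in polylines:
        x0, y0 = poly[0]
        if first:
            lines.append(f"G0 X{x0:.4f} Y{y0:.4f} Z{z_mm:.4f} F{f_word:.1f}")
            first = False
        else:
            lines.append(f"G0 X{x0:.4f} Y{y0:.4f}")
        for (xa, ya), (xb, yb) in zip(poly, poly[1:]):
            e += float(np.hypot(xb - xa, yb - ya))
            lines.append(f"G1 X{xb:.4f} Y{yb:.4f} E{e:.5f}")
    return "\n".join(lines) + "\n"


# gradient serpentine geometry shared by the fixture and its default defects
_GRAD_SPACINGS = [0.8, 1.0, 1.25, 1.55, 1.9]
_GRAD_X = (-4.0, 4.0)
_GRAD_Y0 = -4.0


def _gradient_serpentine() -> list[tuple[float, float]]:
    pts = [( _GRAD_X[0], _GRAD_Y0)]
    y = _GRAD_Y0
    left_to_right = True
    for i in range(len(_GRAD_SPACINGS) + 1):
        x_end = _GRAD_X[1] if left_to_right else _GRAD_X[0]
        pts.append((x_end, y))
        if i < len(_GRAD_SPACINGS):
            y += _GRAD_SPACINGS[i]
            pts.append((x_end, y))
        left_to_right = not left_to_right
    return pts


def _hatch_lines(angle_deg: float, spacing: float, half: float = 3.2) -> list[list[tuple[float, float]]]:
    """Parallel infill lines at the given angle clipped to a square patch."""
    theta = np.deg2rad(angle_deg)
    d = np.array([np.cos(theta), np.sin(theta)])
    n = np.array([-np.sin(theta), np.cos(theta)])
    lines = []
    span = half * 2.2
    k = 0
    offsets = np.arange(-half + spacing, half - spacing / 2, spacing)
    for off in offsets:
        p0 = n * off - d * span
        p1 = n * off + d * span
        # clip to the square by sampling the segment
        ts = np.linspace(0, 1, 801)
        seg = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
        inside = (np.abs(seg[:, 0]) <= half) & (np.abs(seg[:, 1]) <= half)
        if not inside.any():
            continue
        a, b = seg[inside][0], seg[inside][-1]
        pts = [(float(a[0]), float(a[1])), (float(b[0]), float(b[1]))]
        if k % 2:
            pts = pts[::-1]  # serpentine ordering
        lines.append(pts)
        k += 1
    return lines


SCENARIO_NAMES = (
    "minimal_line",
    "gradient_scaffold",
    "nose_like",
    "ear_like_90",
    "ear_like_60",
)


def scenario_fixtures(name: str, *, grid_n: int = 256, seed: int = 0) -> ScenarioBundle:
    """Small, scaled-down scenario bundles with print parameters matching the
    studied jobs (HAP gradient scaffold, silicone nose, PCL ear)."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}")

    if name == "minimal_line":
        cfg = JobConfig(nozzle_diameter_mm=0.41, pressure_mpa=0.18,
                        layer_thickness_mm=0.25, speed_mm_s=10.0,
                        grid_nx=grid_n, grid_ny=grid_n)
        gcode = _program([[(-4.5, 0.0), (4.5, 0.0)]], z_mm=0.25, speed_mm_s=10.0)
        return ScenarioBundle(name, gcode, cfg, DefectSpec(seed=seed))

    if name == "gradient_scaffold":
        cfg = JobConfig(nozzle_diameter_mm=0.41, pressure_mpa=0.18,
                        layer_thickness_mm=0.25, speed_mm_s=10.0,
                        grid_nx=grid_n, grid_ny=grid_n)
        gcode = _program([_gradient_serpentine()], z_mm=0.25, speed_mm_s=10.0)
        # default defect set: one repairable breakage (3.6 mm), a 1.2 mm
        # control gap, a 2 mm under-extrusion stretch, one turnaround blob,
        # one out-of-path stringing thread
        spec = DefectSpec(
            breakage_mm=[(2.0, 5.6), (10.0, 11.2)],
            scaled_mm=[(18.5, 20.5, 0.5)],
            blobs=[((4.0, -3.6), 0.18, 0.12)],
            threads=[([(-2.0, -2.7), (2.0, -2.7)], 0.10)],
            seed=seed,
        )
        return ScenarioBundle(name, gcode, cfg, spec)

    if name == "nose_like":
        cfg = JobConfig(nozzle_diameter_mm=0.21, pressure_mpa=0.15,
                        layer_thickness_mm=0.18, speed_mm_s=10.0,
                        grid_nx=grid_n, grid_ny=grid_n)
        # closed rounded contour with a nostril-like inner loop
        t = np.linspace(0, 2 * np.pi, 33)
        outer = [(3.5 * np.cos(a), 4.2 * np.sin(a)) for a in t]
        inner = [(1.0 * np.cos(a) + 0.8, 0.7 * np.sin(a) - 1.5) for a in t]
        gcode = _program([outer, inner], z_mm=0.18, speed_mm_s=10.0)
        return ScenarioBundle(name, gcode, cfg, DefectSpec(seed=seed))

    # ear-like cross-hatch patches: identical outlines, 90 vs 60 degree infill
    angle = 90.0 if name == "ear_like_90" else 60.0
    cfg = JobConfig(nozzle_diameter_mm=0.15, pressure_mpa=0.55,
                    layer_thickness_mm=0.18, speed_mm_s=2.0,
                    grid_nx=grid_n, grid_ny=grid_n)
    half = 3.2
    outline = [(-half, -half), (half, -half), (half, half), (-half, half), (-half, -half)]
    infill = _hatch_lines(angle, spacing=1.1, half=half - 0.25)
    gcode = _program([outline] + infill, z_mm=0.18, speed_mm_s=2.0)
    return ScenarioBundle(name, gcode, cfg, DefectSpec(seed=seed))
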
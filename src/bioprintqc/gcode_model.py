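"""Target-model generation from GCode toolpaths.

The printer's GCode program is the ground truth for where material *should*
be: each extruding G0/G1 move is a straight filament segment at a layer Z.
This module parses such programs into segments, groups them into layers,
rasterizes each layer onto a fixed millimetre grid (Bresenham centerline,
then a disc dilation to the calibrated filament width) and records the
calibrated filament height as the per-pixel target thickness. The resulting
``TargetModelMap`` is the reference against which the measured print is
compared downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.morphology import dilation, disk

__all__ = [
    "GridSpec",
    "PrintSegment",
    "LayerPath",
    "CalibrationTable",
    "TargetModelMap",
    "MultiLayerTargetModel",
    "GCodeDialect",
    "GCodeParseError",
    "parse_gcode",
    "group_layers",
    "bresenham_points",
    "lookup_filament_geometry",
    "rasterize_layer",
    "stack_layers",
    "LAYER_COLORS",
]


class GCodeParseError(ValueError):
    """Raised for malformed GCode, carrying the offending line number."""


@dataclass(frozen=True)
class GridSpec:
    """Millimetre <-> pixel mapping of the model space.

    The model space is a closed x/y extent (default [-5, 5] mm, or
    [-9.5, 9.5] mm in wide-field mode) sampled on an ``ny`` x ``nx`` pixel
    grid with pixel centers at ``extent_min + (i + 0.5) * pitch``. Arrays are
    indexed ``(row, col) == (y, x)`` with row 0 at the y minimum.
    """

    x_extent_mm: tuple[float, float] = (-5.0, 5.0)
    y_extent_mm: tuple[float, float] = (-5.0, 5.0)
    nx: int = 1024
    ny: int = 1024
    wide_field: bool = False

    def __post_init__(self) -> None:
        if self.wide_field and self.x_extent_mm == (-5.0, 5.0) and self.y_extent_mm == (-5.0, 5.0):
            object.__setattr__(self, "x_extent_mm", (-9.5, 9.5))
            object.__setattr__(self, "y_extent_mm", (-9.5, 9.5))
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs at least 2 pixels per axis")
        if self.x_extent_mm[1] <= self.x_extent_mm[0] or self.y_extent_mm[1] <= self.y_extent_mm[0]:
            raise ValueError("grid extents must have positive width")

    @property
    def pitch_x(self) -> float:
        return (self.x_extent_mm[1] - self.x_extent_mm[0]) / self.nx

    @property
    def pitch_y(self) -> float:
        return (self.y_extent_mm[1] - self.y_extent_mm[0]) / self.ny

    @property
    def pitch(self) -> float:
        """Isotropic pixel pitch (mm/px); x and y agree on the default grids."""
        return self.pitch_x

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def mm_to_pixel(self, x_mm, y_mm) -> tuple[np.ndarray, np.ndarray]:
        """Map mm coordinates to (col, row) indices of the nearest pixel
        center; ties round toward +inf. Results are clipped to the grid."""
        col = np.floor((np.asarray(x_mm, float) - self.x_extent_mm[0]) / self.pitch_x)
        row = np.floor((np.asarray(y_mm, float) - self.y_extent_mm[0]) / self.pitch_y)
        col = np.clip(col, 0, self.nx - 1).astype(int)
        row = np.clip(row, 0, self.ny - 1).astype(int)
        return col, row

    def pixel_to_mm(self, col, row) -> tuple[np.ndarray, np.ndarray]:
        x = self.x_extent_mm[0] + (np.asarray(col, float) + 0.5) * self.pitch_x
        y = self.y_extent_mm[0] + (np.asarray(row, float) + 0.5) * self.pitch_y
        return x, y

    def contains_mm(self, x_mm: float, y_mm: float) -> bool:
        return (
            self.x_extent_mm[0] <= x_mm <= self.x_extent_mm[1]
            and self.y_extent_mm[0] <= y_mm <= self.y_extent_mm[1]
        )


@dataclass(frozen=True)
class PrintSegment:
    """One straight nozzle move at a layer Z.

    ``extruding`` distinguishes filament advance from travel/retraction; a
    non-extruding segment never contributes pixels to a target map. Pressure
    is not a GCode word, so it is attached from the job configuration.
    """

    start_mm: tuple[float, float]
    end_mm: tuple[float, float]
    z_mm: float
    speed_mm_s: float
    pressure_mpa: float
    extruding: bool

    def __post_init__(self) -> None:
        if self.speed_mm_s <= 0:
            raise ValueError("segment speed must be positive")

    @property
    def length_mm(self) -> float:
        return float(np.hypot(self.end_mm[0] - self.start_mm[0], self.end_mm[1] - self.start_mm[1]))


@dataclass
class LayerPath:
    """All segments of one layer, in GCode order."""

    z_mm: float
    segments: list[PrintSegment]
    ordinal: int = 1


@dataclass
class CalibrationTable:
    """(speed, pressure) -> (filament width, filament height) lookup.

    Exact table points return the tabulated pair; other queries are resolved
    per ``mode``: "nearest" returns the closest entry, "linear" interpolates
    (piecewise-linear along whichever of speed/pressure actually varies, or
    a 2-D linear fit if both do), clamped to the table's convex hull.
    """

    entries: list[tuple[tuple[float, float], tuple[float, float]]]
    mode: str = "linear"

    def __post_init__(self) -> None:
        for (_s, _p), (w, h) in self.entries:
            if w <= 0 or h <= 0:
                raise ValueError("calibrated widths and heights must be positive")

    @classmethod
    def constant(cls, width_mm: float, height_mm: float) -> "CalibrationTable":
        """Single-entry table: the default when no calibration is supplied
        (width = nozzle inner diameter, height = layer thickness)."""
        return cls(entries=[((0.0, 0.0), (width_mm, height_mm))], mode="nearest")


def lookup_filament_geometry(
    speed_mm_s: float, pressure_mpa: float, table: CalibrationTable
) -> tuple[float, float]:
    """Resolve target filament (width, height) in mm for given print
    parameters using the calibration table."""
    if not table.entries:
        raise ValueError("calibration table is empty")
    pts = np.array([k for k, _ in table.entries], float)
    vals = np.array([v for _, v in table.entries], float)
    q = np.array([speed_mm_s, pressure_mpa], float)

    exact = np.all(pts == q, axis=1)
    if exact.any():
        w, h = vals[int(np.argmax(exact))]
        return float(w), float(h)
    if len(table.entries) == 1 or table.mode == "nearest":
        d = np.hypot(pts[:, 0] - q[0], pts[:, 1] - q[1])
        w, h = vals[int(np.argmin(d))]
        return float(w), float(h)

    # linear mode: clamp the query into the table's bounding ranges first
    q = np.clip(q, pts.min(axis=0), pts.max(axis=0))
    varying = [ax for ax in (0, 1) if np.unique(pts[:, ax]).size > 1]
    if len(varying) == 1:
        ax = varying[0]
        order = np.argsort(pts[:, ax])
        xk = pts[order, ax]
        w = float(np.interp(q[ax], xk, vals[order, 0]))
        h = float(np.interp(q[ax], xk, vals[order, 1]))
        return w, h
    from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

    out = []
    for col in (0, 1):
        lin = LinearNDInterpolator(pts, vals[:, col])
        v = lin(q[None, :])[0]
        if np.isnan(v):  # outside the convex hull after range clamping
            v = NearestNDInterpolator(pts, vals[:, col])(q[None, :])[0]
        out.append(float(v))
    return out[0], out[1]


@dataclass
class TargetModelMap:
    """Rasterized target of one layer (or one print-imaging round).

    ``target_thickness`` holds the calibrated filament height in mm (0 =
    background), ``path_mask`` is exactly its support, ``centerline`` marks
    the Bresenham raster before width dilation and ``centerline_points`` is
    the same set in toolpath order (used for arc-length measurements).
    ``target_width`` is the per-pixel calibrated filament width.
    """

    grid: GridSpec
    z_mm: float
    target_thickness: np.ndarray
    path_mask: np.ndarray
    centerline: np.ndarray
    centerline_points: list[tuple[int, int]]  # ordered (row, col)
    target_width: np.ndarray
    ordinal: int = 1


@dataclass
class MultiLayerTargetModel:
    layers: list[TargetModelMap]
    colors: list[tuple[float, float, float]] = field(default_factory=list)


@dataclass(frozen=True)
class GCodeDialect:
    """Configurable GCode conventions.

    With ``extrusion_from_e`` (default) a move extrudes iff its E word
    advances past the running E position; otherwise paired on/off command
    codes toggle the extrusion state. F is mm/min per standard GCode and is
    converted to mm/s internally.
    """

    extrusion_from_e: bool = True
    extrusion_on_codes: tuple[str, ...] = ()
    extrusion_off_codes: tuple[str, ...] = ()


_WORD_RE = re.compile(r"([A-Za-z])([-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)$")


def _strip_comment(line: str) -> str:
    line = line.split(";", 1)[0]
    return re.sub(r"\([^)]*\)", "", line)


def parse_gcode(
    text: str,
    *,
    dialect: GCodeDialect | None = None,
    pressure_mpa: float = 0.18,
    default_speed_mm_s: float = 10.0,
) -> list[PrintSegment]:
    """Parse GCode text into print segments with modal state.

    One segment is emitted per motion line that moves in X-Y from an
    established position; the first positioning move only sets the start
    point. Raises :class:`GCodeParseError` (with the line number) for
    malformed coordinate words or for X-Y motion before any Z is set.
    """
    dialect = dialect or GCodeDialect()
    segments: list[PrintSegment] = []
    pos: tuple[float, float] | None = None
    z: float | None = None
    speed = default_speed_mm_s
    e_pos = 0.0
    extrude_toggle = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        words = {}
        tokens = line.split()
        for tok in tokens:
            m = _WORD_RE.match(tok)
            if m is None:
                raise GCodeParseError(f"line {lineno}: malformed word {tok!r}")
            letter = m.group(1).upper()
            words.setdefault(letter, []).append(float(m.group(2)))

        cmds = {f"{t[0].upper()}{t[1:]}" for t in tokens if t}
        if dialect.extrusion_on_codes and cmds & set(dialect.extrusion_on_codes):
            extrude_toggle = True
            continue
        if dialect.extrusion_off_codes and cmds & set(dialect.extrusion_off_codes):
            extrude_toggle = False
            continue

        g = words.get("G", [None])[0]
        if g is None or int(g) not in (0, 1):
            continue  # non-motion command (M-codes etc.)

        if "F" in words:
            speed = words["F"][0] / 60.0  # mm/min -> mm/s
        if "Z" in words:
            z = words["Z"][0]

        has_xy = "X" in words or "Y" in words
        if not has_xy:
            continue
        if z is None:
            raise GCodeParseError(f"line {lineno}: X/Y motion before any Z is set")

        x = words.get("X", [pos[0] if pos else None])[0]
        y = words.get("Y", [pos[1] if pos else None])[0]
        if pos is None and (x is None or y is None):
            raise GCodeParseError(f"line {lineno}: incomplete first position")
        new_pos = (float(x), float(y))

        if dialect.extrusion_from_e:
            if "E" in words:
                e_new = words["E"][0]
                extruding = e_new > e_pos
                e_pos = e_new
            else:
                extruding = False
        else:
            extruding = extrude_toggle

        if pos is not None:
            segments.append(
                PrintSegment(
                    start_mm=pos,
                    end_mm=new_pos,
                    z_mm=float(z),
                    speed_mm_s=speed,
                    pressure_mpa=pressure_mpa,
                    extruding=extruding,
                )
            )
        pos = new_pos
    return segments


def group_layers(
    segments: Sequence[PrintSegment], *, layer_thickness_mm: float = 0.25
) -> list[LayerPath]:
    """Partition segments into layers by Z (tolerance: half the layer
    thickness), ascending in z, ordinals 1..K, GCode order kept per layer."""
    if not segments:
        return []
    tol = layer_thickness_mm / 2.0
    reps: list[float] = []  # representative z per cluster
    buckets: dict[int, list[PrintSegment]] = {}
    for seg in segments:
        for i, zr in enumerate(reps):
            if abs(seg.z_mm - zr) < tol:
                buckets[i].append(seg)
                break
        else:
            reps.append(seg.z_mm)
            buckets[len(reps) - 1] = [seg]
    order = np.argsort(reps)
    return [
        LayerPath(z_mm=reps[i], segments=buckets[i], ordinal=k + 1)
        for k, i in enumerate(order)
    ]


def bresenham_points(
    p0: tuple[int, int], p1: tuple[int, int], shape: tuple[int, int] | None = None
) -> list[tuple[int, int]]:
    """Standard Bresenham raster from p0 to p1 inclusive, 8-connected.

    Points are (row, col). If ``shape`` is given, out-of-grid endpoints raise
    ``ValueError``.
    """
    r0, c0 = int(p0[0]), int(p0[1])
    r1, c1 = int(p1[0]), int(p1[1])
    if shape is not None:
        for r, c in ((r0, c0), (r1, c1)):
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValueError(f"endpoint ({r}, {c}) outside grid of shape {shape}")
    dr = abs(r1 - r0)
    dc = abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dc - dr
    r, c = r0, c0
    pts = []
    while True:
        pts.append((r, c))
        if r == r1 and c == c1:
            break
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr
    return pts


def rasterize_layer(
    layer: LayerPath, grid: GridSpec, table: CalibrationTable | None = None
) -> TargetModelMap:
    """Rasterize one layer into a target model map.

    The centerline is the union of Bresenham rasters of the extruding
    segments; the path mask dilates each segment's raster with a disc of
    radius round(width / (2 * pitch)) pixels; target thickness is the
    calibrated filament height on the mask. Where segments of different
    calibration overlap, the larger width/height wins.
    """
    if table is None:
        table = CalibrationTable.constant(0.41, 0.25)
    ny, nx = grid.shape
    thickness = np.zeros((ny, nx), float)
    width_field = np.zeros((ny, nx), float)
    centerline = np.zeros((ny, nx), bool)
    points: list[tuple[int, int]] = []

    # group segment rasters by calibrated geometry so each (w, h) needs one
    # dilation pass
    groups: dict[tuple[float, float], np.ndarray] = {}
    for seg in layer.segments:
        if not seg.extruding:
            continue
        for x, y in (seg.start_mm, seg.end_mm):
            if not grid.contains_mm(x, y):
                raise ValueError(
                    f"segment {seg.start_mm}->{seg.end_mm} endpoint ({x}, {y}) "
                    f"outside grid extents x={grid.x_extent_mm}, y={grid.y_extent_mm}"
                )
        c0, r0 = grid.mm_to_pixel(*seg.start_mm)
        c1, r1 = grid.mm_to_pixel(*seg.end_mm)
        pts = bresenham_points((int(r0), int(c0)), (int(r1), int(c1)), shape=(ny, nx))
        if points and pts and pts[0] == points[-1]:
            pts_for_order = pts[1:]  # shared joint between consecutive segments
        else:
            pts_for_order = pts
        points.extend(pts_for_order)
        w, h = lookup_filament_geometry(seg.speed_mm_s, seg.pressure_mpa, table)
        key = (w, h)
        if key not in groups:
            groups[key] = np.zeros((ny, nx), bool)
        rows, cols = zip(*pts)
        groups[key][list(rows), list(cols)] = True
        centerline[list(rows), list(cols)] = True

    # thicker deposit dominates where differing geometries overlap
    for (w, h) in sorted(groups, key=lambda k: (k[0], k[1])):
        radius = int(round(w / (2.0 * grid.pitch)))
        mask = groups[(w, h)]
        if radius > 0:
            mask = dilation(mask, disk(radius))
        thickness[mask] = np.maximum(thickness[mask], h)
        width_field[mask] = np.maximum(width_field[mask], w)

    return TargetModelMap(
        grid=grid,
        z_mm=layer.z_mm,
        target_thickness=thickness,
        path_mask=thickness > 0,
        centerline=centerline,
        centerline_points=points,
        target_width=width_field,
        ordinal=layer.ordinal,
    )


# Z color coding of stacked layers: first two entries are deep blue and green,
# then a spread of distinct hues for deeper stacks.
LAYER_COLORS: list[tuple[float, float, float]] = [
    (0.0, 0.0, 0.55),  # deep blue
    (0.0, 0.8, 0.0),   # green
    (0.9, 0.6, 0.0),
    (0.8, 0.0, 0.8),
    (0.0, 0.75, 0.75),
    (0.9, 0.1, 0.1),
    (0.5, 0.5, 1.0),
    (1.0, 1.0, 0.3),
]


def stack_layers(maps: Sequence[TargetModelMap]) -> MultiLayerTargetModel:
    """Stack per-layer maps with Z-related color coding.

    Layers must share a GridSpec; ordinals must increase with z.
    """
    maps = list(maps)
    if maps:
        g0 = maps[0].grid
        for m in maps[1:]:
            if m.grid != g0:
                raise ValueError("all layers must share the same GridSpec")
        maps = sorted(maps, key=lambda m: m.ordinal)
        zs = [m.z_mm for m in maps]
        if any(z2 <= z1 for z1, z2 in zip(zs, zs[1:])):
            raise ValueError("layer ordinals must increase strictly with z")
    colors = [LAYER_COLORS[i % len(LAYER_COLORS)] for i in range(len(maps))]
    return MultiLayerTargetModel(layers=maps, colors=colors)


def render_stack(model: MultiLayerTargetModel) -> np.ndarray:
    """RGB composite of a layer stack; later layers paint over earlier ones."""
    if not model.layers:
        raise ValueError("empty stack")
    ny, nx = model.layers[0].grid.shape
    rgb = np.zeros((ny, nx, 3), float)
    for m, color in zip(model.layers, model.colors):
        rgb[m.path_mask] = color
    return rgb
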
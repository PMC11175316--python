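"""Secondary-printing repair of breakage and under-extrusion runs.

Defect runs at least 1.5 mm long can be repaired by a secondary print pass
over the defective span: travel to the run start, extrude along the run to
its end, stop. Repair toolpaths are emitted as GCode in the same dialect the
parser reads, so a generated program round-trips through ``parse_gcode``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .defect_map import DefectClass, DefectRun
from .gcode_model import GridSpec

__all__ = [
    "RepairMove",
    "RepairPlan",
    "select_repairable",
    "plan_repairs",
    "generate_repair_gcode",
    "relative_improvement_pct",
    "verify_repair",
]

MIN_REPAIR_LENGTH_MM = 1.5  # secondary printing triggers at runs >= 1.5 mm


@dataclass
class RepairMove:
    """One extruding repair pass along a defective run (polyline in mm)."""

    points_mm: list[tuple[float, float]]
    z_mm: float
    speed_mm_s: float
    pressure_mpa: float
    defect_class: DefectClass


@dataclass
class RepairPlan:
    runs: list[DefectRun]
    moves: list[RepairMove]
    min_length_mm: float = MIN_REPAIR_LENGTH_MM


def select_repairable(
    runs: list[DefectRun],
    min_length_mm: float = MIN_REPAIR_LENGTH_MM,
    classes: tuple[DefectClass, ...] = (
        DefectClass.FILAMENT_BREAKAGE,
        DefectClass.UNDER_EXTRUSION,
    ),
) -> list[DefectRun]:
    """Runs that warrant repair: breakage or under-extrusion reaching or
    exceeding the minimum length (threshold inclusive). Over-extrusion can
    never be fixed by adding material and is never selected."""
    return [
        r
        for r in runs
        if r.defect_class in classes and r.length_mm >= min_length_mm
    ]


def _merge_collinear(points: list[tuple[float, float]], tol: float = 1e-9) -> list[tuple[float, float]]:
    """Drop interior points collinear with their neighbors (cross-product test)."""
    if len(points) <= 2:
        return points
    merged = [points[0]]
    for prev, cur, nxt in zip(points, points[1:], points[2:]):
        cross = (cur[0] - prev[0]) * (nxt[1] - prev[1]) - (cur[1] - prev[1]) * (
            nxt[0] - prev[0]
        )
        if abs(cross) > tol:
            merged.append(cur)
    merged.append(points[-1])
    return merged


def plan_repairs(
    runs: list[DefectRun],
    grid: GridSpec,
    *,
    speed_mm_s: float = 10.0,
    pressure_mpa: float = 0.18,
    min_length_mm: float = MIN_REPAIR_LENGTH_MM,
    classes: tuple[DefectClass, ...] = (DefectClass.FILAMENT_BREAKAGE,),
) -> RepairPlan:
    """Build a repair plan from measured runs.

    Each selected run becomes one repair move along its centerline pixels
    converted to mm, with collinear points merged (a straight gap yields a
    single start->end line). By default only breakage runs get a secondary
    print pass; under-extrusion is better addressed by parameter adjustment
    but may be included via ``classes``.
    """
    selected = select_repairable(runs, min_length_mm, classes)
    moves = []
    for run in selected:
        xs, ys = grid.pixel_to_mm(
            [c for _, c in run.pixels], [r for r, _ in run.pixels]
        )
        pts = _merge_collinear(list(zip(map(float, np.atleast_1d(xs)), map(float, np.atleast_1d(ys)))))
        moves.append(
            RepairMove(
                points_mm=pts,
                z_mm=run.z_mm,
                speed_mm_s=speed_mm_s,
                pressure_mpa=pressure_mpa,
                defect_class=run.defect_class,
            )
        )
    return RepairPlan(runs=selected, moves=moves, min_length_mm=min_length_mm)


def generate_repair_gcode(plan: RepairPlan) -> str:
    """Emit the secondary-printing program for a repair plan.

    Per move: a travel (G0, no E) to the start, then extruding G1 moves (E
    advancing by the path length) along the polyline. An empty plan yields a
    program with a comment header and zero motion lines.
    """
    lines = ["; bioprintqc secondary-printing repair program"]
    if not plan.moves:
        lines.append("; no repairable defects")
        return "\n".join(lines) + "\n"
    e = 0.0
    for i, mv in enumerate(plan.moves, start=1):
        lines.append(f"; repair {i}: {mv.defect_class.name.lower()}")
        x0, y0 = mv.points_mm[0]
        f_word = mv.speed_mm_s * 60.0
        lines.append(f"G0 X{x0:.4f} Y{y0:.4f} Z{mv.z_mm:.4f} F{f_word:.1f}")
        for (xa, ya), (xb, yb) in zip(mv.points_mm, mv.points_mm[1:]):
            e += float(np.hypot(xb - xa, yb - ya))
            lines.append(f"G1 X{xb:.4f} Y{yb:.4f} E{e:.5f}")
    return "\n".join(lines) + "\n"


def relative_improvement_pct(before: float, after: float) -> float:
    """Relative fidelity change in percent: (after - before) / before * 100."""
    if before == 0:
        raise ValueError("undefined improvement from zero fidelity")
    return (after - before) / before * 100.0


def verify_repair(
    fidelity_before: float,
    fidelity_after: float,
    *,
    areas_before: dict[str, float] | None = None,
    areas_after: dict[str, float] | None = None,
) -> dict:
    """Before/after repair report with the relative improvement in %."""
    report = {
        "fidelity_before": float(fidelity_before),
        "fidelity_after": float(fidelity_after),
        "improvement_pct": relative_improvement_pct(fidelity_before, fidelity_after),
    }
    if areas_before is not None:
        report["defect_areas_before_mm2"] = areas_before
    if areas_after is not None:
        report["defect_areas_after_mm2"] = areas_after
    return report
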
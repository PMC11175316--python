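"""End-to-end print-imaging pipeline.

One *round* of the alternating print-imaging workflow covers one or more
printed layers: the GCode defines the round's target map (per-pixel sum of
the covered layers' thicknesses), the scan provides the measured thickness,
and the comparison yields the defect map, the fidelity score and, where
breakage runs reach the repair threshold, a secondary-printing plan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import JobConfig
from .defect_map import (
    DefectClass,
    DefectMap,
    DefectRun,
    classify_in_path,
    compose_defect_map,
    detect_stringing,
    mask_recon_in_path,
    measure_defect_runs,
    render_defect_map,
)
from .fidelity import FidelityResult, build_recon_full, fidelity_series, layer_fidelity
from .gcode_model import (
    GridSpec,
    TargetModelMap,
    group_layers,
    parse_gcode,
    rasterize_layer,
)
from .oct_reconstruction import (
    AcquisitionMeta,
    OCTVolume,
    ReconstructedModelMap,
    compute_thickness,
    detect_surface,
)
from .repair import RepairPlan, generate_repair_gcode, plan_repairs

__all__ = ["RoundResult", "RunReport", "build_targets", "combine_round_target",
           "reconstruct_observation", "run_pipeline", "render_report"]


@dataclass
class RoundResult:
    round_index: int
    target: TargetModelMap
    recon: ReconstructedModelMap
    defect_map: DefectMap
    fidelity: FidelityResult
    runs: list[DefectRun]
    repair_plan: RepairPlan
    repair_gcode: str | None


@dataclass
class RunReport:
    config: JobConfig
    rounds: list[RoundResult]
    fidelity_summary: dict
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config.to_dict(),
            "fidelity_summary": self.fidelity_summary,
            "rounds": [
                {
                    "round": r.round_index,
                    "z_mm": r.target.z_mm,
                    "mean_ssim": r.fidelity.mean_ssim,
                    "class_areas_mm2": r.defect_map.class_areas_mm2(),
                    "defect_runs": [
                        {
                            "class": run.defect_class.name.lower(),
                            "start_mm": list(run.start_mm),
                            "end_mm": list(run.end_mm),
                            "length_mm": run.length_mm,
                            "z_mm": run.z_mm,
                        }
                        for run in r.runs
                    ],
                    "n_repair_moves": len(r.repair_plan.moves),
                }
                for r in self.rounds
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def build_targets(config: JobConfig, gcode_text: str) -> list[TargetModelMap]:
    """GCode text -> per-layer target maps under the job's grid/calibration."""
    segs = parse_gcode(
        gcode_text,
        dialect=config.dialect(),
        pressure_mpa=config.pressure_mpa,
        default_speed_mm_s=config.speed_mm_s,
    )
    layers = group_layers(segs, layer_thickness_mm=config.layer_thickness_mm)
    grid = config.grid()
    table = config.calibration()
    return [rasterize_layer(layer, grid, table) for layer in layers]


def combine_round_target(layers: list[TargetModelMap]) -> TargetModelMap:
    """Merge the layers covered by one imaging round: thicknesses add
    per pixel, masks and centerlines union, widths take the maximum."""
    if not layers:
        raise ValueError("a round must cover at least one layer")
    if len(layers) == 1:
        return layers[0]
    base = layers[0]
    thickness = np.zeros_like(base.target_thickness)
    width = np.zeros_like(base.target_width)
    centerline = np.zeros_like(base.centerline)
    points: list[tuple[int, int]] = []
    for m in layers:
        thickness += m.target_thickness
        width = np.maximum(width, m.target_width)
        centerline |= m.centerline
        points.extend(m.centerline_points)
    return TargetModelMap(
        grid=base.grid,
        z_mm=layers[-1].z_mm,
        target_thickness=thickness,
        path_mask=thickness > 0,
        centerline=centerline,
        centerline_points=points,
        target_width=width,
        ordinal=layers[-1].ordinal,
    )


def reconstruct_observation(
    obs,
    config: JobConfig,
    grid: GridSpec,
    *,
    base_surface=None,
    round_index: int = 1,
) -> ReconstructedModelMap:
    """Normalize one round's observation into a ReconstructedModelMap.

    Accepts an existing map, a raw height array (mm), or an
    ``(OCTVolume, OCTVolume_base, AcquisitionMeta)`` triple which is run
    through surface detection and the thickness formula.
    """
    if isinstance(obs, ReconstructedModelMap):
        return obs
    if isinstance(obs, np.ndarray):
        return ReconstructedModelMap(thickness_mm=obs.astype(float), grid=grid,
                                     round_index=round_index)
    volume, base_volume, meta = obs
    print_surface = detect_surface(volume)
    base = base_surface if base_surface is not None else detect_surface(base_volume)
    return compute_thickness(print_surface, base, meta, volume.dz_mm, grid=grid)


def run_pipeline(
    config: JobConfig,
    gcode_text: str,
    observations: list,
    *,
    layers_per_round: int = 1,
    emit_repair_gcode: bool = True,
) -> RunReport:
    """Run target generation, reconstruction, defect mapping, fidelity and
    repair planning for every imaging round.

    ``observations[i]`` is round i's scan (see ``reconstruct_observation``);
    round i covers layers ``i*layers_per_round .. (i+1)*layers_per_round``.
    Stage errors are re-raised with the round index attached.
    """
    layer_maps = build_targets(config, gcode_text)
    grid = config.grid()
    repair_classes = tuple(DefectClass[c.upper()] for c in config.repair_classes)

    rounds: list[RoundResult] = []
    for i, obs in enumerate(observations, start=1):
        try:
            covered = layer_maps[(i - 1) * layers_per_round : i * layers_per_round]
            target = combine_round_target(covered)
            recon = reconstruct_observation(obs, config, grid, round_index=i)
            in_path = mask_recon_in_path(recon, target)
            labels_in = classify_in_path(
                in_path, target, config.tolerance_mm, zero_eps_mm=config.dz_mm / 2.0
            )
            stringing = detect_stringing(
                recon, target, dilation_radius_px=config.stringing_dilation_px,
                zero_eps_mm=config.dz_mm / 2.0,
            )
            dmap = compose_defect_map(
                labels_in, stringing, grid,
                tolerance_mm=config.tolerance_mm, z_mm=target.z_mm, round_index=i,
            )
            runs = measure_defect_runs(dmap, target)
            evaluation = build_recon_full(dmap, recon)
            fid = layer_fidelity(
                target, evaluation, window_px=config.ssim_window_px, round_index=i
            )
            plan = plan_repairs(
                runs, grid,
                speed_mm_s=config.speed_mm_s, pressure_mpa=config.pressure_mpa,
                min_length_mm=config.min_repair_length_mm, classes=repair_classes,
            )
            gcode = generate_repair_gcode(plan) if emit_repair_gcode and plan.moves else None
        except Exception as exc:  # annotate with the failing round
            raise type(exc)(f"round {i}: {exc}") from exc
        rounds.append(
            RoundResult(
                round_index=i, target=target, recon=recon, defect_map=dmap,
                fidelity=fid, runs=runs, repair_plan=plan, repair_gcode=gcode,
            )
        )
    if rounds:
        _, summary = fidelity_series([r.fidelity for r in rounds])
    else:
        summary = {"n_layers": 0}
    return RunReport(config=config, rounds=rounds, fidelity_summary=summary,
                     seed=config.seed)


def render_report(report: RunReport, out_dir: str | Path) -> list[Path]:
    """Write per-round figure panels and a Markdown summary; returns paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for r in report.rounds:
        fig, axes = plt.subplots(1, 4, figsize=(16, 4))
        axes[0].imshow(r.target.target_thickness, origin="lower", cmap="viridis")
        axes[0].set_title("target thickness (mm)")
        axes[1].imshow(np.nan_to_num(r.recon.thickness_mm), origin="lower", cmap="viridis")
        axes[1].set_title("reconstructed thickness (mm)")
        axes[2].imshow(render_defect_map(r.defect_map), origin="lower")
        axes[2].set_title("defect characterization")
        axes[3].imshow(r.fidelity.ssim_map, origin="lower", cmap="magma", vmin=-1, vmax=1)
        axes[3].set_title(f"SSIM (mean {r.fidelity.mean_ssim:.4f})")
        for ax in axes:
            ax.set_xticks([])
            ax.set_yticks([])
        p = out / f"round_{r.round_index:02d}.png"
        fig.savefig(p, dpi=110, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    if report.rounds:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        xs = [r.round_index for r in report.rounds]
        ys = [r.fidelity.mean_ssim for r in report.rounds]
        ax.bar(xs, ys, color="#2c7fb8")
        ax.set_xlabel("round")
        ax.set_ylabel("fidelity (mean SSIM)")
        ax.set_ylim(0, 1.05)
        p = out / "fidelity_series.png"
        fig.savefig(p, dpi=110, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    lines = ["# Print run summary", ""]
    if not report.rounds:
        lines.append("Zero rounds processed.")
    else:
        s = report.fidelity_summary
        lines.append(
            f"{s['n_layers']} round(s); fidelity "
            f"{s['fidelity_mean']:.4f} ± {s['fidelity_sd']:.4f} (sd)."
        )
        lines.append("")
        lines.append("| round | z (mm) | fidelity | defect runs | repair moves |")
        lines.append("|---|---|---|---|---|")
        for r in report.rounds:
            lines.append(
                f"| {r.round_index} | {r.target.z_mm:.3f} | "
                f"{r.fidelity.mean_ssim:.4f} | {len(r.runs)} | "
                f"{len(r.repair_plan.moves)} |"
            )
    p = out / "summary.md"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)
    return written
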
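import dataclasses

import numpy as np
import pytest

import bioprintqc as q


@pytest.fixture(scope="session")
def gradient_run():
    """Noiseless end-to-end run of the gradient-scaffold scenario at 256x256.

    The scenario injects one repairable 3.6 mm breakage, a 1.2 mm control
    gap, a 2 mm under-extrusion stretch, a turnaround accumulation blob and
    one out-of-path stringing thread. Also runs the simulated repair (the
    3.6 mm gap re-rendered filled) for before/after comparisons.
    """
    bundle = q.scenario_fixtures("gradient_scaffold", grid_n=256, seed=7)
    cfg = bundle.config
    maps = q.build_targets(cfg, bundle.gcode)
    target = maps[0]
    height, gt = q.render_heightmap(target, bundle.defect_spec, tolerance_mm=cfg.tolerance_mm)
    vol, meta = q.render_volume(height, dz_mm=cfg.dz_mm)
    base_vol, _ = q.render_volume(np.zeros_like(height), dz_mm=cfg.dz_mm)
    report = q.run_pipeline(cfg, bundle.gcode, [(vol, base_vol, meta)])

    # simulated repair: drop the repairable gap, keep everything else
    spec_after = dataclasses.replace(bundle.defect_spec, breakage_mm=[(10.0, 11.2)])
    height_after, _ = q.render_heightmap(target, spec_after, tolerance_mm=cfg.tolerance_mm)
    vol_after, meta_after = q.render_volume(height_after, dz_mm=cfg.dz_mm)
    report_after = q.run_pipeline(cfg, bundle.gcode, [(vol_after, base_vol, meta_after)])

    return {
        "bundle": bundle,
        "config": cfg,
        "target": target,
        "height": height,
        "gt": gt,
        "report": report,
        "round": report.rounds[0],
        "report_after": report_after,
        "round_after": report_after.rounds[0],
    }


@pytest.fixture()
def minimal_run():
    """Noiseless perfect print of a single 9 mm line."""
    bundle = q.scenario_fixtures("minimal_line", grid_n=256, seed=1)
    cfg = bundle.config
    maps = q.build_targets(cfg, bundle.gcode)
    height, gt = q.render_heightmap(maps[0], bundle.defect_spec)
    vol, meta = q.render_volume(height, dz_mm=cfg.dz_mm)
    base_vol, _ = q.render_volume(np.zeros_like(height), dz_mm=cfg.dz_mm)
    report = q.run_pipeline(cfg, bundle.gcode, [(vol, base_vol, meta)])
    return {"bundle": bundle, "target": maps[0], "gt": gt, "report": report}
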
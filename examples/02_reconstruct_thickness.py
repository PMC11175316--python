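"""Reconstruct printed thickness from an OCT-style volume.

A synthetic scan of a 0.25 mm print on a *tilted* base platform shows how
referencing each acquisition to the base scan cancels base unevenness:
thickness = (base_index + platform_descent - surface_index) * dz.
"""

import numpy as np

import bioprintqc as q

bundle = q.scenario_fixtures("minimal_line", grid_n=256)
target = q.build_targets(bundle.config, bundle.gcode)[0]
height, _ = q.render_heightmap(target, q.DefectSpec())

# base plane tilted by 10 px across the field; descent of 4 px since base scan
tilt = 85 + 10 * np.linspace(0, 1, 256)[None, :] * np.ones((256, 1))
vol, meta = q.render_volume(height, dz_mm=0.01, base_index_px=tilt,
                            z_set_height_px=4.0)
base_vol, _ = q.render_volume(np.zeros_like(height), dz_mm=0.01,
                              base_index_px=tilt)

surface = q.detect_surface(vol)
base = q.detect_surface(base_vol)
recon = q.compute_thickness(surface, base, meta, dz_mm=0.01, grid=target.grid)

on = target.path_mask
print(f"mean thickness on path: {recon.thickness_mm[on].mean():.4f} mm "
      f"(true height 0.25 mm; tilt cancelled by base referencing)")
print(f"max |error| on path:    {np.abs(recon.thickness_mm[on] - height[on]).max():.4f} mm "
      f"(bounded by the 0.01 mm axial pixel)")
print(f"off-path thickness:     {np.nan_to_num(recon.thickness_mm)[~on].max():.4f} mm")

profile = q.extract_cross_section(recon.thickness_mm, col=128)
plateau = int((profile > 0.2).sum())
print(f"cross-section plateau:  {plateau} px wide "
      f"= {plateau * target.grid.pitch:.3f} mm (the 0.41 mm filament)")
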
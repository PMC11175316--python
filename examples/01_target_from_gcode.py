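"""Rasterize a GCode toolpath into a target model map.

A two-line program draws one 9 mm filament. The calibrated filament width
(0.41 mm nozzle) and height (0.25 mm layer) become the per-pixel target the
printed structure is later compared against.
"""

import numpy as np

import bioprintqc as q

gcode = """\
G1 X-4.5 Y0 Z0.25 F600
G1 X4.5 Y0 E9.0
"""

segments = q.parse_gcode(gcode, pressure_mpa=0.18)
print(f"parsed {len(segments)} segment(s); first: "
      f"{segments[0].start_mm} -> {segments[0].end_mm} at "
      f"{segments[0].speed_mm_s:.1f} mm/s, z = {segments[0].z_mm} mm")

layers = q.group_layers(segments, layer_thickness_mm=0.25)
grid = q.GridSpec()  # 1024 x 1024 over [-5, 5] mm
target = q.rasterize_layer(layers[0], grid)

cols = np.where(target.path_mask.any(axis=0))[0]
stripe_px = int(target.path_mask[:, cols[len(cols) // 2]].sum())
print(f"grid pitch: {grid.pitch:.6f} mm/px")
print(f"stripe width: {stripe_px} px = {stripe_px * grid.pitch:.3f} mm "
      f"(calibrated filament width 0.41 mm)")
print(f"target thickness on path: {target.target_thickness.max():.2f} mm "
      f"(the 0.25 mm layer height); background pixels are 0")
print(f"path covers {target.path_mask.sum()} px "
      f"= {target.path_mask.sum() * grid.pitch**2:.2f} mm^2 "
      f"(approx. 9 mm x 0.41 mm = 3.69 mm^2 plus rounded end caps)")
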
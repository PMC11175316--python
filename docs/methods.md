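# Methods

This note documents the models, parameter choices and numerical conventions
behind `bioprintqc`, and what its synthetic-data tests do and do not show
about instrument data.

## Target model generation

GCode is the authoritative statement of intent. The parser keeps modal state
(last-seen Z, feed rate, E position) and emits one straight segment per
motion line once an X–Y position is established; F is mm/min per standard
GCode and converted to mm/s internally. Extrusion state comes from the
E word by default (an advancing E means deposition; a receding E is a
retraction) or from configurable on/off command codes, since firmware
dialects differ. Print pressure is not a GCode word; it is a per-job
constant supplied in the configuration, matching how pneumatic extruders are
actually operated (one regulator setting per model).

Segments are grouped into layers by Z with tolerance |Δz| < layer
thickness/2 — tight enough to split real layers, loose enough to absorb
float formatting jitter in emitted GCode.

The model space is a closed extent (default [−5, 5] mm per axis, [−9.5,
9.5] mm wide-field) sampled 1024×1024 (configurable). Pixel centers sit at
`min + (i + 0.5)·pitch`; mm→pixel rounds to the nearest center with ties
toward +∞, so the round-trip error is at most half a pitch. Each extruding
segment is rasterized with the classic integer Bresenham algorithm
(8-connected, endpoints inclusive — verified exhaustively against a
brute-force nearest-pixel sampler), then dilated with a disc of radius
`round(width / (2·pitch))`, which reproduces the round footprint of an
extruded filament. The calibrated filament height becomes the per-pixel
target thickness. Where segments with different calibrations overlap, the
larger width/height wins: physically, the thicker deposit dominates the
stack-up. Layer stacks are colored by ordinal, deep blue then green first.

Calibration is a (speed, pressure) → (width, height) table with nearest or
linear interpolation, clamped to the tabulated ranges. When no table is
supplied, width defaults to the nozzle inner diameter and height to the
layer thickness — the behaviour of a well-tuned extruder at its nominal
operating point, and the configuration used by all bundled scenarios.

## Thickness reconstruction

Input volumes are intensity-reconstructed OCT-style stacks with axes
(y, x, z), z the depth axis, axial resolution ΔZ in mm/px. Surface
detection scans each lateral column for the shallowest voxel exceeding a
threshold, optionally after 1-D smoothing along depth. The default
threshold is Otsu's value over the whole volume: a two-phase (bright
material / dim background) separation that does not depend on the volume
fraction of material. A mean + k·std alternative is provided
(`method="mean_std"`), but note it fails once the bright phase fills more
than roughly a third of the volume, because the global std then pushes the
threshold above the signal level. Columns that never cross the threshold
are marked invalid.

Printed thickness per pixel is

    thickness = (z_base + z_descent − z_surface) · ΔZ,

where `z_base` is the base-platform surface index from a reference scan,
`z_descent` the platform descent (in pixels) since that scan, and
`z_surface` the current surface index. The multiplication by ΔZ applies to
the whole pixel-valued difference — the only dimensionally consistent
reading. Because every round is referenced to the same base scan, any base
unevenness (tilt, waviness) cancels exactly; this is a tested invariant.
Negative thickness (surface apparently below the descended base) signals a
registration error: it is clipped to zero and counted, never silently kept.
Invalid columns propagate as NaN; inside the target path they are treated
as zero thickness for classification and therefore read as breakage, which
is the desired failure mode for a column with no detectable material.
Surface indices are always reported in the depth-downward frame; volumes
stored upside-down set `z_down=False` and are flipped on load.

Rounds may cover several printed layers (deep-penetration materials are
imaged every layer; opaque pastes every few layers). A round's target is
then the per-pixel sum of the covered layers' thicknesses, the union of
their masks and centerlines.

## Defect classification

Classification authority is the toolpath centerline: for each centerline
pixel the measured thickness t is compared with the target T under
tolerance δ (default 0.05 mm):

| state | rule |
|---|---|
| normal | T − δ ≤ t ≤ T + δ (band edges inclusive) |
| under-extrusion | ε ≤ t < T − δ |
| over-extrusion | t > T + δ |
| filament breakage | t < ε (and T ≠ 0) |

The zero test uses ε = ΔZ/2 in the pipeline (half an axial pixel) because
an exact float zero is fragile; with that convention the four rules
partition all (t, T > 0) pairs, which is property-tested. Centerline labels
are propagated laterally by assigning every in-path pixel the label of its
nearest centerline pixel — an exact, tie-stable realization of "spread over
the local filament half-width". When crossing paths give a pixel two
targets, the rasterizer's max rule already decided the larger target wins.

Stringing is morphological: binarize the reconstruction (t > ε),
skeletonize, dilate the skeleton with a disc (default radius = filament
half-width in pixels), intersect with the inverted path mask, then clean
with a morphological opening (default 3×3 square). The dilation radius and
opening element are configurable because their interplay sets the minimum
feature size that survives: with a small dilation radius the 3×3 opening
removes isolated speckle but keeps threads longer than the element; with
the default half-width radius, sub-element debris is instead suppressed by
the binarization threshold. Stringing and in-path labels are disjoint by
construction; an overlap raises an internal error rather than silently
overwriting.

Defect runs are maximal same-class stretches along the *ordered* centerline;
arc length adds one pitch per axis step and √2·pitch per diagonal step, and
a jump between non-adjacent centerline points (a travel move) terminates the
run. Run endpoints are reported in mm.

## Fidelity

The evaluation field keeps the reconstruction wherever the defect map is
non-background (in-path states plus stringing) and zeros elsewhere, so
out-of-path material is penalized and clean background is not rewarded with
spurious structure. SSIM uses uniform (box) windows with reflective border
padding and population (not sample) moments; the window defaults to the
filament diameter in pixels, forced odd (43 px on the default grid for a
0.41 mm filament). Stability constants are the conventional
c1 = (0.01·L)², c2 = (0.03·L)² with L the dynamic range of the compared
fields (the maximum target/measured thickness). The layer's fidelity is the
mean of the SSIM map over the full grid; a restriction to the union of
supports is available. Identity, the constant-image closed form
(2ab + c1)/(a² + b² + c1) and symmetry hold to 1e−9 and are tested against
scikit-image's implementation configured identically. Because window
weighting and constants of any particular instrument pipeline may differ,
absolute fidelity values are comparable within this package, not across
implementations.

Multi-layer series are summarized as mean ± sd (ddof = 1; a single layer
reports sd 0 by convention).

## Repair

Breakage and under-extrusion runs qualify for repair at length ≥ 1.5 mm
(threshold inclusive); over-extrusion can never be fixed by adding material.
The pipeline's secondary-printing GCode is emitted for breakage runs only by
default — re-depositing over already-present thin material risks
over-extrusion, and under-extrusion is better addressed by parameter
adjustment — but `JobConfig.repair_classes` can include under-extrusion,
in which case material is re-deposited at nominal parameters (with a
calibration table one could instead pick a speed that deposits the deficit).
Each selected run becomes a travel move to the run start followed by
extruding moves along its centerline converted to mm with collinear points
merged; a straight gap therefore becomes a single start→end line at the
defective layer's Z. Emitted programs round-trip through the package's own
parser to within 1e−3 mm. No endpoint extension is applied; an optional
configurable overlap for start/stop under-deposition defaults to off.

## Synthetic data generator

The generator emulates what the instrument sees, not the physics of
extrusion. An ideal print is the target footprint at target height
(flat-topped cross-section — surface maps are top-surface heights). Defects
are injected by arc-length position along the toolpath: breakage intervals
zero the height, scaled intervals multiply it (0.5 → clear under-extrusion,
1.3 → clear over-extrusion at the default tolerance), blobs add radially
tapered bumps (auto-placeable at turnarounds), threads add thin off-path
material. Injection intervals are snapped to the centerline sampling by half
a pixel on each side so the rendered arc length matches the request to
within one pitch. Ground truth (true heights, labels from the same
thresholds applied to the true heights, run table) is returned alongside.

Volumes are rendered by inverting the thickness formula: each column is
bright from `base + descent − height/ΔZ` downward (signal 1.0 over
background 0.02), with optional multiplicative gamma speckle of chosen
contrast — the standard first-order model for OCT-like intensity noise.
Everything is seeded; identical seeds give bit-identical outputs.

Bundled scenarios use the studied print parameters: the gradient-spacing
serpentine (0.41 mm nozzle, 0.18 MPa, 0.25 mm layers, 10 mm/s), a nose-like
silicone contour (0.21 mm, 0.15 MPa, 0.18 mm), and ear-like cross-hatch
patches in 90° and 60° infill (0.15 mm, 0.55 MPa, 0.18 mm, 2 mm/s). Tests
and the acceptance script run them at 256×256 (pitch 0.039 mm) rather than
1024×1024 — the pipeline is resolution-independent and the smaller grid
exercises identical code paths; the default defect set for the gradient
scenario (3.6 mm breakage, 1.2 mm control gap, 2 mm under-extrusion at
scale 0.5, one turnaround blob of 0.12 mm extra height, one 0.1 mm thread)
spans all five print states with one run on each side of the repair
threshold.

What passing synthetic tests shows: the geometry, thresholds, morphology,
SSIM and repair logic are correct to pixel/axial-pixel precision. What they
do not show: robustness to real OCT artifacts (subsurface scattering,
refraction at curved surfaces, attenuation-limited penetration, lateral
registration error between rounds), because the generator injects defects
rather than letting them emerge from material behaviour.

## Known limitations

- Stringing area is reported after skeleton dilation, so it overestimates
  the area of sub-filament-width threads (their location and presence are
  exact; the label band is as wide as the dilation disc).
- Classification near defect boundaries is quantized to one pixel along the
  path and to the dilation radius laterally.
- Fidelity of tapered features (blobs) depends on ΔZ quantization exactly at
  the tolerance band edge.
- A calibration table is the user's responsibility; without one, corner
  speed changes do not change the target width.
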
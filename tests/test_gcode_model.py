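"""Target-model generation: parsing, grids, Bresenham, rasterization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bioprintqc as q
from bioprintqc.gcode_model import render_stack


# ---------------------------------------------------------------- parsing

def test_empty_program_yields_no_segments():
    assert q.parse_gcode("") == []


def test_two_line_program_one_segment():
    segs = q.parse_gcode("G1 X0 Y0 Z0.25 F600\nG1 X9 Y0 E9.0")
    assert len(segs) == 1
    s = segs[0]
    assert s.start_mm == (0.0, 0.0)
    assert s.end_mm == (9.0, 0.0)
    assert s.z_mm == 0.25
    assert s.speed_mm_s == pytest.approx(10.0)  # 600 mm/min
    assert s.extruding


def test_retraction_move_is_non_extruding():
    text = "G1 X1 Y1 Z0.25 F600 E1.0\nG1 X2 Y2 E0.5"
    segs = q.parse_gcode(text)
    assert len(segs) == 1
    assert segs[0].start_mm == (1.0, 1.0)
    assert segs[0].end_mm == (2.0, 2.0)
    assert not segs[0].extruding


def test_travel_without_e_is_non_extruding():
    segs = q.parse_gcode("G0 X0 Y0 Z0.25 F600\nG0 X3 Y0")
    assert len(segs) == 1 and not segs[0].extruding


def test_toggle_dialect():
    dialect = q.GCodeDialect(
        extrusion_from_e=False, extrusion_on_codes=("M760",), extrusion_off_codes=("M761",)
    )
    text = "G1 X0 Y0 Z0.25 F600\nM760\nG1 X5 Y0\nM761\nG1 X6 Y0"
    segs = q.parse_gcode(text, dialect=dialect)
    assert [s.extruding for s in segs] == [True, False]


def test_malformed_word_names_line():
    with pytest.raises(q.GCodeParseError, match="line 2"):
        q.parse_gcode("G1 X0 Y0 Z0.25 F600\nG1 Xoops Y0")


def test_motion_before_z_is_error():
    with pytest.raises(q.GCodeParseError, match="Z"):
        q.parse_gcode("G1 X0 Y0 F600")


def test_comments_are_ignored():
    segs = q.parse_gcode("; header\nG1 X0 Y0 Z0.25 F600 ; inline\nG1 X1 Y0 E1")
    assert len(segs) == 1


# ----------------------------------------------------------- layer grouping

def test_group_layers_partitions_by_z():
    def seg(z):
        return q.PrintSegment((0, 0), (1, 0), z, 10.0, 0.18, True)

    layers = q.group_layers([seg(0.25), seg(0.25), seg(0.50)], layer_thickness_mm=0.25)
    assert [len(l.segments) for l in layers] == [2, 1]
    assert [l.ordinal for l in layers] == [1, 2]
    assert layers[0].z_mm < layers[1].z_mm


def test_group_layers_empty():
    assert q.group_layers([]) == []


def test_group_layers_tolerance_merges_close_z():
    def seg(z):
        return q.PrintSegment((0, 0), (1, 0), z, 10.0, 0.18, True)

    layers = q.group_layers([seg(0.25), seg(0.2500001)], layer_thickness_mm=0.25)
    assert len(layers) == 1 and len(layers[0].segments) == 2


# ----------------------------------------------------------------- Bresenham

def test_bresenham_degenerate_point():
    assert q.bresenham_points((0, 0), (0, 0)) == [(0, 0)]


def test_bresenham_axis_aligned():
    assert q.bresenham_points((0, 0), (0, 3)) == [(0, 0), (0, 1), (0, 2), (0, 3)]


def test_bresenham_out_of_grid_raises():
    with pytest.raises(ValueError, match="outside grid"):
        q.bresenham_points((0, 0), (5, 5), shape=(4, 4))


from oracles import bresenham_oracle as _oracle_line


@given(
    dr=st.integers(min_value=-16, max_value=16),
    dc=st.integers(min_value=-16, max_value=16),
)
@settings(max_examples=200, deadline=None)
def test_bresenham_matches_nearest_pixel_oracle(dr, dc):
    p0 = (20, 20)
    p1 = (20 + dr, 20 + dc)
    assert q.bresenham_points(p0, p1) == _oracle_line(p0, p1)


# --------------------------------------------------------------- calibration

def test_calibration_exact_point_returns_tabulated_pair():
    table = q.CalibrationTable(entries=[((10.0, 0.18), (0.41, 0.25))])
    assert q.lookup_filament_geometry(10.0, 0.18, table) == (0.41, 0.25)


def test_calibration_single_entry_clamps_everywhere():
    table = q.CalibrationTable.constant(0.41, 0.25)
    assert q.lookup_filament_geometry(99.0, 9.9, table) == (0.41, 0.25)


def test_calibration_linear_interpolation():
    table = q.CalibrationTable(
        entries=[((10.0, 0.18), (0.40, 0.25)), ((12.0, 0.18), (0.36, 0.25))],
        mode="linear",
    )
    w, h = q.lookup_filament_geometry(11.0, 0.18, table)
    assert w == pytest.approx(0.38)
    assert h == pytest.approx(0.25)


def test_calibration_empty_table_is_error():
    with pytest.raises(ValueError, match="empty"):
        q.lookup_filament_geometry(10, 0.18, q.CalibrationTable(entries=[]))


# -------------------------------------------------------------- grid mapping

def test_mm_pixel_round_trip_within_one_pitch():
    grid = q.GridSpec()
    rng = np.random.default_rng(0)
    x = rng.uniform(-5, 5, 1000)
    y = rng.uniform(-5, 5, 1000)
    col, row = grid.mm_to_pixel(x, y)
    x2, y2 = grid.pixel_to_mm(col, row)
    assert np.max(np.abs(x2 - x)) <= grid.pitch_x
    assert np.max(np.abs(y2 - y)) <= grid.pitch_y


def test_wide_field_extents():
    grid = q.GridSpec(wide_field=True)
    assert grid.x_extent_mm == (-9.5, 9.5)
    assert grid.y_extent_mm == (-9.5, 9.5)


# -------------------------------------------------------------- rasterization

def _layer(segs, z=0.25):
    return q.LayerPath(z_mm=z, segments=segs, ordinal=1)


def _seg(p0, p1, extruding=True, z=0.25):
    return q.PrintSegment(p0, p1, z, 10.0, 0.18, extruding)


def test_rasterize_no_extrusion_gives_zero_map():
    grid = q.GridSpec(nx=128, ny=128)
    m = q.rasterize_layer(_layer([_seg((0, 0), (3, 0), extruding=False)]), grid)
    assert not m.path_mask.any()
    assert m.target_thickness.max() == 0


def test_rasterize_stripe_width_matches_calibrated_width():
    # default 1024 grid: pitch ~0.009766 mm, 0.41 mm filament -> 43 px stripe
    grid = q.GridSpec()
    m = q.rasterize_layer(_layer([_seg((-4.5, 0.0), (4.5, 0.0))]), grid)
    cols = np.where(m.path_mask.any(axis=0))[0]
    mid = cols[len(cols) // 2]
    stripe = int(m.path_mask[:, mid].sum())
    expected = 2 * round(0.205 / grid.pitch) + 1
    assert stripe == expected == 43
    assert m.target_thickness.max() == pytest.approx(0.25)


def test_rasterize_area_fraction_matches_geometry():
    grid = q.GridSpec(nx=512, ny=512)
    m = q.rasterize_layer(_layer([_seg((-4.5, 0.0), (4.5, 0.0))]), grid)
    area = m.path_mask.sum() * grid.pitch_x * grid.pitch_y
    analytic = 9.0 * 0.41
    # allow the end caps plus a one-pixel ring around the stripe perimeter
    slack = np.pi * 0.205**2 + 2 * (9.0 + 0.41) * grid.pitch
    assert abs(area - analytic) <= slack


def test_rasterize_order_insensitive_for_disjoint_segments():
    grid = q.GridSpec(nx=256, ny=256)
    a = _seg((-4, -2), (4, -2))
    b = _seg((-4, 2), (4, 2))
    m1 = q.rasterize_layer(_layer([a, b]), grid)
    m2 = q.rasterize_layer(_layer([b, a]), grid)
    assert np.array_equal(m1.target_thickness, m2.target_thickness)
    assert np.array_equal(m1.path_mask, m2.path_mask)
    assert np.array_equal(m1.centerline, m2.centerline)


def test_rasterize_endpoint_outside_grid_raises():
    grid = q.GridSpec(nx=64, ny=64)
    with pytest.raises(ValueError, match="outside grid"):
        q.rasterize_layer(_layer([_seg((0, 0), (40, 0))]), grid)


def test_path_mask_iff_positive_thickness(gradient_run):
    m = gradient_run["target"]
    assert np.array_equal(m.path_mask, m.target_thickness > 0)
    assert not (m.centerline & ~m.path_mask).any()  # centerline within path


def test_overlap_larger_geometry_wins():
    grid = q.GridSpec(nx=256, ny=256)
    table = q.CalibrationTable(
        entries=[((10.0, 0.18), (0.41, 0.25)), ((12.0, 0.18), (0.82, 0.50))],
        mode="nearest",
    )
    thin = _seg((-3, 0), (3, 0))
    thick = q.PrintSegment((0, -3), (0, 3), 0.25, 12.0, 0.18, True)
    m = q.rasterize_layer(_layer([thin, thick]), grid, table)
    col, row = grid.mm_to_pixel(0.0, 0.0)
    assert m.target_thickness[row, col] == pytest.approx(0.50)
    assert m.target_width[row, col] == pytest.approx(0.82)


# -------------------------------------------------------------------- stacks

def test_stack_single_layer_composite_equals_layer():
    grid = q.GridSpec(nx=64, ny=64)
    m = q.rasterize_layer(_layer([_seg((-2, 0), (2, 0))]), grid)
    stack = q.stack_layers([m])
    rgb = render_stack(stack)
    assert np.array_equal(rgb[m.path_mask][0], np.array(stack.colors[0]))
    assert (rgb[~m.path_mask] == 0).all()


def test_stack_two_layers_deep_blue_then_green():
    grid = q.GridSpec(nx=64, ny=64)
    m1 = q.rasterize_layer(_layer([_seg((-2, -1), (2, -1))]), grid)
    m2 = q.rasterize_layer(
        q.LayerPath(0.5, [_seg((-2, 1), (2, 1), z=0.5)], ordinal=2), grid
    )
    stack = q.stack_layers([m1, m2])
    assert stack.colors[0] == (0.0, 0.0, 0.55)  # deep blue
    assert stack.colors[1] == (0.0, 0.8, 0.0)  # green


def test_stack_empty_layers_render_black():
    grid = q.GridSpec(nx=32, ny=32)
    empties = [
        q.rasterize_layer(q.LayerPath(0.25 * (k + 1), [], ordinal=k + 1), grid)
        for k in range(3)
    ]
    rgb = render_stack(q.stack_layers(empties))
    assert (rgb == 0).all()


def test_stack_mixed_grids_error():
    g1, g2 = q.GridSpec(nx=32, ny=32), q.GridSpec(nx=64, ny=64)
    m1 = q.rasterize_layer(_layer([]), g1)
    m2 = q.rasterize_layer(_layer([]), g2)
    with pytest.raises(ValueError, match="GridSpec"):
        q.stack_layers([m1, m2])
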
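"""Defect classification rules, stringing morphology, run measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bioprintqc as q
from bioprintqc.defect_map import DefectClass, classify_thickness


def _stripe_target(grid_n=128, y=0.0, half_len=3.0):
    grid = q.GridSpec(nx=grid_n, ny=grid_n)
    seg = q.PrintSegment((-half_len, y), (half_len, y), 0.25, 10.0, 0.18, True)
    return q.rasterize_layer(q.LayerPath(0.25, [seg], 1), grid)


def _recon(arr, grid):
    return q.ReconstructedModelMap(thickness_mm=np.asarray(arr, float), grid=grid)


# -------------------------------------------------------------------- masking

def test_mask_all_true_is_identity():
    target = _stripe_target()
    target.path_mask[:] = True
    field = np.random.default_rng(0).uniform(0, 0.3, target.grid.shape)
    out = q.mask_recon_in_path(_recon(field, target.grid), target)
    assert np.array_equal(out, field)


def test_mask_all_false_zeroes_field():
    target = _stripe_target()
    target.path_mask[:] = False
    out = q.mask_recon_in_path(_recon(np.full(target.grid.shape, 0.25), target.grid), target)
    assert (out == 0).all()


def test_mask_stripe_pointwise_product():
    target = _stripe_target()
    out = q.mask_recon_in_path(_recon(np.full(target.grid.shape, 0.25), target.grid), target)
    assert np.allclose(out[target.path_mask], 0.25)
    assert (out[~target.path_mask] == 0).all()


def test_mask_grid_mismatch_error():
    target = _stripe_target(128)
    with pytest.raises(ValueError, match="grid"):
        q.mask_recon_in_path(_recon(np.zeros((64, 64)), q.GridSpec(nx=64, ny=64)), target)


# --------------------------------------------------------- thickness rules

@pytest.mark.parametrize(
    "t, expected",
    [
        (0.25, DefectClass.NORMAL),        # exact match
        (0.0, DefectClass.FILAMENT_BREAKAGE),
        (0.31, DefectClass.OVER_EXTRUSION),
        (0.12, DefectClass.UNDER_EXTRUSION),
        (0.30, DefectClass.NORMAL),        # upper band edge inclusive
        (0.20, DefectClass.NORMAL),        # lower band edge inclusive
        (0.305, DefectClass.OVER_EXTRUSION),
        (0.195, DefectClass.UNDER_EXTRUSION),
        (1e-9, DefectClass.FILAMENT_BREAKAGE),  # below the zero threshold
    ],
)
def test_thickness_rules_with_band_edges(t, expected):
    assert classify_thickness(t, 0.25, tolerance_mm=0.05, zero_eps_mm=1e-6) == expected


def test_background_where_no_target():
    assert classify_thickness(0.3, 0.0) == DefectClass.BACKGROUND


@given(
    t=st.floats(min_value=0, max_value=1.0),
    target=st.floats(min_value=0.11, max_value=0.9),
)
@settings(max_examples=300, deadline=None)
def test_exactly_one_rule_fires(t, target):
    """For any (printed, target) pair the four in-path rules partition."""
    label = classify_thickness(t, target, tolerance_mm=0.05, zero_eps_mm=1e-3)
    eps, delta = 1e-3, 0.05
    fired = [
        t < eps,                                            # breakage
        eps <= t < target - delta,                          # under
        target - delta <= t <= target + delta,              # normal
        t > target + delta,                                 # over
    ]
    assert sum(fired) == 1
    assert label != DefectClass.BACKGROUND


def test_tolerance_monotonicity():
    """Widening the band never adds under/over pixels or removes normal ones."""
    rng = np.random.default_rng(5)
    t = rng.uniform(0, 0.5, 4000)
    target = np.full_like(t, 0.25)
    counts = []
    for delta in (0.01, 0.03, 0.05, 0.10, 0.2):
        from bioprintqc.defect_map import _classify_values

        labels = _classify_values(t, target, delta, 1e-6)
        counts.append(
            (
                int((labels == DefectClass.UNDER_EXTRUSION).sum()),
                int((labels == DefectClass.OVER_EXTRUSION).sum()),
                int((labels == DefectClass.NORMAL).sum()),
            )
        )
    for (u1, o1, n1), (u2, o2, n2) in zip(counts, counts[1:]):
        assert u2 <= u1 and o2 <= o1 and n2 >= n1


def test_perfect_print_is_all_normal():
    target = _stripe_target()
    recon = _recon(target.target_thickness.copy(), target.grid)
    in_path = q.mask_recon_in_path(recon, target)
    labels = q.classify_in_path(in_path, target, 0.05)
    assert (labels[target.path_mask] == DefectClass.NORMAL).all()
    assert (labels[~target.path_mask] == DefectClass.BACKGROUND).all()
    stringing = q.detect_stringing(recon, target)
    assert not stringing.any()


def test_labels_propagate_across_filament_width():
    target = _stripe_target()
    field = target.target_thickness.copy()
    # zero a band of columns: breakage should span the full stripe width there
    cols = np.where(target.centerline.any(axis=0))[0]
    kill = cols[10:30]
    field[:, kill] = 0.0
    labels = q.classify_in_path(field, target, 0.05)
    on = target.path_mask[:, kill]
    assert (labels[:, kill][on] == DefectClass.FILAMENT_BREAKAGE).all()


# ------------------------------------------------------------------ stringing

def test_thread_outside_path_is_stringing():
    target = _stripe_target(grid_n=128)
    field = target.target_thickness.copy()
    # 1-px-wide thread off the path, longer than the 3x3 opening element
    row = 20
    field[row, 30:70] = 0.1
    stringing = q.detect_stringing(
        _recon(field, target.grid), target, dilation_radius_px=1
    )
    assert stringing[row, 40:60].all()
    labels = q.classify_in_path(q.mask_recon_in_path(_recon(field, target.grid), target), target)
    dmap = q.compose_defect_map(labels, stringing, target.grid)
    assert (dmap.labels[row, 40:60] == DefectClass.STRINGING).all()


def test_isolated_pixel_removed_by_opening():
    target = _stripe_target(grid_n=128)
    field = target.target_thickness.copy()
    field[20, 50] = 0.1  # single out-of-path speckle, smaller than the element
    stringing = q.detect_stringing(
        _recon(field, target.grid), target, dilation_radius_px=1
    )
    assert not stringing.any()


def test_recon_equal_to_target_no_stringing():
    target = _stripe_target()
    stringing = q.detect_stringing(_recon(target.target_thickness, target.grid), target)
    assert not stringing.any()


# ------------------------------------------------------------------ composing

def test_counts_partition_the_grid(gradient_run):
    dmap = gradient_run["round"].defect_map
    counts = dmap.class_counts()
    assert sum(counts.values()) == dmap.grid.nx * dmap.grid.ny


def test_breakage_and_stringing_colors_present(gradient_run):
    dmap = gradient_run["round"].defect_map
    rgb = q.render_defect_map(dmap)
    present = {tuple(c) for c in np.unique(rgb.reshape(-1, 3), axis=0)}
    from bioprintqc.defect_map import DEFECT_COLORS

    for cls in (DefectClass.BACKGROUND, DefectClass.NORMAL,
                DefectClass.FILAMENT_BREAKAGE, DefectClass.STRINGING):
        assert tuple(DEFECT_COLORS[cls]) in present


def test_overlap_between_stringing_and_path_is_internal_error():
    target = _stripe_target()
    labels = np.full(target.grid.shape, DefectClass.NORMAL, np.uint8)
    stringing = np.ones(target.grid.shape, bool)
    with pytest.raises(RuntimeError, match="overlap"):
        q.compose_defect_map(labels, stringing, target.grid)


# ----------------------------------------------------------------------- runs

def test_no_defects_no_runs():
    target = _stripe_target()
    recon = _recon(target.target_thickness, target.grid)
    labels = q.classify_in_path(q.mask_recon_in_path(recon, target), target)
    dmap = q.compose_defect_map(labels, np.zeros(target.grid.shape, bool), target.grid)
    assert q.measure_defect_runs(dmap, target) == []


def test_two_gaps_yield_two_runs():
    target = _stripe_target(grid_n=256)
    field = target.target_thickness.copy()
    cols = np.where(target.centerline.any(axis=0))[0]
    field[:, cols[10:20]] = 0.0
    field[:, cols[40:50]] = 0.0
    labels = q.classify_in_path(field, target, 0.05)
    dmap = q.compose_defect_map(labels, np.zeros(target.grid.shape, bool), target.grid)
    runs = [r for r in q.measure_defect_runs(dmap, target)
            if r.defect_class == DefectClass.FILAMENT_BREAKAGE]
    assert len(runs) == 2


def test_run_length_and_endpoints_match_injection(gradient_run):
    pitch = gradient_run["target"].grid.pitch
    runs = gradient_run["round"].runs
    breakage = sorted(
        (r for r in runs if r.defect_class == DefectClass.FILAMENT_BREAKAGE),
        key=lambda r: -r.length_mm,
    )
    assert len(breakage) == 2  # the 3.6 mm gap and the 1.2 mm control gap
    gt_runs = {
        round(g["length_mm"], 1): g
        for g in gradient_run["gt"].runs
        if g["class"] == DefectClass.FILAMENT_BREAKAGE
    }
    long, short = breakage
    assert long.length_mm == pytest.approx(3.6, abs=pitch)
    assert short.length_mm == pytest.approx(1.2, abs=pitch)
    g = gt_runs[3.6]
    for measured, truth in ((long.start_mm, g["start_mm"]), (long.end_mm, g["end_mm"])):
        assert np.hypot(measured[0] - truth[0], measured[1] - truth[1]) <= pitch
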
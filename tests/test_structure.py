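"""Structure metrics: hand-checked examples, invariants, and brute-force
equivalence of every windowed metric on a small landscape."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from firesev.grid import LandscapeGrid
from firesev.structure import (
    WindowSpec,
    forest_mask,
    homogeneity_index,
    ladder_fuel_index,
    mean_gap_area,
    mean_height,
    simpson_evenness,
    spatial_homogeneity,
    stem_density,
)
from firesev.synthetic import generate_stem_map

from conftest import stem_map_from_points


# ---------------------------------------------------------------------------
# forest mask
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "cover,kept",
    [(0.50, True), (0.10, False), (0.101, True), (0.0, False)],
)
def test_forest_mask_is_strict_at_ten_percent(cover, kept):
    assert forest_mask(np.array([[cover]]))[0, 0] == kept


def test_forest_mask_rejects_bad_cover():
    with pytest.raises(ValueError):
        forest_mask(np.array([[1.2]]))


# ---------------------------------------------------------------------------
# density / height examples
# ---------------------------------------------------------------------------


def test_stem_density_examples(small_grid):
    # 81 stems inside the full 90x90 window centered on pixel (5, 5)
    rng = np.random.default_rng(0)
    pts = np.column_stack(
        [rng.uniform(120, 210, 81), rng.uniform(120, 210, 81)]
    )
    sm = stem_map_from_points(pts, small_grid)
    d = stem_density(sm, small_grid, WindowSpec(90))
    assert d[5, 5] == pytest.approx(81 / 0.81)
    # far corner window holds nothing
    assert d[19, 19] == 0.0


def test_stem_density_stand_scale_hand_value():
    # 304 stems in a full 390x390 window -> 304 / 15.21 ha = 19.99 stems/ha
    grid = LandscapeGrid(0.0, 0.0, 13, 13, 30.0)
    rng = np.random.default_rng(1)
    pts = np.column_stack([rng.uniform(0, 390, 304), rng.uniform(0, 390, 304)])
    sm = stem_map_from_points(pts, grid)
    d = stem_density(sm, grid, WindowSpec(390))
    assert d[6, 6] == pytest.approx(304 / 15.21, rel=1e-12)
    assert d[6, 6] == pytest.approx(19.99, abs=5e-3)


def test_mean_height_examples(small_grid):
    sm = stem_map_from_points([(45, 45), (46, 45), (44, 45)], small_grid)
    sm.height[:] = [10.0, 20.0, 30.0]
    h = mean_height(sm, small_grid, WindowSpec(90))
    assert h[1, 1] == pytest.approx(20.0)
    lone = stem_map_from_points([(45, 45)], small_grid, height=7.0)
    assert mean_height(lone, small_grid, WindowSpec(90))[1, 1] == pytest.approx(7.0)
    # empty window -> NaN marker
    assert np.isnan(mean_height(lone, small_grid, WindowSpec(90))[19, 19])


# ---------------------------------------------------------------------------
# homogeneity
# ---------------------------------------------------------------------------


def test_homogeneity_four_corner_configuration():
    pts = [(25, 25), (25, 75), (75, 25), (75, 75)]
    assert homogeneity_index(np.array(pts), 100.0 * 100.0) == pytest.approx(2.0)


def test_homogeneity_two_stem_configuration():
    pts = [(45, 50), (55, 50)]  # 10 m apart in a 100x100 box
    h = homogeneity_index(np.array(pts), 1e4)
    assert h == pytest.approx(10 / (0.5 * np.sqrt(1e4 / 2)), rel=1e-12)
    assert h == pytest.approx(0.2828, abs=5e-4)


def test_homogeneity_needs_two_points():
    assert np.isnan(homogeneity_index(np.array([[1.0, 1.0]]), 100.0))


@given(st.floats(min_value=0.1, max_value=50.0))
def test_homogeneity_scale_invariance(scale):
    rng = np.random.default_rng(7)
    pts = rng.uniform(0, 100, size=(40, 2))
    h1 = homogeneity_index(pts, 1e4)
    h2 = homogeneity_index(pts * scale, 1e4 * scale**2)
    assert h2 == pytest.approx(h1, rel=1e-9)


def test_pattern_regimes_bracket_csr():
    """Hard-core patterns are regular (h > 1), Thomas clustered (h < 1)."""
    grid = LandscapeGrid(0, 0, 10, 10, 30.0)
    area = 300.0 * 300.0
    h_reg, h_clu = [], []
    for seed in range(100):
        reg = generate_stem_map(grid, "regular", 300, min_spacing=4.0, seed=seed)
        clu = generate_stem_map(
            grid,
            "clustered",
            1.0,
            cluster_parent_intensity=5.0,
            cluster_size=20.0,
            cluster_sd=5.0,
            seed=seed,
        )
        h_reg.append(homogeneity_index(reg.points, area))
        h_clu.append(homogeneity_index(clu.points, area))
    assert np.mean(h_reg) > 1.0
    assert np.mean(h_clu) < 1.0


# ---------------------------------------------------------------------------
# gap area
# ---------------------------------------------------------------------------


def test_gap_area_empty_and_full(small_grid):
    empty = stem_map_from_points(np.empty((0, 2)), small_grid)
    g = mean_gap_area(empty, small_grid, WindowSpec(90))
    assert g[5, 5] == pytest.approx(8100.0)
    # a giant crown covering everything
    big = stem_map_from_points([(300, 300)], small_grid, crown_radius=500.0)
    assert mean_gap_area(big, small_grid, WindowSpec(90))[5, 5] == 0.0


def test_gap_area_single_circular_crown(small_grid):
    # crown r=5 m at the center of the (5,5) window: one gap of
    # 8100 - 25*pi m^2, within rasterization tolerance
    sm = stem_map_from_points([(165.0, 165.0)], small_grid, crown_radius=5.0)
    g = mean_gap_area(sm, small_grid, WindowSpec(90))
    expected = 8100.0 - 25.0 * np.pi
    assert g[5, 5] == pytest.approx(expected, rel=0.01)


def test_gap_area_weakly_decreases_with_more_crowns(small_grid):
    rng = np.random.default_rng(3)
    pts = np.column_stack([rng.uniform(0, 600, 40), rng.uniform(0, 600, 40)])
    prev = None
    for k in (0, 10, 20, 40):
        sm = stem_map_from_points(pts[:k] if k else np.empty((0, 2)), small_grid,
                                  crown_radius=4.0)
        g = np.nanmean(mean_gap_area(sm, small_grid, WindowSpec(90)))
        if prev is not None:
            assert g <= prev + 1e-9
        prev = g


# ---------------------------------------------------------------------------
# ladder fuels
# ---------------------------------------------------------------------------


def test_ladder_equal_bands_has_unit_evenness():
    c = np.array([0.5, 0.5, 0.5, 0.5]).reshape(4, 1)
    assert simpson_evenness(c)[0] == pytest.approx(1.0)
    assert ladder_fuel_index(c)[0] == pytest.approx(0.5)


def test_ladder_zero_cover_is_zero():
    c = np.zeros((4, 1))
    assert ladder_fuel_index(c)[0] == 0.0


def test_ladder_hand_computed_profile():
    # c = (0.4, 0.4, 0, 0.4): q = 4, E = 0.75, mu = 0.3, l = 0.225
    c = np.array([0.4, 0.4, 0.0, 0.4]).reshape(4, 1)
    assert simpson_evenness(c)[0] == pytest.approx(0.75)
    assert ladder_fuel_index(c)[0] == pytest.approx(0.225)


def test_ladder_truncates_at_tallest_occupied_band():
    # only band 1 occupied: q = 1, E = 1, l = mean of all four bands
    c = np.array([0.4, 0.0, 0.0, 0.0]).reshape(4, 1)
    assert simpson_evenness(c)[0] == pytest.approx(1.0)
    assert ladder_fuel_index(c)[0] == pytest.approx(0.1)


@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=4, max_size=4)
)
def test_ladder_invariants(cover):
    c = np.array(cover).reshape(4, 1)
    E = simpson_evenness(c)[0]
    l = ladder_fuel_index(c)[0]
    mu = c.mean()
    assert E <= 1.0 + 1e-9
    assert l <= mu + 1e-9
    # permuting the occupied prefix 1..q leaves evenness unchanged
    occupied = np.flatnonzero(c[:, 0] > 0)
    if len(occupied):
        q = occupied.max() + 1
        perm = np.concatenate([np.random.default_rng(0).permutation(q), np.arange(q, 4)])
        assert simpson_evenness(c[perm])[0] == pytest.approx(E, rel=1e-12)


# ---------------------------------------------------------------------------
# brute-force equivalence of all windowed metrics
# ---------------------------------------------------------------------------


def brute_window_bounds(grid, r, c, hw):
    c0, c1 = max(c - hw, 0), min(c + hw, grid.n_cols - 1)
    r0, r1 = max(r - hw, 0), min(r + hw, grid.n_rows - 1)
    xmin = grid.x0 + c0 * grid.pixel_size
    xmax = grid.x0 + (c1 + 1) * grid.pixel_size
    ymin = grid.y0 + r0 * grid.pixel_size
    ymax = grid.y0 + (r1 + 1) * grid.pixel_size
    return xmin, xmax, ymin, ymax


def brute_members(sm, bounds):
    xmin, xmax, ymin, ymax = bounds
    return (sm.x >= xmin) & (sm.x < xmax) & (sm.y >= ymin) & (sm.y < ymax)


def brute_canopy(sm, grid, cell):
    ns = int(round(grid.pixel_size / cell))
    nr, nc = grid.n_rows * ns, grid.n_cols * ns
    cx = grid.x0 + (np.arange(nc) + 0.5) * cell
    cy = grid.y0 + (np.arange(nr) + 0.5) * cell
    mask = np.zeros((nr, nc), dtype=bool)
    for row_block in range(0, nr, 100):
        ys = cy[row_block : row_block + 100]
        d2 = (
            (ys[:, None, None] - sm.y[None, None, :]) ** 2
            + (cx[None, :, None] - sm.x[None, None, :]) ** 2
        )
        mask[row_block : row_block + 100] = (
            d2 <= (sm.crown_radius[None, None, :] ** 2)
        ).any(axis=2)
    return mask


@pytest.mark.parametrize("side", [90, 390])
def test_windowed_metrics_match_bruteforce(small_grid, random_stems, side):
    from scipy import ndimage

    grid, sm = small_grid, random_stems
    window = WindowSpec(side)
    hw = window.half_width_pixels(grid)
    dens = stem_density(sm, grid, window)
    hgt = mean_height(sm, grid, window)
    hom = spatial_homogeneity(sm, grid, window)
    cell = 0.75
    gap = mean_gap_area(sm, grid, window, cell=cell)
    canopy = brute_canopy(sm, grid, cell)
    ns = int(round(grid.pixel_size / cell))
    eight = np.ones((3, 3), int)

    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            bounds = brute_window_bounds(grid, r, c, hw)
            xmin, xmax, ymin, ymax = bounds
            area = (xmax - xmin) * (ymax - ymin)
            members = brute_members(sm, bounds)
            n = members.sum()
            # density: exact count over clipped area
            assert dens[r, c] == pytest.approx(n / (area / 1e4), rel=1e-12)
            # height
            if n:
                assert hgt[r, c] == pytest.approx(sm.height[members].mean(), rel=1e-9)
            else:
                assert np.isnan(hgt[r, c])
            # homogeneity via direct pairwise distances
            if n >= 2:
                pts = np.column_stack([sm.x[members], sm.y[members]])
                d2 = ((pts[:, None] - pts[None, :]) ** 2).sum(-1)
                np.fill_diagonal(d2, np.inf)
                nn = np.sqrt(d2.min(axis=1)).mean()
                expected = nn / (0.5 * np.sqrt(area / n))
                assert hom[r, c] == pytest.approx(expected, rel=1e-9)
            else:
                assert np.isnan(hom[r, c])
            # gaps: label the clipped fine window
            fr = slice(int((ymin - grid.y0) / cell), int((ymax - grid.y0) / cell))
            fc = slice(int((xmin - grid.x0) / cell), int((xmax - grid.x0) / cell))
            gaps = ~canopy[fr, fc]
            if not gaps.any():
                assert gap[r, c] == 0.0
            else:
                labels, _ = ndimage.label(gaps, structure=eight)
                sizes = np.bincount(labels.ravel())[1:]
                assert gap[r, c] == pytest.approx(sizes.mean() * cell * cell, rel=1e-9)


def test_strict_edge_mode_masks_border(small_grid, random_stems):
    d = stem_density(random_stems, small_grid, WindowSpec(90, edge="strict"))
    assert np.isnan(d[0, 0]) and np.isnan(d[19, 7])
    assert np.isfinite(d[1:-1, 1:-1]).all()


def test_window_spec_rejects_bad_sides(small_grid):
    with pytest.raises(ValueError):
        WindowSpec(100).validate(small_grid)  # not a multiple of 30
    with pytest.raises(ValueError):
        WindowSpec(120).validate(small_grid)  # even multiple
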
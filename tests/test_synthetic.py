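"""Generators: point-process statistics, cover bands, DEM, stations,
fire spread, and the severity model."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from firesev.grid import LandscapeGrid
from firesev.synthetic import (
    DEFAULT_BETA,
    generate_cover_bands,
    generate_dem,
    generate_stations,
    generate_stem_map,
    simulate_fire,
    simulate_severity,
)

from conftest import stem_map_from_points


# ---------------------------------------------------------------------------
# stem maps
# ---------------------------------------------------------------------------


def test_poisson_counts_mean_and_dispersion():
    """Counts across seeds behave like Poisson(intensity * area):
    correct mean and unit variance/mean ratio (chi-square test, alpha 1%)."""
    grid = LandscapeGrid(0, 0, 10, 10, 30.0)  # 9 ha
    lam = 100.0 * 9.0
    counts = np.array(
        [len(generate_stem_map(grid, "random", 100.0, seed=s)) for s in range(200)]
    )
    assert counts.mean() == pytest.approx(lam, abs=4 * np.sqrt(lam / 200))
    disp = (len(counts) - 1) * counts.var(ddof=1) / counts.mean()
    lo, hi = stats.chi2.ppf([0.005, 0.995], len(counts) - 1)
    assert lo < disp < hi


def test_poisson_mean_count_at_scale():
    # 100/ha on 900x900 m -> mean 8100 over seeds
    grid = LandscapeGrid(0, 0, 30, 30, 30.0)
    counts = [len(generate_stem_map(grid, "random", 100.0, seed=s)) for s in range(60)]
    assert np.mean(counts) == pytest.approx(8100, rel=0.01)


def test_hardcore_respects_minimum_spacing():
    grid = LandscapeGrid(0, 0, 10, 10, 30.0)
    for seed in range(5):
        sm = generate_stem_map(grid, "regular", 300.0, min_spacing=5.0, seed=seed)
        tree = cKDTree(sm.points)
        assert len(tree.query_pairs(5.0 - 1e-9)) == 0


def test_hardcore_infeasible_spacing_raises():
    grid = LandscapeGrid(0, 0, 10, 10, 30.0)
    with pytest.raises(ValueError, match="infeasible"):
        # mean spacing at 400/ha is 5 m; ask for more
        generate_stem_map(grid, "regular", 400.0, min_spacing=6.0, seed=0)


def test_nonpositive_intensity_raises():
    grid = LandscapeGrid(0, 0, 5, 5, 30.0)
    with pytest.raises(ValueError):
        generate_stem_map(grid, "random", 0.0, seed=0)


def test_unknown_pattern_raises():
    grid = LandscapeGrid(0, 0, 5, 5, 30.0)
    with pytest.raises(ValueError):
        generate_stem_map(grid, "fractal", 10.0, seed=0)


def test_generators_are_deterministic():
    grid = LandscapeGrid(0, 0, 10, 10, 30.0)
    for pattern in ("random", "clustered", "regular"):
        a = generate_stem_map(grid, pattern, 150.0, min_spacing=4.0, seed=11)
        b = generate_stem_map(grid, pattern, 150.0, min_spacing=4.0, seed=11)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.height, b.height)
    assert np.array_equal(
        generate_dem(grid, 100, 300, seed=5), generate_dem(grid, 100, 300, seed=5)
    )
    fa = simulate_fire(grid, (5, 5), n_steps=16, seed=5)
    fb = simulate_fire(grid, (5, 5), n_steps=16, seed=5)
    assert np.array_equal(fa.burn_time, fb.burn_time, equal_nan=True)
    pd.testing.assert_frame_equal(fa.detections, fb.detections)


def test_heights_respect_detection_floor():
    grid = LandscapeGrid(0, 0, 10, 10, 30.0)
    sm = generate_stem_map(
        grid, "random", 200.0, height_mean_log=np.log(5.0), height_sd_log=0.6, seed=0
    )
    assert sm.height.min() >= 4.0
    assert (sm.crown_radius > 0).all() and sm.crown_radius.max() <= 10.0


# ---------------------------------------------------------------------------
# cover bands
# ---------------------------------------------------------------------------


def test_cover_bands_empty_landscape(small_grid):
    sm = stem_map_from_points(np.empty((0, 2)), small_grid)
    bands = generate_cover_bands(sm, small_grid, understory_cover=0.0, seed=0)
    assert bands.shape == (4, 20, 20)
    assert np.all(bands == 0.0)


def test_cover_bands_single_tree_band_assignment(small_grid):
    # a 10 m tree whose crown blankets its pixel: full cover in the
    # 8-16 m band for that pixel, nothing anywhere else
    sm = stem_map_from_points([(45.0, 45.0)], small_grid, height=10.0, crown_radius=25.0)
    bands = generate_cover_bands(sm, small_grid, understory_cover=0.0, seed=0)
    assert bands[1, 1, 1] == pytest.approx(1.0)
    assert bands[0].sum() == 0 and bands[2].sum() == 0 and bands[3].sum() == 0


def test_cover_bands_tall_stand_area_fraction(small_grid):
    """35 m trees at known crown area -> band-4 cover matches the
    area fraction from an independent fine rasterization."""
    rng = np.random.default_rng(8)
    pts = np.column_stack([rng.uniform(0, 600, 250), rng.uniform(0, 600, 250)])
    sm = stem_map_from_points(pts, small_grid, height=35.0, crown_radius=5.0)
    bands = generate_cover_bands(sm, small_grid, understory_cover=0.0, cell=1.5, seed=0)
    # oracle: dense distance computation on the same lattice
    cell = 1.5
    cx = (np.arange(400) + 0.5) * cell
    covered = np.zeros((400, 400), bool)
    for i in range(0, 400, 50):
        d2 = (cx[i : i + 50, None, None] - sm.y[None, None, :]) ** 2 + (
            cx[None, :, None] - sm.x[None, None, :]
        ) ** 2
        covered[i : i + 50] = (d2 <= 25.0).any(axis=2)
    oracle = covered.reshape(20, 20, 20, 20).mean(axis=(1, 3))
    assert bands[3] == pytest.approx(oracle, abs=1e-12)
    assert bands[:3].sum() == 0.0


def test_understory_only_touches_first_band(small_grid):
    sm = stem_map_from_points(np.empty((0, 2)), small_grid)
    bands = generate_cover_bands(sm, small_grid, understory_cover=0.2, seed=1)
    assert bands[0].min() >= 0 and bands[0].max() <= 1 and bands[0].mean() > 0.05
    assert np.all(bands[1:] == 0)


# ---------------------------------------------------------------------------
# DEM
# ---------------------------------------------------------------------------


def test_dem_flat_when_amplitude_zero():
    grid = LandscapeGrid(0, 0, 12, 12, 30.0)
    dem = generate_dem(grid, 0.0, 300.0, seed=0)
    assert np.ptp(dem) == 0.0


def test_dem_relief_amplitude_is_peak_to_peak():
    grid = LandscapeGrid(0, 0, 40, 40, 30.0)
    dem = generate_dem(grid, 250.0, 300.0, seed=3)
    assert np.ptp(dem) == pytest.approx(250.0)


def test_dem_variogram_range_tracks_correlation_length():
    """Empirical semivariogram range (95% of sill, averaged over six
    realizations and both axes) within a factor 2 of the requested
    300 m correlation length."""
    grid = LandscapeGrid(0, 0, 120, 120, 30.0)
    lags = np.arange(1, 60)
    gammas, sills = [], []
    for seed in range(6):
        z = generate_dem(grid, 100.0, 300.0, seed=seed)
        z = z - z.mean()
        gammas.append(
            [
                0.25 * np.mean((z[:, h:] - z[:, :-h]) ** 2)
                + 0.25 * np.mean((z[h:] - z[:-h]) ** 2)
                for h in lags
            ]
        )
        sills.append(z.var())
    gamma = np.mean(gammas, axis=0)
    sill = np.mean(sills)
    assert gamma.max() >= 0.95 * sill
    est_range = lags[np.argmax(gamma >= 0.95 * sill)] * 30.0
    assert 150.0 <= est_range <= 600.0


# ---------------------------------------------------------------------------
# stations
# ---------------------------------------------------------------------------


def test_station_series_bounds_and_determinism():
    grid = LandscapeGrid(0, 0, 20, 20, 30.0)
    dem = generate_dem(grid, 300.0, 500.0, seed=1)
    sts = generate_stations(grid, 3, dem, n_hours=48, seed=9)
    assert len(sts) == 3
    for st in sts:
        rh = st.data["relative_humidity"]
        assert rh.min() >= 0 and rh.max() <= 100
        assert st.data["wind_speed"].min() >= 0
        assert st.data["fuel_moisture"].min() >= 0
        assert np.all(np.diff(st.data["t_hours"]) > 0)
    again = generate_stations(grid, 3, dem, n_hours=48, seed=9)
    pd.testing.assert_frame_equal(sts[0].data, again[0].data)
    with pytest.raises(ValueError):
        generate_stations(grid, 0, dem, seed=0)


# ---------------------------------------------------------------------------
# fire spread
# ---------------------------------------------------------------------------


def test_deterministic_wave_is_manhattan_distance():
    grid = LandscapeGrid(0, 0, 15, 15, 30.0)
    fire = simulate_fire(
        grid, (7, 7), spread_prob=1.0, step_hours=1.0, n_steps=30,
        detection_rate_per_km2=0.0, seed=0,
    )
    R, C = np.meshgrid(np.arange(15), np.arange(15), indexing="ij")
    manhattan = np.abs(R - 7) + np.abs(C - 7)
    assert np.array_equal(fire.burn_time, manhattan.astype(float))


def test_burned_region_is_connected_and_contains_ignition():
    grid = LandscapeGrid(0, 0, 40, 40, 30.0)
    fire = simulate_fire(grid, (20, 20), spread_prob=0.5, n_steps=60, seed=4)
    burned = np.isfinite(fire.burn_time)
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    _, n_comp = ndimage.label(burned, structure=four)
    assert n_comp == 1
    assert burned[20, 20] and fire.burn_time[20, 20] == 0.0


def test_detections_inside_extent_with_expected_rate():
    """Mean detections per run match p_detect times newly burned pixels
    (Monte-Carlo over 100 seeds)."""
    grid = LandscapeGrid(0, 0, 21, 21, 30.0)
    rate = 20.0
    p_detect = rate * 0.03 * 0.03  # per-pixel detection probability
    counts, expected = [], None
    for seed in range(100):
        fire = simulate_fire(
            grid, (10, 10), spread_prob=1.0, step_hours=1.0, n_steps=10,
            detection_rate_per_km2=rate, seed=seed,
        )
        xmin, ymin, xmax, ymax = grid.extent
        assert fire.detections["x"].between(xmin, xmax).all()
        assert fire.detections["y"].between(ymin, ymax).all()
        counts.append(len(fire.detections))
        n_burned = np.isfinite(fire.burn_time).sum()  # deterministic wave
        expected = p_detect * n_burned
    se = np.sqrt(expected * (1 - p_detect) / 100)
    assert np.mean(counts) == pytest.approx(expected, abs=4 * se + 1e-9)


def test_ignition_outside_grid_raises():
    grid = LandscapeGrid(0, 0, 5, 5, 30.0)
    with pytest.raises(ValueError):
        simulate_fire(grid, (9, 2), seed=0)


# ---------------------------------------------------------------------------
# severity
# ---------------------------------------------------------------------------


def test_intercept_only_prevalence_is_half():
    table = pd.DataFrame({"dummy": np.zeros(40_000)})
    truth = simulate_severity(table, {"intercept": 0.0}, seed=0)
    assert truth.probability == pytest.approx(0.5)
    assert truth.outcome.mean() == pytest.approx(0.5, abs=3 * 0.5 / 200)


def test_prevalence_converges_to_mean_probability():
    rng = np.random.default_rng(5)
    table = pd.DataFrame({"x": rng.normal(size=60_000)})
    truth = simulate_severity(table, {"intercept": 0.3, "x": 0.8}, seed=1)
    target = truth.probability.mean()
    se = np.sqrt(target * (1 - target) / len(table))
    assert truth.outcome.mean() == pytest.approx(target, abs=3 * se)


def test_cbi_is_consistent_with_outcome_and_monotone():
    rng = np.random.default_rng(6)
    table = pd.DataFrame({"x": rng.normal(size=5000)})
    truth = simulate_severity(table, {"x": 1.0}, seed=2)
    assert np.all((truth.cbi > 2.25) == (truth.outcome == 1))
    assert truth.cbi.min() >= 0 and truth.cbi.max() <= 3.0
    for cls in (0, 1):
        sel = truth.outcome == cls
        order = np.argsort(truth.linear_predictor[sel])
        assert np.all(np.diff(truth.cbi[sel][order]) >= 0)


def test_unknown_beta_name_raises():
    table = pd.DataFrame({"x": np.zeros(5)})
    with pytest.raises(KeyError):
        simulate_severity(table, {"nope": 1.0}, seed=0)
    with pytest.raises(KeyError):
        simulate_severity(table, {"x:nope": 1.0}, seed=0)


def test_default_beta_matches_reported_effects():
    assert DEFAULT_BETA["stem_density"] == 0.32
    assert DEFAULT_BETA["hdw:ladder_index"] == -0.063
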
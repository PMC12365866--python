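"""Synthetic landscapes with known ground truth.

Every downstream stage of the severity pipeline (structure metrics, fire
timing, weather interpolation, logistic inference) is exercised against
data produced here, where the generating process — stem pattern, canopy
cover, terrain, fire spread, weather, and the severity model itself — is
known exactly.

Stem patterns cover the three regimes that matter for the spatial
homogeneity index: complete spatial randomness (homogeneous Poisson),
clustering (Thomas process), and regularity (hard-core thinning, the
plantation-like end of the spectrum). Heights are lognormal with a 4 m
detection floor, matching the LiDAR stem-detection threshold; crown radii
follow a power-law allometry ``r = a * height**b`` capped at 10 m.

The fire model is a stochastic cellular front: it is not a physical fire
model, only a source of known per-pixel burn times with realistic
satellite-detection sparsity (375 m footprint, positional jitter).

The severity model is a logistic regression on standardized covariates;
its default coefficient vector uses the stand-scale effect sizes reported
for the northern Sierra Nevada fires this package is built around
(stem density 0.32, hot-dry-windy 0.41, ladder fuels 0.21, homogeneity
0.13, height -0.10, fuel moisture -0.13, and the three weather
interactions 0.15 / 0.15 / -0.063).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grid import LandscapeGrid

__all__ = [
    "StemMap",
    "StationSeries",
    "FireTruth",
    "SeverityTruth",
    "DEFAULT_BETA",
    "generate_stem_map",
    "generate_cover_bands",
    "generate_dem",
    "generate_stations",
    "simulate_fire",
    "simulate_severity",
]

#: Standardized log-odds effects used as the default severity truth.
DEFAULT_BETA: dict[str, float] = {
    "intercept": 0.26,  # logit(0.565), the public-land base rate
    "stem_density": 0.32,
    "hdw": 0.41,
    "ladder_index": 0.21,
    "homogeneity": 0.13,
    "mean_height": -0.10,
    "fuel_moisture": -0.13,
    "hdw:stem_density": 0.15,
    "hdw:mean_height": 0.15,
    "hdw:ladder_index": -0.063,
}

#: Height band edges (m) for canopy cover strata: 2-8, 8-16, 16-32, 32+.
BAND_EDGES = (2.0, 8.0, 16.0, 32.0, np.inf)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class StemMap:
    """Individual-tree records over a rectangular extent.

    ``x``, ``y`` in meters, ``height`` in meters (>= 4, the LiDAR
    detection floor), ``crown_radius`` in meters (> 0).
    """

    x: np.ndarray
    y: np.ndarray
    height: np.ndarray
    crown_radius: np.ndarray
    grid: LandscapeGrid

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("y", "height", "crown_radius"):
            if len(getattr(self, name)) != n:
                raise ValueError("stem attribute arrays must share a length")
        if n and self.height.min() < 4.0 - 1e-9:
            raise ValueError("stem heights must be >= 4 m (detection floor)")
        if n and self.crown_radius.min() <= 0:
            raise ValueError("crown radii must be positive")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "height": self.height,
                "crown_radius": self.crown_radius,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, grid: LandscapeGrid) -> "StemMap":
        return cls(
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            height=df["height"].to_numpy(float),
            crown_radius=df["crown_radius"].to_numpy(float),
            grid=grid,
        )


@dataclass
class StationSeries:
    """Hourly weather record of one station.

    ``data`` has columns ``t_hours`` (strictly increasing, hours on the
    shared fire clock), ``temperature`` (degC), ``relative_humidity`` (%),
    ``wind_speed`` (m/s), ``fuel_moisture`` (% of 10-h dead fuels).
    """

    station_id: str
    x: float
    y: float
    elevation: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.data["t_hours"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        rh = self.data["relative_humidity"].to_numpy()
        if rh.min() < 0 or rh.max() > 100:
            raise ValueError("relative humidity outside [0, 100]")
        if self.data["wind_speed"].min() < 0:
            raise ValueError("wind speed must be non-negative")
        if self.data["fuel_moisture"].min() < 0:
            raise ValueError("fuel moisture must be non-negative")


@dataclass
class FireTruth:
    """Ground-truth burn times plus the detections a satellite would see.

    ``burn_time`` is hours since ignition, NaN where unburned;
    ``detections`` has columns x, y, t_hours.
    """

    burn_time: np.ndarray
    detections: pd.DataFrame
    grid: LandscapeGrid
    ignition: tuple[int, int]
    step_hours: float


@dataclass
class SeverityTruth:
    """Severity generated from a known logistic model on a pixel table."""

    beta: dict[str, float]
    linear_predictor: np.ndarray
    probability: np.ndarray
    outcome: np.ndarray
    cbi: np.ndarray


# ---------------------------------------------------------------------------
# Stem maps
# ---------------------------------------------------------------------------


def _draw_heights(n: int, rng: np.random.Generator, mean_log: float, sd_log: float) -> np.ndarray:
    """Lognormal heights truncated below at 4 m (resampling rejection)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mean_log, sd_log, size=max(n - filled, 16))
        keep = draw[draw >= 4.0]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def crown_radius_from_height(
    height: np.ndarray, a: float = 0.5, b: float = 0.6, cap: float = 10.0
) -> np.ndarray:
    """Power-law crown allometry ``r = a * h**b``, capped."""
    return np.minimum(a * np.asarray(height, float) ** b, cap)


def generate_stem_map(
    grid: LandscapeGrid,
    pattern: str = "random",
    intensity: float = 100.0,
    *,
    seed=None,
    height_mean_log: float = np.log(18.0),
    height_sd_log: float = 0.35,
    crown_a: float = 0.5,
    crown_b: float = 0.6,
    crown_cap: float = 10.0,
    cluster_parent_intensity: float = 5.0,
    cluster_size: float = 20.0,
    cluster_sd: float = 5.0,
    min_spacing: float = 5.0,
) -> StemMap:
    """Draw a stem map from one of three point processes.

    Parameters
    ----------
    pattern:
        ``random`` (homogeneous Poisson), ``clustered`` (Thomas process:
        Poisson parents at ``cluster_parent_intensity`` per ha, Poisson
        offspring count with mean ``cluster_size``, isotropic Gaussian
        dispersal with sd ``cluster_sd`` m), or ``regular`` (Poisson
        candidates thinned to a hard-core minimum spacing).
    intensity:
        Target stems per hectare. For ``regular`` this is the candidate
        intensity before thinning, so the realized density is lower.
    """
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent
    area_ha = grid.width * grid.height / 1e4

    if pattern == "random":
        n = rng.poisson(intensity * area_ha)
        x = rng.uniform(xmin, xmax, n)
        y = rng.uniform(ymin, ymax, n)
    elif pattern == "clustered":
        # pad the parent window so clusters straddling the edge contribute
        pad = 4.0 * cluster_sd
        parea_ha = (grid.width + 2 * pad) * (grid.height + 2 * pad) / 1e4
        n_par = rng.poisson(cluster_parent_intensity * parea_ha)
        px = rng.uniform(xmin - pad, xmax + pad, n_par)
        py = rng.uniform(ymin - pad, ymax + pad, n_par)
        counts = rng.poisson(cluster_size, n_par)
        x = np.repeat(px, counts) + rng.normal(0.0, cluster_sd, counts.sum())
        y = np.repeat(py, counts) + rng.normal(0.0, cluster_sd, counts.sum())
        keep = (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)
        x, y = x[keep], y[keep]
    elif pattern == "regular":
        mean_spacing = 1.0 / np.sqrt(intensity / 1e4)  # m, at the candidate intensity
        if min_spacing >= mean_spacing:
            raise ValueError(
                f"min_spacing {min_spacing} m is infeasible at intensity "
                f"{intensity}/ha (implied mean spacing {mean_spacing:.2f} m)"
            )
        n = rng.poisson(intensity * area_ha)
        cx = rng.uniform(xmin, xmax, n)
        cy = rng.uniform(ymin, ymax, n)
        x, y = _hardcore_thin(cx, cy, min_spacing)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    height = _draw_heights(len(x), rng, height_mean_log, height_sd_log)
    crown = crown_radius_from_height(height, crown_a, crown_b, crown_cap)
    return StemMap(x=x, y=y, height=height, crown_radius=crown, grid=grid)


def _hardcore_thin(x: np.ndarray, y: np.ndarray, min_spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Sequential (Matern-II style) thinning to a hard minimum spacing."""
    from scipy.spatial import cKDTree

    if len(x) == 0:
        return x, y
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    keep = np.ones(len(pts), dtype=bool)
    # arrival order = array order (candidates were drawn i.i.d., so this
    # is already a uniformly random order)
    for i, j in tree.query_pairs(min_spacing):
        a, b = (i, j) if i < j else (j, i)
        if keep[a]:
            keep[b] = False
    return x[keep], y[keep]


# ---------------------------------------------------------------------------
# Cover bands
# ---------------------------------------------------------------------------


def _stamp_disks(
    mask: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    radius: np.ndarray,
    cell: float,
    x0: float,
    y0: float,
) -> None:
    """Set True every cell of ``mask`` whose center lies in some disk."""
    n_rows, n_cols = mask.shape
    for xi, yi, ri in zip(x, y, radius):
        c0 = max(int(np.floor((xi - ri - x0) / cell - 0.5)), 0)
        c1 = min(int(np.ceil((xi + ri - x0) / cell + 0.5)), n_cols - 1)
        r0 = max(int(np.floor((yi - ri - y0) / cell - 0.5)), 0)
        r1 = min(int(np.ceil((yi + ri - y0) / cell + 0.5)), n_rows - 1)
        if c1 < c0 or r1 < r0:
            continue
        cx = x0 + (np.arange(c0, c1 + 1) + 0.5) * cell
        cy = y0 + (np.arange(r0, r1 + 1) + 0.5) * cell
        dx2 = (cx - xi) ** 2
        dy2 = (cy - yi) ** 2
        mask[r0 : r1 + 1, c0 : c1 + 1] |= dy2[:, None] + dx2[None, :] <= ri**2


def canopy_mask(
    stem_map: StemMap,
    grid: LandscapeGrid,
    cell: float = 0.75,
    min_height: float | None = None,
    max_height: float | None = None,
    crowns=None,
) -> np.ndarray:
    """Fine-resolution boolean canopy raster (cell centers covered by a crown).

    ``crowns`` may supply explicit shapely polygons (one per stem record)
    in place of the circular-crown default. The 0.75 m default matches the
    canopy-height-model cell size of the source LiDAR product.
    """
    n_sub = int(round(grid.pixel_size / cell))
    if abs(n_sub * cell - grid.pixel_size) > 1e-9:
        raise ValueError("cell must divide the pixel size exactly")
    shape = (grid.n_rows * n_sub, grid.n_cols * n_sub)
    mask = np.zeros(shape, dtype=bool)
    sel = np.ones(len(stem_map), dtype=bool)
    if min_height is not None:
        sel &= stem_map.height >= min_height
    if max_height is not None:
        sel &= stem_map.height < max_height
    if crowns is None:
        _stamp_disks(
            mask,
            stem_map.x[sel],
            stem_map.y[sel],
            stem_map.crown_radius[sel],
            cell,
            grid.x0,
            grid.y0,
        )
    else:
        import shapely

        for poly, use in zip(crowns, sel):
            if not use or poly.is_empty:
                continue
            bx0, by0, bx1, by1 = poly.bounds
            c0 = max(int(np.floor((bx0 - grid.x0) / cell - 0.5)), 0)
            c1 = min(int(np.ceil((bx1 - grid.x0) / cell + 0.5)), shape[1] - 1)
            r0 = max(int(np.floor((by0 - grid.y0) / cell - 0.5)), 0)
            r1 = min(int(np.ceil((by1 - grid.y0) / cell + 0.5)), shape[0] - 1)
            if c1 < c0 or r1 < r0:
                continue
            cx = grid.x0 + (np.arange(c0, c1 + 1) + 0.5) * cell
            cy = grid.y0 + (np.arange(r0, r1 + 1) + 0.5) * cell
            X, Y = np.meshgrid(cx, cy)
            mask[r0 : r1 + 1, c0 : c1 + 1] |= shapely.contains_xy(poly, X, Y)
    return mask


def generate_cover_bands(
    stem_map: StemMap,
    grid: LandscapeGrid,
    *,
    understory_cover: float = 0.15,
    understory_correlation: float = 150.0,
    cell: float = 1.5,
    seed=None,
) -> np.ndarray:
    """Per-pixel cover fractions in the 2-8 / 8-16 / 16-32 / 32+ m strata.

    A tree's crown contributes to the band containing its top height.
    The understory term adds a smooth, clipped random cover field to the
    lowest band, emulating shrubs and regeneration the stem map does not
    carry. Returns an array of shape ``(4, n_rows, n_cols)``.
    """
    rng = np.random.default_rng(seed)
    n_sub = int(round(grid.pixel_size / cell))
    bands = np.zeros((4, grid.n_rows, grid.n_cols))
    for k in range(4):
        lo, hi = BAND_EDGES[k], BAND_EDGES[k + 1]
        mask = canopy_mask(stem_map, grid, cell=cell, min_height=lo, max_height=hi)
        bands[k] = mask.reshape(grid.n_rows, n_sub, grid.n_cols, n_sub).mean(axis=(1, 3))
    if understory_cover > 0:
        noise = rng.normal(size=grid.shape)
        sigma = understory_correlation / 2.0 / grid.pixel_size
        smooth = gaussian_filter(noise, sigma, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            smooth = smooth / sd
        shrub = np.clip(understory_cover * (1.0 + 0.8 * smooth), 0.0, 1.0)
        bands[0] = np.clip(bands[0] + shrub, 0.0, 1.0)
    return bands


# ---------------------------------------------------------------------------
# Terrain and weather inputs
# ---------------------------------------------------------------------------


def generate_dem(
    grid: LandscapeGrid,
    relief_amplitude: float = 400.0,
    correlation_length: float = 1500.0,
    *,
    base_elevation: float = 1200.0,
    seed=None,
) -> np.ndarray:
    """Smooth random topography: low-pass-filtered Gaussian noise.

    ``correlation_length`` is the practical semivariogram range: the
    white-noise field is smoothed with a Gaussian kernel of sd
    ``correlation_length / 3.5`` (meters), which puts the 95%-sill lag of
    the resulting Gaussian covariance at about the correlation length.
    The surface is then rescaled so the peak-to-peak relief equals
    ``relief_amplitude``.
    """
    if relief_amplitude < 0:
        raise ValueError("relief_amplitude must be >= 0")
    if correlation_length <= 0:
        raise ValueError("correlation_length must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=grid.shape)
    sigma = correlation_length / 3.5 / grid.pixel_size
    dem = gaussian_filter(noise, sigma, mode="reflect")
    ptp = dem.max() - dem.min()
    if relief_amplitude == 0 or ptp == 0:
        return np.full(grid.shape, base_elevation)
    dem = (dem - dem.min()) / ptp * relief_amplitude
    return dem + base_elevation - relief_amplitude / 2.0


def generate_stations(
    grid: LandscapeGrid,
    n_stations: int,
    dem: np.ndarray,
    *,
    n_hours: int = 96,
    seed=None,
    base_temperature: float = 28.0,
    lapse_rate: float = 6.5e-3,
    diurnal_amplitude: float = 8.0,
    base_rh: float = 25.0,
    base_wind: float = 4.0,
    base_fuel_moisture: float = 6.0,
) -> list[StationSeries]:
    """Place weather stations and synthesize hourly diurnal series.

    Temperature follows a sinusoidal diurnal cycle (peak at 15:00) minus
    an elevation lapse; relative humidity mirrors temperature; wind is a
    positive AR(1); 10-h fuel moisture tracks humidity. All series share
    the fire clock (hour 0 = ignition).
    """
    if n_stations < 1:
        raise ValueError("n_stations must be >= 1")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent
    zref = float(np.mean(dem))
    t = np.arange(n_hours, dtype=float)
    stations = []
    for i in range(n_stations):
        sx = rng.uniform(xmin, xmax)
        sy = rng.uniform(ymin, ymax)
        r, c = grid.pixel_of(sx, sy)
        z = float(dem[r, c])
        phase = 2 * np.pi * (t % 24 - 15.0) / 24.0
        temp = (
            base_temperature
            - lapse_rate * (z - zref)
            + diurnal_amplitude * np.cos(phase)
            + rng.normal(0, 1.0, n_hours)
        )
        rh = np.clip(
            base_rh - 2.2 * (temp - base_temperature) + rng.normal(0, 3.0, n_hours),
            0.0,
            100.0,
        )
        wind = np.empty(n_hours)
        wind[0] = base_wind
        eps = rng.normal(0, 1.2, n_hours)
        for h in range(1, n_hours):
            wind[h] = base_wind + 0.7 * (wind[h - 1] - base_wind) + eps[h]
        wind = np.clip(wind, 0.0, None)
        fm = np.clip(base_fuel_moisture + 0.08 * (rh - base_rh) + rng.normal(0, 0.4, n_hours), 1.0, None)
        data = pd.DataFrame(
            {
                "t_hours": t,
                "temperature": temp,
                "relative_humidity": rh,
                "wind_speed": wind,
                "fuel_moisture": fm,
            }
        )
        stations.append(
            StationSeries(station_id=f"RAWS{i:02d}", x=sx, y=sy, elevation=z, data=data)
        )
    return stations


# ---------------------------------------------------------------------------
# Fire spread and detections
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def simulate_fire(
    grid: LandscapeGrid,
    ignition: tuple[int, int],
    *,
    spread_prob: float = 0.8,
    wind_bias: tuple[float, float] | None = None,
    step_hours: float = 0.5,
    n_steps: int = 96,
    window_hours: float = 8.0,
    detection_rate_per_km2: float = 7.1,
    footprint_m: float = 375.0,
    seed=None,
) -> FireTruth:
    """Stochastic cellular fire front with satellite-style detections.

    Each step, every unburned 4-neighbor of a burning pixel ignites with
    probability ``spread_prob``, optionally biased by a wind vector
    ``(direction_deg_from_north, strength in [0, 1])``. Detections are
    drawn per 8-h window: each newly burned pixel is seen with probability
    ``detection_rate_per_km2 * pixel_area_km2`` and reported at its burn
    time with position jittered uniformly by half the nominal footprint.
    """
    r0, c0 = ignition
    if not (0 <= r0 < grid.n_rows and 0 <= c0 < grid.n_cols):
        raise ValueError("ignition pixel outside the grid")
    rng = np.random.default_rng(seed)
    burn_step = np.full(grid.shape, -1, dtype=np.int64)
    burn_step[r0, c0] = 0

    bias = {}
    for dr, dc in _NEIGHBOR_OFFSETS:
        if wind_bias is None:
            bias[(dr, dc)] = 1.0
        else:
            wdir, wstr = wind_bias
            theta = np.deg2rad(wdir)
            wind_vec = np.array([np.cos(theta), np.sin(theta)])  # (north, east)
            step_vec = np.array([dr, dc], dtype=float)
            bias[(dr, dc)] = 1.0 + wstr * float(wind_vec @ step_vec)

    for step in range(1, n_steps + 1):
        burning = burn_step >= 0
        newly = np.zeros(grid.shape, dtype=bool)
        for (dr, dc), b in bias.items():
            shifted = np.zeros(grid.shape, dtype=bool)
            src = burning
            if dr >= 0:
                rs_dst = slice(dr, grid.n_rows)
                rs_src = slice(0, grid.n_rows - dr)
            else:
                rs_dst = slice(0, grid.n_rows + dr)
                rs_src = slice(-dr, grid.n_rows)
            if dc >= 0:
                cs_dst = slice(dc, grid.n_cols)
                cs_src = slice(0, grid.n_cols - dc)
            else:
                cs_dst = slice(0, grid.n_cols + dc)
                cs_src = slice(-dc, grid.n_cols)
            shifted[rs_dst, cs_dst] = src[rs_src, cs_src]
            candidate = shifted & ~burning & ~newly
            p = min(max(spread_prob * b, 0.0), 1.0)
            ignite = candidate & (rng.random(grid.shape) < p)
            newly |= ignite
        burn_step[newly] = step
        if not newly.any() and step > 1:
            break

    burn_time = np.where(burn_step >= 0, burn_step * step_hours, np.nan)

    # detections per window
    xmin, ymin, xmax, ymax = grid.extent
    X, Y = grid.center_mesh()
    p_detect = min(detection_rate_per_km2 * grid.pixel_size**2 / 1e6, 1.0)
    half = footprint_m / 2.0
    tmax = np.nanmax(burn_time)
    n_windows = int(np.floor(tmax / window_hours)) + 1
    recs = []
    for w in range(n_windows):
        lo, hi = w * window_hours, (w + 1) * window_hours
        newly = (burn_time >= lo) & (burn_time < hi)
        idx = np.flatnonzero(newly.ravel())
        if idx.size == 0:
            continue
        seen = idx[rng.random(idx.size) < p_detect]
        if seen.size == 0:
            continue
        dx = rng.uniform(-half, half, seen.size)
        dy = rng.uniform(-half, half, seen.size)
        px = np.clip(X.ravel()[seen] + dx, xmin, np.nextafter(xmax, xmin))
        py = np.clip(Y.ravel()[seen] + dy, ymin, np.nextafter(ymax, ymin))
        recs.append(
            pd.DataFrame({"x": px, "y": py, "t_hours": burn_time.ravel()[seen]})
        )
    detections = (
        pd.concat(recs, ignore_index=True)
        if recs
        else pd.DataFrame(columns=["x", "y", "t_hours"])
    )
    return FireTruth(
        burn_time=burn_time,
        detections=detections,
        grid=grid,
        ignition=ignition,
        step_hours=step_hours,
    )


# ---------------------------------------------------------------------------
# Severity
# ---------------------------------------------------------------------------


def severity_linear_predictor(table: pd.DataFrame, beta: dict[str, float]) -> np.ndarray:
    """X @ beta for a named coefficient vector over a covariate table.

    Interaction terms are written ``"a:b"`` (product of the two named,
    already-standardized columns). Categorical offsets are written
    ``"col=level"`` (indicator). ``"intercept"`` is the constant term.
    """
    lp = np.zeros(len(table))
    for name, value in beta.items():
        if name == "intercept":
            lp += value
        elif ":" in name:
            a, b = name.split(":", 1)
            for col in (a, b):
                if col not in table.columns:
                    raise KeyError(f"interaction references unknown covariate {col!r}")
            lp += value * table[a].to_numpy(float) * table[b].to_numpy(float)
        elif "=" in name:
            col, level = name.split("=", 1)
            if col not in table.columns:
                raise KeyError(f"beta references unknown covariate {col!r}")
            lp += value * (table[col].astype(str) == level).to_numpy(float)
        else:
            if name not in table.columns:
                raise KeyError(f"beta references unknown covariate {name!r}")
            lp += value * table[name].to_numpy(float)
    return lp


def simulate_severity(
    table: pd.DataFrame, beta: dict[str, float] | None = None, *, seed=None,
    cbi_threshold: float = 2.25,
) -> SeverityTruth:
    """Bernoulli severity outcomes from a logistic model on a pixel table.

    The continuous CBI-like value is a deterministic monotone map of the
    model probability within each outcome class, anchored so that
    ``outcome == 1``  iff  ``cbi > cbi_threshold`` (strictly).
    """
    if beta is None:
        beta = dict(DEFAULT_BETA)
    rng = np.random.default_rng(seed)
    lp = severity_linear_predictor(table, beta)
    prob = expit(lp)
    outcome = (rng.random(len(table)) < prob).astype(np.int8)
    # monotone-in-probability CBI within each class; strictly > threshold
    # for the high class because prob is strictly positive
    cbi = np.where(
        outcome == 1,
        cbi_threshold + (3.0 - cbi_threshold) * prob,
        cbi_threshold * prob,
    )
    return SeverityTruth(
        beta=dict(beta),
        linear_predictor=lp,
        probability=prob,
        outcome=outcome,
        cbi=cbi,
    )
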
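"""Fire-weather fields: station interpolation and the hot-dry-windy index.

Station series are averaged over each 8-h burn window, then spread
across the landscape with weights that decay with horizontal distance
and elevation difference, ``w_i propto (d_i + d0)**-2 * (|dz_i| + z0)**-1``
(normalized per pixel). The hot-dry-windy index is wind speed times
vapor pressure deficit, computed from the window means; VPD uses the
Tetens saturation-vapor-pressure approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import LandscapeGrid
from .synthetic import StationSeries
from .timing import BurnSchedule

__all__ = [
    "vpd_hpa",
    "hot_dry_windy",
    "WeatherWindowRaster",
    "interpolate_weather",
]


def vpd_hpa(temperature, relative_humidity):
    """Vapor pressure deficit (hPa) from air temperature (degC) and RH (%).

    Saturation vapor pressure by Tetens:
    ``e_s = 6.112 * exp(17.67 T / (T + 243.5))`` hPa.
    """
    t = np.asarray(temperature, dtype=float)
    rh = np.asarray(relative_humidity, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity outside [0, 100]")
    es = 6.112 * np.exp(17.67 * t / (t + 243.5))
    return es * (1.0 - rh / 100.0)


def hot_dry_windy(wind_speed, vpd):
    """Hot-dry-windy index: wind speed (m/s) times VPD (hPa)."""
    w = np.asarray(wind_speed, dtype=float)
    v = np.asarray(vpd, dtype=float)
    if np.any(w < 0) or np.any(v < 0):
        raise ValueError("wind speed and VPD must be non-negative")
    return w * v


@dataclass
class WeatherWindowRaster:
    """Interpolated weather, one 2-D field per variable per burn window.

    Arrays have shape ``(n_windows, n_rows, n_cols)``; window ``w`` is
    stored at index ``w - 1``.
    """

    hdw: np.ndarray
    fuel_moisture: np.ndarray
    temperature: np.ndarray
    relative_humidity: np.ndarray
    wind_speed: np.ndarray
    vpd: np.ndarray
    schedule: BurnSchedule

    def at_burn_window(self, variable: str) -> np.ndarray:
        """Collapse a stack to each pixel's value in its own burn window."""
        stack = getattr(self, variable)
        win = self.schedule.window
        out = np.full(win.shape, np.nan)
        for w in range(1, self.schedule.n_windows + 1):
            sel = win == w
            out[sel] = stack[w - 1][sel]
        return out


def _station_window_means(
    station: StationSeries, t0: float, window_hours: float, n_windows: int
) -> dict[str, np.ndarray]:
    t = station.data["t_hours"].to_numpy(float)
    hourly_vpd = vpd_hpa(
        station.data["temperature"].to_numpy(float),
        station.data["relative_humidity"].to_numpy(float),
    )
    cols = {
        "temperature": station.data["temperature"].to_numpy(float),
        "relative_humidity": station.data["relative_humidity"].to_numpy(float),
        "wind_speed": station.data["wind_speed"].to_numpy(float),
        "fuel_moisture": station.data["fuel_moisture"].to_numpy(float),
        "vpd": hourly_vpd,
    }
    out = {k: np.full(n_windows, np.nan) for k in cols}
    for w in range(n_windows):
        sel = (t >= t0 + w * window_hours) & (t < t0 + (w + 1) * window_hours)
        if not sel.any():
            raise ValueError(
                f"station {station.station_id} has no observations in burn "
                f"window {w + 1}"
            )
        for k, v in cols.items():
            out[k][w] = v[sel].mean()
    return out


def interpolate_weather(
    stations: list[StationSeries],
    dem: np.ndarray,
    schedule: BurnSchedule,
    *,
    d0: float = 1.0,
    z0: float = 10.0,
    distance_exponent: float = 2.0,
    elevation_exponent: float = 1.0,
) -> WeatherWindowRaster:
    """Distance- and elevation-weighted station averages per burn window.

    Every station contributes to every pixel; the offsets ``d0`` (m) and
    ``z0`` (m) keep weights finite at zero distance while letting a
    co-located station dominate. Window means are taken per station
    first; HDW is the product of the window-mean wind and window-mean
    VPD fields.
    """
    if len(stations) < 1:
        raise ValueError("at least one station is required")
    grid = schedule.grid
    if dem.shape != grid.shape:
        raise ValueError("DEM does not match the schedule grid")
    n_windows = schedule.n_windows
    X, Y = grid.center_mesh()

    weights = []
    means = []
    for st in stations:
        d = np.hypot(X - st.x, Y - st.y)
        dz = np.abs(dem - st.elevation)
        weights.append((d + d0) ** -distance_exponent * (dz + z0) ** -elevation_exponent)
        means.append(
            _station_window_means(st, schedule.t_start, schedule.window_hours, n_windows)
        )
    wsum = np.sum(weights, axis=0)

    fields = {}
    for var in ("temperature", "relative_humidity", "wind_speed", "fuel_moisture", "vpd"):
        stack = np.zeros((n_windows,) + grid.shape)
        for w in range(n_windows):
            acc = np.zeros(grid.shape)
            for wt, mn in zip(weights, means):
                acc += wt * mn[var][w]
            stack[w] = acc / wsum
        fields[var] = stack
    hdw = hot_dry_windy(fields["wind_speed"], np.clip(fields["vpd"], 0.0, None))
    return WeatherWindowRaster(
        hdw=hdw,
        fuel_moisture=fields["fuel_moisture"],
        temperature=fields["temperature"],
        relative_humidity=fields["relative_humidity"],
        wind_speed=fields["wind_speed"],
        vpd=fields["vpd"],
        schedule=schedule,
    )
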
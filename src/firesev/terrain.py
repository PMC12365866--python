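"""Topographic indices from a 30 m DEM.

Slope and aspect use Horn's 3x3 finite differences; the topographic
position index (TPI) is focal elevation minus the mean elevation of all
pixel centers within a 300 m radius (focal pixel excluded); heat load is
the McCune-Keon potential-radiation index with aspect folded about the
southwest axis.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

__all__ = ["slope_aspect", "tpi", "heat_load", "TerrainRasters", "terrain_indices"]

from dataclasses import dataclass


@dataclass
class TerrainRasters:
    slope: np.ndarray        # degrees
    aspect: np.ndarray       # degrees clockwise from north; NaN where flat
    tpi: np.ndarray          # meters
    heat_load: np.ndarray    # dimensionless, > 0


def _horn_gradients(dem: np.ndarray, pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """dz/dx (eastward) and dz/dy (northward) by Horn's method.

    Rows are ordered south to north (row 0 southernmost), so +row is
    +y/north. Edges use replicated padding.
    """
    z = np.pad(dem.astype(float), 1, mode="edge")
    c = z[1:-1, 1:-1]
    w_ = z[1:-1, :-2]
    e_ = z[1:-1, 2:]
    s_ = z[:-2, 1:-1]
    n_ = z[2:, 1:-1]
    sw = z[:-2, :-2]
    se = z[:-2, 2:]
    nw = z[2:, :-2]
    ne = z[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * pixel_size)
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * pixel_size)
    return dzdx, dzdy


def slope_aspect(dem: np.ndarray, pixel_size: float = 30.0) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and aspect (degrees clockwise from N; NaN if flat)."""
    if dem.ndim != 2 or min(dem.shape) < 3:
        raise ValueError("DEM must be a 2-D raster of at least 3x3 pixels")
    dzdx, dzdy = _horn_gradients(dem, pixel_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # aspect = compass bearing of the downslope direction (-grad z)
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect = np.where(slope > 0, aspect, np.nan)
    return slope, aspect


def tpi(dem: np.ndarray, pixel_size: float = 30.0, radius: float = 300.0) -> np.ndarray:
    """Topographic position index: elevation minus the neighborhood mean.

    The neighborhood is every pixel whose center lies within ``radius``
    of the focal center, the focal pixel excluded; positive on ridges,
    negative in valleys. Edge pixels use whatever neighbors exist.
    """
    if radius < pixel_size:
        raise ValueError("radius must be at least one pixel")
    k = int(np.floor(radius / pixel_size))
    off = np.arange(-k, k + 1) * pixel_size
    kernel = (off[:, None] ** 2 + off[None, :] ** 2) <= radius**2
    kernel[k, k] = False
    kernel = kernel.astype(float)
    z = dem.astype(float)
    nbr_sum = ndimage.correlate(z, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.correlate(np.ones_like(z), kernel, mode="constant", cval=0.0)
    return z - nbr_sum / nbr_cnt


def heat_load(latitude: float, slope: np.ndarray, aspect: np.ndarray) -> np.ndarray:
    """McCune-Keon heat-load index from latitude, slope, and aspect.

    Aspect (degrees from north) is folded about the southwest axis,
    ``folded = |180 - |aspect - 225||``, so that SW-facing slopes score
    highest; then

    ``HL = exp(0.339 + 0.808 cos(lat) cos(slope)
               - 0.196 sin(lat) sin(slope) - 0.482 cos(folded) sin(slope))``

    with all angles in radians. Valid for latitudes 0-60 deg N and
    slopes up to 60 deg; aspect may be NaN where slope is zero (it then
    does not matter and is treated as 0).
    """
    if not (0.0 <= latitude <= 60.0):
        warnings.warn(
            f"latitude {latitude} outside the published 0-60 degN domain",
            stacklevel=2,
        )
    s = np.radians(np.asarray(slope, dtype=float))
    a = np.asarray(aspect, dtype=float)
    folded = np.radians(np.abs(180.0 - np.abs(np.where(np.isnan(a), 0.0, a) - 225.0)))
    lat = np.radians(latitude)
    ln_hl = (
        0.339
        + 0.808 * np.cos(lat) * np.cos(s)
        - 0.196 * np.sin(lat) * np.sin(s)
        - 0.482 * np.cos(folded) * np.sin(s)
    )
    return np.exp(ln_hl)


def terrain_indices(
    dem: np.ndarray,
    pixel_size: float = 30.0,
    *,
    latitude: float = 40.0,
    tpi_radius: float = 300.0,
) -> TerrainRasters:
    """Convenience bundle: slope, aspect, TPI, and heat load for one DEM."""
    slope, aspect = slope_aspect(dem, pixel_size)
    return TerrainRasters(
        slope=slope,
        aspect=aspect,
        tpi=tpi(dem, pixel_size, tpi_radius),
        heat_load=heat_load(latitude, slope, aspect),
    )
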
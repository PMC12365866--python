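"""Forest-structure metrics on moving windows.

Five metrics describe pre-fire forest structure, each evaluated for the
square window (90 m "neighborhood" or 390 m "stand" scale) centered on
every 30 m pixel:

* **stem density** — stems per hectare (trees >= 4 m tall);
* **mean height** — arithmetic mean stem height (m);
* **spatial homogeneity** — observed mean nearest-neighbor distance
  divided by its expectation under complete spatial randomness,
  ``h = mean_i min_j d_ij / (0.5 * sqrt(A / N))`` with N stems in a
  window of area A. ``h < 1`` indicates clustering, ``h > 1`` regularity
  (the plantation signature). The uncorrected Clark-Evans form is used:
  no edge correction, with N and A taken from the window after clipping
  to the landscape;
* **mean gap area** — mean area (m^2) of the connected components of
  canopy-free ground within the window, rasterized at 0.75 m with
  8-connectivity; gap portions outside the window are excluded;
* **ladder fuels index** — per 30 m pixel only: Simpson evenness of
  canopy cover across the 2-8/8-16/16-32/32+ m strata up to the tallest
  occupied band, times the mean cover of all four bands,
  ``l = mu_c * (1/q) * (sum_{k<=q} c_k)^2 / sum_{k<=q} c_k^2``.

Windows are clipped at the landscape edge and the clipped area used
(``edge="clip"``); ``edge="strict"`` instead returns NaN where the full
window does not fit. Pixels whose window holds no stems get density 0 but
NaN height/homogeneity, and drop out of model tables downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import LandscapeGrid
from .synthetic import StemMap, canopy_mask

__all__ = [
    "WindowSpec",
    "forest_mask",
    "stem_density",
    "mean_height",
    "spatial_homogeneity",
    "mean_gap_area",
    "ladder_fuel_index",
    "homogeneity_index",
    "simpson_evenness",
]


@dataclass(frozen=True)
class WindowSpec:
    """Square moving window centered on a focal pixel.

    ``side_length`` must be an odd multiple of the pixel size so the
    window aligns with pixel boundaries (90 and 390 m for 30 m pixels).
    """

    side_length: float
    edge: str = "clip"

    def half_width_pixels(self, grid: LandscapeGrid) -> int:
        k = self.side_length / grid.pixel_size
        ki = int(round(k))
        if abs(k - ki) > 1e-9 or ki % 2 != 1 or ki < 1:
            raise ValueError(
                f"window side {self.side_length} m must be an odd multiple "
                f"of the pixel size {grid.pixel_size} m"
            )
        return ki // 2

    def validate(self, grid: LandscapeGrid) -> None:
        self.half_width_pixels(grid)
        if self.edge not in ("clip", "strict"):
            raise ValueError("edge must be 'clip' or 'strict'")


def forest_mask(cover_over_4m: np.ndarray, threshold: float = 0.10) -> np.ndarray:
    """Forested-pixel mask: strictly more than 10% cover of trees > 4 m."""
    cover = np.asarray(cover_over_4m, dtype=float)
    if cover.min() < 0 or cover.max() > 1:
        raise ValueError("cover fractions must lie in [0, 1]")
    return cover > threshold


# ---------------------------------------------------------------------------
# Window machinery
# ---------------------------------------------------------------------------


def _window_sums(per_pixel: np.ndarray, hw: int) -> np.ndarray:
    """Sum of a per-pixel field over the (2*hw+1)^2 window, zero-padded."""
    k = 2 * hw + 1
    kernel = np.ones((k, k))
    return ndimage.correlate(per_pixel, kernel, mode="constant", cval=0.0)


def _window_pixel_counts(grid: LandscapeGrid, hw: int) -> np.ndarray:
    return _window_sums(np.ones(grid.shape), hw)


def _strict_interior(grid: LandscapeGrid, hw: int) -> np.ndarray:
    ok = np.zeros(grid.shape, dtype=bool)
    if grid.n_rows > 2 * hw and grid.n_cols > 2 * hw:
        ok[hw : grid.n_rows - hw, hw : grid.n_cols - hw] = True
    return ok


def _apply_edge(values: np.ndarray, grid: LandscapeGrid, window: WindowSpec, hw: int) -> np.ndarray:
    if window.edge == "strict":
        out = np.where(_strict_interior(grid, hw), values, np.nan)
        return out
    return values


# ---------------------------------------------------------------------------
# Density and height
# ---------------------------------------------------------------------------


def _per_pixel_counts(stem_map: StemMap, grid: LandscapeGrid, weights=None) -> np.ndarray:
    counts = np.zeros(grid.shape)
    inside = grid.contains(stem_map.x, stem_map.y)
    r, c = grid.pixel_of(stem_map.x[inside], stem_map.y[inside])
    w = None if weights is None else np.asarray(weights)[inside]
    np.add.at(counts, (r, c), 1.0 if w is None else w)
    return counts


def stem_density(stem_map: StemMap, grid: LandscapeGrid, window: WindowSpec) -> np.ndarray:
    """Stems per hectare in the clipped window around each pixel."""
    window.validate(grid)
    hw = window.half_width_pixels(grid)
    counts = _window_sums(_per_pixel_counts(stem_map, grid), hw)
    # uniform_filter is a floating sum of integers: snap to exact counts
    counts = np.round(counts)
    area_ha = _window_pixel_counts(grid, hw).round() * grid.pixel_area_ha
    return _apply_edge(counts / area_ha, grid, window, hw)


def mean_height(stem_map: StemMap, grid: LandscapeGrid, window: WindowSpec) -> np.ndarray:
    """Mean stem height per window; NaN where the window holds no stems."""
    window.validate(grid)
    hw = window.half_width_pixels(grid)
    counts = np.round(_window_sums(_per_pixel_counts(stem_map, grid), hw))
    sums = _window_sums(_per_pixel_counts(stem_map, grid, weights=stem_map.height), hw)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / counts, np.nan)
    return _apply_edge(out, grid, window, hw)


# ---------------------------------------------------------------------------
# Spatial homogeneity (nearest-neighbor ratio)
# ---------------------------------------------------------------------------


def homogeneity_index(points: np.ndarray, area: float) -> float:
    """Uncorrected Clark-Evans nearest-neighbor ratio for one point set.

    ``h = (mean nearest-neighbor distance) / (0.5 * sqrt(area / N))``.
    Returns NaN for fewer than two points.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        return float("nan")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return float(d[:, 1].mean() / (0.5 * np.sqrt(area / n)))


def spatial_homogeneity(
    stem_map: StemMap,
    grid: LandscapeGrid,
    window: WindowSpec,
    *,
    n_candidates: int = 12,
) -> np.ndarray:
    """Clark-Evans homogeneity per moving window.

    Nearest neighbors are found *within* each window. For speed, each
    stem's global k-nearest neighbors are precomputed; the within-window
    nearest neighbor is read off that candidate list when it provably
    equals the exact answer (candidate distance <= k-th global distance),
    with a brute-force fallback otherwise. Results are exact.
    """
    window.validate(grid)
    hw = window.half_width_pixels(grid)
    n = len(stem_map)
    out = np.full(grid.shape, np.nan)
    if n == 0:
        return out

    inside = grid.contains(stem_map.x, stem_map.y)
    x = stem_map.x[inside]
    y = stem_map.y[inside]
    n = len(x)
    if n == 0:
        return out
    rows, cols = grid.pixel_of(x, y)
    order = np.lexsort((cols, rows))
    x, y, rows, cols = x[order], y[order], rows[order], cols[order]
    pts = np.column_stack([x, y])

    k = min(n_candidates + 1, n)
    tree = cKDTree(pts)
    nbr_dist, nbr_idx = tree.query(pts, k=k)
    if k == 1:
        nbr_dist = nbr_dist[:, None]
        nbr_idx = nbr_idx[:, None]
    cand_dist = nbr_dist[:, 1:]
    cand_idx = nbr_idx[:, 1:]
    dk = nbr_dist[:, -1]

    # CSR layout of stems by pixel row
    row_start = np.searchsorted(rows, np.arange(grid.n_rows + 1))
    px = grid.pixel_size

    for r in range(grid.n_rows):
        r0, r1 = max(r - hw, 0), min(r + hw, grid.n_rows - 1)
        for c in range(grid.n_cols):
            c0, c1 = max(c - hw, 0), min(c + hw, grid.n_cols - 1)
            members = []
            for rr in range(r0, r1 + 1):
                a, b = row_start[rr], row_start[rr + 1]
                if a == b:
                    continue
                lo = a + np.searchsorted(cols[a:b], c0)
                hi = a + np.searchsorted(cols[a:b], c1 + 1)
                if hi > lo:
                    members.append(np.arange(lo, hi))
            if not members:
                continue
            S = np.concatenate(members) if len(members) > 1 else members[0]
            m = len(S)
            if m < 2:
                continue
            area = (r1 - r0 + 1) * (c1 - c0 + 1) * px * px
            if m <= n_candidates + 1:
                # tiny window: direct pairwise distances
                sub = pts[S]
                d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
                np.fill_diagonal(d2, np.inf)
                nn = np.sqrt(d2.min(axis=1))
            else:
                ci = cand_idx[S]
                in_win = (
                    (rows[ci] >= r0)
                    & (rows[ci] <= r1)
                    & (cols[ci] >= c0)
                    & (cols[ci] <= c1)
                )
                dmat = np.where(in_win, cand_dist[S], np.inf)
                nn = dmat.min(axis=1)
                # certificate: the candidate answer is exact when it does
                # not exceed the k-th global neighbor distance
                bad = nn > dk[S]
                if bad.any():
                    sub = pts[S]
                    for i in np.flatnonzero(bad):
                        d2 = ((sub - sub[i]) ** 2).sum(-1)
                        d2[i] = np.inf
                        nn[i] = np.sqrt(d2.min())
            out[r, c] = nn.mean() / (0.5 * np.sqrt(area / m))
    return _apply_edge(out, grid, window, hw)


# ---------------------------------------------------------------------------
# Gap area
# ---------------------------------------------------------------------------

_EIGHT = np.ones((3, 3), dtype=int)


def mean_gap_area(
    stem_map: StemMap,
    grid: LandscapeGrid,
    window: WindowSpec,
    *,
    cell: float = 0.75,
    crowns=None,
    _canopy: np.ndarray | None = None,
) -> np.ndarray:
    """Mean canopy-gap area (m^2) per moving window.

    Gaps are 8-connected components of canopy-free cells in a 0.75 m
    rasterization of the crown map, clipped to the window; a fully
    covered window scores 0 and an empty window scores the window area.
    ``crowns`` may carry shapely crown polygons; by default circular
    crowns from the stem map are used.
    """
    window.validate(grid)
    hw = window.half_width_pixels(grid)
    canopy = (
        _canopy
        if _canopy is not None
        else canopy_mask(stem_map, grid, cell=cell, crowns=crowns)
    )
    n_sub = int(round(grid.pixel_size / cell))
    cell_area = cell * cell
    out = np.full(grid.shape, np.nan)
    nR, nC = grid.shape
    for r in range(nR):
        fr0 = max(r - hw, 0) * n_sub
        fr1 = (min(r + hw, nR - 1) + 1) * n_sub
        for c in range(nC):
            fc0 = max(c - hw, 0) * n_sub
            fc1 = (min(c + hw, nC - 1) + 1) * n_sub
            gaps = ~canopy[fr0:fr1, fc0:fc1]
            if not gaps.any():
                out[r, c] = 0.0
                continue
            labels, n_lab = ndimage.label(gaps, structure=_EIGHT)
            sizes = np.bincount(labels.ravel())[1:]
            out[r, c] = sizes.mean() * cell_area
    return _apply_edge(out, grid, window, hw)


# ---------------------------------------------------------------------------
# Ladder fuels
# ---------------------------------------------------------------------------


def simpson_evenness(cover: np.ndarray) -> np.ndarray:
    """Simpson evenness of cover over bands 1..q (q = tallest occupied band).

    ``E = (1/q) * (sum_{k<=q} c_k)^2 / sum_{k<=q} c_k^2``; equals 1 when
    all bands up to q have identical cover. Input shape ``(4, ...)``;
    all-zero profiles return 0.
    """
    c = np.asarray(cover, dtype=float)
    if c.shape[0] != 4:
        raise ValueError("cover must have 4 bands on the first axis")
    if c.min() < 0 or c.max() > 1:
        raise ValueError("cover fractions must lie in [0, 1]")
    occupied = c > 0
    any_cover = occupied.any(axis=0)
    # q = index (1-based) of tallest band with cover > 0
    q = 4 - occupied[::-1].argmax(axis=0)
    band_le_q = np.arange(1, 5).reshape((4,) + (1,) * (c.ndim - 1)) <= q
    cq = np.where(band_le_q, c, 0.0)
    s1 = cq.sum(axis=0)
    s2 = (cq**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        E = np.where(any_cover, s1**2 / np.where(s2 > 0, s2, 1.0) / q, 0.0)
    return E


def ladder_fuel_index(cover: np.ndarray) -> np.ndarray:
    """Ladder fuels index per pixel: mean four-band cover times evenness."""
    c = np.asarray(cover, dtype=float)
    mu = c.mean(axis=0)
    return mu * simpson_evenness(c)
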
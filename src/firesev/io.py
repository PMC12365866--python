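"""File formats: GeoTIFF-style rasters, CSV tables, GeoJSON geometry.

Rasters are written as plain TIFF (via :mod:`tifffile`) with a JSON
sidecar (``<name>.tif.json``) carrying the grid geometry — south-west
origin, pixel size, nodata — in a planar local-meter CRS. Arrays are
stored north-up on disk and flipped back to the package's row-0-south
convention on read. Only square, unrotated pixel geometries are
accepted. Every writer can attach run metadata (seed, parameters,
config hash) to the sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import LandscapeGrid

__all__ = [
    "write_raster",
    "read_raster",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
    "stems_to_geojson",
    "config_hash",
    "file_sha256",
]


class RasterFormatError(ValueError):
    """Raised for unsupported raster geometry (rotation, non-square pixels)."""


def write_raster(
    path, data: np.ndarray, grid: LandscapeGrid, *, nodata: float | None = None,
    metadata: dict | None = None,
) -> Path:
    """Write a 2-D (or banded 3-D, bands-first) raster plus a JSON sidecar."""
    import tifffile

    path = Path(path)
    data = np.asarray(data)
    if data.ndim == 2:
        shape = data.shape
        disk = data[::-1]  # north-up on disk
    elif data.ndim == 3:
        shape = data.shape[1:]
        disk = data[:, ::-1]
    else:
        raise ValueError("raster must be 2-D or bands-first 3-D")
    if shape != grid.shape:
        raise ValueError(f"data shape {shape} does not match grid {grid.shape}")
    tifffile.imwrite(path, disk, photometric="minisblack")
    sidecar = {
        "x0": grid.x0,
        "y0": grid.y0,
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "pixel_size": grid.pixel_size,
        "rotation": 0.0,
        "crs": "local-cartesian-meters",
        "nodata": nodata,
        "dtype": str(data.dtype),
        "metadata": metadata or {},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_raster(path) -> tuple[np.ndarray, LandscapeGrid, dict]:
    """Read a raster written by :func:`write_raster`; returns (array, grid, meta)."""
    import tifffile

    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise RasterFormatError(f"missing geometry sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if meta.get("rotation", 0.0) != 0.0:
        raise RasterFormatError("rotated raster transforms are not supported")
    grid = LandscapeGrid(
        x0=meta["x0"],
        y0=meta["y0"],
        n_rows=meta["n_rows"],
        n_cols=meta["n_cols"],
        pixel_size=meta["pixel_size"],
    )
    disk = tifffile.imread(path)
    data = disk[::-1] if disk.ndim == 2 else disk[:, ::-1]
    return np.ascontiguousarray(data), grid, meta


def write_table(path, table: pd.DataFrame, *, metadata: dict | None = None) -> Path:
    """CSV with a JSON schema/metadata sidecar."""
    path = Path(path)
    table.to_csv(path, index=False)
    sidecar = {
        "columns": {c: str(t) for c, t in table.dtypes.items()},
        "n_rows": len(table),
        "metadata": metadata or {},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path, obj: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def stems_to_geojson(path, stem_map, *, crowns: bool = False, metadata: dict | None = None) -> Path:
    """Stems as GeoJSON points, or crown circles as polygons."""
    from shapely.geometry import Point, mapping

    feats = []
    for x, y, h, r in zip(stem_map.x, stem_map.y, stem_map.height, stem_map.crown_radius):
        geom = Point(x, y).buffer(r, quad_segs=16) if crowns else Point(x, y)
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {"height": float(h), "crown_radius": float(r)},
            }
        )
    obj = {
        "type": "FeatureCollection",
        "features": feats,
        "metadata": metadata or {},
    }
    path = Path(path)
    path.write_text(json.dumps(obj))
    return path


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config_dict, sort_keys=True, default=_json_default)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
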
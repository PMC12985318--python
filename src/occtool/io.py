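"""Plain-text raster and tabular I/O.

Rasters travel as ESRI ASCII grids (.asc): a six-line header followed by
rows of values from north to south, which matches the package's row-0-at-
the-top grid convention. The format carries a single ``cellsize``, so only
grids with equal longitude and latitude resolution are written. All
coordinates are WGS 84 (EPSG:4326); a ``.prj``-style sidecar is not
emitted because the CRS is fixed package-wide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from occtool.geo_core import GeoGrid, LandCoverMap

_NODATA = -9999

OCCURRENCE_COLUMNS = ["record_id", "species", "lon", "lat", "source", "date"]


def write_ascii_grid(
    path: str,
    grid: GeoGrid,
    values: np.ndarray,
    valid: np.ndarray | None = None,
    fmt: str = "%d",
    nodata: float = _NODATA,
) -> None:
    """Write a 2-D field on ``grid`` as an ESRI ASCII grid."""
    if abs(grid.res_lon - grid.res_lat) > 1e-12:
        raise ValueError("ASCII grids require square cells (res_lon == res_lat)")
    values = np.asarray(values)
    if valid is not None:
        values = np.where(np.asarray(valid, dtype=bool), values, nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.lon_min!r}\n"
        f"yllcorner {grid.lat_min!r}\n"
        f"cellsize {grid.res_lon!r}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt=fmt)


def read_ascii_grid(path: str) -> tuple[GeoGrid, np.ndarray, np.ndarray]:
    """Read an ESRI ASCII grid; returns (grid, values, valid_mask)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    res = header["cellsize"]
    if "xllcorner" in header:
        lon_min, lat_min = header["xllcorner"], header["yllcorner"]
    else:  # cell-centre registered variant
        lon_min = header["xllcenter"] - res / 2
        lat_min = header["yllcenter"] - res / 2
    grid = GeoGrid(
        lon_min=lon_min,
        lat_min=lat_min,
        lon_max=lon_min + n_cols * res,
        lat_max=lat_min + n_rows * res,
        res_lon=res,
        res_lat=res,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    values = values.reshape(n_rows, n_cols)
    valid = values != header["nodata_value"]
    return grid, values, valid


def write_landcover(path: str, lc: LandCoverMap) -> None:
    write_ascii_grid(path, lc.grid, lc.codes, valid=lc.valid, fmt="%d")


def read_landcover(path: str, year_label: str = "") -> LandCoverMap:
    grid, values, valid = read_ascii_grid(path)
    return LandCoverMap(grid=grid, codes=values.astype(int), valid=valid, year_label=year_label)


def read_occurrence_csv(path: str) -> pd.DataFrame:
    """Read an occurrence table; the six standard columns are required,
    extra columns pass through untouched."""
    df = pd.read_csv(path, dtype={"record_id": str, "species": str})
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV missing required columns: {missing}")
    return df


def write_occurrence_csv(path: str, df: pd.DataFrame) -> None:
    ordered = [c for c in OCCURRENCE_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    df[ordered].to_csv(path, index=False)
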
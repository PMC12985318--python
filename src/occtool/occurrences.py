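"""Quality control, spatial thinning and annotation of occurrence records.

An :class:`OccurrenceSet` wraps an ordered pandas DataFrame of
georeferenced records (columns ``record_id, species, lon, lat, source,
date``; extras pass through) together with an append-only provenance log
recording each filter applied and the record counts before and after.

The cleaning pipeline mirrors standard occurrence-data practice for
national-scale mapping: drop exact coordinate duplicates per species,
drop records with missing or implausible locations or falling outside the
study boundary, then spatially thin so retained records respect a minimum
nearest-neighbour distance (1 km by default), limiting effort-related
pseudo-replication in heavily surveyed places.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from occtool.geo_core import LandCoverMap, PolygonSet, haversine_km, point_to_cell, points_in_polygons


@dataclass
class OccurrenceSet:
    """Ordered occurrence records plus an append-only provenance log."""

    records: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"record_id", "species", "lon", "lat"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        ids = self.records["record_id"]
        if ids.notna().all() and ids.duplicated().any():
            raise ValueError("record_ids must be unique")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def log(self, step: str, n_before: int, n_after: int, detail: str = "") -> None:
        line = f"{step}: {n_before} -> {n_after} records"
        if detail:
            line += f" ({detail})"
        self.provenance.append(line)

    def _derive(self, records: pd.DataFrame, step: str, detail: str = "") -> "OccurrenceSet":
        out = OccurrenceSet(records=records.copy(), provenance=list(self.provenance))
        out.log(step, len(self.records), len(records), detail)
        return out


def deduplicate(occ: OccurrenceSet, decimals: int = 6) -> OccurrenceSet:
    """Drop repeat records of a species at the same coordinates.

    Coordinates are compared after rounding to ``decimals`` places
    (6 decimals is ~0.1 m, effectively exact matching); the first record of
    each (species, lon, lat) group in input order is kept. Co-located
    records of *different* species are all retained.
    """
    df = occ.records
    key = pd.DataFrame(
        {
            "species": df["species"],
            "lon": df["lon"].round(decimals),
            "lat": df["lat"].round(decimals),
        }
    )
    keep = ~key.duplicated(keep="first")
    return occ._derive(df[keep], "deduplicate", f"{(~keep).sum()} duplicates removed")


def plausibility_filter(occ: OccurrenceSet, boundary: PolygonSet) -> OccurrenceSet:
    """Drop records with missing, out-of-range or out-of-boundary locations.

    Each dropped record is logged with its reason. Boundary membership uses
    the covers predicate: a record on the boundary edge is kept.
    """
    df = occ.records
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    missing = lon.isna() | lat.isna()
    bad_range = ~missing & ((lon < -180) | (lon > 180) | (lat < -90) | (lat > 90))
    candidate = ~missing & ~bad_range
    inside = np.zeros(len(df), dtype=bool)
    if candidate.any():
        inside[candidate.to_numpy()] = points_in_polygons(
            lon[candidate].to_numpy(), lat[candidate].to_numpy(), boundary
        )
    outside = candidate.to_numpy() & ~inside
    detail = (
        f"{int(missing.sum())} missing coordinates, "
        f"{int(bad_range.sum())} invalid range, "
        f"{int(outside.sum())} outside boundary"
    )
    return occ._derive(df[inside], "plausibility_filter", detail)


def thin(
    occ: OccurrenceSet,
    min_km: float = 1.0,
    per_species: bool = True,
    seed: int | None = None,
) -> OccurrenceSet:
    """Greedy spatial thinning to a minimum nearest-neighbour distance.

    Records are visited in input order (or a seeded random order when
    ``seed`` is given, to quantify order sensitivity); a record is retained
    iff its great-circle distance to every already-retained record of its
    thinning group is >= ``min_km``. Groups are species when
    ``per_species`` (co-located records of different taxa are biologically
    independent) or the whole set otherwise. The procedure is idempotent
    and deterministic given the visiting order.
    """
    if min_km < 0:
        raise ValueError("min_km must be non-negative")
    df = occ.records
    order = np.arange(len(df))
    if seed is not None:
        order = np.random.default_rng(seed).permutation(order)
    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)
    groups = df["species"].to_numpy() if per_species else np.zeros(len(df))
    kept_idx: dict[object, list[int]] = {}
    keep = np.zeros(len(df), dtype=bool)
    for i in order:
        g = groups[i]
        prior = kept_idx.setdefault(g, [])
        if prior:
            d = haversine_km(lon[i], lat[i], lon[prior], lat[prior])
            if np.min(d) < min_km:
                continue
        prior.append(i)
        keep[i] = True
    mode = "per-species" if per_species else "global"
    return occ._derive(
        df[keep].sort_index(), "thin", f"min_km={min_km}, {mode}, {int((~keep).sum())} removed"
    )


def annotate(
    occ: OccurrenceSet,
    lc: LandCoverMap,
    pas: PolygonSet | None = None,
    regions: PolygonSet | None = None,
) -> pd.DataFrame:
    """Attach land-cover class, protection flag and region to each record.

    The land-cover class comes from the grid cell containing the record
    (missing for off-grid or nodata cells); ``inside_pa`` uses the union of
    the protected-area polygons; ``region`` is the name of the first
    containing region polygon. Summary contingency tables are available via
    :func:`summary_tables`.
    """
    df = occ.records.copy()
    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)
    row, col, ok = point_to_cell(lc.grid, lon, lat)
    lc_class = np.full(len(df), np.nan)
    on_grid = ok.copy()
    on_grid[ok] &= lc.valid[row[ok], col[ok]]
    lc_class[on_grid] = lc.codes[row[on_grid], col[on_grid]]
    df["lc_class"] = lc_class
    if pas is not None:
        df["inside_pa"] = points_in_polygons(lon, lat, pas)
    if regions is not None:
        names = np.full(len(df), None, dtype=object)
        for geom, name in zip(regions.polygons, regions.names):
            import shapely

            shapely.prepare(geom)
            hit = shapely.covers(geom, shapely.points(lon, lat)) & (names == None)  # noqa: E711
            names[hit] = name
        df["region"] = names
    return df


def summary_tables(annotated: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Species-by-class, species-by-region and species-by-PA-status tables."""
    out: dict[str, pd.DataFrame] = {}
    if "lc_class" in annotated:
        out["species_by_class"] = pd.crosstab(annotated["species"], annotated["lc_class"])
    if "region" in annotated:
        out["species_by_region"] = pd.crosstab(annotated["species"], annotated["region"])
    if "inside_pa" in annotated:
        out["species_by_pa"] = pd.crosstab(annotated["species"], annotated["inside_pa"])
    return out
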
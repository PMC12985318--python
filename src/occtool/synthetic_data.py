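"""Synthetic landscapes, occurrences and protected areas with known truth.

Every pipeline stage can be exercised on generated data whose ground
truth is known exactly: a two-date categorical landscape with planted
per-class conversion probabilities, a clustered (Thomas-style
parent-offspring) occurrence point process with planted land-cover
affinity and protected-area enrichment, and a polygon set hitting a
target coverage fraction of the study boundary.

The default scenario emulates the statistical structure of a humid
tropical country dominated by one persistent evergreen-forest class
(~86% of the area, ~98% persistence over the period, losses dominated by
conversion to cropland), with ~480 occurrence points across six taxa
concentrated in forest, and a protected-area network covering ~18.5% of
the land with a planted enrichment that yields ~40% of points inside —
the order of magnitude of the national study this package is built
around. Grid size (200x200 cells at 0.01 degrees) is kept small enough
that the full pipeline runs in well under a minute.

All generators are deterministic given the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from occtool.geo_core import GeoGrid, LandCoverMap, PolygonSet, point_to_cell
from occtool.occurrences import OccurrenceSet

#: Deviation of one degree of latitude, used to convert dispersal scales.
KM_PER_DEG = 111.19


def _default_mixture() -> dict[int, float]:
    # FAO-LCCS-style codes: 50 forest, 10/11/30 croplands, 40 mosaic
    # natural vegetation, 190 urban
    return {50: 0.86, 10: 0.015, 11: 0.015, 30: 0.01, 40: 0.09, 190: 0.01}


def _default_conversion() -> dict[int, dict[int, float]]:
    return {
        50: {50: 0.98, 10: 0.006, 11: 0.004, 30: 0.004, 40: 0.005, 190: 0.001},
        10: {10: 0.97, 50: 0.02, 30: 0.01},
        11: {11: 0.97, 50: 0.015, 10: 0.015},
        30: {30: 0.96, 50: 0.025, 10: 0.015},
        40: {40: 0.95, 50: 0.04, 10: 0.01},
        190: {190: 1.0},
    }


def _default_species() -> dict[str, int]:
    # six taxa, quotas proportional to the observation-frequency profile
    # of a strongly ape-dominated national record set (total 481)
    return {
        "Gorilla gorilla": 140,
        "Pan troglodytes": 126,
        "Mandrillus sphinx": 114,
        "Allochrocebus solatus": 50,
        "Galagidae": 26,
        "Lorisidae": 25,
    }


@dataclass
class ScenarioConfig:
    """Ground-truth parameters of a synthetic study scenario."""

    # grid: 200x200 cells of 0.01 degrees near the equator
    lon_min: float = 11.0
    lat_min: float = -1.0
    res_deg: float = 0.01
    n_rows: int = 200
    n_cols: int = 200
    # landscape
    mixture: dict[int, float] = field(default_factory=_default_mixture)
    conversion: dict[int, dict[int, float]] = field(default_factory=_default_conversion)
    smooth_sigma_cells: float = 3.0  # spatial autocorrelation scale of date-1 classes
    # occurrence point process
    species_quota: dict[str, int] = field(default_factory=_default_species)
    parents_per_species: int = 5  # 0 disables clustering (CSR proposals)
    dispersal_sigma_km: float = 8.0
    class_weights: dict[int, float] = field(default_factory=lambda: {50: 1.0})
    default_class_weight: float = 0.85
    # protected areas
    n_pas: int = 8
    pa_coverage: float = 0.185  # target union share f of the boundary area
    pa_enrichment: float = 2.96  # planted acceptance multiplier rho inside PAs
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ValueError("class mixture must sum to 1")
        for a, row in self.conversion.items():
            if a not in self.mixture:
                raise ValueError(f"conversion row for class {a} absent from the mixture")
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"conversion row for class {a} must sum to 1")
        if not (0 < self.pa_coverage < 1):
            raise ValueError("pa_coverage must lie in (0, 1)")
        if self.pa_enrichment <= 0:
            raise ValueError("pa_enrichment must be positive")

    @property
    def grid(self) -> GeoGrid:
        return GeoGrid(
            lon_min=self.lon_min,
            lat_min=self.lat_min,
            lon_max=self.lon_min + self.n_cols * self.res_deg,
            lat_max=self.lat_min + self.n_rows * self.res_deg,
            res_lon=self.res_deg,
            res_lat=self.res_deg,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
        )

    def boundary(self) -> BaseGeometry:
        """Study boundary: the rectangular grid extent."""
        g = self.grid
        return box(g.lon_min, g.lat_min, g.lon_max, g.lat_max)

    def weight_of(self, code: int) -> float:
        return self.class_weights.get(code, self.default_class_weight)


def gen_landscape(cfg: ScenarioConfig) -> tuple[LandCoverMap, LandCoverMap, dict]:
    """Two-date categorical landscape with planted conversion rates.

    Date-1 classes come from a Gaussian-smoothed noise field thresholded
    at the mixture quantiles, giving spatially coherent patches whose
    areal shares match the mixture; date-2 applies the per-class
    conversion probabilities independently per cell. Returns both maps
    plus a truth dict with the realized transition counts.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid
    field_ = ndimage.gaussian_filter(rng.standard_normal(grid.shape), cfg.smooth_sigma_cells)
    ranks = field_.ravel().argsort().argsort() / field_.size  # uniform in [0,1)
    codes = np.empty(field_.size, dtype=int)
    lo = 0.0
    items = sorted(cfg.mixture.items())
    for code, share in items:
        hi = lo + share
        codes[(ranks >= lo) & (ranks < hi)] = code
        lo = hi
    codes[ranks >= lo] = items[-1][0]  # numerical remainder
    codes = codes.reshape(grid.shape)

    codes2 = codes.copy()
    for a, row in cfg.conversion.items():
        cells = codes == a
        n = int(cells.sum())
        if n == 0:
            continue
        dest = np.array(sorted(row))
        prob = np.array([row[d] for d in dest])
        codes2[cells] = rng.choice(dest, size=n, p=prob)

    valid = np.ones(grid.shape, dtype=bool)
    lc1 = LandCoverMap(grid=grid, codes=codes, valid=valid, year_label="t1")
    lc2 = LandCoverMap(grid=grid, codes=codes2, valid=valid.copy(), year_label="t2")
    all_codes = set(cfg.mixture) | {b for row in cfg.conversion.values() for b in row}
    classes = np.array(sorted(all_codes))
    lut = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    np.add.at(
        counts,
        (
            np.vectorize(lut.get)(codes.ravel()),
            np.vectorize(lut.get)(codes2.ravel()),
        ),
        1,
    )
    truth = {
        "classes": classes.tolist(),
        "transition_counts": counts.tolist(),
        "mixture": dict(cfg.mixture),
        "conversion": {a: dict(r) for a, r in cfg.conversion.items()},
    }
    return lc1, lc2, truth


def gen_protected_areas(
    cfg: ScenarioConfig, boundary: BaseGeometry | None = None, max_iter: int = 60
) -> tuple[PolygonSet, dict]:
    """Random rectangular reserves hitting the target coverage fraction.

    Rectangle centres are drawn uniformly inside the boundary; all
    rectangles are scaled jointly until the clipped union area is within
    2% of ``pa_coverage`` times the boundary area. Categories alternate
    official / oecm. Raises if the budget of scaling iterations cannot
    reach the target.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    boundary = cfg.boundary() if boundary is None else boundary
    target = cfg.pa_coverage * boundary.area
    minx, miny, maxx, maxy = boundary.bounds
    centers = []
    while len(centers) < cfg.n_pas:
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if boundary.covers(shapely.points(x, y)):
            centers.append((x, y))
    aspect = rng.uniform(0.6, 1.6, size=cfg.n_pas)
    rel = rng.uniform(0.5, 1.5, size=cfg.n_pas)
    # initial half-size: n disjoint squares would exactly tile the target
    s = float(np.sqrt(target / cfg.n_pas) / 2)
    achieved = 0.0
    for _ in range(max_iter):
        polys = [
            box(x - s * r * a, y - s * r / a, x + s * r * a, y + s * r / a).intersection(boundary)
            for (x, y), r, a in zip(centers, rel, aspect)
        ]
        achieved = unary_union(polys).area
        if abs(achieved - target) <= 0.02 * target:
            break
        s *= float(np.sqrt(target / achieved))
    else:
        raise RuntimeError(
            f"could not reach coverage {cfg.pa_coverage:.3f}; achieved {achieved / boundary.area:.3f}"
        )
    cats = ["official" if i % 2 == 0 else "oecm" for i in range(cfg.n_pas)]
    names = [f"reserve_{i}" for i in range(cfg.n_pas)]
    pset = PolygonSet(polygons=polys, names=names, categories=cats)
    truth = {
        "pa_realized_fraction": achieved / boundary.area,
        "pa_target_fraction": cfg.pa_coverage,
        "n_pas": cfg.n_pas,
    }
    return pset, truth


def gen_occurrences(
    cfg: ScenarioConfig, lc: LandCoverMap, pas: PolygonSet
) -> tuple[OccurrenceSet, dict]:
    """Clustered occurrence points with planted affinity and enrichment.

    A Thomas-style process per species: parent centres drawn uniformly
    over the grid, offspring proposed around a random parent with
    isotropic Gaussian dispersal (``dispersal_sigma_km``), or proposed
    uniformly when ``parents_per_species`` is 0 (the CSR limiting case).
    A proposal landing on a valid cell is accepted with probability
    proportional to its class weight, multiplied by the planted enrichment
    rho when it falls inside a protected area. Ground-truth labels (cell
    class, PA membership) are stored per point.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    grid = lc.grid
    max_w = max(
        max(cfg.class_weights.values(), default=0.0), cfg.default_class_weight
    ) * max(cfg.pa_enrichment, 1.0)
    if max_w <= 0:
        raise ValueError("all placement weights are zero; quota unreachable")
    union = pas.union
    shapely.prepare(union)
    sigma_deg = cfg.dispersal_sigma_km / KM_PER_DEG
    rows_out: list[dict] = []
    rid = 0
    for species, quota in cfg.species_quota.items():
        if cfg.parents_per_species > 0:
            par_lon = rng.uniform(grid.lon_min, grid.lon_max, cfg.parents_per_species)
            par_lat = rng.uniform(grid.lat_min, grid.lat_max, cfg.parents_per_species)
        accepted = 0
        guard = 0
        while accepted < quota:
            guard += 1
            if guard > 200_000:
                raise RuntimeError(f"quota for {species} unreachable with given weights")
            if cfg.parents_per_species > 0:
                k = rng.integers(cfg.parents_per_species)
                lon = par_lon[k] + rng.normal(0, sigma_deg)
                lat = par_lat[k] + rng.normal(0, sigma_deg)
            else:
                lon = rng.uniform(grid.lon_min, grid.lon_max)
                lat = rng.uniform(grid.lat_min, grid.lat_max)
            row, col, ok = point_to_cell(grid, lon, lat)
            if not ok or not lc.valid[row, col]:
                continue
            code = int(lc.codes[row, col])
            inside = bool(shapely.covers(union, shapely.points(lon, lat)))
            w = cfg.weight_of(code) * (cfg.pa_enrichment if inside else 1.0)
            if rng.random() >= w / max_w:
                continue
            rows_out.append(
                {
                    "record_id": f"synth_{rid:05d}",
                    "species": species,
                    "lon": float(lon),
                    "lat": float(lat),
                    "source": "field" if rng.random() < 0.93 else "public_db",
                    "date": "",
                    "true_class": code,
                    "true_inside_pa": inside,
                }
            )
            rid += 1
            accepted += 1
    df = pd.DataFrame(rows_out)
    occ = OccurrenceSet(records=df, provenance=[f"gen_occurrences: {len(df)} records generated"])
    truth = {
        "n_points": len(df),
        "inside_pa_fraction": float(df["true_inside_pa"].mean()),
        "class_counts": df["true_class"].value_counts().to_dict(),
        "rho": cfg.pa_enrichment,
    }
    return occ, truth


def implied_inside_probability(rho: float, f: float) -> float:
    """Inside-PA acceptance probability rho*f / (rho*f + (1 - f)) implied
    by a planted enrichment ``rho`` over a PA area fraction ``f`` when the
    proposal process and class weights are spatially uniform."""
    return rho * f / (rho * f + (1 - f))
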
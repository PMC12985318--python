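"""Monte Carlo test of protected-area enrichment of occurrence points.

The question: do occurrence records fall inside the protected-area
network more often than points scattered at complete spatial randomness
(CSR) over the valid landscape would? The null distribution is built by
repeatedly dropping the same number of points uniformly over the valid
(non-nodata) land-cover cells — each simulated point sits at a uniform
random position inside a uniformly sampled cell — and recording the
proportion that land inside the PA union. The p-value is the proportion
of simulations with an inside-proportion greater than or equal to the
observed one, and the enrichment ratio is the observed proportion over
the null mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from occtool.geo_core import LandCoverMap, PolygonSet, points_in_polygons


@dataclass
class EnrichmentResult:
    """Observed inside-PA share, CSR null draws and derived statistics."""

    n_points: int
    observed_count: int
    observed_prop: float
    null_draws: np.ndarray
    n_iter: int
    seed: int
    area_weighted: bool = False

    @property
    def null_mean(self) -> float:
        return float(self.null_draws.mean())

    @property
    def enrichment(self) -> float:
        return self.observed_prop / self.null_mean if self.null_mean > 0 else np.inf

    @property
    def p_value(self) -> float:
        """Share of simulations with inside-proportion >= observed."""
        return float(np.mean(self.null_draws >= self.observed_prop))

    @property
    def p_value_corrected(self) -> float:
        """(1 + exceedances) / (1 + N) permutation-style alternative."""
        return float((1 + np.sum(self.null_draws >= self.observed_prop)) / (1 + self.n_iter))

    def p_label(self) -> str:
        p = self.p_value
        return f"< {1 / self.n_iter:g}" if p == 0 else f"{p:g}"

    def to_dict(self) -> dict:
        return {
            "n": self.n_points,
            "observed_count": self.observed_count,
            "observed_prop": self.observed_prop,
            "null_mean": self.null_mean,
            "enrichment": self.enrichment,
            "p_value": self.p_value,
            "p_label": self.p_label(),
            "N_iter": self.n_iter,
            "seed": self.seed,
            "area_weighted": self.area_weighted,
        }


def observed_inside(lon, lat, pas: PolygonSet) -> tuple[int, float]:
    """Count and proportion of points inside the PA union (overlaps once,
    boundary points inside)."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    if lon.size == 0:
        raise ValueError("need at least one point")
    if len(pas) == 0:
        import warnings

        warnings.warn("empty polygon set: observed proportion is 0", stacklevel=2)
        return 0, 0.0
    inside = points_in_polygons(lon, lat, pas)
    return int(inside.sum()), float(inside.mean())


def csr_null(
    n: int,
    valid: LandCoverMap,
    pas: PolygonSet,
    n_iter: int = 10_000,
    seed: int = 0,
    area_weighted: bool = False,
) -> np.ndarray:
    """CSR null distribution of the inside-PA proportion.

    Per iteration, ``n`` cells are drawn (with replacement) uniformly from
    the valid cells of ``valid`` — or proportionally to their geodesic
    area when ``area_weighted`` — and each point is placed uniformly
    inside its cell. Returns the ``n_iter`` inside-PA proportions.
    """
    if n <= 0 or n_iter <= 0:
        raise ValueError("n and n_iter must be positive")
    rows, cols = np.nonzero(valid.valid)
    if rows.size == 0:
        raise ValueError("no valid cells to sample from")
    rng = np.random.default_rng(seed)
    grid = valid.grid
    weights = None
    if area_weighted:
        from occtool.geo_core import cell_area_field

        w = cell_area_field(grid).area[rows, cols]
        weights = w / w.sum()
    union = pas.union
    shapely.prepare(union)
    draws = np.empty(n_iter)
    # vectorise across iterations in blocks to bound memory
    block = max(1, int(2_000_000 // n))
    for b0 in range(0, n_iter, block):
        b1 = min(b0 + block, n_iter)
        k = (b1 - b0) * n
        idx = rng.choice(rows.size, size=k, p=weights)
        jit_lon = rng.random(k)
        jit_lat = rng.random(k)
        lon = grid.lon_min + (cols[idx] + jit_lon) * grid.res_lon
        lat = grid.lat_max - (rows[idx] + jit_lat) * grid.res_lat
        inside = shapely.covers(union, shapely.points(lon, lat))
        draws[b0:b1] = inside.reshape(b1 - b0, n).mean(axis=1)
    return draws


def enrichment_test(
    lon,
    lat,
    valid: LandCoverMap,
    pas: PolygonSet,
    n_iter: int = 10_000,
    seed: int = 0,
    area_weighted: bool = False,
) -> EnrichmentResult:
    """Observed inside-PA share against the CSR null; see module docs."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    count, prop = observed_inside(lon, lat, pas)
    draws = csr_null(lon.size, valid, pas, n_iter=n_iter, seed=seed, area_weighted=area_weighted)
    return EnrichmentResult(
        n_points=int(lon.size),
        observed_count=count,
        observed_prop=prop,
        null_draws=draws,
        n_iter=n_iter,
        seed=seed,
        area_weighted=area_weighted,
    )
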
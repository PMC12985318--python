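"""End-to-end pipeline orchestration: QC -> change -> hotspots -> enrichment.

A single :class:`RunConfig` carries every stage parameter and an explicit
seed for each stochastic stage; the run report embeds the config and its
hash so results always travel with the choices that produced them.
Inputs can come from files (ASCII-grid rasters, GeoJSON polygons, CSV
occurrences) or from a built-in synthetic scenario.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from occtool import io as occio
from occtool.geo_core import PolygonSet, cell_area_field, coregister, points_in_polygons
from occtool.hotspot_analysis import (
    class_tally,
    classify,
    count_grid,
    gi_star,
    kde_surface,
    largest_patch_area,
    percentile_area,
)
from occtool.landcover_change import (
    class_area_table,
    decompose_class_change,
    forest_loss_driver_test,
    stability_at_points,
    transition_matrix,
)
from occtool.occurrences import OccurrenceSet, annotate, deduplicate, plausibility_filter, thin
from occtool.pa_enrichment import enrichment_test
from occtool.synthetic_data import ScenarioConfig, gen_landscape, gen_occurrences, gen_protected_areas


@dataclass
class RunConfig:
    """All pipeline parameters in one serialisable object."""

    # inputs: either paths, or None to use the synthetic scenario
    lc_t1_path: str | None = None
    lc_t2_path: str | None = None
    occurrences_path: str | None = None
    boundary_path: str | None = None
    pas_path: str | None = None
    synthetic: bool = True
    scenario: dict = field(default_factory=dict)  # ScenarioConfig overrides
    # QC
    min_km: float = 1.0
    per_species: bool = True
    # change analysis
    focal_class: int = 50
    availability_mode: str = "nonfocal_2022"
    # hotspots
    kde_bandwidth_deg: float = 0.2
    kde_grid: int = 500
    gi_res_deg: float = 0.05
    density_percentile: float = 90.0
    # enrichment
    n_iter: int = 1000
    seed: int = 0
    area_weighted_null: bool = False
    out_dir: str = "occtool_run"

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic:
        scen = ScenarioConfig(**{"seed": cfg.seed, **cfg.scenario})
        lc1, lc2, lc_truth = gen_landscape(scen)
        boundary = PolygonSet(polygons=[scen.boundary()], names=["study_area"])
        pas, pa_truth = gen_protected_areas(scen, scen.boundary())
        occ, occ_truth = gen_occurrences(scen, lc2, pas)
        truth = {"landscape": lc_truth, "pas": pa_truth, "occurrences": occ_truth}
        return lc1, lc2, occ, boundary, pas, truth
    lc1 = occio.read_landcover(cfg.lc_t1_path, year_label="t1")
    lc2 = occio.read_landcover(cfg.lc_t2_path, year_label="t2")
    occ = OccurrenceSet(records=occio.read_occurrence_csv(cfg.occurrences_path))
    boundary = PolygonSet.from_geojson(cfg.boundary_path)
    pas = PolygonSet.from_geojson(cfg.pas_path)
    return lc1, lc2, occ, boundary, pas, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write all outputs under ``cfg.out_dir``.

    Returns the run report (also written as ``report.json``). A stage
    failure raises with the stage name; outputs of completed stages are
    retained on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(cfg), "config_hash": cfg.digest()}
    stage = "load_inputs"
    try:
        lc1, lc2, occ, boundary, pas, truth = _load_inputs(cfg)
        if truth is not None:
            with open(out / "truth.json", "w") as fh:
                json.dump(truth, fh, indent=1)
            occio.write_landcover(out / "lc_t1.asc", lc1)
            occio.write_landcover(out / "lc_t2.asc", lc2)
            occio.write_occurrence_csv(out / "occurrences.csv", occ.records)
            pas.to_geojson(out / "pas.geojson")
            boundary.to_geojson(out / "boundary.geojson")

        stage = "qc"
        lc2r = coregister(lc1, lc2)
        occ_d = deduplicate(occ)
        occ_p = plausibility_filter(occ_d, boundary)
        occ_t = thin(occ_p, min_km=cfg.min_km, per_species=cfg.per_species)
        report["qc"] = {
            "n_input": len(occ),
            "n_deduplicated": len(occ_d),
            "n_plausible": len(occ_p),
            "n_thinned": len(occ_t),
            "provenance": occ_t.provenance,
        }
        annotated = annotate(occ_t, lc2r, pas=pas)
        occio.write_occurrence_csv(out / "occurrences_qc.csv", annotated)
        (out / "provenance.log").write_text("\n".join(occ_t.provenance) + "\n")

        stage = "change"
        areas = cell_area_field(lc1.grid)
        mask = lc1.valid & lc2r.valid
        t1_table = class_area_table(lc1, areas, mask)
        t2_table = class_area_table(lc2r, areas, mask)
        merged = t1_table.join(t2_table, lsuffix="_t1", rsuffix="_t2", how="outer").fillna(0.0)
        merged["delta_area"] = merged["area_km2_t2"] - merged["area_km2_t1"]
        merged["delta_prop"] = merged["prop_t2"] - merged["prop_t1"]
        merged.to_csv(out / "class_areas.csv")
        T = transition_matrix(lc1, lc2r, areas)
        T.to_long().to_csv(out / "transitions.csv", index=False)
        dec = decompose_class_change(T, cfg.focal_class)
        chisq = forest_loss_driver_test(
            lc1, lc2r, focal=cfg.focal_class, availability_mode=cfg.availability_mode
        )
        with open(out / "chisq.json", "w") as fh:
            json.dump(chisq.to_dict(), fh, indent=1)
        stab_table, stab = stability_at_points(occ_t, lc1, lc2r)
        report["change"] = {
            "total_area_km2": T.total_area,
            "focal_class": cfg.focal_class,
            "persistence_km2": dec.persistence_km2,
            "persistence_pct": dec.persistence_pct,
            "gross_losses_km2": dec.gross_losses_km2,
            "gross_gains_km2": dec.gross_gains_km2,
            "net_km2": dec.net_km2,
            "loss_pct_by_dest": {int(k): v for k, v in dec.loss_pct_by_dest.items()},
            "gain_pct_by_source": {int(k): v for k, v in dec.gain_pct_by_source.items()},
            "chi2": chisq.chi2,
            "chi2_p": chisq.p_value,
            "stability": stab,
        }

        stage = "hotspots"
        g = boundary.union.bounds  # (minx, miny, maxx, maxy)
        from occtool.geo_core import GeoGrid

        kde_grid = GeoGrid.from_extent(g[0], g[1], g[2], g[3], cfg.kde_grid, cfg.kde_grid)
        lon_c, lat_c = kde_grid.centers()
        lon2d, lat2d = np.meshgrid(lon_c, lat_c)
        inside = points_in_polygons(lon2d.ravel(), lat2d.ravel(), boundary).reshape(kde_grid.shape)
        pts = occ_t.records
        surf = kde_surface(
            pts["lon"].to_numpy(float),
            pts["lat"].to_numpy(float),
            kde_grid,
            bandwidth_deg=cfg.kde_bandwidth_deg,
            mask=inside,
        )
        occio.write_ascii_grid(
            out / "density.asc", kde_grid, surf.density, valid=surf.mask, fmt="%.6e"
        )
        kde_areas = cell_area_field(kde_grid)
        top_area = percentile_area(surf, kde_areas, cfg.density_percentile)
        thr = float(np.percentile(surf.masked_values(), cfg.density_percentile))
        patch = largest_patch_area(surf, kde_areas, thr)
        hg = count_grid(
            pts["lon"].to_numpy(float), pts["lat"].to_numpy(float), g, res_deg=cfg.gi_res_deg
        )
        lon_c, lat_c = hg.grid.centers()
        lon2d, lat2d = np.meshgrid(lon_c, lat_c)
        hg.mask[:] = points_in_polygons(lon2d.ravel(), lat2d.ravel(), boundary).reshape(
            hg.grid.shape
        )
        hg = classify(gi_star(hg))
        hg.to_frame().to_csv(out / "hotspots.csv", index=False)
        occio.write_ascii_grid(out / "hotspot_classes.asc", hg.grid, hg.classes, valid=hg.mask)
        report["hotspots"] = {
            "top_decile_area_km2": top_area,
            "largest_patch_km2": patch,
            "class_tally": class_tally(hg),
            "n_cells": int(hg.mask.sum()),
        }

        stage = "enrichment"
        res = enrichment_test(
            pts["lon"].to_numpy(float),
            pts["lat"].to_numpy(float),
            lc2r,
            pas,
            n_iter=cfg.n_iter,
            seed=cfg.seed,
            area_weighted=cfg.area_weighted_null,
        )
        with open(out / "enrichment.json", "w") as fh:
            json.dump(res.to_dict(), fh, indent=1)
        report["enrichment"] = res.to_dict()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
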
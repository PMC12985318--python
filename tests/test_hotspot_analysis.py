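"""KDE surfaces, Gi* statistics, FDR adjustment and hotspot classification."""

import numpy as np
import pytest
from scipy import stats

from occtool.geo_core import GeoGrid, cell_area_field, point_to_cell
from occtool.hotspot_analysis import (
    CLASS_CODES,
    DensitySurface,
    HotspotGrid,
    bh_adjust,
    class_tally,
    classify,
    count_grid,
    gi_star,
    kde_surface,
    largest_patch_area,
    percentile_area,
)


def brute_force_gi_star(counts):
    """Double-loop Ord-Getis Gi* on a full rectangular grid."""
    n_rows, n_cols = counts.shape
    n = counts.size
    xbar = counts.mean()
    s = np.sqrt((counts**2).mean() - xbar**2)
    z = np.zeros_like(counts, dtype=float)
    for i in range(n_rows):
        for j in range(n_cols):
            wsum, w = 0.0, 0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n_rows and 0 <= jj < n_cols:
                        wsum += counts[ii, jj]
                        w += 1
            denom = s * np.sqrt((n * w - w**2) / (n - 1))
            z[i, j] = (wsum - xbar * w) / denom
    return z


def hg_from_counts(counts):
    counts = np.asarray(counts, dtype=float)
    grid = GeoGrid.from_extent(0, 0, counts.shape[1] * 0.05, counts.shape[0] * 0.05,
                               n_rows=counts.shape[0], n_cols=counts.shape[1])
    return HotspotGrid(grid=grid, counts=counts, mask=np.ones(counts.shape, bool))


class TestKde:
    def test_single_point_peak_value(self):
        grid = GeoGrid.from_extent(0, 0, 1, 1, n_rows=101, n_cols=101)
        # place the point exactly on a cell centre
        lon, lat = grid.cell_center(50, 50)
        surf = kde_surface([lon], [lat], grid, bandwidth_deg=0.2)
        h = 0.2
        assert surf.density.max() == pytest.approx(1 / (2 * np.pi * h**2), rel=1e-12)
        assert np.unravel_index(surf.density.argmax(), surf.density.shape) == (50, 50)

    def test_value_at_one_bandwidth_is_exp_minus_half_of_peak(self):
        grid = GeoGrid.from_extent(0, 0, 1, 1, n_rows=101, n_cols=101)
        lon, lat = grid.cell_center(50, 50)
        h = 0.2
        surf = kde_surface([lon], [lat], grid, bandwidth_deg=h)
        row, col, _ = point_to_cell(grid, lon + h, lat)
        ratio = surf.density[row, col] / surf.density[50, 50]
        # cell centre sits within half a cell of the exact offset h
        d = abs((grid.cell_center(row, col)[0]) - lon)
        assert ratio == pytest.approx(np.exp(-(d**2) / (2 * h**2)), rel=1e-12)
        assert ratio == pytest.approx(np.exp(-0.5), rel=0.1)

    def test_mirror_symmetry(self):
        grid = GeoGrid.from_extent(0, 0, 1, 1, n_rows=40, n_cols=40)
        surf = kde_surface([0.3, 0.7], [0.4, 0.4], grid, bandwidth_deg=0.15)
        np.testing.assert_allclose(surf.density, surf.density[:, ::-1], rtol=1e-10)

    def test_integrates_to_one_unmasked(self):
        # generous grid so the kernels' mass is inside the window
        grid = GeoGrid.from_extent(-2, -2, 3, 3, n_rows=250, n_cols=250)
        surf = kde_surface([0.4, 0.6], [0.5, 0.5], grid, bandwidth_deg=0.1)
        integral = surf.density.sum() * grid.res_lon * grid.res_lat
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_zero_points_rejected(self, unit_grid):
        with pytest.raises(ValueError, match="point"):
            kde_surface([], [], unit_grid)

    def test_bandwidth_stability_on_clustered_points(self):
        # hotspot geography is robust to the bandwidth choice: top-decile
        # cell sets at adjacent bandwidths overlap strongly
        rng = np.random.default_rng(31)
        centres = [(1.2, 1.2), (2.8, 2.4)]  # country-scale domain, ~17 km clusters
        lon = np.concatenate([rng.normal(cx, 0.15, 150) for cx, _ in centres])
        lat = np.concatenate([rng.normal(cy, 0.15, 150) for _, cy in centres])
        grid = GeoGrid.from_extent(0, 0, 4, 4, n_rows=80, n_cols=80)
        tops = []
        for h in (0.1, 0.2, 0.3):
            surf = kde_surface(lon, lat, grid, bandwidth_deg=h)
            thr = np.percentile(surf.density, 90)
            tops.append(set(map(tuple, np.argwhere(surf.density > thr))))
        for a, b in zip(tops, tops[1:]):
            jaccard = len(a & b) / len(a | b)
            assert jaccard > 0.5


class TestPercentileAndPatches:
    def _surface(self, values, res=0.05):
        values = np.asarray(values, dtype=float)
        grid = GeoGrid.from_extent(0, 0, values.shape[1] * res, values.shape[0] * res,
                                   n_rows=values.shape[0], n_cols=values.shape[1])
        return DensitySurface(grid=grid, density=values, bandwidth_deg=0.2,
                              mask=np.ones(values.shape, bool))

    def test_constant_surface_zero_area_above_any_percentile(self):
        surf = self._surface(np.full((5, 5), 3.0))
        areas = cell_area_field(surf.grid)
        assert percentile_area(surf, areas, 90) == 0.0

    def test_distinct_values_top_decile_area(self):
        rng = np.random.default_rng(32)
        vals = rng.permutation(100).reshape(10, 10).astype(float)
        surf = self._surface(vals, res=0.01)  # near-equator, cells ~equal area
        areas = cell_area_field(surf.grid)
        got = percentile_area(surf, areas, 90)
        # 9 cells strictly above the interpolated 90th percentile of 0..99
        expected = areas.area[vals > np.percentile(vals, 90)].sum()
        assert got == pytest.approx(expected)
        assert got / areas.total() == pytest.approx(0.09, abs=0.02)

    def test_median_splits_area_in_half(self):
        vals = np.arange(100, dtype=float).reshape(10, 10)
        surf = self._surface(vals, res=0.01)
        areas = cell_area_field(surf.grid)
        frac = percentile_area(surf, areas, 50) / areas.total()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_invalid_percentile_rejected(self):
        surf = self._surface(np.ones((3, 3)))
        with pytest.raises(ValueError, match="percentile"):
            percentile_area(surf, cell_area_field(surf.grid), 100)

    def test_single_cell_patch(self):
        vals = np.zeros((5, 5))
        vals[2, 2] = 1.0
        surf = self._surface(vals)
        areas = cell_area_field(surf.grid)
        assert largest_patch_area(surf, areas, 0.5) == pytest.approx(areas.area[2, 2])

    def test_diagonal_cells_form_one_patch(self):
        vals = np.zeros((5, 5))
        vals[1, 1] = vals[2, 2] = 1.0
        surf = self._surface(vals)
        areas = cell_area_field(surf.grid)
        expected = areas.area[1, 1] + areas.area[2, 2]
        assert largest_patch_area(surf, areas, 0.5) == pytest.approx(expected)

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(33)
        vals = (rng.random((15, 15)) > 0.6).astype(float)
        surf = self._surface(vals)
        areas = cell_area_field(surf.grid)

        def flood_fill_max(binary):
            seen = np.zeros_like(binary, bool)
            best = 0.0
            for i in range(binary.shape[0]):
                for j in range(binary.shape[1]):
                    if binary[i, j] and not seen[i, j]:
                        area, stack = 0.0, [(i, j)]
                        seen[i, j] = True
                        while stack:
                            a, b = stack.pop()
                            area += areas.area[a, b]
                            for da in (-1, 0, 1):
                                for db in (-1, 0, 1):
                                    aa, bb = a + da, b + db
                                    if (0 <= aa < binary.shape[0] and 0 <= bb < binary.shape[1]
                                            and binary[aa, bb] and not seen[aa, bb]):
                                        seen[aa, bb] = True
                                        stack.append((aa, bb))
                        best = max(best, area)
            return best

        assert largest_patch_area(surf, areas, 0.5) == pytest.approx(flood_fill_max(vals > 0.5))

    def test_no_cell_above_threshold_gives_zero(self):
        surf = self._surface(np.zeros((4, 4)))
        assert largest_patch_area(surf, cell_area_field(surf.grid), 1.0) == 0.0


class TestCountGrid:
    def test_no_points_all_zero(self):
        hg = count_grid([], [], (0, 0, 1, 1), res_deg=0.25)
        assert hg.counts.sum() == 0

    def test_one_point_per_cell_centre(self):
        hg0 = count_grid([], [], (0, 0, 0.15, 0.15), res_deg=0.05)
        rows, cols = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
        lon, lat = hg0.grid.cell_center(rows.ravel(), cols.ravel())
        hg = count_grid(lon, lat, (0, 0, 0.15, 0.15), res_deg=0.05)
        np.testing.assert_array_equal(hg.counts, np.ones((3, 3)))

    def test_counts_sum_to_points_inside(self):
        rng = np.random.default_rng(34)
        lon = rng.uniform(0, 1, 400)
        lat = rng.uniform(0, 1, 400)
        hg = count_grid(lon, lat, (0, 0, 1, 1), res_deg=0.05)
        assert hg.counts.sum() == 400

    def test_outside_points_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            hg = count_grid([0.5, 5.0], [0.5, 0.5], (0, 0, 1, 1), res_deg=0.5)
        assert hg.counts.sum() == 1 and hg.n_dropped == 1


class TestGiStar:
    def test_constant_field_all_zero_with_warning(self):
        hg = hg_from_counts(np.full((4, 4), 2.0))
        with pytest.warns(UserWarning, match="constant"):
            out = gi_star(hg)
        assert np.all(out.z == 0)

    def test_five_by_five_centre_worked_example(self):
        counts = np.zeros((5, 5))
        counts[2, 2] = 1.0
        out = gi_star(hg_from_counts(counts))
        assert out.z[2, 2] == pytest.approx(0.64 / 0.48, rel=1e-6)
        assert out.z[2, 2] == pytest.approx(1.3333, abs=1e-4)

    def test_five_by_five_corner_worked_example(self):
        counts = np.zeros((5, 5))
        counts[2, 2] = 1.0
        out = gi_star(hg_from_counts(counts))
        s = np.sqrt(24 / 625)
        expected = -0.16 / (s * np.sqrt(84 / 24))
        assert out.z[0, 0] == pytest.approx(expected, rel=1e-9)
        assert out.z[0, 0] == pytest.approx(-0.4364, abs=1e-4)

    def test_matches_brute_force_on_random_grids(self):
        rng = np.random.default_rng(35)
        for _ in range(50):
            counts = rng.poisson(2.0, size=(10, 10)).astype(float)
            if counts.std() == 0:
                continue
            out = gi_star(hg_from_counts(counts))
            np.testing.assert_allclose(out.z, brute_force_gi_star(counts), atol=1e-12)

    def test_mask_restricts_cell_universe(self):
        counts = np.zeros((5, 5))
        counts[2, 2] = 1.0
        grid = GeoGrid.from_extent(0, 0, 0.25, 0.25, n_rows=5, n_cols=5)
        mask = np.ones((5, 5), bool)
        mask[0, :] = False
        out = gi_star(HotspotGrid(grid=grid, counts=counts, mask=mask))
        assert out.meta["n_cells"] == 20
        assert np.all(out.z[0, :] == 0)

    def test_csr_prefdr_rejection_rate_near_nominal(self):
        # under dense uniform multinomial counts (normal-approximation
        # regime) ~5% of |z| exceed 1.96 before FDR control
        rng = np.random.default_rng(36)
        rates = []
        for _ in range(50):
            counts = rng.multinomial(80_000, np.full(1600, 1 / 1600)).reshape(40, 40)
            out = gi_star(hg_from_counts(counts.astype(float)))
            rates.append((np.abs(out.z) >= 1.96).mean())
        rates = np.asarray(rates)
        se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - 0.05) < 3 * se


class TestBhAdjust:
    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_hand_example_all_q_004(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.123]), [0.123])

    def test_matches_step_up_oracle_and_dominates_raw(self):
        def step_up(p):
            p = np.asarray(p, float)
            order = np.argsort(p)
            n = len(p)
            q = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * n / rank)
                q[idx] = running
            return q

        rng = np.random.default_rng(37)
        p = rng.uniform(0, 1, 200)
        q = bh_adjust(p)
        np.testing.assert_allclose(q, step_up(p), atol=1e-12)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            bh_adjust([0.5, 1.2])


class TestClassify:
    def _classified(self, z_val, p_val):
        counts = np.zeros((3, 3))
        grid = GeoGrid.from_extent(0, 0, 0.15, 0.15, n_rows=3, n_cols=3)
        hg = HotspotGrid(
            grid=grid,
            counts=counts,
            mask=np.ones((3, 3), bool),
            z=np.full((3, 3), z_val),
            p=np.full((3, 3), p_val),
        )
        return classify(hg)

    def test_strong_hotspot_is_hot99(self):
        out = self._classified(3.0, 0.001)
        assert np.all(out.classes == CLASS_CODES["hot99"])

    def test_z_alone_insufficient(self):
        # q fails the conjunction even though z passes
        out = self._classified(2.0, 0.20)
        assert np.all(out.classes == CLASS_CODES["ns"])

    def test_strong_coldspot_is_cold99(self):
        out = self._classified(-2.6, 0.005)
        assert np.all(out.classes == CLASS_CODES["cold99"])

    def test_moderate_hotspot_is_hot95(self):
        out = self._classified(2.0, 0.02)
        assert np.all(out.classes == CLASS_CODES["hot95"])

    def test_planted_cluster_detected_as_hotspot(self):
        rng = np.random.default_rng(38)
        lon = np.concatenate([rng.normal(0.5, 0.03, 150), rng.uniform(0, 1, 50)])
        lat = np.concatenate([rng.normal(0.5, 0.03, 150), rng.uniform(0, 1, 50)])
        hg = count_grid(lon, lat, (0, 0, 1, 1), res_deg=0.05)
        out = classify(gi_star(hg))
        row, col, _ = point_to_cell(out.grid, 0.5, 0.5)
        assert out.classes[row, col] >= CLASS_CODES["hot95"]
        tally = class_tally(out)
        assert tally["hot95"] + tally["hot99"] >= 1
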
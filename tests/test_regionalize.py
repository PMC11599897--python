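"""Permutation scoring, region clustering and spatial synchrony."""

import numpy as np
import pytest

from paleocycles import (CellScore, GridSeries, RadiocarbonDate,
                         RegionPartition, cluster_regions,
                         cluster_weighting_factor, great_circle_km,
                         local_deviation_scores, regional_mean_rgr,
                         spatial_autocorrelation, synchrony_vs_extent)
from paleocycles.regionalize import slice_windows


class TestSliceWindows:
    def test_default_tiling(self):
        w = slice_windows()
        assert w[0] == (9800.0, 9400.0)
        assert w[-1] == (3400.0, 3000.0)
        assert len(w) == 17
        assert all(a - b == 400.0 for a, b in w)


class TestGreatCircle:
    def test_zero_distance(self):
        assert great_circle_km(10, 50, 10, 50) == 0.0

    def test_one_degree_longitude_at_equator(self):
        # 2*pi*6371/360 = 111.19 km
        assert great_circle_km(0, 0, 1, 0) == pytest.approx(111.19, abs=0.05)

    def test_symmetry(self):
        assert great_circle_km(5, 40, 25, 60) == \
            pytest.approx(great_circle_km(25, 60, 5, 40))

    def test_quarter_circumference(self):
        assert great_circle_km(0, 0, 0, 90) == \
            pytest.approx(np.pi * 6371.0 / 2.0, rel=1e-9)


class TestWeightingFactor:
    def test_value_at_n_star(self):
        assert cluster_weighting_factor(120.0) == pytest.approx(2.0)

    def test_limits(self):
        assert cluster_weighting_factor(1e6) == pytest.approx(1.0)
        assert cluster_weighting_factor(0.0) == pytest.approx(1.0 + np.e ** 10)

    def test_monotone_decreasing(self):
        ns = np.linspace(0, 600, 100)
        f = [cluster_weighting_factor(n) for n in ns]
        assert np.all(np.diff(f) <= 0)          # flat only once underflowed
        assert np.all(np.diff(f[:40]) < 0)


def dates_for_cell(rng, ages, cx, cy, n_sites=8, sd=25.0, cell_deg=4.0):
    """Dates in 4-degree cell (cx, cy) spread over n_sites sites."""
    out = []
    for i, a in enumerate(ages):
        s = i % n_sites
        lon = (cx + 0.15 + 0.7 * (s % 4) / 4) * cell_deg
        lat = (cy + 0.15 + 0.7 * (s // 4) / 2) * cell_deg
        out.append(RadiocarbonDate(lab_id=f"c{cx}_{cy}_{i}",
                                   c14_age=float(a), c14_sd=sd,
                                   lon=lon, lat=lat,
                                   site_id=f"site{cx}_{cy}_{s}"))
    return out


class TestLocalDeviationScores:
    SLICE = (6400.0, 6000.0)
    CELLS = [(2, 12), (3, 12), (2, 13), (3, 13)]   # 4 adjacent 4-deg cells

    def _uniform_dates(self, rng, per_cell=60):
        dates = []
        for cx, cy in self.CELLS:
            ages = rng.uniform(5600, 6800, per_cell)
            dates += dates_for_cell(rng, ages, cx, cy)
        return dates

    def test_homogeneous_null_no_significant_cells(self, identity_curve):
        rng = np.random.default_rng(101)
        dates = self._uniform_dates(rng)
        scores = local_deviation_scores(dates, identity_curve, self.SLICE,
                                        n_perm=199, seed=7)
        assert len(scores) == 4
        assert all(s.score == 0.0 for s in scores)
        assert all(0.0 < s.p <= 1.0 and 0.0 < s.q <= 1.0 for s in scores)

    def test_injected_growth_cell_detected(self, identity_curve):
        rng = np.random.default_rng(202)
        dates = []
        for cx, cy in self.CELLS[1:]:
            dates += dates_for_cell(rng, rng.uniform(5600, 6800, 150), cx, cy)
        # hot cell: date density grows exponentially (0.004 per a) towards
        # younger ages, so its slice growth exceeds the continental rate
        hot = self.CELLS[0]
        u = rng.uniform(size=500)
        growth, span = 0.004, 1200.0
        offs = np.log(1 + u * (np.exp(growth * span) - 1)) / growth
        dates += dates_for_cell(rng, 6800.0 - offs, *hot, n_sites=8)
        scores = local_deviation_scores(dates, identity_curve, self.SLICE,
                                        n_perm=199, seed=7)
        by_cell = {s.cell: s for s in scores}
        assert by_cell[hot].score > 0
        assert by_cell[hot].p < 0.05 and by_cell[hot].q < 0.05
        assert by_cell[hot].deviation > 0
        others_sig = [s for s in scores if s.cell != hot and s.score > 0]
        assert len(others_sig) == 0

    def test_sparse_cells_excluded(self, identity_curve):
        rng = np.random.default_rng(303)
        dates = self._uniform_dates(rng, per_cell=40)
        dates += dates_for_cell(rng, rng.uniform(5800, 6600, 5), 9, 9)
        scores = local_deviation_scores(dates, identity_curve, self.SLICE,
                                        n_perm=49, seed=1,
                                        min_cell_dates=10)
        assert (9, 9) not in {s.cell for s in scores}
        assert len(scores) == 4

    def test_single_cell_raises(self, identity_curve):
        rng = np.random.default_rng(404)
        dates = dates_for_cell(rng, rng.uniform(5800, 6600, 40), 2, 12)
        with pytest.raises(ValueError):
            local_deviation_scores(dates, identity_curve, self.SLICE,
                                   n_perm=49, seed=1)


WEST_CELLS = [(cx, cy) for cx in (0, 1, 2, 3) for cy in (10, 11, 12)]
EAST_CELLS = [(cx, cy) for cx in (7, 8, 9, 10) for cy in (10, 11, 12)]


def fabricated_scores(west_score=1.9, east_score=-1.9, n_dates=10):
    """Two spatial blobs of 12 4-degree cells with opposite signed scores."""
    out = []
    for cells, sc in ((WEST_CELLS, west_score), (EAST_CELLS, east_score)):
        for cx, cy in cells:
            out.append(CellScore(cell=(cx, cy), lon=(cx + 0.5) * 4,
                                 lat=(cy + 0.5) * 4, n_dates=n_dates,
                                 deviation=sc, p=0.01, q=0.02, score=sc))
    return out


class TestClusterRegions:
    def test_two_blob_recovery(self):
        # 10 dates per cell: any split beyond the two blobs drops a
        # cluster far below N* = 120 and the penalty rejects it
        part = cluster_regions(fabricated_scores(), (6400, 6000), seed=0)
        assert part.k == 2
        labels = {}
        for lab, cells in part.region_cells.items():
            for c in cells:
                labels[c] = lab
        west = {labels[c] for c in WEST_CELLS}
        east = {labels[c] for c in EAST_CELLS}
        assert len(west) == 1 and len(east) == 1 and west != east

    def test_penalty_controls_cluster_count(self):
        # abundant dates remove the size constraint and finer partitions
        # win on within-cluster scatter alone
        rich = cluster_regions(fabricated_scores(n_dates=500),
                               (6400, 6000), seed=0)
        poor = cluster_regions(fabricated_scores(n_dates=10),
                               (6400, 6000), seed=0)
        assert poor.k == 2
        assert rich.k > poor.k

    def test_fine_grid_projection_containment(self):
        part = cluster_regions(fabricated_scores(), (6400, 6000), seed=0)
        # each 4-deg cell maps to 40x40 cells at 0.1 deg
        assert len(part.cell_assignment) == 24 * 40 * 40
        labels = {c: lab for lab, cells in part.region_cells.items()
                  for c in cells}
        for (fx, fy), lab in part.cell_assignment.items():
            assert labels[(fx // 40, fy // 40)] == lab

    def test_bookkeeping(self):
        part = cluster_regions(fabricated_scores(n_dates=100),
                               (6400, 6000), seed=0)
        assert sum(part.region_dates.values()) == 24 * 100
        assert part.n_min == min(part.region_dates.values())
        assert all(a > 0 for a in part.region_area.values())

    def test_too_few_cells_raise(self):
        with pytest.raises(ValueError):
            cluster_regions(fabricated_scores()[:1], (6400, 6000))


def simple_partition(region_cells, cell_deg=4.0):
    from paleocycles.calibration import _cell_area_km2
    area = {lab: sum(_cell_area_km2(c, cell_deg) for c in cells)
            for lab, cells in region_cells.items()}
    return RegionPartition(slice_window=(9800.0, 3000.0),
                           cell_assignment={}, region_cells=region_cells,
                           region_dates={lab: 100 for lab in region_cells},
                           region_area=area, k=len(region_cells),
                           n_min=100, weighted_withinss=0.0)


class TestRegionalMean:
    def test_area_weighted_average(self, identity_curve, rng):
        part = simple_partition({0: [(2, 12)], 1: [(3, 12)]})
        dates = dates_for_cell(rng, rng.uniform(4500, 7500, 80), 2, 12)
        dates += dates_for_cell(rng, rng.uniform(4500, 7500, 80), 3, 12)
        regional, cont = regional_mean_rgr(part, dates, identity_curve,
                                           window=(8000, 4000))
        assert set(regional) == {0, 1}
        a0, a1 = part.region_area[0], part.region_area[1]
        expect = (a0 * regional[0].values + a1 * regional[1].values) / (a0 + a1)
        both = np.isfinite(regional[0].values) & np.isfinite(regional[1].values)
        np.testing.assert_allclose(cont.values[both], expect[both])

    def test_single_region_nan_skipped(self, identity_curve, rng):
        # where only one region is defined the average equals that region
        part = simple_partition({0: [(2, 12)], 1: [(3, 12)]})
        dates = dates_for_cell(rng, rng.uniform(4500, 7500, 80), 2, 12)
        dates += dates_for_cell(rng, rng.uniform(6000, 7500, 80), 3, 12)
        regional, cont = regional_mean_rgr(part, dates, identity_curve,
                                           window=(8000, 4000))
        only0 = np.isfinite(regional[0].values) & ~np.isfinite(regional[1].values)
        if only0.any():
            np.testing.assert_allclose(cont.values[only0],
                                       regional[0].values[only0])

    def test_dates_outside_partition_raise(self, identity_curve, rng):
        part = simple_partition({0: [(20, 20)]})
        dates = dates_for_cell(rng, rng.uniform(4500, 7500, 40), 2, 12)
        with pytest.raises(ValueError):
            regional_mean_rgr(part, dates, identity_curve, window=(8000, 4000))


class TestSpatialStructure:
    @staticmethod
    def _regional_set(rng, n=120):
        # regions 0,1 adjacent and identical; region 2 far and independent
        common = rng.standard_normal(n)
        series = {
            0: GridSeries(14900, 100, common + 0.1 * rng.standard_normal(n)),
            1: GridSeries(14900, 100, common + 0.1 * rng.standard_normal(n)),
            2: GridSeries(14900, 100, rng.standard_normal(n)),
        }
        part = simple_partition({0: [(2, 12)], 1: [(3, 12)], 2: [(12, 12)]})
        return series, part

    def test_near_pairs_more_correlated(self, rng):
        series, part = self._regional_set(rng)
        centres, mean_r, cnts = spatial_autocorrelation(series, part,
                                                        bin_km=500.0)
        near = mean_r[cnts > 0][0]           # first populated bin: pair (0,1)
        far = np.nanmean(mean_r[centres > 2000][
            cnts[centres > 2000] > 0])
        assert near > 0.9
        assert near > far + 0.5

    def test_pair_counts(self, rng):
        series, part = self._regional_set(rng)
        _, _, cnts = spatial_autocorrelation(series, part)
        assert cnts.sum() == 3               # all unordered pairs binned

    def test_too_few_regions_raise(self, rng):
        series, part = self._regional_set(rng)
        del series[2]
        with pytest.raises(ValueError):
            spatial_autocorrelation(series, part)


class TestSynchronyVsExtent:
    def test_windows_grow_and_empty_skipped(self, rng):
        common = rng.standard_normal(120)
        series = {
            0: GridSeries(14900, 100, common + 0.2 * rng.standard_normal(120)),
            1: GridSeries(14900, 100, common + 0.2 * rng.standard_normal(120)),
        }
        part = simple_partition({0: [(2, 12)], 1: [(3, 12)]})
        forcing = GridSeries(14900, 100, rng.standard_normal(120))
        windows = [(8.0, 12.0, 48.0, 52.0),     # region 0 only
                   (8.0, 16.0, 48.0, 52.0),     # both regions
                   (60.0, 64.0, 0.0, 4.0)]      # empty, skipped
        out = synchrony_vs_extent(series, part, forcing, windows)
        assert len(out) == 2
        assert out[0]["n_regions"] == 1 and out[1]["n_regions"] == 2
        assert out[1]["area_km2"] > out[0]["area_km2"]
        for row in out:
            assert 0.0 <= row["overlap"] <= 100.0

    def test_self_forcing_full_overlap(self, rng):
        v = rng.standard_normal(120)
        series = {0: GridSeries(14900, 100, v),
                  1: GridSeries(14900, 100, v)}
        part = simple_partition({0: [(2, 12)], 1: [(3, 12)]})
        forcing = GridSeries(14900, 100, v)
        out = synchrony_vs_extent(series, part, forcing,
                                  [(0.0, 20.0, 40.0, 60.0)])
        assert out[0]["overlap"] == pytest.approx(100.0, abs=1e-9)
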
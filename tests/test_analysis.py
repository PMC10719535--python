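"""Reduction maps, intensity classes, distance classes and series reports."""

import numpy as np
import pytest
from shapely.geometry import LineString

import alleyshade as A
from alleyshade.analysis import (
    DISTANCE_CLASSES,
    INTENSITY_LABELS,
    distance_masks,
    field_mask,
    intensity_table,
    reduction_map,
    series_report,
    strip_mask,
)
from alleyshade.shading import SimulationArchive
from alleyshade.trees import RowLayout

SHAPE = (20, 30)


def _uniform(v):
    return np.full(SHAPE, float(v))


class TestReductionMap:
    def test_equal_layers_give_zero_reduction(self):
        r = reduction_map(_uniform(5.0), _uniform(5.0))
        assert np.allclose(r.values[r.valid], 0.0)

    def test_ninety_percent_scenario_gives_ten_percent(self):
        r = reduction_map(0.9 * _uniform(5.0), _uniform(5.0))
        assert np.allclose(r.values[r.valid], 10.0)

    def test_full_occlusion_gives_hundred_percent(self):
        scn = _uniform(5.0)
        scn[3, 3] = 0.0
        r = reduction_map(scn, _uniform(5.0))
        assert r.values[3, 3] == pytest.approx(100.0)

    def test_strip_and_field_masks_invalidate_cells(self):
        strip = np.zeros(SHAPE, bool)
        strip[0, :] = True
        field = np.ones(SHAPE, bool)
        field[:, 0] = False
        r = reduction_map(_uniform(4.0), _uniform(5.0), strip=strip, field=field)
        assert not r.valid[0, 5] and not r.valid[5, 0]
        assert np.isnan(r.values[0, 5])

    def test_zero_baseline_flagged_with_warning(self):
        base = _uniform(5.0)
        base[2, 2] = 0.0
        with pytest.warns(UserWarning, match="non-positive baseline"):
            r = reduction_map(_uniform(4.0), base)
        assert not r.valid[2, 2]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            reduction_map(_uniform(1.0), np.ones((3, 3)))


class TestIntensityTable:
    def test_uniform_fifteen_percent_lands_in_ten_twenty_bin(self):
        r = reduction_map(0.85 * _uniform(10.0), _uniform(10.0))
        table = intensity_table(r)
        assert table["10-20%"] == pytest.approx(100.0)
        assert table.drop("10-20%").sum() == pytest.approx(0.0)

    def test_half_one_percent_half_twentyfive(self):
        base = _uniform(10.0)
        scn = base.copy()
        scn[:10, :] *= 0.99
        scn[10:, :] *= 0.75
        table = intensity_table(reduction_map(scn, base))
        assert table["<2%"] == pytest.approx(50.0)
        assert table["20-30%"] == pytest.approx(50.0)

    def test_random_map_matches_loop_histogram(self):
        rng = np.random.default_rng(3)
        base = _uniform(10.0)
        scn = base * (1.0 - rng.uniform(0.0, 0.45, SHAPE))
        r = reduction_map(scn, base)
        table = intensity_table(r)
        edges = [(0.0, 2.0), (2.0, 5.0), (5.0, 10.0), (10.0, 20.0), (20.0, 30.0), (30.0, 1e9)]
        vals = r.values[r.valid]
        for label, (lo, hi) in zip(INTENSITY_LABELS, edges):
            manual = sum(1 for v in vals if lo <= v < hi) if lo else sum(1 for v in vals if v < hi)
            assert table[label] == pytest.approx(100.0 * manual / vals.size)

    def test_shares_always_sum_to_hundred(self):
        rng = np.random.default_rng(11)
        base = _uniform(10.0)
        scn = base * (1.0 - rng.uniform(-0.01, 0.6, SHAPE))
        table = intensity_table(reduction_map(scn, base))
        assert table.sum() == pytest.approx(100.0, abs=0.01)

    def test_empty_mask_rejected(self):
        r = reduction_map(_uniform(1.0), _uniform(1.0), field=np.zeros(SHAPE, bool))
        with pytest.raises(ValueError, match="empty"):
            intensity_table(r)


def _ns_layout(x=100.0, grid_extent=200.0):
    line = LineString([(x, 0.0), (x, grid_extent)])
    return RowLayout([], [line], line.length, orientation_deg=0.0, row_width=1.0)


class TestDistanceMasks:
    def test_cell_two_metres_east_of_ns_row(self):
        grid = A.synthetic_dem("flat", 40, 200, 1.0)
        masks = distance_masks(_ns_layout(x=100.0, grid_extent=40.0), grid)
        r, c = 20, 102  # cell centre x=102.5 -> 2.5 m east
        assert masks[("E", (0.5, 3.0))][r, c]
        assert not masks[("W", (0.5, 3.0))][r, c]

    def test_sixteen_metres_belongs_to_no_class(self):
        grid = A.synthetic_dem("flat", 40, 200, 1.0)
        masks = distance_masks(_ns_layout(x=100.0, grid_extent=40.0), grid)
        col = 116  # centre 116.5 -> 16.5 m east
        assert not any(m[:, col].any() for m in masks.values())

    def test_nearest_row_wins_between_two_rows(self):
        grid = A.synthetic_dem("flat", 40, 200, 1.0)
        la = LineString([(100.0, 0.0), (100.0, 40.0)])
        lb = LineString([(132.0, 0.0), (132.0, 40.0)])
        layout = RowLayout([], [la, lb], 80.0, orientation_deg=0.0, row_width=1.0)
        masks = distance_masks(layout, grid)
        # centre x=114.5: 14.5 m east of row A, 17.5 m west of row B
        assert masks[("E", (12.0, 15.0))][20, 114]
        assert not masks[("W", (12.0, 15.0))][20, 114]

    def test_masks_are_pairwise_disjoint(self):
        grid = A.synthetic_dem("flat", 40, 200, 1.0)
        masks = list(distance_masks(_ns_layout(x=100.0, grid_extent=40.0), grid).values())
        total = sum(m.astype(int) for m in masks)
        assert total.max() <= 1

    def test_we_rows_labelled_north_south(self):
        grid = A.synthetic_dem("flat", 60, 60, 1.0)
        line = LineString([(0.0, 30.0), (60.0, 30.0)])
        layout = RowLayout([], [line], 60.0, orientation_deg=90.0, row_width=1.0)
        masks = distance_masks(layout, grid)
        sides = {side for side, _ in masks}
        assert sides == {"N", "S"}

    def test_empty_layout_rejected(self):
        grid = A.synthetic_dem("flat", 10, 10, 1.0)
        with pytest.raises(ValueError, match="centrelines"):
            distance_masks(RowLayout([], [], 0.0, 0.0, 1.0), grid)


class TestSeriesReport:
    def _archive(self, grid, scn, base):
        archive = SimulationArchive(grid=grid, interval_minutes=60)
        archive.monthly[(2021, 6)] = {"scenario": scn, "baseline": base}
        return archive

    def test_identical_layers_give_all_zero_series(self):
        grid = A.synthetic_dem("flat", 40, 120, 1.0)
        base = np.full(grid.elevation.shape, 100.0)
        report = series_report(self._archive(grid, base.copy(), base), _ns_layout(60.0, 40.0))
        assert np.allclose(report["mean_reduction_pct"].to_numpy(), 0.0)

    def test_attenuated_east_band_isolated_in_its_series(self):
        """Only the 0.5-3 m east band attenuated by 20%: its series reads 20,
        every other class 0."""
        grid = A.synthetic_dem("flat", 40, 120, 1.0)
        layout = _ns_layout(60.0, 40.0)
        base = np.full(grid.elevation.shape, 100.0)
        scn = base.copy()
        band = distance_masks(layout, grid)[("E", (0.5, 3.0))]
        scn[band] *= 0.8
        report = series_report(self._archive(grid, scn, base), layout)
        classes = report[report["side"] != "field"]
        hit = classes[(classes["side"] == "E") & (classes["dist_class"] == "0.5-3 m")]
        assert hit["mean_reduction_pct"].iloc[0] == pytest.approx(20.0)
        rest = classes.drop(hit.index)
        assert np.allclose(rest["mean_reduction_pct"].dropna().to_numpy(), 0.0)

    def test_field_summary_energy_bookkeeping(self):
        grid = A.synthetic_dem("flat", 40, 120, 1.0)
        base = np.full(grid.elevation.shape, 100.0)
        report = series_report(self._archive(grid, base.copy(), base), _ns_layout(60.0, 40.0))
        row = report[report["side"] == "field"].iloc[0]
        assert row["mean_scenario_kwh_m2"] == pytest.approx(100.0)
        # strip cells removed from the energy total as well
        n_valid = int(
            (~strip_mask(_ns_layout(60.0, 40.0), grid) & grid.mask).sum()
        )
        assert row["total_scenario_gwh"] == pytest.approx(100.0 * n_valid * 1.0 / 1e6)

    def test_end_to_end_recompute_matches_stored_rasters(self, single_row_run):
        """Series for a real one-row run equal a from-scratch recomputation."""
        dem, layout, archive = single_row_run
        report = series_report(archive, layout)
        scn = archive.annual_map(2021, "scenario")
        base = archive.annual_map(2021, "baseline")
        strip = strip_mask(layout, dem)
        rmap = reduction_map(scn, base, strip=strip, field=dem.mask, period="2021")
        masks = distance_masks(layout, dem)
        classes = report[report["side"] != "field"]
        for _, row in classes.iterrows():
            lo = float(row["dist_class"].split("-")[0])
            hi = float(row["dist_class"].split("-")[1].removesuffix(" m"))
            sel = masks[(row["side"], (lo, hi))] & rmap.valid
            if sel.any():
                assert row["mean_reduction_pct"] == pytest.approx(float(np.nanmean(rmap.values[sel])))
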
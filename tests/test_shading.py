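"""Ray-sphere shadow casting and simulation-loop tests."""

import math
from datetime import date

import numpy as np
import pytest

import alleyshade as A
from alleyshade.radiation import IrradianceMap, RadiationParams
from alleyshade.shading import (
    Scenario,
    load_archive,
    ray_sphere_intersect,
    save_archive,
    shade_step,
    shadow_mask,
    simulate,
)
from alleyshade.solar import Moment, SunPosition
from alleyshade.trees import CrownSphere, TreePosition
from conftest import brute_force_shadow_mask

from datetime import datetime, timezone


def _moment(alt, az=180.0):
    return Moment(datetime(2021, 6, 1, 12, tzinfo=timezone.utc), 0, SunPosition(az, alt))


class TestRaySphere:
    SPHERE_AHEAD = CrownSphere(0.0, 0.0, 10.0, 3.0)

    def test_ray_through_centre_hits(self):
        assert ray_sphere_intersect((0, 0, 0), (0, 0, 1), self.SPHERE_AHEAD)

    def test_lateral_miss(self):
        assert not ray_sphere_intersect((0, 0, 0), (0, 0, 1), CrownSphere(10.0, 0.0, 10.0, 3.0))

    def test_sphere_behind_origin_misses(self):
        assert not ray_sphere_intersect((0, 0, 0), (0, 0, 1), CrownSphere(0.0, 0.0, -10.0, 3.0))

    def test_grazing_tangency_counts_as_hit(self):
        assert ray_sphere_intersect((0, 0, 0), (0, 0, 1), CrownSphere(3.0, 0.0, 10.0, 3.0))

    def test_origin_inside_sphere_hits(self):
        assert ray_sphere_intersect((0, 0, 10), (0, 0, 1), self.SPHERE_AHEAD)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError, match="non-zero"):
            ray_sphere_intersect((0, 0, 0), (0, 0, 0), self.SPHERE_AHEAD)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            ray_sphere_intersect((0, 0, 0), (0, 0, 2.0), self.SPHERE_AHEAD)


class TestShadowMask:
    def test_shadow_ellipse_area_oracle(self):
        """Opaque sphere r=3 at 10 m, sun at 45 deg: shadow covers ~pi r^2/sin(a)
        one-metre cells."""
        dem = A.synthetic_dem("flat", 100, 100, 1.0)
        sphere = CrownSphere(50.0, 30.0, 10.0, 3.0)
        mask = shadow_mask(dem, [sphere], sun=SunPosition(180.0, 45.0))
        expected = math.pi * 9.0 / math.sin(math.radians(45.0))
        assert mask.sum() == pytest.approx(expected, rel=0.10)

    def test_shadow_centroid_displaced_sunward_distance(self):
        """Sun due south at 45 deg: centroid lies due north at ~centre height."""
        dem = A.synthetic_dem("flat", 100, 100, 1.0)
        sphere = CrownSphere(50.0, 30.0, 10.0, 3.0)
        mask = shadow_mask(dem, [sphere], sun=SunPosition(180.0, 45.0))
        X, Y = dem.cell_centers()
        assert X[mask].mean() == pytest.approx(50.0, abs=0.5)
        assert Y[mask].mean() - 30.0 == pytest.approx(10.0, rel=0.10)

    @pytest.mark.parametrize("alt,az", [(45.0, 180.0), (10.0, 90.0), (70.0, 300.0), (30.0, 10.0)])
    def test_exact_equality_with_brute_force(self, alt, az):
        """Windowed accelerated mask equals the all-pairs quadratic reference."""
        rng = np.random.default_rng(42)
        dem = A.synthetic_dem("gaussian_hill", 60, 60, 1.0, amplitude=5.0, sigma=12.0)
        spheres = [
            CrownSphere(rng.uniform(10, 50), rng.uniform(10, 50), rng.uniform(6, 18), rng.uniform(1, 4))
            for _ in range(5)
        ]
        sun = SunPosition(az, alt)
        assert np.array_equal(shadow_mask(dem, spheres, sun=sun), brute_force_shadow_mask(dem, spheres, sun))

    def test_nodata_cells_never_shaded(self):
        z = np.zeros((20, 20))
        z[5, 5] = -9999.0
        dem = A.DEMGrid(z, 0, 0, 1.0)
        mask = shadow_mask(dem, [CrownSphere(5.5, 14.5, 5.0, 4.0)], sun=SunPosition(180.0, 45.0))
        assert not mask[5, 5]

    def test_sun_below_horizon_no_shadow(self):
        dem = A.synthetic_dem("flat", 10, 10, 1.0)
        mask = shadow_mask(dem, [CrownSphere(5, 5, 5, 3)], sun=SunPosition(0.0, -5.0))
        assert not mask.any()


class TestShadeStep:
    def _uniform_pisr(self, dem, value=400.0):
        return IrradianceMap(np.full(dem.elevation.shape, value), dem)

    def test_no_trees_is_identity(self, flat_dem):
        pisr = self._uniform_pisr(flat_dem)
        res = shade_step(_moment(45.0), flat_dem, [], 0.25, pisr)
        assert np.array_equal(res.shaded_pisr.values, pisr.values)
        assert not res.shadow_mask.any()

    def test_transmittance_multiplier_is_exact(self, flat_dem):
        pisr = self._uniform_pisr(flat_dem, 400.0)
        sphere = CrownSphere(20.0, 15.0, 10.0, 3.0)
        res = shade_step(_moment(45.0), flat_dem, [sphere], 0.25, pisr)
        assert res.shadow_mask.any()
        assert np.all(res.shaded_pisr.values[res.shadow_mask] == 100.0)
        assert np.all(res.shaded_pisr.values[~res.shadow_mask] == 400.0)

    def test_shaded_never_exceeds_unshaded(self, flat_dem):
        pisr = self._uniform_pisr(flat_dem)
        res = shade_step(_moment(30.0), flat_dem, [CrownSphere(20, 20, 8, 3)], 0.5, pisr)
        assert np.all(res.shaded_pisr.values <= pisr.values)
        equal = res.shaded_pisr.values == pisr.values
        assert np.array_equal(equal, ~res.shadow_mask)

    def test_sun_down_returns_input_unmodified(self, flat_dem):
        pisr = self._uniform_pisr(flat_dem)
        res = shade_step(_moment(-3.0), flat_dem, [CrownSphere(20, 20, 8, 3)], 0.25, pisr)
        assert res.shaded_pisr is pisr

    def test_overlap_attenuates_once_by_default(self, flat_dem):
        pisr = self._uniform_pisr(flat_dem, 400.0)
        twin = [CrownSphere(20.0, 15.0, 10.0, 3.0), CrownSphere(20.0, 15.0, 10.5, 3.0)]
        res = shade_step(_moment(45.0), flat_dem, twin, 0.25, pisr)
        assert np.all(res.shaded_pisr.values[res.shadow_mask] == 100.0)

    def test_overlap_stacking_behind_flag(self, flat_dem):
        pisr = self._uniform_pisr(flat_dem, 400.0)
        twin = [CrownSphere(20.0, 15.0, 10.0, 3.0), CrownSphere(20.0, 15.0, 10.0, 3.0)]
        res = shade_step(_moment(45.0), flat_dem, twin, 0.25, pisr, stack_overlaps=True)
        assert np.any(res.shaded_pisr.values == 400.0 * 0.25**2)

    def test_grid_mismatch_rejected(self, flat_dem):
        other = A.synthetic_dem("flat", 10, 10, 1.0)
        with pytest.raises(ValueError, match="grid"):
            shade_step(_moment(45.0), flat_dem, [], 0.25, self._uniform_pisr(other))


class TestSimulate:
    def _scenario(self, site, trees, years=1, interval=240):
        dem = A.synthetic_dem("flat", 12, 12, 4.0, base=54.0)
        return Scenario(
            site=site,
            dem=dem,
            trees=trees,
            pattern=A.TreeGrowthPattern(),
            planting_date=date(2001, 1, 1),
            start=date(2021, 1, 1),
            years=years,
            interval_minutes=interval,
        )

    def test_zero_trees_scenario_equals_baseline_bitwise(self, site):
        archive = simulate(self._scenario(site, []))
        for maps in archive.monthly.values():
            assert np.array_equal(maps["scenario"], maps["baseline"], equal_nan=True)

    def test_repeat_run_is_deterministic(self, site):
        trees = [TreePosition(24.0, 24.0)]
        a = simulate(self._scenario(site, trees))
        b = simulate(self._scenario(site, trees))
        assert a.monthly.keys() == b.monthly.keys()
        for key in a.monthly:
            for layer in ("scenario", "baseline"):
                assert np.array_equal(a.monthly[key][layer], b.monthly[key][layer], equal_nan=True)

    def test_shaded_annual_integral_below_baseline(self, site):
        archive = simulate(self._scenario(site, [TreePosition(24.0, 24.0)]))
        scn = archive.annual_map(2021, "scenario")
        base = archive.annual_map(2021, "baseline")
        assert np.all(scn <= base + 1e-12)
        assert np.nansum(scn) < np.nansum(base)

    def test_halving_interval_converges_within_one_percent(self, site):
        """Annual integral on a flat no-tree run moves <1% from 20- to 40-min steps."""
        a = simulate(self._scenario(site, [], interval=20)).annual_map(2021, "baseline")
        b = simulate(self._scenario(site, [], interval=40)).annual_map(2021, "baseline")
        assert np.nanmean(b) == pytest.approx(np.nanmean(a), rel=0.01)

    def test_archive_round_trip(self, site, tmp_path):
        archive = simulate(self._scenario(site, [TreePosition(24.0, 24.0)]))
        save_archive(archive, tmp_path / "run", manifest={"config_hash": "abc"})
        back = load_archive(tmp_path / "run")
        assert back.monthly.keys() == archive.monthly.keys()
        for key in archive.monthly:
            for layer in ("scenario", "baseline"):
                assert np.allclose(
                    back.monthly[key][layer], archive.monthly[key][layer], equal_nan=True, atol=1e-12
                )
        assert back.moment_counts == archive.moment_counts
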
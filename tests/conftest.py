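"""Shared fixtures: synthetic surfaces, layouts, and session-scoped simulations."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest
from shapely.geometry import LineString, Polygon

import alleyshade as A
from alleyshade.fixtures import FIXTURE_SITE, synthetic_field_dem, synthetic_field_polygon
from alleyshade.shading import ORIGIN_LIFT, Scenario, simulate
from alleyshade.trees import RowLayout, TreePosition


def brute_force_shadow_mask(dem, spheres, sun):
    """Independent all-pairs quadratic-solve shadow reference (pure loops)."""
    v = A.sun_vector(sun)
    d = np.array([v.e, v.n, v.u])
    X, Y = dem.cell_centers()
    Z = dem.elevation + ORIGIN_LIFT
    out = np.zeros(dem.elevation.shape, dtype=bool)
    for r in range(dem.n_rows):
        for c in range(dem.n_cols):
            if not dem.mask[r, c]:
                continue
            o = np.array([X[r, c], Y[r, c], Z[r, c]])
            for s in spheres:
                oc = o - np.array([s.x, s.y, s.z])
                b = float(oc @ d)
                c2 = float(oc @ oc) - s.radius**2
                disc = b * b - c2
                if disc >= 0.0 and (-b + np.sqrt(disc)) > 1e-6:
                    out[r, c] = True
                    break
    return out


@pytest.fixture(scope="session")
def site():
    return FIXTURE_SITE


@pytest.fixture
def flat_dem():
    return A.synthetic_dem("flat", 40, 40, 1.0, base=0.0)


@pytest.fixture(scope="session")
def field_polygon():
    return synthetic_field_polygon()


@pytest.fixture(scope="session")
def coarse_field_dem():
    return A.resample(synthetic_field_dem(1.0), 4)


def _field_scenario(orientation_deg, row_spacing, dem, years=1, age_at_start=59):
    layout = A.layout_rows(synthetic_field_polygon(), orientation_deg, row_spacing, 12.0, 1.0, 20.0)
    start = date(2021, 1, 1)
    planting = date(start.year - age_at_start, start.month, start.day)
    scenario = Scenario(
        site=FIXTURE_SITE,
        dem=dem,
        trees=layout.positions,
        pattern=A.TreeGrowthPattern(),
        planting_date=planting,
        start=start,
        years=years,
        interval_minutes=60,
    )
    return layout, scenario


@pytest.fixture(scope="session")
def ns_year60(coarse_field_dem):
    """North-south design (32 m rows) simulated through year 60 of growth."""
    layout, scenario = _field_scenario(0.0, 32.0, coarse_field_dem)
    return layout, simulate(scenario)


@pytest.fixture(scope="session")
def we_year60(coarse_field_dem):
    """West-east design (36 m rows) simulated through year 60 of growth."""
    layout, scenario = _field_scenario(90.0, 36.0, coarse_field_dem)
    return layout, simulate(scenario)


@pytest.fixture(scope="session")
def single_row_run():
    """One north-south tree row in the middle of a flat field, one year."""
    dem = A.synthetic_dem("flat", 50, 80, 4.0, base=54.0)  # 320 x 200 m
    x_mid = 160.0
    line = LineString([(x_mid, 20.0), (x_mid, 180.0)])
    positions = [TreePosition(x_mid, y) for y in np.arange(26.0, 180.0, 12.0)]
    layout = RowLayout(
        positions=positions,
        centrelines=[line],
        total_row_length=line.length,
        orientation_deg=0.0,
        row_width=1.0,
    )
    scenario = Scenario(
        site=FIXTURE_SITE,
        dem=dem,
        trees=positions,
        pattern=A.TreeGrowthPattern(),
        planting_date=date(1991, 1, 1),  # 30-year-old trees
        start=date(2021, 1, 1),
        years=1,
        interval_minutes=20,
    )
    return dem, layout, simulate(scenario)
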
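"""Deterministic synthetic study fixtures.

No field DEM or boundary polygon is deposited with the method this package
implements, so the fixtures emulate the described site: a gently sloped
6.4 ha rectangular field (320 m x 200 m) in northern Brandenburg at about
54 m elevation with roughly 7 m of total relief and a shallow depression in
the north, plus flat and tilted-plane control surfaces.  Two ready-made
scenario configs mirror the two published alley-cropping designs:
north-south rows at 32 m spacing and west-east rows at 36 m spacing, both
with 12 m tree spacing, 1 m row width and a 20 m field-edge buffer.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon, mapping

from .config import RunConfig, ScenarioLayout, Schedule
from .solar import Site
from .terrain import DEMGrid, synthetic_dem, write_dem

__all__ = ["synthetic_field_dem", "synthetic_field_polygon", "write_fixtures", "FIXTURE_SITE"]

FIELD_ORIGIN = (1000.0, 2000.0)
FIELD_SIZE = (320.0, 200.0)  # east-west, north-south extent, metres
FIXTURE_SITE = Site(latitude=52.9, longitude=12.8, utc_offset=1.0)


def synthetic_field_polygon() -> Polygon:
    """Rectangular 6.4 ha field boundary in metric map coordinates."""
    x0, y0 = FIELD_ORIGIN
    w, h = FIELD_SIZE
    return Polygon([(x0, y0), (x0 + w, y0), (x0 + w, y0 + h), (x0, y0 + h)])


def synthetic_field_dem(cell_size: float = 1.0) -> DEMGrid:
    """Gently sloped field surface: ~54 m mean elevation, ~7 m relief.

    A 1.8% west-falling plane with a Gaussian depression near the northern
    edge, mirroring the qualitative description of the study site.
    """
    x0, y0 = FIELD_ORIGIN
    w, h = FIELD_SIZE
    n_cols = int(round(w / cell_size))
    n_rows = int(round(h / cell_size))
    grid = synthetic_dem(
        "plane",
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell_size,
        origin_x=x0,
        origin_y=y0,
        base=54.0,
        grade=0.018,
        downslope_azimuth_deg=270.0,
    )
    X, Y = grid.cell_centers()
    cx, cy = x0 + 0.3 * w, y0 + 0.85 * h  # depression in the north
    r2 = (X - cx) ** 2 + (Y - cy) ** 2
    grid.elevation = grid.elevation - 1.5 * np.exp(-r2 / (2.0 * 35.0**2))
    return grid


def write_fixtures(out_dir: str | Path, cell_size: float = 1.0) -> dict[str, Path]:
    """Write the synthetic DEMs, field polygon and the two scenario configs.

    Output is deterministic: regenerating into the same directory is
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    dem = synthetic_field_dem(cell_size)
    paths["dem_field"] = out / "dem_field.asc"
    write_dem(dem, paths["dem_field"])

    flat = synthetic_dem(
        "flat",
        n_rows=dem.n_rows,
        n_cols=dem.n_cols,
        cell_size=cell_size,
        origin_x=FIELD_ORIGIN[0],
        origin_y=FIELD_ORIGIN[1],
        base=54.0,
    )
    paths["dem_flat"] = out / "dem_flat.asc"
    write_dem(flat, paths["dem_flat"])

    poly = synthetic_field_polygon()
    paths["field"] = out / "field.geojson"
    geojson = {"type": "Feature", "properties": {"name": "synthetic field"}, "geometry": mapping(poly)}
    paths["field"].write_text(json.dumps(geojson, indent=2, sort_keys=True) + "\n")

    common = dict(
        site=FIXTURE_SITE,
        schedule=Schedule(start=date(2021, 1, 1), years=1, interval_minutes=20),
        dem_path="dem_field.asc",
        field_path="field.geojson",
        planting_date=date(2021, 1, 1),
    )
    ns = RunConfig(
        layout=ScenarioLayout(orientation_deg=0.0, row_spacing=32.0, tree_spacing=12.0, row_width=1.0, buffer=20.0),
        output_dir="out_ns",
        **common,
    )
    we = RunConfig(
        layout=ScenarioLayout(orientation_deg=90.0, row_spacing=36.0, tree_spacing=12.0, row_width=1.0, buffer=20.0),
        output_dir="out_we",
        **common,
    )
    paths["config_ns"] = out / "scenario_ns.yaml"
    paths["config_we"] = out / "scenario_we.yaml"
    ns.to_yaml(paths["config_ns"])
    we.to_yaml(paths["config_we"])
    return paths
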
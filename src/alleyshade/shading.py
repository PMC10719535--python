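"""Shadow casting of crown spheres onto the terrain and the simulation loop.

For every daylight moment a ray is cast from each surface cell toward the
sun; a cell whose ray intersects any crown sphere keeps only the seasonal
crown transmittance of its clear-sky irradiance.  Overlapping crowns
attenuate once by default (boolean union); multiplicative stacking per
intersected crown is available behind a flag.

Ray origins are the cell-centre ground points lifted by 1 cm so rays never
graze their own sloped face.  The per-sphere candidate window (projected
shadow-footprint bounding box) is a pure acceleration device: results are
identical to the all-pairs quadratic test, which the test suite asserts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from datetime import date
from typing import Sequence

import numpy as np

from .radiation import IrradianceMap, RadiationParams, _components, pisr_values
from .solar import Moment, SunPosition, Site, generate_moments, sun_vector
from .terrain import DEMGrid, slope_aspect
from .trees import CrownSphere, TreeGrowthPattern, TreePosition, growth_state, tree_age_years

__all__ = ["ShadeResult", "ray_sphere_intersect", "shadow_mask", "shade_step", "simulate", "SimulationArchive"]

RAY_EPS = 1e-6  # m, guards self-intersection at the ray origin
ORIGIN_LIFT = 0.01  # m, cell-centre ray origins float this far above ground


@dataclass
class ShadeResult:
    """Shaded irradiance plus the shadow mask for one moment."""

    shaded_pisr: IrradianceMap
    shadow_mask: np.ndarray | None
    moment: Moment | None = None


def ray_sphere_intersect(origin, direction, sphere: CrownSphere, eps: float = RAY_EPS) -> bool:
    """True iff the half-line ``origin + t*direction`` (t > eps) meets the sphere.

    Tangency (zero discriminant) counts as a hit.  ``direction`` must be a
    unit vector.
    """
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0.0:
        raise ValueError("ray direction must be non-zero")
    if abs(norm - 1.0) > 1e-6:
        raise ValueError("ray direction must be a unit vector")
    o = np.asarray(origin, dtype=float)
    oc = o - np.array([sphere.x, sphere.y, sphere.z])
    b = float(np.dot(oc, d))
    c = float(np.dot(oc, oc)) - sphere.radius**2
    disc = b * b - c
    if disc < 0.0:
        return False
    t_far = -b + math.sqrt(disc)
    return t_far > eps


def _cell_origins(dem: DEMGrid):
    X, Y = dem.cell_centers()
    return X, Y, dem.elevation + ORIGIN_LIFT


def shadow_mask(
    dem: DEMGrid,
    spheres: Sequence[CrownSphere],
    sun: SunPosition | None = None,
    direction=None,
    count: bool = False,
) -> np.ndarray:
    """Boolean grid of cells whose sun ray intersects at least one crown sphere.

    With ``count=True`` returns the integer number of intersected spheres per
    cell instead.  Either a :class:`SunPosition` or an explicit unit ENU
    ``direction`` may be given.  Nodata cells are never shaded.
    """
    if direction is None:
        if sun is None:
            raise ValueError("either sun or direction is required")
        v = sun_vector(sun)
        direction = (v.e, v.n, v.u)
    de, dn, du = (float(c) for c in direction)
    out = np.zeros(dem.elevation.shape, dtype=(np.int32 if count else bool))
    if not spheres or du <= 0.0:
        return out
    X, Y, Z = _cell_origins(dem)
    zmin = float(np.nanmin(np.where(dem.mask, dem.elevation, np.nan)))
    zmax = float(np.nanmax(np.where(dem.mask, dem.elevation, np.nan)))
    cs = dem.cell_size
    xs = dem.x_centers()
    ys = dem.y_centers()  # descending
    sin_a = du  # direction is unit, so up-component = sin(altitude)
    for s in spheres:
        pad = s.radius / max(sin_a, 1.0 / 38.0) + cs
        # project the centre to the ground elevation range along -direction
        t_lo = max((s.z - zmax) / du, 0.0)
        t_hi = max((s.z - zmin) / du, 0.0)
        px = np.array([s.x - t_lo * de, s.x - t_hi * de])
        py = np.array([s.y - t_lo * dn, s.y - t_hi * dn])
        x0, x1 = px.min() - pad, px.max() + pad
        y0, y1 = py.min() - pad, py.max() + pad
        c0 = int(np.searchsorted(xs, x0, side="left"))
        c1 = int(np.searchsorted(xs, x1, side="right"))
        r0 = int(np.searchsorted(-ys, -y1, side="left"))
        r1 = int(np.searchsorted(-ys, -y0, side="right"))
        if c0 >= c1 or r0 >= r1:
            continue
        ocx = X[r0:r1, c0:c1] - s.x
        ocy = Y[r0:r1, c0:c1] - s.y
        ocz = Z[r0:r1, c0:c1] - s.z
        b = ocx * de + ocy * dn + ocz * du
        c2 = ocx * ocx + ocy * ocy + ocz * ocz - s.radius**2
        disc = b * b - c2
        hit = disc >= 0.0
        np.sqrt(np.where(hit, disc, 0.0), out=disc)
        hit &= (disc - b) > RAY_EPS
        if count:
            out[r0:r1, c0:c1] += hit
        else:
            out[r0:r1, c0:c1] |= hit
    out[~dem.mask] = 0
    return out


def terrain_occlusion_mask(dem: DEMGrid, sun: SunPosition, step: float | None = None) -> np.ndarray:
    """True where the terrain itself hides the sun from a cell.

    Rays are marched from each cell centre toward the sun, sampling the
    bilinear terrain surface every ``step`` metres (default: one cell) until
    the ray climbs above the DEM's maximum elevation.
    """
    v = sun_vector(sun)
    out = np.zeros(dem.elevation.shape, dtype=bool)
    if v.u <= 0.0:
        return out
    step = step or dem.cell_size
    X, Y, Z = _cell_origins(dem)
    zmax = float(np.nanmax(np.where(dem.mask, dem.elevation, np.nan)))
    horiz = math.hypot(v.e, v.n)
    if horiz == 0.0:
        return out
    t_exit = (zmax - dem.elevation.min()) / v.u + step
    t = step
    blocked = np.zeros_like(out)
    while t <= t_exit:
        px = X + t * v.e
        py = Y + t * v.n
        pz = Z + t * v.u
        inside = dem.contains(px, py)
        if not inside.any():
            break
        surf = dem.bilinear(px, py)
        blocked |= inside & (surf > pz)
        if (pz > zmax).all():
            break
        t += step
    blocked[~dem.mask] = False
    return blocked


def shade_step(
    moment: Moment,
    dem: DEMGrid,
    spheres: Sequence[CrownSphere],
    transmittance: float,
    pisr: IrradianceMap,
    stack_overlaps: bool = False,
    keep_mask: bool = True,
) -> ShadeResult:
    """Attenuate one moment's PISR map by tree-crown shadows.

    Shadowed cells keep ``pisr * transmittance`` (or ``transmittance**k`` for
    k intersected crowns when ``stack_overlaps`` is on); with the sun at or
    below the horizon the input map is returned unmodified.
    """
    if pisr.values.shape != dem.elevation.shape:
        raise ValueError("pisr grid does not match the DEM grid")
    if moment.sun is None:
        raise ValueError("moment lacks a computed SunPosition")
    if moment.sun.altitude_deg <= 0.0:
        return ShadeResult(shaded_pisr=pisr, shadow_mask=None, moment=moment)
    if stack_overlaps:
        k = shadow_mask(dem, spheres, sun=moment.sun, count=True)
        shaded = pisr.values * np.power(transmittance, k)
        mask = k > 0
    else:
        mask = shadow_mask(dem, spheres, sun=moment.sun)
        shaded = np.where(mask, pisr.values * transmittance, pisr.values)
    out = IrradianceMap(values=shaded, grid=pisr.grid, units=pisr.units, period=pisr.period)
    return ShadeResult(shaded_pisr=out, shadow_mask=(mask if keep_mask else None), moment=moment)


# ---------------------------------------------------------------------------
# Full simulation


@dataclass
class SimulationArchive:
    """Monthly integrated PISR maps, shaded scenario and tree-free baseline.

    Keys of ``monthly`` are ``(year, month)``; each value is a dict with
    ``scenario`` and ``baseline`` kWh m^-2 arrays.  ``moment_counts`` logs the
    number of daylight moments folded into each year.
    """

    grid: DEMGrid
    interval_minutes: float
    monthly: dict[tuple[int, int], dict[str, np.ndarray]] = dc_field(default_factory=dict)
    moment_counts: dict[int, int] = dc_field(default_factory=dict)

    def years(self) -> list[int]:
        return sorted({y for y, _ in self.monthly})

    def months(self, year: int) -> list[int]:
        return sorted(m for y, m in self.monthly if y == year)

    def monthly_map(self, year: int, month: int, layer: str) -> np.ndarray:
        return self.monthly[(year, month)][layer]

    def annual_map(self, year: int, layer: str) -> np.ndarray:
        months = self.months(year)
        if not months:
            raise KeyError(f"no data for year {year}")
        return sum(self.monthly[(year, m)][layer] for m in months)


def save_archive(archive: SimulationArchive, run_dir, manifest: dict | None = None) -> None:
    """Write an archive as `<run>/<year>/<month>_<layer>.asc` plus a manifest.

    Layout: one ESRI ASCII raster per (year, month, layer in
    {scenario, baseline}); a `manifest.json` records grid geometry, interval
    and any caller-supplied metadata (e.g. the config hash).  Saving after
    each simulated year gives a resumable checkpoint.
    """
    import json
    from pathlib import Path

    from .terrain import DEMGrid, write_dem

    run = Path(run_dir)
    run.mkdir(parents=True, exist_ok=True)
    g = archive.grid
    for (year, month), maps in sorted(archive.monthly.items()):
        ydir = run / str(year)
        ydir.mkdir(exist_ok=True)
        for layer, values in maps.items():
            out = np.where(np.isfinite(values), values, g.nodata)
            write_dem(
                DEMGrid(out, g.origin_x, g.origin_y, g.cell_size, g.nodata, g.crs_label),
                ydir / f"{month:02d}_{layer}.asc",
            )
    meta = {
        "interval_minutes": archive.interval_minutes,
        "moment_counts": {str(k): v for k, v in archive.moment_counts.items()},
        "units": "kWh/m^2",
    }
    meta.update(manifest or {})
    (run / "manifest.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def load_archive(run_dir) -> SimulationArchive:
    """Read an archive written by :func:`save_archive`."""
    import json
    from pathlib import Path

    from .terrain import read_dem

    run = Path(run_dir)
    meta = json.loads((run / "manifest.json").read_text())
    archive = None
    for ydir in sorted(p for p in run.iterdir() if p.is_dir()):
        year = int(ydir.name)
        for f in sorted(ydir.glob("*_*.asc")):
            month_s, layer = f.stem.split("_", 1)
            grid = read_dem(f)
            if archive is None:
                archive = SimulationArchive(grid=grid, interval_minutes=meta["interval_minutes"])
            vals = np.where(grid.mask, grid.elevation, np.nan)
            archive.monthly.setdefault((year, int(month_s)), {})[layer] = vals
    if archive is None:
        raise FileNotFoundError(f"no archive rasters under {run}")
    archive.moment_counts = {int(k): v for k, v in meta.get("moment_counts", {}).items()}
    return archive


@dataclass
class Scenario:
    """Everything one simulation run needs."""

    site: Site
    dem: DEMGrid
    trees: Sequence[TreePosition]
    pattern: TreeGrowthPattern
    planting_date: date
    start: date
    years: int
    interval_minutes: int = 20
    radiation: RadiationParams = dc_field(default_factory=RadiationParams)
    stack_overlaps: bool = False


def simulate(scenario: Scenario, progress=None) -> SimulationArchive:
    """Run the shade-modelling loop over the full schedule.

    For every daylight moment the tree state is updated from its fractional
    age and calendar month, crown spheres are rebuilt, the clear-sky PISR map
    is computed, shadows are cast, and both the shaded (scenario) and
    unshaded (tree-free baseline) maps are accumulated into monthly
    kWh m^-2 rasters.  Deterministic: no randomness anywhere.
    """
    dem = scenario.dem
    sa = slope_aspect(dem)
    params = scenario.radiation
    moments = generate_moments(scenario.start, scenario.years, scenario.interval_minutes, scenario.site)
    archive = SimulationArchive(grid=dem, interval_minutes=scenario.interval_minutes)
    hours = scenario.interval_minutes / 60.0

    xy = np.array([[p.x, p.y] for p in scenario.trees], dtype=float).reshape(-1, 2)
    if xy.size:
        inside = dem.contains(xy[:, 0], xy[:, 1])
        if not inside.all():
            raise ValueError("tree position outside DEM extent")
        ground = dem.bilinear(xy[:, 0], xy[:, 1])
    else:
        ground = np.empty(0)

    for m in moments:
        ts = m.timestamp
        key = (ts.year, ts.month)
        if key not in archive.monthly:
            shape = dem.elevation.shape
            archive.monthly[key] = {"scenario": np.zeros(shape), "baseline": np.zeros(shape)}
            if progress is not None:
                progress(key)
        if params.include_terrain_occlusion:
            occl = terrain_occlusion_mask(dem, m.sun)
            direct, diffuse = _components(m.sun, sa, params)
            pisr = np.where(occl, 0.0, direct) + diffuse
        else:
            pisr = pisr_values(m.sun, sa, params)
        contrib = pisr * (hours / 1000.0)
        archive.monthly[key]["baseline"] += contrib
        if xy.size:
            age = tree_age_years(scenario.planting_date, ts)
            state = growth_state(scenario.pattern, max(age, 0.0), ts)
            r = state.crown_radius
            zc = ground + max(state.height - r, r)
            spheres = [CrownSphere(x, y, z, r) for (x, y), z in zip(xy, zc)]
            if scenario.stack_overlaps:
                k = shadow_mask(dem, spheres, sun=m.sun, count=True)
                shaded = contrib * np.power(state.transmittance, k)
            else:
                mask = shadow_mask(dem, spheres, sun=m.sun)
                shaded = np.where(mask, contrib * state.transmittance, contrib)
            archive.monthly[key]["scenario"] += shaded
        else:
            archive.monthly[key]["scenario"] += contrib
        archive.moment_counts[ts.year] = archive.moment_counts.get(ts.year, 0) + 1
    for maps in archive.monthly.values():
        for layer in maps.values():
            layer[~dem.mask] = np.nan
    return archive
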
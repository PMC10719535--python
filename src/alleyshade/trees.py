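"""Tree growth, crown geometry and alley-cropping row layouts.

Growth is deliberately simple: constant height and stem-diameter rates and a
linear crown-diameter allometry on DBH (diameter at breast height, cm),

    crown_diameter [m] = 0.1393 * DBH + 2.6937

as published for wild service tree (Sorbus torminalis).  The crown is a
sphere whose top sits at tree height, clamped so young trees' crowns rest on
the ground.  Deciduous foliage is a two-state seasonal cycle: foliated
May-October with crown opacity 0.75, leafless November-April with opacity
0.20.  The shading multiplier applied to radiation under a crown is the
*transmittance* 1 - opacity, so a summer-shaded cell keeps 25% of its
radiation and a winter-shaded cell 80%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import date, datetime
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

from .terrain import DEMGrid

__all__ = [
    "TreeGrowthPattern",
    "TreeState",
    "TreePosition",
    "CrownSphere",
    "RowLayout",
    "growth_state",
    "crown_spheres",
    "layout_rows",
]

FOLIATED_MONTHS = frozenset({5, 6, 7, 8, 9, 10})  # May through October


@dataclass(frozen=True)
class TreeGrowthPattern:
    """Species growth parameters.

    Defaults are for wild service tree: 0.25 m/yr height, 0.5 cm/yr DBH
    (5 mm/yr), the published crown-diameter allometry, and the two seasonal
    crown opacities.
    """

    height_rate: float = 0.25  # m per year
    dbh_rate: float = 0.5  # cm per year
    crown_slope: float = 0.1393  # m crown per cm DBH
    crown_intercept: float = 2.6937  # m
    opacity_foliated: float = 0.75
    opacity_leafless: float = 0.20

    def __post_init__(self) -> None:
        if self.height_rate < 0 or self.dbh_rate < 0:
            raise ValueError("growth rates must be non-negative")
        for o in (self.opacity_foliated, self.opacity_leafless):
            if not 0.0 <= o <= 1.0:
                raise ValueError("opacities must lie in [0, 1]")

    def opacity(self, month: int) -> float:
        return self.opacity_foliated if month in FOLIATED_MONTHS else self.opacity_leafless


@dataclass(frozen=True)
class TreeState:
    """Realized tree size and crown transmittance at a given age and date."""

    age: float  # years, fractional
    height: float  # m
    dbh: float  # cm
    crown_diameter: float  # m
    transmittance: float  # fraction of radiation passing the crown

    @property
    def crown_radius(self) -> float:
        return self.crown_diameter / 2.0


@dataclass(frozen=True)
class TreePosition:
    x: float
    y: float
    planting_date: date | None = None


@dataclass(frozen=True)
class CrownSphere:
    x: float
    y: float
    z: float  # centre elevation, m
    radius: float


@dataclass
class RowLayout:
    """Tree positions plus the row centrelines they were placed on."""

    positions: list[TreePosition]
    centrelines: list[LineString]
    total_row_length: float
    orientation_deg: float
    row_width: float

    @property
    def n_trees(self) -> int:
        return len(self.positions)


def growth_state(pattern: TreeGrowthPattern, age: float, when: date | datetime) -> TreeState:
    """Tree state at a (fractional) age on a calendar date.

    Height and DBH grow linearly from zero at planting; the crown diameter
    follows the allometry (a newly planted tree already carries the 2.69 m
    intercept crown, as the published relation prescribes at DBH 0).
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    dbh = pattern.dbh_rate * age
    return TreeState(
        age=age,
        height=pattern.height_rate * age,
        dbh=dbh,
        crown_diameter=pattern.crown_slope * dbh + pattern.crown_intercept,
        transmittance=1.0 - pattern.opacity(when.month),
    )


def tree_age_years(planting_date: date, when: datetime | date) -> float:
    """Fractional age in (mean Gregorian) years from planting to a moment."""
    if isinstance(when, datetime):
        when = when.date()
    return (when - planting_date).days / 365.2425


def crown_spheres(
    positions: Sequence[TreePosition] | np.ndarray,
    state: TreeState,
    dem: DEMGrid,
) -> list[CrownSphere]:
    """Place crown spheres on the terrain for trees sharing one growth state.

    The sphere top is at ``ground + height``; for young trees whose height is
    below the crown diameter the sphere is clamped to rest on the ground
    (``centre z = ground + max(height - radius, radius)``).  Ground elevation
    comes from bilinear interpolation of the DEM.
    """
    if isinstance(positions, np.ndarray):
        xy = np.asarray(positions, dtype=float).reshape(-1, 2)
    else:
        xy = np.array([[p.x, p.y] for p in positions], dtype=float).reshape(-1, 2)
    if xy.size == 0:
        return []
    inside = dem.contains(xy[:, 0], xy[:, 1])
    if not inside.all():
        bad = xy[~inside][0]
        raise ValueError(f"tree position outside DEM extent: ({bad[0]}, {bad[1]})")
    ground = dem.bilinear(xy[:, 0], xy[:, 1])
    r = state.crown_radius
    zc = ground + max(state.height - r, r)
    return [CrownSphere(x=float(x), y=float(y), z=float(z), radius=r) for (x, y), z in zip(xy, zc)]


def _canonical_endpoints(line: LineString) -> LineString:
    """Orient a segment so its start is the lexicographically smaller endpoint.

    Keeps tree placement identical for row orientations that differ by 180
    degrees.
    """
    coords = list(line.coords)
    # round to nm so a ~1e-13 m numeric offset cannot flip the ordering
    def key(c):
        return (round(c[0], 9), round(c[1], 9))

    if key(coords[-1]) < key(coords[0]):
        coords = coords[::-1]
    return LineString(coords)


def layout_rows(
    field: Polygon | str,
    orientation_deg: float,
    row_spacing: float,
    tree_spacing: float,
    row_width: float = 1.0,
    buffer: float = 20.0,
    planting_date: date | None = None,
) -> RowLayout:
    """Generate parallel tree rows inside an inward-buffered field polygon.

    Rows run along ``orientation_deg`` (degrees clockwise from north, so 0 is
    north-south and 90 is west-east), spaced ``row_spacing`` apart
    perpendicular to that direction and anchored so one row axis passes
    through the buffered polygon's centroid.  Each row is clipped to the
    buffered polygon and trees are placed every ``tree_spacing`` along it,
    starting half a spacing from the row end.  An over-large buffer that
    swallows the polygon yields an empty layout with a warning.
    """
    if row_spacing <= 0 or tree_spacing <= 0:
        raise ValueError("row_spacing and tree_spacing must be positive")
    if isinstance(field, str):
        field = shapely.from_wkt(field)
    if not field.is_valid or field.is_empty:
        raise ValueError("field polygon is invalid or empty")
    inner = field.buffer(-buffer) if buffer > 0 else field
    if inner.is_empty:
        warnings.warn("buffer collapses the field polygon; empty layout", stacklevel=2)
        return RowLayout([], [], 0.0, orientation_deg, row_width)

    theta = math.radians(orientation_deg)
    d = np.array([math.sin(theta), math.cos(theta)])  # along-row direction
    nvec = np.array([math.cos(theta), -math.sin(theta)])  # perpendicular (right of d)
    cx, cy = inner.centroid.x, inner.centroid.y

    # perpendicular offsets of the buffered polygon's corners from the anchor
    hull = np.asarray(inner.envelope.exterior.coords)
    offs = (hull[:, 0] - cx) * nvec[0] + (hull[:, 1] - cy) * nvec[1]
    k_min = math.ceil(round(offs.min() / row_spacing, 9))
    k_max = math.floor(round(offs.max() / row_spacing, 9))
    half_diag = math.hypot(*(np.ptp(hull, axis=0))) + row_spacing

    positions: list[TreePosition] = []
    centrelines: list[LineString] = []
    total_len = 0.0
    for k in range(k_min, k_max + 1):
        px = cx + k * row_spacing * nvec[0]
        py = cy + k * row_spacing * nvec[1]
        long_line = LineString(
            [
                (px - half_diag * d[0], py - half_diag * d[1]),
                (px + half_diag * d[0], py + half_diag * d[1]),
            ]
        )
        clipped = long_line.intersection(inner)
        if clipped.is_empty:
            continue
        parts = getattr(clipped, "geoms", [clipped])
        for part in parts:
            if not isinstance(part, LineString) or part.length <= 0:
                continue
            part = _canonical_endpoints(part)
            L = part.length
            t = tree_spacing / 2.0
            while t <= L:
                pt = part.interpolate(t)
                positions.append(TreePosition(pt.x, pt.y, planting_date))
                t += tree_spacing
            centrelines.append(part)
            total_len += L
    return RowLayout(positions, centrelines, total_len, orientation_deg, row_width)
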
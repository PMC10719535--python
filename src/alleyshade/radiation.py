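"""Clear-sky potential incoming solar radiation (PISR) on terrain.

Per-cell instantaneous irradiance uses the classic lumped-atmospheric-
transmittance formulation:

    direct  = S0 * tau**m * cos(theta_i)        (clamped at 0)
    diffuse = S0 * (0.271 - 0.294 * tau**m) * sin(alpha) * svf

with S0 the solar constant (1367 W m^-2), tau the bulk atmospheric
transmittance (default 0.70), m = 1/sin(alpha) the relative air mass (capped
at 38 near the horizon), alpha the apparent solar altitude and theta_i the
incidence angle between the sun vector and the cell's surface normal.
Negative diffuse values (possible at tau near 1) are clamped to zero.
Integration over a uniform schedule uses the left-rectangle rule and reports
kWh m^-2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .solar import Moment, SunPosition, sun_vector
from .terrain import DEMGrid, SlopeAspectGrid, surface_normals

__all__ = ["RadiationParams", "IrradianceMap", "pisr_instant", "pisr_integrate"]

MAX_AIR_MASS = 38.0


@dataclass(frozen=True)
class RadiationParams:
    """Parameters of the clear-sky model."""

    solar_constant: float = 1367.0  # W m^-2
    transmittance: float = 0.70  # lumped atmospheric transmittance per air mass
    include_diffuse: bool = True
    sky_view_factor: float = 1.0  # isotropic SVF applied to diffuse
    include_terrain_occlusion: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.transmittance <= 1.0:
            raise ValueError("transmittance must lie in (0, 1]")


@dataclass
class IrradianceMap:
    """Per-cell irradiance sharing a DEM's grid geometry.

    ``values`` are W m^-2 for instantaneous maps or kWh m^-2 for integrated
    ones; ``period`` labels what the map covers.
    """

    values: np.ndarray
    grid: DEMGrid
    units: str = "W/m^2"
    period: str = ""

    def masked(self) -> np.ndarray:
        return np.where(self.grid.mask, self.values, np.nan)


def _components(sun: SunPosition, sa: SlopeAspectGrid, params: RadiationParams):
    """(direct, diffuse) arrays in W m^-2; zeros when the sun is down."""
    alt = sun.altitude_deg
    shape = sa.slope_deg.shape
    if alt <= 0.0:
        z = np.zeros(shape)
        return z, z.copy()
    sin_a = math.sin(math.radians(alt))
    m = min(1.0 / sin_a, MAX_AIR_MASS)
    tau_m = params.transmittance**m
    v = sun_vector(sun)
    ne_, nn, nu = surface_normals(sa)
    cos_inc = np.clip(ne_ * v.e + nn * v.n + nu * v.u, 0.0, None)
    direct = params.solar_constant * tau_m * cos_inc
    if params.include_diffuse:
        diff_h = params.solar_constant * (0.271 - 0.294 * tau_m) * sin_a
        diffuse = np.full(shape, max(diff_h, 0.0) * params.sky_view_factor)
    else:
        diffuse = np.zeros(shape)
    return direct, diffuse


def pisr_values(sun: SunPosition, sa: SlopeAspectGrid, params: RadiationParams) -> np.ndarray:
    """Instantaneous PISR as a bare array (fast path for the simulation loop)."""
    direct, diffuse = _components(sun, sa, params)
    return direct + diffuse


def pisr_instant(
    sun: SunPosition,
    sa: SlopeAspectGrid,
    params: RadiationParams = RadiationParams(),
    grid: DEMGrid | None = None,
    occlusion_mask: np.ndarray | None = None,
) -> IrradianceMap:
    """Instantaneous clear-sky irradiance map (W m^-2) for one sun position.

    ``occlusion_mask`` (True where terrain hides the sun) suppresses the
    direct component only.
    """
    direct, diffuse = _components(sun, sa, params)
    if occlusion_mask is not None:
        direct = np.where(occlusion_mask, 0.0, direct)
    values = direct + diffuse
    if grid is not None:
        values = np.where(grid.mask, values, np.nan)
    return IrradianceMap(values=values, grid=grid, units="W/m^2", period="instant")


def pisr_integrate(
    moments: Sequence[Moment],
    sa: SlopeAspectGrid,
    params: RadiationParams = RadiationParams(),
    interval_minutes: float = 20.0,
    grid: DEMGrid | None = None,
    period: str = "",
) -> IrradianceMap:
    """Integrate instantaneous PISR over a uniform schedule into kWh m^-2.

    Left-rectangle rule: each daylight moment contributes its instantaneous
    map times the interval length.  Moments must carry their sun position.
    """
    total = np.zeros_like(sa.slope_deg, dtype=float)
    hours = interval_minutes / 60.0
    for m in moments:
        if m.sun is None:
            raise ValueError("moment lacks a computed SunPosition")
        if m.sun.altitude_deg <= 0.0:
            continue
        total += pisr_values(m.sun, sa, params) * hours
    total /= 1000.0  # Wh -> kWh
    if grid is not None:
        total = np.where(grid.mask, total, np.nan)
    return IrradianceMap(values=total, grid=grid, units="kWh/m^2", period=period)
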
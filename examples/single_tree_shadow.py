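"""Shadow of a single mature tree crown on flat ground.

Casts the shadow of one 60-year crown sphere at a 45-degree sun due south,
compares the shaded-cell count with the analytic shadow-ellipse area
pi*r^2/sin(altitude), and shows the seasonal attenuation of the clear-sky
irradiance underneath.
"""

import math
from datetime import date, datetime, timezone

import numpy as np

from alleyshade import (
    IrradianceMap,
    Moment,
    SunPosition,
    TreeGrowthPattern,
    TreePosition,
    crown_spheres,
    growth_state,
    shade_step,
    shadow_mask,
    synthetic_dem,
)

dem = synthetic_dem("flat", 100, 100, 1.0)
state = growth_state(TreeGrowthPattern(), 60.0, date(2021, 7, 1))
[sphere] = crown_spheres([TreePosition(50.0, 30.0)], state, dem)
print(f"crown sphere: radius {sphere.radius:.3f} m, centre {sphere.z:.3f} m above ground")

sun = SunPosition(azimuth_deg=180.0, altitude_deg=45.0)
mask = shadow_mask(dem, [sphere], sun=sun)
analytic = math.pi * sphere.radius**2 / math.sin(math.radians(sun.altitude_deg))
print(f"shaded cells: {mask.sum()} (analytic ellipse area {analytic:.1f} m^2)")
X, Y = dem.cell_centers()
print(f"shadow centroid: {X[mask].mean():.1f}, {Y[mask].mean():.1f} (tree at 50, 30; sun due south)")

pisr = IrradianceMap(np.full(dem.elevation.shape, 400.0), dem)
for month, label in ((7, "July, foliated"), (1, "January, leafless")):
    state = growth_state(TreeGrowthPattern(), 60.0, date(2021, month, 1))
    moment = Moment(datetime(2021, month, 1, 12, tzinfo=timezone.utc), 0, sun)
    res = shade_step(moment, dem, [sphere], state.transmittance, pisr)
    under = res.shaded_pisr.values[res.shadow_mask][0]
    print(f"{label}: 400 W/m^2 under the crown becomes {under:.0f} W/m^2")
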
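"""Wild-service-tree growth trajectory under the default pattern.

Prints height, stem diameter (DBH), crown diameter and the seasonal crown
transmittance at selected ages.  Height and DBH grow linearly (0.25 m/yr,
0.5 cm/yr); the crown diameter follows the allometry 0.1393*DBH + 2.6937.
"""

from datetime import date

from alleyshade import TreeGrowthPattern, growth_state

pattern = TreeGrowthPattern()
print("age [yr]  height [m]  DBH [cm]  crown [m]  T_summer  T_winter")
for age in (0, 10, 20, 30, 40, 50, 60):
    summer = growth_state(pattern, age, date(2021, 7, 1))
    winter = growth_state(pattern, age, date(2021, 1, 1))
    print(
        f"{age:8d}  {summer.height:10.2f}  {summer.dbh:8.1f}  "
        f"{summer.crown_diameter:9.4f}  {summer.transmittance:8.2f}  {winter.transmittance:8.2f}"
    )

# T_summer = 0.25 means a cell shadowed by a foliated crown keeps 25% of its
# clear-sky radiation; the leafless winter crown lets 80% through.
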
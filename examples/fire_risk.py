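"""Understory fire risk from fuel load and near-surface soil moisture.

The patch is fire-prone when the top-30-cm soil moisture drops strictly
below (1-f)*theta_Wp + f*theta_Fc; while dry, the fire disturbance rate
is I x fuel carbon and the flammable area follows as a saturating
percentage per year.
"""

from canopy2cohorts.fire import (FlammabilityParams, FuelInventory,
                                 SoilState, flammable_area)

fuel = FuelInventory(litter=0.8, cwd=1.0, grass_seedling_agb=0.2)
params = FlammabilityParams()          # I=0.5, f=0.02, z_F=0.30 m, dt=1 yr

for label, theta in (("wet season", 0.30), ("dry season", 0.12)):
    soil = SoilState(thickness=(0.15, 0.15), theta=(theta, theta),
                     theta_wp=0.15, theta_fc=0.35)
    res = flammable_area(fuel, soil, params)
    print(f"{label}: theta_bar={res.mean_moisture:.3f} "
          f"(threshold {res.threshold:.3f})  dry={res.dry}  "
          f"lambda_F={res.lambda_f:.2f} /yr  alpha_F={res.alpha_f:.1f} %/yr")
# With 2.0 kgC m-2 of fuel the dry-season rate is 1.0 /yr, i.e. a
# flammable area of 63.2 %/yr; wet soil shuts the model off entirely,
# whatever the fuel load.
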
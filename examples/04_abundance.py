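"""Scale a habitat-suitability surface to a population estimate.

Maximum density D_max is the mean of published upper-level density
estimates after excluding extreme values (>4 per hectare); suitability s
maps linearly to density s*D_max/2, and summing over 1-km² cells gives the
total. The interval has relative half-width SD/D_max, the coefficient of
variation of the published estimates.
"""

import numpy as np

import koalasdm as k
from koalasdm.products import SuitabilityRaster

densities = k.default_density_table()
dmax = k.estimate_dmax(densities, exclusion_threshold=4.0)
print(f"density table: {len(densities)} values, {len(dmax.excluded_ha)} excluded "
      f"(> {dmax.exclusion_threshold}/ha)")
print(f"D_max = {dmax.mean_ha:.2f} +/- {dmax.sd_ha:.2f} per ha "
      f"= {dmax.mean_km2:.0f} +/- {dmax.sd_km2:.0f} per km^2 "
      f"(CV {dmax.cv_percent:.1f}%)")

# a suitability surface averaging ~0.26 over a 5576-km^2 study frame
rng = np.random.default_rng(0)
raster = SuitabilityRaster(values=np.clip(rng.normal(0.26, 0.1, (8, 697)), 0, 1),
                           model="example", n_iterations=1, offset_reference=0.0)
est = k.estimate_abundance(raster, dmax)
print(f"\nstudy area {est.total_area_km2:.0f} km^2, "
      f"suitability sum {est.sum_suitability:.0f}")
print(f"population estimate: {est.mean:,.0f} "
      f"(interval {est.ci_low:,.0f} - {est.ci_high:,.0f})")
print(f"implied mean density: {est.density_low_km2:.1f} - "
      f"{est.density_high_km2:.1f} per km^2")
print("-> the wide interval reflects the spread of published maximum")
print("   densities, not sampling error in the suitability surface.")
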
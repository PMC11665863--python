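"""Air-to-water temperature transfer: a few conversions and the annual summary.

The logistic transfer T_water = 32 / (1 + exp(-0.13 T_air + 1.94)) maps any
air temperature into (0, 32) °C.  Annual water variables are computed by
converting each month first and aggregating afterwards — the curve is
nonlinear, so the order matters.
"""

import numpy as np
import pandas as pd

from fishwarm import aggregate_annual, air_to_water, water_to_air

for t_air in (-10.0, 0.0, 1.94 / 0.13, 25.0, 40.0):
    print(f"air {t_air:7.2f} °C  ->  water {air_to_water(t_air):7.3f} °C")
print(f"midpoint air temperature (water = 16 °C): {water_to_air(16.0):.4f} °C")

# one site-year of monthly maxima with a July peak
months = np.arange(1, 13)
tmax = 12.0 + 10.0 * np.cos(2 * np.pi * (months - 7) / 12)
clim = pd.DataFrame(
    {"site_id": "demo", "year": 2000, "month": months, "tmax_air_c": tmax}
)
annual = aggregate_annual(clim)
print("\nannual summary (water scale):")
print(annual.to_string(index=False))
print(
    "\nt_avg is the mean of the 12 converted monthly values; t_max is their"
    "\nmaximum (the July month).  Converting the annual-mean air temperature"
    f"\ninstead would give {air_to_water(float(tmax.mean())):.3f} °C — not t_avg."
)
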
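"""[CO] trend, regression on deforestation, and the increment sensitivity scan.

Couples an annual carbon-monoxide series to total fire counts, regresses it
on time and on deforested area, and scans how much selected years must be
reduced before the [CO] time trend becomes significant.  A second,
hand-built series with an explicit emission-import shock on 2007 and 2010
shows the scan locating the shock size.
"""

import numpy as np
import pandas as pd

from amazonfires import (SyntheticConfig, annual_deforestation_km2, co_trend,
                         co_on_deforestation, generate_co_series, sensitivity_scan)
from amazonfires.synthetic import generate_fire_seasons, generate_landscape

config = SyntheticConfig(seed=8)  # default 60x60 grid, 2003-2019
landscape = generate_landscape(config)
detections, _ = generate_fire_seasons(config, landscape)
totals = (detections.assign(year=pd.to_datetime(detections["date"]).dt.year)
          .groupby("year").size().reindex(config.years, fill_value=0))
co = generate_co_series(config, totals)

t = co_trend(co)
print(f"[CO] on time:          R² = {t.r_squared:.2f}, p = {t.p_value:.3f}")
r = co_on_deforestation(co, annual_deforestation_km2(landscape))
print(f"[CO] on deforestation: R² = {r.r_squared:.2f}, p = {r.p_value:.3f}")

scan = sensitivity_scan(co, target_years=(2007, 2010), step_pct=5.0, alpha=0.05)
if scan.minimal_reduction_pct is None:
    print("coupled series: no reduction up to 50% reaches significance")
else:
    print(f"coupled series: minimal reduction {scan.minimal_reduction_pct:.0f}% "
          f"(p = {scan.p_at_minimum:.3f})")

# A series whose decline is masked only by an import shock on 2007/2010:
years = np.arange(2003, 2016)
shocked = pd.Series(110.0 - 0.45 * (years - 2003), index=years)
shocked.loc[[2007, 2010]] *= 1.12  # +12% imported emissions in those years
base = co_trend(shocked)
scan2 = sensitivity_scan(shocked, target_years=(2007, 2010), step_pct=5.0)
print(f"shocked series: p = {base.p_value:.3f} unadjusted; minimal reduction "
      f"{scan2.minimal_reduction_pct:.0f}% restores the significant decline "
      f"(p = {scan2.p_at_minimum:.3f}, R² = {scan2.r2_at_minimum:.2f})")
# Removing only the years that carry emissions imported from outside the
# biome reveals the underlying decline in fire-driven emissions.
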
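"""EOF/PC decomposition of standardized annual fire maps, per fire type.

Prints the explained-variance spectrum of the leading modes for each fire
type and the year in which the leading PC peaks.
"""

from amazonfires import (SyntheticConfig, classify_all, decompose,
                         rasterize_counts, standardize, variance_table)
from amazonfires.synthetic import generate_fire_seasons, generate_landscape

config = SyntheticConfig(grid_rows=40, grid_cols=40, seed=4,
                         base_detections_per_pixel=2.0)
landscape = generate_landscape(config)
detections, _ = generate_fire_seasons(config, landscape)
labeled = classify_all(detections, landscape)

decomps = {}
for t in ("deforestation", "maintenance", "forest"):
    sub = labeled[labeled["fire_type"] == t]
    z = standardize(rasterize_counts(sub, config.years, config.grid_spec))
    decomps[t] = decompose(z, fire_type=t)

table = variance_table(decomps)
for t, d in decomps.items():
    first6 = table[(table.fire_type == t) & (table["mode"] <= 6)]
    pc1 = d.pcs["PC1"]
    print(f"{t:14s} first 6 modes explain {first6['explained_pct'].sum():5.1f}% "
          f"| PC1 peaks in {int(pc1.abs().idxmax())}")
# A flatter spectrum means less spatially/temporally coherent fire activity;
# PC peaks in drought years are the spatial fingerprint of fire-season
# exacerbation.
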
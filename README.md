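# amazonfires

Diagnostics for the fire–deforestation *decoupling* question in the Brazilian
Amazon: as deforestation fell after 2004, did fire activity fall with it, or
did drought-driven burning take over as the dominant regime?

The package implements, as a reusable and fully tested pipeline, the analysis
chain used to answer that question from satellite active-fire records:

1. **Fire-type classification.** Every ~1-km pixel-year with detections is
   labelled from fire persistence and land-cover history:
   *deforestation* fires if detections occur on ≥ 2 distinct days and the
   pixel's annual deforestation rate is ≥ 5%; else *forest* (understory)
   fires if detections span ≤ 3 days, year-2000 tree cover is ≥ 70% and
   cumulative deforestation since 2001 is ≤ 20%; else *maintenance*
   (pasture/cropland) fires.
2. **Trend statistics.** Two-tailed Mann–Kendall test (tie-corrected variance,
   ±1 continuity correction, exact enumeration p for short series) with the
   Theil–Sen slope $\hat\beta = \mathrm{med}_{i<j}\,(x_j-x_i)/(t_j-t_i)$, OLS
   with R² and the slope t-test, the fires-per-km²-deforested ratio, and
   regressions stratified by deforestation-policy (PPCDAm) phase.
3. **Anomaly extent.** Per-pixel standardized anomalies
   $z_{p,t} = (c_{p,t}-\bar c_p)/s_p$ and the percent of area with $z > 2$
   per year — a fire-season severity index.
4. **FRP intensity.** Fire-radiative-power densities and percentiles (FRP90)
   by type and year, and a single-breakpoint (broken stick) least-squares fit
   of the annual FRP90 series with Mann–Kendall tests on both branches.
5. **EOF/PC modes.** SVD of the years × pixels anomaly matrix per fire type:
   explained-variance spectra, PC time series, EOF sign maps.
6. **[CO] emissions.** Trend and deforestation regressions of annual mean
   carbon monoxide at 800 hPa, a shifted 12-month window adjustment, and the
   increment sensitivity scan (reduce selected years by k%, find the minimal
   k making the trend significant).
7. **Synthetic generator.** A seeded emulator of all inputs — landscape,
   fire seasons with three behavioural types, [CO] — with recorded ground
   truth, so every stage is testable without the (multi-GB) source archives.

It is aimed at fire-ecology and land-use researchers who want the method
chain reproducible on their own detection tables (INPE BDQueimadas / MODIS
style CSV) and rasters, or on synthetic data.

## Worked example

```bash
python examples/classify_fire_types.py
```

```
21487 detections over 2003-2019
overall composition (classified | truth):
  deforestation    5.7% |   5.7%
  maintenance     35.8% |  35.8%
  forest          58.5% |  58.5%
label mismatches vs truth: 0
```

The classifier recovers the generator's ground truth exactly because the
synthetic strata are disjoint; the composition differs from the configured
8/39/53% mix only because drought years amplify forest and maintenance
fires. The other `examples/` scripts each exercise one capability:

```bash
python examples/decoupling_trends.py
```

```
fire-count trend: -115 counts/yr (95% Sen CI -158 to -92), MK p = 6.5e-05, significant at 1%: True
fires per km² deforested: drought years 1734.4 vs non-drought 656.4 (fully separated: True)
```

A declining fire-count trend together with drought years standing clearly
above non-drought years in fires per km² deforested is the signature of
climate-driven burning layered on a shrinking deforestation driver.

The same analyses run from the shell:

```bash
amazonfires run-all --seed 1 --outdir out/
amazonfires classify --config my_config.yaml
```

`run-all` writes the eight analysis products (annual type counts, ratio
series, phase regressions, anomaly extents, [CO] analyses, FRP summaries,
breakpoint report, mode decompositions) plus a JSON manifest with content
hashes; re-running with the same seed reproduces every file byte for byte.
In `files` mode the same pipeline runs on user-supplied CSV/NetCDF inputs.

## Layout

- `src/amazonfires/` — `synthetic`, `io`, `classify`, `trends`, `anomalies`,
  `intensity`, `modes`, `emissions`, `pipeline`, `cli`
- `examples/` — one narrative script per capability
- `tests/` — unit, property and end-to-end suites
- `docs/methods.md` — models, assumptions, parameter choices, limitations
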
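# sheepmove

Analysis of statutory sheep movement records for designing and interpreting
slaughterhouse-based surveillance.

Slaughterhouses are convenient fixed sampling points for animal-health
surveillance (disease monitoring, antimicrobial-resistance surveys), but the
sheep that arrive at any one slaughterhouse are a spatially and seasonally
biased subset of the national flock. National traceability databases record
every batch movement between premises — departure, read location,
destination (each a County Parish Holding number, CPH), date, animal count
and electronic-ID (EID) read count — and `sheepmove` turns those records
into the quantities a surveillance designer needs:

* **Movement classification and annual summaries** — every movement is
  classed as within / out of / into the country, with batch and sheep counts,
  class percentages and batch-vs-read data-quality discrepancies per year.
* **Deduplicated slaughter populations** — a sale through a market generates
  two batch records for one consignment (farm→market→abattoir, then
  market→abattoir), double-counting the sheep; `sheepmove` removes the
  market leg by matching market, destination, a date window and either
  overlapping EID reads or equal head counts, then splits moves into the
  standard populations: SSSP (domestic-origin sheep to slaughter anywhere in
  GB), its subsets SISP (slaughtered in-country) and SOSP (slaughtered
  across the border), and the excluded non-domestic-origin remainder.
* **Catchment areas on a fixed-area hexagonal grid** — holdings are mapped
  (precise coordinates, else parish centroid) and binned into congruent
  115 km² hexagons (a hexagonal tessellation is the Voronoi diagram of its
  centers, so binning is an exact nearest-center query); a slaughterhouse's
  catchment is the per-cell distribution of its suppliers, with quarterly
  decomposition for seasonality.
* **Survey representativeness** — per catchment cell, the observed number of
  sampled holdings O is compared with the expectation E under proportional
  allocation via χ² = (O − E)²/E; cells are adequately sampled (χ² ≤ 2),
  not sampled, or over-/under-sampled.
* **Origin–destination matrices** — 14 × 14 regional matrices of
  within-country non-slaughter sheep flows, normalized by departure row or
  destination column, quartile-binned, and sliced by quarter.
* **Batch-size model** — a log-link Poisson GLM of batch size on movement
  class; with a class-only factor the exponentiated coefficients are exactly
  ratios of class sample means (reported under the conventional
  "odds ratio" label).

Because the underlying statutory data are access-restricted, the package
ships a synthetic-data generator (`sheepmove.synthetic_data`) that
reproduces their known structure — dual market records, 4% EID mis-reads,
15% batch-only sheep, 35% of holdings without coordinates, a September-peak
movement calendar, heavy-tailed batch sizes — together with ground truth
for every downstream stage.

## Worked example

```python
import sheepmove as sm

cfg = sm.SimConfig(moves_per_year=2000, years=(2017,), seed=1)
premises, parishes, census, batch, reads, truth = sm.generate_dataset(cfg)

slaughter = sm.identify_slaughter_moves(batch, premises)
dedup = sm.deduplicate_market_legs(slaughter, reads, premises)
print(len(slaughter), "slaughter records,", len(dedup.removed),
      "market legs removed,", len(dedup.kept), "kept")

table = sm.population_summary(dedup.kept, premises, census)
print(table[["sssp_sheep", "sisp_pct_of_sssp", "sosp_pct_of_sssp"]])
```

prints

```
1034 slaughter records, 345 market legs removed, 689 kept
      sssp_sheep  sisp_pct_of_sssp  sosp_pct_of_sssp
year
2017       11980              63.0              37.0
```

— 1,034 raw slaughter-destination records collapse to 689 consignments once
the 345 market legs are removed; of the 11,980 domestic-origin slaughter
sheep, 63.0% were slaughtered in-country (this split is configuration- and
seed-dependent). On the published worked-example counts, the same code
reproduces the familiar figures: a 2015 within-country batch share of
54.1%, a mean of 4,514,194 sheep moved per year, and a slaughter population
at 33.6% of the census total with 49.1% slaughtered in-country.

The same pipeline is available from the shell:

```sh
sheepmove --seed 7 --out data simulate
sheepmove --config config.yaml --out results all
```

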
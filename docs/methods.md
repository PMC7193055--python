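# Methods

This note documents the models, conventions and numerical choices behind
`sheepmove`, in the spirit of a statistical package's model documentation.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A **batch movement record** is one consignment of sheep between two
premises on one date: departure CPH, optional read-location CPH (a Critical
Control Point, CCP — a market or slaughterhouse where EID tags are
scanned), destination CPH, animal count and read count. An **individual
read record** is one EID detection at a CCP. The **premises registry** maps
each CPH to a type (farm, market, slaughterhouse, other), a country
(the study country vs the rest of the island), a region, a parish and
optional planar coordinates (meters, national-grid-like; no geodesy is
performed anywhere).

Movements are classified by endpoint countries: WITHIN (both domestic),
OUT_OF (domestic departure, external destination), INTO (the reverse).
Records with neither endpoint domestic are out of scope and rejected.
Records whose endpoints cannot be resolved are quarantined to a reject
table with reasons, never silently dropped: count-based outputs include
them; only spatial stages exclude them.

## Slaughter populations and deduplication

A consignment sold through a market on its way to slaughter appears twice:
record 1 (farm departure, market read, slaughterhouse destination) and
record 2 (market departure, slaughterhouse read and destination). Keeping
both double-counts the sheep. The deduplicator removes record 2 when a
record 1 exists with the same market and destination, a date within
`window_days` (default 1 — lairage transit is same-or-next-day; the
matching tolerance is configurable because the source systems do not
prescribe one), and either (a) at least one EID tag read for both records
or (b) equal animal counts. EID overlap outranks count equality and each
removal logs its basis, since count-only matches are lower-confidence.
Matching is one-to-one and greedy in date order, which makes the operation
deterministic and idempotent.

The deduplicated slaughter moves split into: SSSP (domestic-origin sheep to
any GB slaughterhouse), partitioned into SISP (domestic slaughterhouse) and
SOSP (external slaughterhouse); non-domestic-origin sheep slaughtered
domestically form a fourth group excluded from SSSP totals. "Origin" is
always the departure premises of the move immediately prior to slaughter —
lifetime tracing is impossible in these data, a recognised limitation.

Annual summary tables report class counts with percentages to one decimal
place. The table builder accepts explicit per-year totals distinct from the
class sums, because recorded annual totals can include records that defy
classification; percentages are then computed against the recorded totals.

## Hexagonal grid and catchments

The tessellation uses congruent regular hexagons of a configurable area
(default 115 km²), circumradius R = sqrt(2A / (3√3)) ≈ 6,653 m at the
default. Orientation defaults to flat-top and the origin is the extent's
lower-left corner; both are recorded in output metadata since any congruent
tiling is equally valid. Cells extend one ring beyond the extent so the
rectangle is covered without gaps.

Point binning exploits the fact that a hexagonal tiling is the Voronoi
diagram of its centers: the containing cell is the nearest center (KD-tree
query), with an exact point-in-hexagon check to flag points beyond the grid
edge. Points equidistant from several centers (cell boundaries) go to the
lowest incident cell id — a declared convention, exercised by tests against
a brute-force polygon-containment oracle. The tie tolerance is 1e-9·R.

A slaughterhouse's catchment is the per-cell distribution of its supplying
holdings and their sheep, each cell expressed as a percentage of a
reference population total (SISP or SSSP) so catchments are comparable.
Holdings are located by precise coordinates when present, else by parish
centroid; holdings with neither are tallied as unmappable, and cell totals
plus the unmappable remainder always reconcile to throughput. Quarterly
layers express each quarter's per-cell sheep as a percentage of the annual
*mappable* throughput, so the four layers' grand totals sum to exactly
100; the unmappable share is reported separately rather than smeared over
the denominator. Coastline trimming is replaced by an optional clip
polygon; with none supplied, no cells are dropped.

## Representativeness scoring

For a survey of holdings sampled at one slaughterhouse, each catchment cell
(a cell with ≥ 1 supplying holding — cells outside the catchment are never
scored) receives an expectation E_i = n·h_i/Σh under proportional
allocation of the n sampled holdings to the h_i supplying holdings per
cell, and a statistic χ²_i = (O_i − E_i)²/E_i. Categories: O = 0 →
not sampled; χ² ≤ threshold (default 2) → adequate; otherwise oversampled
(O > E) or undersampled (O < E). The four-way scheme is reported because
"oversampled" conventionally conflates both departures; a switch merges
undersampled into oversampled for the two-way reading. The threshold of 2
is a pragmatic cut-off for a large-df chi-square treated as approximately
normal; it is exposed in configuration and the scoring is monotone in it.
The sampling unit is the holding (distinct sampled holdings per cell), not
the specimen. A cell with E = 0 but O > 0 has an undefined statistic and is
categorized oversampled by convention, with a flag.

## Origin–destination matrices

Matrices count sheep in within-country, non-slaughter moves between the 14
agricultural regions, departure rows × destination columns, diagonal =
intra-regional. Region order is fixed alphabetically and echoed in output
headers so heat-map twins are comparable across runs. Two normalizations:
by departure row (rows sum to 100%) and by destination column; zero-total
rows/columns are reported absent rather than divided. Quartile binning of
the nonzero entries uses empirical 0.25/0.5/0.75 quantiles with linear
interpolation and half-open bins (lower, upper]; zeros form a distinct
"none" category and are excluded from the quantile computation — a declared
convention, since pooling zeros would collapse the lower bins in sparse
matrices. Quarterly matrices partition the annual matrix exactly.

## Batch-size model

Batch sizes are counts ≥ 1, modeled with a log-link Poisson GLM on movement
class indicators. With a class-only factor the model is saturated: the
fitted class means equal the sample means and each exponentiated
coefficient equals a ratio of class means — the closed form used as the
test oracle (agreement to 1e-8 relative). Exponentiated coefficients are
labelled "odds ratio" in exports to match conventional reporting, though
they are rate ratios. Significance is a Wald test at p < 0.05 against the
reference class (default: movements into the country, the largest-batch
class). Batch sizes are strongly overdispersed relative to Poisson
(empirical maxima in the thousands against means of tens); the default
follows the plain-Poisson convention, and a quasi-Poisson switch inflates
the covariance by the Pearson dispersion for honest standard errors without
changing the coefficients. All-movements and slaughter-only subsets are fit
as separate models.

## Synthetic data generator

The generator emulates the statistical structure of statutory movement
data, with defaults chosen as the study conditions the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `p_missing_coords` | 0.35 | farms without coordinates (parish centroid only) |
| `p_misread` | 0.04 | per-animal, per-CCP EID read suppression |
| `p_batch_only_sheep` | 0.15 | animals with no reads anywhere |
| `p_via_market` | 0.5 | slaughter moves routed through a market (dual records) |
| `p_cross_border_out` / `in` | 0.48 / 0.022 | class mix of batches |
| `batch_mean_by_class` | 15 / 15 / 56 | within / out / into mean batch size |
| `slaughter_batch_mean_by_class` | 24 / 13 / 107 | slaughter-move analogue |
| `moves_per_year` | 2000 | logical consignments per year |
| `p_slaughter` | 0.35 | share of moves destined for slaughter (roughly a third of sheep go to slaughter annually) |
| `dispersion` | 0.6 | negative-binomial shape k |

Batch sizes are negative binomial (mean m, shape k, variance m + m²/k)
truncated at ≥ 1 — Poisson tails cannot produce the observed four-digit
maxima — with Poisson available as an option for model-recovery tests.
Truncation inflates a distribution's mean, so the generator solves the
fixed point m′ = m·(1 − P₀(m′)) and draws from the law whose *truncated*
mean is exactly the configured class mean. Months are allocated
multinomially on a 12-weight seasonal profile (September maximum, secondary
March peak, June minimum — the qualitative shape of the sheep calendar
year, user-overridable since no quantitative within-year profile is
established); days are uniform within the month. An optional
`quarter_gate` confines a region's departures to one calendar quarter, used
to verify the seasonal catchment decomposition. Regions are a rectangular
14-way partition of the planar extent carrying the agricultural-region
names; geometry is deliberately schematic. External (rest-of-GB) premises
sit in a band south of the extent.

Randomness uses one master seed with independent named substreams (CRC-32
of the component name as a spawn key), so adding a component never shifts
another's draws and identical configs are byte-identical on disk.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: real coastline and region geometry, CPH
county-code semantics, demographic aging and age structure of consignments,
market-to-farm onward sales chains, cross-border recording asymmetries, and
correlated (non-independent) mis-reads within a batch. Oracle tests prove
the pipeline's algebra and matching logic, not the realism of any one
parameter value.

## Problem sizes and tolerances

Oracle tests run at 10,000 moves (deduplication), 10,000 random points
(hexagon binning), 500 replicates of 2,000 batches (GLM interval coverage)
— sizes at which binomial/multinomial sampling error is far below the
assertion tolerances while the whole suite stays fast. Key tolerances:
hexagon area 1e-6 relative; chi-square agreement 1e-12 relative; GLM closed
form 1e-8 relative; matrix denormalization 1e-9 relative; percentage sums
±0.1 (one-decimal rounding). Degenerate inputs are values, not errors,
wherever the quantity is meaningfully absent (zero reads → absent excess,
zero parish area → absent density, zero-total row → absent percentages);
they are errors where the computation is undefined (empty catchment for
expected counts, single-class GLM).

## Known limitations

* Only the move immediately prior to slaughter is visible, so catchments
  describe immediate origins, not birth origins.
* The dedup count-equality fallback can mispair two same-day, same-count
  consignments through the same market to the same slaughterhouse; totals
  are unaffected (one leg is still removed per pair).
* Plain-Poisson p-values are anti-conservative under the overdispersion the
  generator itself produces; use the quasi-Poisson switch for inference.
* GeoJSON output uses planar coordinates, not longitude/latitude; consumers
  expecting WGS84 must reproject.
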
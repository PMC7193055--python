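"""Synthetic sheep movement datasets with known ground truth.

Real statutory movement records (traceability databases, agricultural census,
premises registers) are access-restricted, so every downstream stage of this
package is exercised on simulated data that reproduces the statistical
structure those records are known to have:

* dual recording of market-routed slaughter moves (farm->market->abattoir
  emits two batch records, double-counting the sheep unless deduplicated);
* individual electronic-ID read records at Critical Control Points, with a
  configurable mis-read rate (default 4%) and a share of batch sheep carrying
  no individual reads at all (default 15%);
* about a third of holdings lacking coordinates (default 35%), resolvable
  only to a parish centroid;
* a strongly seasonal movement calendar (September peak, secondary March
  peak, June trough);
* heavier-tailed batch sizes for moves into the country than for moves
  within or out of it.

The generator also emits a :class:`GroundTruth` object — true slaughterhouse
throughputs, the exact set of duplicated record pairs, the true movement
class of every record — which the test-suite uses as an oracle.
"""

from __future__ import annotations

import calendar
import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ingest_classify import (
    PTYPE_FARM,
    PTYPE_MARKET,
    PTYPE_SLAUGHTERHOUSE,
    REST_OF_GB,
    SCOTLAND,
    MovementClass,
)

#: the 14 agricultural regions used for origin-destination matrices, in the
#: fixed alphabetical order shared by all outputs
REGIONS: tuple[str, ...] = (
    "Argyll",
    "Ayrshire",
    "Borders",
    "Clyde Valley",
    "Dumfries & Galloway",
    "East Central",
    "Fife",
    "Grampian",
    "Highland",
    "Lothian",
    "Orkney",
    "Shetland",
    "Tayside",
    "Western Isles",
)

#: monthly movement weights: large September peak, smaller March peak,
#: June minimum (qualitative seasonal profile of the sheep calendar year)
DEFAULT_MONTHLY_INTENSITY: tuple[float, ...] = (
    4.0, 4.5, 8.0, 5.0, 3.5, 2.5, 4.0, 7.0, 16.0, 12.0, 8.0, 5.0,
)

_CLASSES = (MovementClass.WITHIN.value, MovementClass.OUT_OF.value,
            MovementClass.INTO.value)


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child RNG of one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(zlib.crc32(name.encode()),)))


@dataclass
class SimConfig:
    """Parameters of the synthetic movement-data generator.

    Defaults encode the study conditions the analysis is designed for: 35%
    of holdings without coordinates, 4% mis-reads, 15% batch-only sheep,
    class-specific mean batch sizes of 15/15/56 (within/out/into) for all
    movements and 24/13/107 for slaughter movements.
    """

    n_holdings: int = 400
    n_markets: int = 6
    n_slaughterhouses: int = 8
    n_ext_holdings: int = 40
    n_ext_slaughterhouses: int = 4
    n_regions: int = 14
    n_parishes_per_region: int = 4
    years: Sequence[int] = (2015, 2016, 2017, 2018)
    extent: tuple[float, float, float, float] = (0.0, 0.0, 420_000.0, 700_000.0)
    moves_per_year: int = 2000
    p_slaughter: float = 0.35
    p_missing_coords: float = 0.35
    p_misread: float = 0.04
    p_batch_only_sheep: float = 0.15
    p_via_market: float = 0.5
    p_cross_border_out: float = 0.48
    p_cross_border_in: float = 0.022
    monthly_intensity: Sequence[float] = DEFAULT_MONTHLY_INTENSITY
    batch_mean_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"WITHIN": 15.0, "OUT_OF": 15.0, "INTO": 56.0})
    slaughter_batch_mean_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"WITHIN": 24.0, "OUT_OF": 13.0, "INTO": 107.0})
    dispersion: float = 0.6
    batch_distribution: str = "nbinom"  # or "poisson"
    quarter_gate: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        # normalise sequence fields so configs loaded from YAML/JSON compare
        # equal to ones built in code
        self.years = tuple(int(y) for y in self.years)
        self.extent = tuple(float(v) for v in self.extent)
        self.monthly_intensity = tuple(float(w)
                                       for w in self.monthly_intensity)
        for name in ("p_slaughter", "p_missing_coords", "p_misread",
                     "p_batch_only_sheep", "p_via_market",
                     "p_cross_border_out", "p_cross_border_in"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not a proportion in [0, 1]")
        if self.p_cross_border_out + self.p_cross_border_in > 1.0:
            raise ValueError("cross-border proportions sum above 1")
        if len(self.monthly_intensity) != 12:
            raise ValueError("monthly_intensity needs exactly 12 entries")
        if not any(w > 0 for w in self.monthly_intensity):
            raise ValueError("monthly_intensity must not be all zero")
        if any(w < 0 for w in self.monthly_intensity):
            raise ValueError("monthly_intensity weights must be nonnegative")
        for m in (self.batch_mean_by_class, self.slaughter_batch_mean_by_class):
            if any(v <= 0 for v in m.values()):
                raise ValueError("batch-size means must be positive")
        x0, y0, x1, y1 = self.extent
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"degenerate extent {self.extent}")
        if min(self.n_holdings, self.n_markets, self.n_slaughterhouses) < 1:
            raise ValueError("premises counts must be >= 1")
        if self.batch_distribution not in ("nbinom", "poisson"):
            raise ValueError(
                f"unknown batch_distribution {self.batch_distribution!r}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def regions(self) -> tuple[str, ...]:
        if self.n_regions == len(REGIONS):
            return REGIONS
        return tuple(f"Region {i + 1:02d}" for i in range(self.n_regions))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load a config from YAML or JSON (by file suffix)."""
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text))
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        d["monthly_intensity"] = list(self.monthly_intensity)
        d["extent"] = list(self.extent)
        d["batch_mean_by_class"] = dict(self.batch_mean_by_class)
        d["slaughter_batch_mean_by_class"] = dict(
            self.slaughter_batch_mean_by_class)
        d["quarter_gate"] = dict(self.quarter_gate)
        return d


@dataclass
class GroundTruth:
    """Oracle values recorded while generating the dataset."""

    #: (slaughterhouse_cph, year) -> sheep actually delivered (each logical
    #: move counted once, regardless of dual recording)
    true_slaughter_count: dict
    #: (first_leg_record_id, market_leg_record_id) pairs of dual records
    duplicated_record_pairs: set
    #: record_id -> endpoint-based movement class
    true_class_of_record: dict
    #: record_id -> slaughter population (SISP/SOSP/POP4) for kept slaughter
    #: records
    true_population_of_record: dict
    #: (holding_cph, slaughterhouse_cph, year, quarter) -> sheep
    per_holding_supply: dict


# ---------------------------------------------------------------------------
# Premises and parish registry


def _region_block(config: SimConfig, region_idx: int
                  ) -> tuple[float, float, float, float]:
    """Rectangular block of the extent assigned to one region (7x2 layout
    for 14 regions, otherwise as square a grid as fits)."""
    n = config.n_regions
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    x0, y0, x1, y1 = config.extent
    dx = (x1 - x0) / ncols
    dy = (y1 - y0) / nrows
    r, c = divmod(region_idx, ncols)
    return (x0 + c * dx, y0 + r * dy, x0 + (c + 1) * dx, y0 + (r + 1) * dy)


def generate_parishes(config: SimConfig) -> pd.DataFrame:
    """Parish table: id, region, area (ha), planar centroid."""
    rng = _substream(config.seed, "parishes")
    rows = []
    for i, region in enumerate(config.regions):
        bx0, by0, bx1, by1 = _region_block(config, i)
        for k in range(config.n_parishes_per_region):
            rows.append({
                "parish_id": f"P{i:02d}{k:02d}",
                "region": region,
                "area_ha": float(np.round(rng.uniform(2_000, 20_000), 1)),
                "centroid_easting": float(np.round(rng.uniform(bx0, bx1), 1)),
                "centroid_northing": float(np.round(rng.uniform(by0, by1), 1)),
            })
    return pd.DataFrame(rows)


def generate_premises(config: SimConfig
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the premises registry and parish table.

    Farms, markets and slaughterhouses get unique CPHs; each Scottish
    premises is assigned a region (a rectangular partition of the extent)
    and a parish.  Exactly ``round(p_missing_coords * n_holdings)`` farms
    have no coordinates but keep a valid parish whose centroid is known.
    A band of rest-of-GB premises (farms and slaughterhouses) sits south of
    the extent for cross-border movements.

    Returns ``(premises, parishes)``.
    """
    parishes = generate_parishes(config)
    rng = _substream(config.seed, "premises")
    regions = config.regions
    rows = []

    def scottish(ptype: str, county: int, serial: int, region_idx: int) -> dict:
        bx0, by0, bx1, by1 = _region_block(config, region_idx)
        region = regions[region_idx]
        pid = parishes.loc[parishes["region"] == region, "parish_id"]
        return {
            "cph": f"{county:02d}/{rng.integers(1, 999):03d}/{serial:04d}",
            "ptype": ptype,
            "country": SCOTLAND,
            "region": region,
            "parish_id": pid.iloc[int(rng.integers(len(pid)))],
            "easting": float(np.round(rng.uniform(bx0, bx1), 1)),
            "northing": float(np.round(rng.uniform(by0, by1), 1)),
        }

    region_of_farm = rng.integers(0, config.n_regions, size=config.n_holdings)
    for i in range(config.n_holdings):
        rows.append(scottish(PTYPE_FARM, 60 + int(region_of_farm[i]) % 30,
                             i + 1, int(region_of_farm[i])))
    for i in range(config.n_markets):
        rows.append(scottish(PTYPE_MARKET, 55, i + 1,
                             int(rng.integers(config.n_regions))))
    for i in range(config.n_slaughterhouses):
        rows.append(scottish(PTYPE_SLAUGHTERHOUSE, 50, i + 1,
                             int(rng.integers(config.n_regions))))

    x0, y0, x1, _ = config.extent
    south = y0 - 0.2 * (config.extent[3] - y0)

    def external(ptype: str, county: int, serial: int) -> dict:
        return {
            "cph": f"{county:02d}/{rng.integers(1, 999):03d}/{serial:04d}",
            "ptype": ptype,
            "country": REST_OF_GB,
            "region": pd.NA,
            "parish_id": pd.NA,
            "easting": float(np.round(rng.uniform(x0, x1), 1)),
            "northing": float(np.round(rng.uniform(south, y0 - 1.0), 1)),
        }

    for i in range(config.n_ext_holdings):
        rows.append(external(PTYPE_FARM, 91, i + 1))
    for i in range(config.n_ext_slaughterhouses):
        rows.append(external(PTYPE_SLAUGHTERHOUSE, 95, i + 1))

    premises = pd.DataFrame(rows)
    if premises["cph"].duplicated().any():
        # county/serial scheme guarantees uniqueness across types; parish
        # component is random, so collisions cannot occur within a type
        raise AssertionError("duplicate CPHs generated")

    n_missing = int(round(config.p_missing_coords * config.n_holdings))
    farm_idx = premises.index[(premises["ptype"] == PTYPE_FARM)
                              & (premises["country"] == SCOTLAND)]
    drop = _substream(config.seed, "missing-coords").choice(
        farm_idx, size=n_missing, replace=False)
    premises.loc[drop, ["easting", "northing"]] = np.nan
    for col in ("cph", "ptype", "country", "region", "parish_id"):
        premises[col] = premises[col].astype("string")
    return premises, parishes


def generate_census(parishes: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """June-census-like sheep counts per parish per year.

    Parish densities are fixed draws between 0 and 8 sheep/hectare (the
    plausible national range) with small year-to-year Poisson variation.
    """
    rng = _substream(config.seed, "census")
    density = rng.uniform(0.0, 8.0, size=len(parishes))
    rows = []
    for year in config.years:
        base = density * parishes["area_ha"].to_numpy()
        counts = rng.poisson(np.maximum(base, 0.0))
        for pid, region, n in zip(parishes["parish_id"], parishes["region"],
                                  counts):
            rows.append({"year": int(year), "parish_id": pid,
                         "region": region, "n_sheep": int(n)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Batch sizes


def _pretruncation_mean(target: np.ndarray, config: SimConfig) -> np.ndarray:
    """Mean of the untruncated count law whose >=1 truncation has mean
    ``target``.

    Truncating at >= 1 inflates the mean by 1/(1 - P(0)), so the raw mean m'
    solves m' = target * (1 - P0(m')); the fixed point is found by
    iteration (P0 is decreasing in m', so this converges monotonically).
    """
    m = np.asarray(target, dtype=float).copy()
    for _ in range(100):
        if config.batch_distribution == "poisson":
            p0 = np.exp(-m)
        else:
            k = config.dispersion
            p0 = (k / (k + m)) ** k
        m_new = target * (1.0 - p0)
        if np.allclose(m_new, m, rtol=1e-12, atol=1e-12):
            break
        m = m_new
    return m


def _draw_batch_sizes(rng: np.random.Generator, means: np.ndarray,
                      config: SimConfig) -> np.ndarray:
    """Count-distribution batch sizes, truncated at >= 1, with the truncated
    mean equal to ``means``.

    Negative binomial by default (observed batch-size maxima vastly exceed
    Poisson tails); plain Poisson available for model-recovery tests.
    Zeros are resampled; any still zero after a few rounds are set to 1
    (probability negligible for realistic means).
    """
    raw = _pretruncation_mean(means, config)
    if config.batch_distribution == "poisson":
        draw = lambda m: rng.poisson(m)
    else:
        k = config.dispersion
        draw = lambda m: rng.negative_binomial(k, k / (k + m))
    sizes = draw(raw)
    for _ in range(20):
        zero = sizes == 0
        if not zero.any():
            break
        sizes[zero] = draw(raw[zero])
    sizes[sizes == 0] = 1
    return sizes.astype(int)


# ---------------------------------------------------------------------------
# Movements


def _dates_for(rng: np.random.Generator, year: int, months: np.ndarray
               ) -> np.ndarray:
    """Uniform day within each move's allocated month."""
    days_in = np.array([calendar.monthrange(year, m)[1] for m in range(1, 13)])
    day = rng.integers(1, days_in[months - 1] + 1)
    return pd.to_datetime({"year": np.full(len(months), year),
                           "month": months, "day": day}).to_numpy()


def generate_movements(premises: pd.DataFrame, config: SimConfig
                       ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate batch movement records, individual read records and truth.

    Each logical move is assigned a class (within / out of / into the
    country), a slaughter flag, a month (multinomial on the seasonal
    profile), a date, and a batch size from the class-specific count
    distribution.  Slaughter moves routed through a market (probability
    ``p_via_market``) emit TWO batch records — the farm-to-slaughterhouse
    record read at the market, and a market-to-slaughterhouse record — and
    are listed in ``GroundTruth.duplicated_record_pairs``.  Individual reads
    are emitted for every animal at every Critical Control Point on its
    route, each suppressed independently with probability ``p_misread``;
    a fraction ``p_batch_only_sheep`` of animals carries no reads at all.
    """
    reg = premises
    farms_scot = reg.loc[(reg["ptype"] == PTYPE_FARM)
                         & (reg["country"] == SCOTLAND)].reset_index(drop=True)
    farms_ext = reg.loc[(reg["ptype"] == PTYPE_FARM)
                        & (reg["country"] == REST_OF_GB)].reset_index(drop=True)
    markets = reg.loc[reg["ptype"] == PTYPE_MARKET].reset_index(drop=True)
    sh_scot = reg.loc[(reg["ptype"] == PTYPE_SLAUGHTERHOUSE)
                      & (reg["country"] == SCOTLAND)].reset_index(drop=True)
    sh_ext = reg.loc[(reg["ptype"] == PTYPE_SLAUGHTERHOUSE)
                     & (reg["country"] == REST_OF_GB)].reset_index(drop=True)
    if len(farms_ext) == 0 and config.p_cross_border_in > 0:
        raise ValueError("cross-border in-moves need external holdings")
    if len(sh_ext) == 0 and config.p_cross_border_out > 0:
        raise ValueError("cross-border slaughter moves need external "
                         "slaughterhouses")

    rng = _substream(config.seed, "movements")
    read_rng = _substream(config.seed, "reads")

    intensity = np.asarray(config.monthly_intensity, dtype=float)
    p_month = intensity / intensity.sum()

    batch_rows: list[dict] = []
    read_rows: list[dict] = []
    truth = GroundTruth({}, set(), {}, {}, {})
    rec_counter = 0
    tag_counter = 0

    def next_record_id() -> str:
        nonlocal rec_counter
        rec_counter += 1
        return f"M{rec_counter:07d}"

    for year in config.years:
        n = config.moves_per_year
        p_within = 1.0 - config.p_cross_border_out - config.p_cross_border_in
        cls = rng.choice(_CLASSES, size=n,
                         p=[p_within, config.p_cross_border_out,
                            config.p_cross_border_in])
        slaughter = rng.random(n) < config.p_slaughter
        months = rng.choice(np.arange(1, 13), size=n, p=p_month)

        # departure premises
        dep_idx = rng.integers(0, len(farms_scot), size=n)
        ext_dep_idx = rng.integers(0, max(len(farms_ext), 1), size=n)
        is_into = cls == MovementClass.INTO.value
        dep = np.where(is_into,
                       farms_ext["cph"].to_numpy()[ext_dep_idx]
                       if len(farms_ext) else "",
                       farms_scot["cph"].to_numpy()[dep_idx])
        dep_region = np.where(is_into, "",
                              farms_scot["region"].to_numpy()[dep_idx])

        # region-specific quarter gating (used to verify seasonal catchment
        # decomposition): departures from a gated region only move in the
        # gated quarter
        if config.quarter_gate:
            for region, quarter in config.quarter_gate.items():
                gated = (dep_region == region)
                if not gated.any():
                    continue
                qmonths = np.arange(3 * (quarter - 1) + 1, 3 * quarter + 1)
                w = p_month[qmonths - 1]
                months[gated] = rng.choice(qmonths, size=int(gated.sum()),
                                           p=w / w.sum())

        dates = _dates_for(rng, int(year), months)

        # destinations
        dst = np.empty(n, dtype=object)
        for i in range(n):
            c = cls[i]
            if slaughter[i]:
                pool = sh_ext if c == MovementClass.OUT_OF.value else sh_scot
            else:
                if c == MovementClass.OUT_OF.value:
                    pool = farms_ext
                else:
                    pool = farms_scot
            j = int(rng.integers(len(pool)))
            if (pool is farms_scot and not slaughter[i]
                    and pool["cph"].iloc[j] == dep[i] and len(pool) > 1):
                j = (j + 1) % len(pool)
            dst[i] = pool["cph"].iloc[j]

        means = np.where(
            slaughter,
            np.vectorize(config.slaughter_batch_mean_by_class.get)(cls),
            np.vectorize(config.batch_mean_by_class.get)(cls)).astype(float)
        sizes = _draw_batch_sizes(rng, means, config)
        via_market = slaughter & (rng.random(n) < config.p_via_market) \
            if len(markets) else np.zeros(n, dtype=bool)
        market_pick = rng.integers(0, max(len(markets), 1), size=n)

        sh_country = reg.set_index("cph")["country"]
        for i in range(n):
            size = int(sizes[i])
            date = pd.Timestamp(dates[i])
            c = cls[i]
            if slaughter[i]:
                dep_is_scot = not is_into[i]
                dst_is_scot = sh_country[dst[i]] == SCOTLAND
                if dep_is_scot:
                    pop = "SISP" if dst_is_scot else "SOSP"
                else:
                    pop = "POP4"
                key = (dst[i], int(year))
                truth.true_slaughter_count[key] = (
                    truth.true_slaughter_count.get(key, 0) + size)
                quarter = (int(months[i]) - 1) // 3 + 1
                skey = (dep[i], dst[i], int(year), quarter)
                truth.per_holding_supply[skey] = (
                    truth.per_holding_supply.get(skey, 0) + size)

                # per-animal read plan
                tags = [f"UK{tag_counter + k + 1:09d}" for k in range(size)]
                tag_counter += size
                batch_only = read_rng.random(size) < config.p_batch_only_sheep

                if via_market[i]:
                    market = markets["cph"].iloc[int(market_pick[i])]
                    r1 = next_record_id()
                    r2 = next_record_id()
                    read_m = (~batch_only) & (read_rng.random(size)
                                              >= config.p_misread)
                    read_s = (~batch_only) & (read_rng.random(size)
                                              >= config.p_misread)
                    for tag, ok in zip(tags, read_m):
                        if ok:
                            read_rows.append({"tag_id": tag, "ccp_cph": market,
                                              "date": date, "batch_ref": r1})
                    for tag, ok in zip(tags, read_s):
                        if ok:
                            read_rows.append({"tag_id": tag, "ccp_cph": dst[i],
                                              "date": date, "batch_ref": r2})
                    batch_rows.append({
                        "record_id": r1, "departure_cph": dep[i],
                        "read_cph": market, "destination_cph": dst[i],
                        "date": date, "n_animals": size,
                        "n_reads": int(read_m.sum())})
                    batch_rows.append({
                        "record_id": r2, "departure_cph": market,
                        "read_cph": dst[i], "destination_cph": dst[i],
                        "date": date, "n_animals": size,
                        "n_reads": int(read_s.sum())})
                    truth.duplicated_record_pairs.add((r1, r2))
                    truth.true_class_of_record[r1] = c
                    # the market leg's own endpoints define its class
                    truth.true_class_of_record[r2] = (
                        MovementClass.WITHIN.value if dst_is_scot
                        else MovementClass.OUT_OF.value)
                    truth.true_population_of_record[r1] = pop
                else:
                    r1 = next_record_id()
                    read_s = (~batch_only) & (read_rng.random(size)
                                              >= config.p_misread)
                    for tag, ok in zip(tags, read_s):
                        if ok:
                            read_rows.append({"tag_id": tag, "ccp_cph": dst[i],
                                              "date": date, "batch_ref": r1})
                    batch_rows.append({
                        "record_id": r1, "departure_cph": dep[i],
                        "read_cph": dst[i], "destination_cph": dst[i],
                        "date": date, "n_animals": size,
                        "n_reads": int(read_s.sum())})
                    truth.true_class_of_record[r1] = c
                    truth.true_population_of_record[r1] = pop
            else:
                r1 = next_record_id()
                batch_rows.append({
                    "record_id": r1, "departure_cph": dep[i],
                    "read_cph": pd.NA, "destination_cph": dst[i],
                    "date": date, "n_animals": size, "n_reads": 0})
                truth.true_class_of_record[r1] = c

    batch = pd.DataFrame(batch_rows, columns=[
        "record_id", "departure_cph", "read_cph", "destination_cph",
        "date", "n_animals", "n_reads"])
    reads = pd.DataFrame(read_rows, columns=[
        "tag_id", "ccp_cph", "date", "batch_ref"])
    for col in ("record_id", "departure_cph", "read_cph", "destination_cph"):
        batch[col] = batch[col].astype("string")
    for col in ("tag_id", "ccp_cph", "batch_ref"):
        if len(reads):
            reads[col] = reads[col].astype("string")
    return batch, reads, truth


def generate_dataset(config: SimConfig):
    """Convenience wrapper: premises, parishes, census, movements, reads,
    truth — all from one config."""
    premises, parishes = generate_premises(config)
    census = generate_census(parishes, config)
    batch, reads, truth = generate_movements(premises, config)
    return premises, parishes, census, batch, reads, truth


# ---------------------------------------------------------------------------
# CSV output


def write_dataset(outdir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Generate a dataset and write the CSV set consumed by the pipeline.

    Writes movements.csv, reads.csv, premises.csv, parishes.csv, census.csv
    plus ground-truth CSVs (truth_*.csv) and the config echo.
    Returns the mapping of logical name to path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    premises, parishes, census, batch, reads, truth = generate_dataset(config)

    paths = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p

    b = batch.copy()
    b["date"] = b["date"].dt.strftime("%Y-%m-%d")
    r = reads.copy()
    if len(r):
        r["date"] = r["date"].dt.strftime("%Y-%m-%d")
    _write("movements", b)
    _write("reads", r)
    _write("premises", premises)
    _write("parishes", parishes)
    _write("census", census)

    _write("truth_slaughter_count", pd.DataFrame(
        [{"slaughterhouse_cph": k[0], "year": k[1], "n_sheep": v}
         for k, v in sorted(truth.true_slaughter_count.items())]))
    _write("truth_duplicated_pairs", pd.DataFrame(
        sorted(truth.duplicated_record_pairs),
        columns=["first_leg_record_id", "market_leg_record_id"]))
    _write("truth_record_class", pd.DataFrame(
        [{"record_id": k, "movement_class": v}
         for k, v in sorted(truth.true_class_of_record.items())]))
    _write("truth_record_population", pd.DataFrame(
        [{"record_id": k, "population": v}
         for k, v in sorted(truth.true_population_of_record.items())]))
    _write("truth_per_holding_supply", pd.DataFrame(
        [{"holding_cph": k[0], "slaughterhouse_cph": k[1], "year": k[2],
          "quarter": k[3], "n_sheep": v}
         for k, v in sorted(truth.per_holding_supply.items())]))

    (outdir / "sim_config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    paths["sim_config"] = outdir / "sim_config.yaml"
    return paths
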
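"""Deduplicated slaughter populations, rankings and time series.

A sheep sold through a market on its way to slaughter generates two batch
records — the farm-to-slaughterhouse move read at the market, and a second
market-to-slaughterhouse move — effectively double-counting the animals.
This module removes the market legs (matching on market, destination, date
window and either overlapping electronic-ID reads or equal animal counts),
then classifies the remaining direct-to-slaughter moves into the standard
slaughter populations:

* SSSP — sheep leaving a Scottish holding directly for slaughter anywhere
  in Great Britain (the union of the next two);
* SISP — the subset slaughtered at a Scottish slaughterhouse;
* SOSP — the subset slaughtered outside Scotland;
* POP4 — non-Scottish-origin sheep slaughtered in Scotland, excluded from
  SSSP totals.

"Origin" always means the departure premises of the move immediately prior
to slaughter; lifetime tracing is not possible from these records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest_classify import (
    PTYPE_MARKET,
    PTYPE_SLAUGHTERHOUSE,
    SCOTLAND,
    registry_index,
)

POP_SISP = "SISP"
POP_SOSP = "SOSP"
POP_POP4 = "POP4"

MATCH_EID = "eid"
MATCH_COUNT = "count"


@dataclass
class DedupResult:
    """Outcome of market-leg removal.

    ``kept`` holds one record per logical move; ``removed`` is the audit
    trail (market-leg id, matched first-leg id, match basis in
    {eid, count}).
    """

    kept: pd.DataFrame
    removed: pd.DataFrame  # columns: market_leg_record_id,
    #          matched_first_leg_record_id, match_basis


def identify_slaughter_moves(records: pd.DataFrame,
                             premises: pd.DataFrame) -> pd.DataFrame:
    """Records whose destination premises is a slaughterhouse (any country)."""
    reg = registry_index(premises)
    dst_type = records["destination_cph"].map(reg["ptype"])
    return records[dst_type == PTYPE_SLAUGHTERHOUSE].copy()


def deduplicate_market_legs(slaughter_records: pd.DataFrame,
                            reads: pd.DataFrame,
                            premises: pd.DataFrame,
                            window_days: int = 1) -> DedupResult:
    """Remove the second (market-to-slaughterhouse) leg of dual records.

    A record R2 departing from a market for a slaughterhouse is removed when
    a first-leg record R1 exists with R1.read_location == R2.departure,
    R1.destination == R2.destination, |R2.date - R1.date| <= window_days,
    and either (a) at least one electronic-ID tag was read for both records
    or (b) the two records carry equal animal counts.  EID overlap beats
    count equality; matching is one-to-one and greedy in date order so the
    result is reproducible and idempotent.
    """
    if window_days < 0:
        raise ValueError(f"window_days must be >= 0, got {window_days}")
    reg = registry_index(premises)
    recs = slaughter_records

    dep_type = recs["departure_cph"].map(reg["ptype"])
    is_market_leg = (dep_type == PTYPE_MARKET).to_numpy()

    # candidate first legs: read at a market en route to the slaughterhouse
    read_type = recs["read_cph"].map(reg["ptype"])
    is_first_leg = (~is_market_leg) & (read_type == PTYPE_MARKET).to_numpy()

    tags_of = (reads.groupby("batch_ref")["tag_id"].agg(set)
               if len(reads) else pd.Series(dtype=object))

    removed_rows = []
    matched_first: set[str] = set()
    window = pd.Timedelta(days=window_days)

    first = recs[is_first_leg]
    second = recs[is_market_leg].sort_values(["date", "record_id"])
    # index first legs by (market, destination) for candidate lookup
    first_by_key: dict[tuple, pd.DataFrame] = {
        key: grp.sort_values(["date", "record_id"])
        for key, grp in first.groupby(["read_cph", "destination_cph"])
    }

    for r2 in second.itertuples(index=False):
        key = (r2.departure_cph, r2.destination_cph)
        cands = first_by_key.get(key)
        if cands is None:
            continue
        in_window = (cands["date"] - r2.date).abs() <= window
        free = ~cands["record_id"].isin(matched_first)
        cands = cands[in_window & free]
        if cands.empty:
            continue
        r2_tags = tags_of.get(r2.record_id, set())
        match_id = None
        basis = None
        if r2_tags:
            for r1 in cands.itertuples(index=False):
                if tags_of.get(r1.record_id, set()) & r2_tags:
                    match_id, basis = r1.record_id, MATCH_EID
                    break
        if match_id is None:
            same_count = cands[cands["n_animals"] == r2.n_animals]
            if not same_count.empty:
                match_id, basis = same_count["record_id"].iloc[0], MATCH_COUNT
        if match_id is not None:
            matched_first.add(match_id)
            removed_rows.append({
                "market_leg_record_id": r2.record_id,
                "matched_first_leg_record_id": match_id,
                "match_basis": basis,
            })

    removed = pd.DataFrame(removed_rows, columns=[
        "market_leg_record_id", "matched_first_leg_record_id", "match_basis"])
    kept = recs[~recs["record_id"].isin(
        set(removed["market_leg_record_id"]))].copy()
    return DedupResult(kept=kept, removed=removed)


def classify_population(records: pd.DataFrame,
                        premises: pd.DataFrame) -> pd.Series:
    """Slaughter population (SISP/SOSP/POP4) of each deduplicated move.

    Origin = departure country, destination = slaughterhouse country.
    Moves with neither endpoint Scottish are out of scope and raise.
    """
    reg = registry_index(premises)
    dep_scot = records["departure_cph"].map(reg["country"]) == SCOTLAND
    dst_scot = records["destination_cph"].map(reg["country"]) == SCOTLAND
    neither = ~dep_scot & ~dst_scot
    if neither.any():
        bad = records.loc[neither, "record_id"].tolist()[:5]
        raise ValueError(f"out-of-scope slaughter moves (no Scottish "
                         f"endpoint): {bad}")
    out = pd.Series(POP_POP4, index=records.index, name="population")
    out[dep_scot & dst_scot] = POP_SISP
    out[dep_scot & ~dst_scot] = POP_SOSP
    return out


def population_summary_from_counts(counts: pd.DataFrame,
                                   census_totals: pd.Series) -> pd.DataFrame:
    """Percentages of the slaughter populations from per-year sheep counts.

    ``counts`` has rows SISP and SOSP, columns years; ``census_totals`` maps
    year to the national sheep population.  Returns per year: SSSP sheep,
    SSSP as % of the census population, and SISP/SOSP sheep with % of SSSP
    (1 decimal).  Years missing from the census report an absent percentage.
    """
    years = list(counts.columns)
    sssp = counts.loc[POP_SISP] + counts.loc[POP_SOSP]
    rows = []
    for y in years:
        census = census_totals.get(y, np.nan)
        total = sssp[y]
        rows.append({
            "year": y,
            "sssp_sheep": int(total),
            "sssp_pct_of_census": (round(100.0 * total / census, 1)
                                   if census == census and census > 0
                                   else np.nan),
            "sisp_sheep": int(counts.loc[POP_SISP, y]),
            "sisp_pct_of_sssp": round(100.0 * counts.loc[POP_SISP, y] / total, 1)
            if total else np.nan,
            "sosp_sheep": int(counts.loc[POP_SOSP, y]),
            "sosp_pct_of_sssp": round(100.0 * counts.loc[POP_SOSP, y] / total, 1)
            if total else np.nan,
        })
    return pd.DataFrame(rows).set_index("year")


def population_summary(deduped: pd.DataFrame, premises: pd.DataFrame,
                       census: pd.DataFrame) -> pd.DataFrame:
    """Per-year slaughter-population table from deduplicated records.

    ``census`` is the parish-level table (year, parish_id, region, n_sheep);
    its per-year national totals form the denominator of the SSSP share.
    Non-Scottish-origin sheep (POP4) are excluded from SSSP totals.
    """
    recs = deduped.copy()
    recs["population"] = classify_population(recs, premises)
    recs["year"] = recs["date"].dt.year
    counts = (recs[recs["population"].isin([POP_SISP, POP_SOSP])]
              .groupby(["population", "year"])["n_animals"].sum()
              .unstack("year", fill_value=0)
              .reindex([POP_SISP, POP_SOSP], fill_value=0))
    census_totals = census.groupby("year")["n_sheep"].sum()
    return population_summary_from_counts(counts, census_totals)


def rank_slaughterhouses(deduped: pd.DataFrame, premises: pd.DataFrame,
                         year: int, by: str = "sheep",
                         reference: str = "SSSP") -> pd.DataFrame:
    """Rank slaughterhouses by annual throughput.

    ``by`` is "sheep" (animal numbers) or "batches" (record counts);
    ``reference`` is "SSSP" (Scottish-origin sheep to any GB slaughterhouse)
    or "SISP" (restricted to Scottish slaughterhouses).  Shares are of the
    reference population's total; ties break by slaughterhouse CPH for
    reproducibility.  An unknown year yields an empty ranking.
    """
    if by not in ("sheep", "batches"):
        raise ValueError(f"by must be 'sheep' or 'batches', got {by!r}")
    if reference not in ("SSSP", "SISP"):
        raise ValueError(f"reference must be 'SSSP' or 'SISP', got "
                         f"{reference!r}")
    recs = deduped.copy()
    recs["population"] = classify_population(recs, premises)
    recs["year"] = recs["date"].dt.year
    wanted = [POP_SISP] if reference == "SISP" else [POP_SISP, POP_SOSP]
    recs = recs[(recs["year"] == year) & recs["population"].isin(wanted)]
    cols = ["slaughterhouse_cph", "throughput", "share_pct",
            "cumulative_share_pct", "rank"]
    if recs.empty:
        return pd.DataFrame(columns=cols)
    grouped = recs.groupby("destination_cph")
    throughput = (grouped["n_animals"].sum() if by == "sheep"
                  else grouped.size())
    total = throughput.sum()
    out = (throughput.rename("throughput").reset_index()
           .rename(columns={"destination_cph": "slaughterhouse_cph"})
           .sort_values(["throughput", "slaughterhouse_cph"],
                        ascending=[False, True])
           .reset_index(drop=True))
    out["share_pct"] = 100.0 * out["throughput"] / total
    out["cumulative_share_pct"] = out["share_pct"].cumsum()
    out["rank"] = np.arange(1, len(out) + 1)
    return out[cols]


def supplier_overlap(deduped: pd.DataFrame,
                     premises: pd.DataFrame) -> pd.DataFrame:
    """Shares of supplying Scottish holdings by slaughter destination country.

    Per year and pooled: counts and percentage shares of holdings that
    supplied Scottish slaughterhouses only, rest-of-GB slaughterhouses only,
    or both.
    """
    reg = registry_index(premises)
    recs = deduped.copy()
    dep_scot = recs["departure_cph"].map(reg["country"]) == SCOTLAND
    recs = recs[dep_scot]
    recs["year"] = recs["date"].dt.year
    recs["dst_scot"] = recs["destination_cph"].map(reg["country"]) == SCOTLAND

    def _categorize(group: pd.DataFrame) -> pd.Series:
        per_holding = group.groupby("departure_cph")["dst_scot"].agg(["any", "all"])
        both = (per_holding["any"] & ~per_holding["all"]).sum()
        scot_only = per_holding["all"].sum()
        ext_only = (~per_holding["any"]).sum()
        n = len(per_holding)
        return pd.Series({
            "n_holdings": n,
            "scotland_only": int(scot_only),
            "rest_of_gb_only": int(ext_only),
            "both": int(both),
            "scotland_only_pct": round(100.0 * scot_only / n, 1) if n else np.nan,
            "rest_of_gb_only_pct": round(100.0 * ext_only / n, 1) if n else np.nan,
            "both_pct": round(100.0 * both / n, 1) if n else np.nan,
        })

    rows = {int(y): _categorize(g) for y, g in recs.groupby("year")}
    rows["pooled"] = _categorize(recs)
    return pd.DataFrame(rows).T


def monthly_series(records: pd.DataFrame,
                   which: str = "all") -> pd.DataFrame:
    """Sheep moved per calendar month per year.

    ``which`` is "all" for every record passed in, or "slaughter" as a label
    when the caller has already restricted (and deduplicated) the records —
    the tallying is identical; the label is echoed in the output for
    provenance.
    """
    recs = records.copy()
    recs["year"] = recs["date"].dt.year
    recs["month"] = recs["date"].dt.month
    out = (recs.groupby(["year", "month"])["n_animals"].sum()
           .unstack("month", fill_value=0)
           .reindex(columns=range(1, 13), fill_value=0))
    out.columns.name = "month"
    out.attrs["filter"] = which
    return out
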
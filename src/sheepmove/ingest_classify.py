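"""Reading, validation, geo-resolution and classification of sheep movement records.

Batch movement records register a departure premises, an optional read
location (a Critical Control Point such as a market or slaughterhouse where
electronic ear tags are scanned) and a destination premises, all keyed by
County Parish Holding (CPH) number.  Individual-animal read records are a
separate stream.  This module parses both, joins them to a premises registry,
resolves each premises to a planar point (precise coordinates when available,
otherwise the parish centroid), and classifies every movement into one of
three classes: within Scotland, out of Scotland, or into Scotland.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCOTLAND = "Scotland"
REST_OF_GB = "rest-of-GB"

#: premises types recognised in the registry
PTYPE_FARM = "farm"
PTYPE_MARKET = "market"
PTYPE_SLAUGHTERHOUSE = "slaughterhouse"
PTYPE_OTHER = "other"

MOVEMENT_COLUMNS = [
    "record_id", "departure_cph", "read_cph", "destination_cph",
    "date", "n_animals", "n_reads",
]
READ_COLUMNS = ["tag_id", "ccp_cph", "date", "batch_ref"]
PREMISES_COLUMNS = [
    "cph", "ptype", "country", "region", "parish_id", "easting", "northing",
]
PARISH_COLUMNS = [
    "parish_id", "region", "area_ha", "centroid_easting", "centroid_northing",
]


class MovementClass(str, enum.Enum):
    """Classes of sheep movement relative to the Scottish border.

    The fourth class used in reporting, "total", is the union of these three.
    """

    WITHIN = "WITHIN"
    OUT_OF = "OUT_OF"
    INTO = "INTO"


class CPHError(ValueError):
    """Raised when a CPH string cannot be parsed."""


@dataclass(frozen=True, order=True)
class CPH:
    """County Parish Holding number: the premises identifier used in GB.

    The canonical string form is ``CC/PPP/HHHH`` (county, parish, holding,
    zero padded); :meth:`__str__` round-trips through :func:`parse_cph`.
    """

    county: int
    parish: int
    holding: int

    def __str__(self) -> str:
        return f"{self.county:02d}/{self.parish:03d}/{self.holding:04d}"


_CPH_RE = re.compile(r"^\s*(\d+)\s*/\s*(\d+)\s*/\s*(\d+)\s*$")


def parse_cph(text: str) -> CPH:
    """Parse a CPH string such as ``"66/123/0001"``.

    Leading/trailing whitespace is tolerated.  Raises :class:`CPHError` for a
    wrong component count or non-numeric parts, naming the offending text.
    """
    if not isinstance(text, str):
        raise CPHError(f"CPH must be a string, got {text!r}")
    parts = text.split("/")
    if len(parts) != 3:
        raise CPHError(f"expected 3 components in CPH {text!r}, got {len(parts)}")
    m = _CPH_RE.match(text)
    if m is None:
        raise CPHError(f"non-numeric component in CPH {text!r}")
    county, parish, holding = (int(g) for g in m.groups())
    return CPH(county, parish, holding)


# ---------------------------------------------------------------------------
# CSV ingestion


def load_movements(path: str | Path) -> pd.DataFrame:
    """Read batch movement records from CSV.

    Dates are parsed as ISO-8601; ``n_animals`` must be >= 1 for every record.
    """
    df = pd.read_csv(path, dtype={c: "string" for c in
                                  ("record_id", "departure_cph", "read_cph",
                                   "destination_cph")})
    missing = set(MOVEMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"movements file {path} missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    df["n_animals"] = df["n_animals"].astype(int)
    df["n_reads"] = df["n_reads"].fillna(0).astype(int)
    if (df["n_animals"] < 1).any():
        bad = df.loc[df["n_animals"] < 1, "record_id"].tolist()[:5]
        raise ValueError(f"n_animals < 1 for records {bad}")
    return df


def load_reads(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: "string" for c in
                                  ("tag_id", "ccp_cph", "batch_ref")})
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reads file {path} missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    return df


def load_premises(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cph": "string", "ptype": "string",
                                  "country": "string", "region": "string",
                                  "parish_id": "string"})
    missing = set(PREMISES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"premises file {path} missing columns {sorted(missing)}")
    if df["cph"].duplicated().any():
        raise ValueError(f"premises file {path} has duplicate CPHs")
    return df


def load_parishes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"parish_id": "string", "region": "string"})
    missing = set(PARISH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"parishes file {path} missing columns {sorted(missing)}")
    return df


def registry_index(premises: pd.DataFrame) -> pd.DataFrame:
    """Return the premises table indexed by CPH for O(1) lookups."""
    if premises.index.name == "cph":
        return premises
    return premises.set_index("cph", drop=False)


# ---------------------------------------------------------------------------
# Geo-resolution

PROV_PRECISE = "precise"
PROV_CENTROID = "centroid"
PROV_UNMAPPABLE = "unmappable"


def resolve_locations(premises: pd.DataFrame,
                      parishes: pd.DataFrame) -> pd.DataFrame:
    """Resolve every premises to a planar point with a provenance tag.

    Precise coordinates are used when available; otherwise the centroid of the
    premises' parish; premises with neither are tagged ``unmappable`` (absence
    is a value, not an error — such premises stay in all count-based outputs
    and are only excluded from spatial stages).

    Returns a copy of ``premises`` with columns ``x``, ``y`` and
    ``provenance`` in {precise, centroid, unmappable} added.
    """
    out = premises.copy()
    cent = parishes.set_index("parish_id")[
        ["centroid_easting", "centroid_northing"]]
    have_xy = out["easting"].notna() & out["northing"].notna()
    out["x"] = out["easting"].where(have_xy)
    out["y"] = out["northing"].where(have_xy)
    out["provenance"] = np.where(have_xy, PROV_PRECISE, PROV_UNMAPPABLE)

    need = ~have_xy & out["parish_id"].notna() & out["parish_id"].isin(cent.index)
    if need.any():
        pid = out.loc[need, "parish_id"]
        out.loc[need, "x"] = cent.loc[pid, "centroid_easting"].to_numpy()
        out.loc[need, "y"] = cent.loc[pid, "centroid_northing"].to_numpy()
        out.loc[need, "provenance"] = PROV_CENTROID
    return out


def geography_report(resolved: pd.DataFrame) -> dict:
    """Data-quality summary of the geo-resolution step."""
    counts = resolved["provenance"].value_counts()
    n = len(resolved)
    return {
        "n_premises": int(n),
        "n_precise": int(counts.get(PROV_PRECISE, 0)),
        "n_centroid": int(counts.get(PROV_CENTROID, 0)),
        "n_unmappable": int(counts.get(PROV_UNMAPPABLE, 0)),
        "pct_without_precise_coords": round(
            100.0 * (n - counts.get(PROV_PRECISE, 0)) / n, 1) if n else None,
    }


# ---------------------------------------------------------------------------
# Movement classification


class OutOfScopeMovement(ValueError):
    """A movement with neither endpoint in Scotland: never part of a Scottish
    movement extract."""


def classify_movements(records: pd.DataFrame,
                       premises: pd.DataFrame) -> pd.Series:
    """Classify each movement as WITHIN / OUT_OF / INTO Scotland.

    Both endpoints must resolve in the registry.  A movement with neither
    endpoint Scottish raises :class:`OutOfScopeMovement`.
    """
    reg = registry_index(premises)
    dep_country = records["departure_cph"].map(reg["country"])
    dst_country = records["destination_cph"].map(reg["country"])
    unresolved = dep_country.isna() | dst_country.isna()
    if unresolved.any():
        bad = records.loc[unresolved, "record_id"].tolist()[:5]
        raise KeyError(f"unresolvable endpoint CPHs for records {bad}")
    dep_scot = dep_country == SCOTLAND
    dst_scot = dst_country == SCOTLAND
    neither = ~dep_scot & ~dst_scot
    if neither.any():
        bad = records.loc[neither, "record_id"].tolist()[:5]
        raise OutOfScopeMovement(
            f"records with neither endpoint in Scotland: {bad}")
    out = pd.Series(MovementClass.WITHIN.value, index=records.index,
                    name="movement_class")
    out[dep_scot & ~dst_scot] = MovementClass.OUT_OF.value
    out[~dep_scot & dst_scot] = MovementClass.INTO.value
    return out


def classify_movement(record: pd.Series, premises: pd.DataFrame) -> MovementClass:
    """Single-record convenience wrapper around :func:`classify_movements`."""
    cls = classify_movements(record.to_frame().T, premises)
    return MovementClass(cls.iloc[0])


# ---------------------------------------------------------------------------
# Annual summary (Table-1 style)

_CLASS_ORDER = [MovementClass.WITHIN.value, MovementClass.OUT_OF.value,
                MovementClass.INTO.value]


def annual_summary_from_counts(batch_counts: pd.DataFrame,
                               sheep_counts: pd.DataFrame,
                               premises_counts: pd.DataFrame | None = None,
                               batch_totals: pd.Series | None = None,
                               sheep_totals: pd.Series | None = None,
                               ) -> pd.DataFrame:
    """Build the annual summary table from already-tallied counts.

    ``batch_counts`` and ``sheep_counts`` are class-by-year tables (rows
    WITHIN/OUT_OF/INTO, columns years).  ``premises_counts`` optionally has
    rows ``total``/``within_scotland``.  Explicit ``batch_totals`` /
    ``sheep_totals`` override the computed class sums as the year totals —
    recorded annual totals can exceed the class partition when some records
    cannot be classified.  Output rows carry the raw count, the percentage
    of the year's total (1 decimal, mirroring the published layout), and a
    final ``mean`` column of across-year means.
    """
    years = list(batch_counts.columns)
    totals = {
        "batches": (batch_counts.sum(axis=0) if batch_totals is None
                    else pd.Series(batch_totals).reindex(years)),
        "sheep": (sheep_counts.sum(axis=0) if sheep_totals is None
                  else pd.Series(sheep_totals).reindex(years)),
    }
    rows: list[tuple[str, str, pd.Series]] = []

    def add_block(name: str, table: pd.DataFrame) -> None:
        rows.append((name, "total", totals[name]))
        for cls in _CLASS_ORDER:
            if cls in table.index:
                rows.append((name, cls, table.loc[cls]))

    if premises_counts is not None:
        for label in premises_counts.index:
            rows.append(("premises", str(label), premises_counts.loc[label]))
    add_block("batches", batch_counts)
    add_block("sheep", sheep_counts)

    records = []
    if premises_counts is not None and "total" in premises_counts.index:
        totals["premises"] = premises_counts.loc["total"]
    for block, label, series in rows:
        counts = series.reindex(years).astype(float)
        rec = {"block": block, "label": label}
        denom = totals.get(block)
        for y in years:
            rec[f"{y}"] = counts[y]
            if denom is not None and label != "total" and denom[y] > 0:
                rec[f"{y}_pct"] = round(100.0 * counts[y] / denom[y], 1)
        rec["mean"] = float(np.round(counts.mean(), 0))
        if denom is not None and label != "total":
            mean_total = float(denom.mean())
            if mean_total > 0:
                rec["mean_pct"] = round(100.0 * counts.mean() / mean_total, 1)
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index(["block", "label"])


def annual_summary(records: pd.DataFrame, premises: pd.DataFrame,
                   years: Sequence[int]) -> pd.DataFrame:
    """Tally movements by year and class and lay out the summary table.

    Per year: batch and sheep counts per movement class with percentages of
    the year's total, distinct premises counts (all, and located in
    Scotland), and a final across-year mean column.  Empty years contribute
    zeros rather than failing.
    """
    recs = records.copy()
    recs["movement_class"] = classify_movements(recs, premises)
    recs["year"] = recs["date"].dt.year
    recs = recs[recs["year"].isin(years)]

    batch = (recs.groupby(["movement_class", "year"]).size()
             .unstack("year", fill_value=0)
             .reindex(index=_CLASS_ORDER, columns=list(years), fill_value=0))
    sheep = (recs.groupby(["movement_class", "year"])["n_animals"].sum()
             .unstack("year", fill_value=0)
             .reindex(index=_CLASS_ORDER, columns=list(years), fill_value=0))

    reg = registry_index(premises)
    prem_rows = {}
    for y in years:
        sub = recs[recs["year"] == y]
        cphs = pd.unique(pd.concat([sub["departure_cph"],
                                    sub["destination_cph"]]))
        prem_rows.setdefault("total", {})[y] = len(cphs)
        countries = reg["country"].reindex(cphs)
        prem_rows.setdefault("within_scotland", {})[y] = int(
            (countries == SCOTLAND).sum())
    premises_counts = pd.DataFrame(prem_rows).T.reindex(columns=list(years))
    return annual_summary_from_counts(batch, sheep, premises_counts)


# ---------------------------------------------------------------------------
# Batch-vs-read discrepancy


def read_discrepancy(batch: pd.DataFrame, reads: pd.DataFrame) -> pd.DataFrame:
    """Per-year comparison of batch-recorded sheep against individual reads.

    Reports the relative excess of batch-recorded sheep over distinct read
    animals, the analogous batch-level excess (batch records vs batches with
    at least one read), and the share of batch sheep with no associated read
    records.  Years with zero reads report absent (NaN) excesses.
    """
    b = batch.copy()
    b["year"] = b["date"].dt.year
    r = reads.copy()
    r["date"] = pd.to_datetime(r["date"])
    r["year"] = r["date"].dt.year

    out = []
    for year, byear in b.groupby("year"):
        ryear = r[r["year"] == year]
        batch_sheep = int(byear["n_animals"].sum())
        batch_records = len(byear)
        read_animals = int(ryear["tag_id"].nunique())
        batches_with_reads = int(ryear["batch_ref"].nunique())
        # sheep in batch records with no read rows at all
        refs_with_reads = set(ryear["batch_ref"].dropna())
        no_read_mask = ~byear["record_id"].isin(refs_with_reads)
        reads_per_batch = ryear.groupby("batch_ref").size()
        matched = byear[~no_read_mask]
        covered = reads_per_batch.reindex(matched["record_id"]).fillna(0)
        batch_only_sheep = int(byear.loc[no_read_mask, "n_animals"].sum()) + int(
            np.maximum(matched["n_animals"].to_numpy() - covered.to_numpy(), 0).sum())
        out.append({
            "year": int(year),
            "batch_sheep": batch_sheep,
            "read_animals": read_animals,
            "sheep_excess_pct": (100.0 * (batch_sheep - read_animals) / read_animals
                                 if read_animals else np.nan),
            "batch_records": batch_records,
            "batches_with_reads": batches_with_reads,
            "batch_excess_pct": (100.0 * (batch_records - batches_with_reads)
                                 / batches_with_reads
                                 if batches_with_reads else np.nan),
            "batch_only_sheep_share": (batch_only_sheep / batch_sheep
                                       if batch_sheep else np.nan),
        })
    return pd.DataFrame(out).set_index("year")


def quarantine_unresolved(records: pd.DataFrame,
                          premises: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (resolvable, quarantined-with-reason).

    Records whose endpoints cannot be resolved in the registry are never
    silently dropped; they are returned with a ``reject_reason`` column so
    they can be written to a reject file and still counted.
    """
    reg = registry_index(premises)
    dep_ok = records["departure_cph"].isin(reg.index)
    dst_ok = records["destination_cph"].isin(reg.index)
    ok = dep_ok & dst_ok
    rejected = records[~ok].copy()
    reasons = np.where(~dep_ok[~ok], "unknown departure CPH",
                       "unknown destination CPH")
    rejected["reject_reason"] = reasons
    return records[ok].copy(), rejected
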
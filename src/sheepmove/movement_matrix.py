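"""Regional origin-destination matrices of non-slaughter sheep movements.

Within-country, non-slaughter movements are aggregated into a 14 x 14 matrix
of sheep counts between agricultural regions (departure rows, destination
columns; the diagonal holds intra-regional moves).  Two normalizations are
provided — each cell as a percentage of its departure row total, or of its
destination column total — together with quartile binning of the nonzero
counts for heat-map display, and per-quarter slices for seasonality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ingest_classify import (
    PTYPE_SLAUGHTERHOUSE,
    MovementClass,
    classify_movements,
    registry_index,
)

MODE_DEPARTURE = "departure"
MODE_DESTINATION = "destination"

BIN_NONE = "none"
QUARTILE_BINS = ("Q1", "Q2", "Q3", "Q4")


def build_matrix(records: pd.DataFrame, premises: pd.DataFrame,
                 regions: list[str] | None = None,
                 exclude_slaughter: bool = True,
                 ) -> pd.DataFrame:
    """Origin-destination sheep-count matrix of within-country moves.

    Cell (i, j) counts sheep moved from region i departures to region j
    destinations.  Only WITHIN-class movements enter; slaughter-destination
    moves are removed when ``exclude_slaughter`` (callers slice the input by
    year or quarter first).  Records whose endpoints carry no region are
    quarantined (returned via ``DataFrame.attrs['n_quarantined']``), never
    silently dropped from accounting.
    """
    reg = registry_index(premises)
    recs = records.copy()
    recs["movement_class"] = classify_movements(recs, premises)
    recs = recs[recs["movement_class"] == MovementClass.WITHIN.value]
    if exclude_slaughter:
        dst_type = recs["destination_cph"].map(reg["ptype"])
        recs = recs[dst_type != PTYPE_SLAUGHTERHOUSE]

    dep_region = recs["departure_cph"].map(reg["region"])
    dst_region = recs["destination_cph"].map(reg["region"])
    missing = dep_region.isna() | dst_region.isna()
    n_quarantined = int(missing.sum())
    recs, dep_region, dst_region = (recs[~missing], dep_region[~missing],
                                    dst_region[~missing])

    if regions is None:
        regions = sorted(set(dep_region) | set(dst_region))
    matrix = (pd.crosstab(dep_region, dst_region,
                          values=recs["n_animals"], aggfunc="sum")
              .reindex(index=regions, columns=regions, fill_value=0)
              .fillna(0).astype(int))
    matrix.index.name = "departure_region"
    matrix.columns.name = "destination_region"
    matrix.attrs["n_quarantined"] = n_quarantined
    return matrix


def normalize(matrix: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Percentage matrix by departure-row or destination-column totals.

    Rows (mode=departure) or columns (mode=destination) sum to 100; rows or
    columns with a zero total are reported absent (NaN) rather than divided.
    """
    if mode == MODE_DEPARTURE:
        totals = matrix.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = matrix.div(totals.where(totals > 0), axis=0) * 100.0
    elif mode == MODE_DESTINATION:
        totals = matrix.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = matrix.div(totals.where(totals > 0), axis=1) * 100.0
    else:
        raise ValueError(f"mode must be 'departure' or 'destination', "
                         f"got {mode!r}")
    return out


def quartile_bins(matrix: pd.DataFrame
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    """Categorize nonzero matrix cells into quartiles of their distribution.

    Zeros form a distinct ``none`` category.  Quartile boundaries are the
    empirical 0.25/0.5/0.75 quantiles of the nonzero entries (linear
    interpolation); bins are half-open (lower, upper] so every value lands
    in exactly one bin.  Returns ``(categorical matrix, boundaries)`` where
    boundaries are the three interior quantiles.
    """
    values = matrix.to_numpy(dtype=float)
    nonzero = values[values > 0]
    cats = np.full(values.shape, BIN_NONE, dtype=object)
    if nonzero.size:
        q = np.quantile(nonzero, [0.25, 0.5, 0.75])
        # half-open bins (lower, upper]: Q1 = (0, q25], ... Q4 = (q75, max]
        edges = np.concatenate([[0.0], q, [np.inf]])
        idx = np.searchsorted(edges, values, side="left") - 1
        idx = np.clip(idx, 0, 3)
        for k, name in enumerate(QUARTILE_BINS):
            cats[(values > 0) & (idx == k)] = name
    else:
        q = np.array([np.nan, np.nan, np.nan])
    out = pd.DataFrame(cats, index=matrix.index, columns=matrix.columns)
    return out, q


def quarterly_matrices(records: pd.DataFrame, premises: pd.DataFrame,
                       year: int, regions: list[str] | None = None,
                       exclude_slaughter: bool = True
                       ) -> dict[int, pd.DataFrame]:
    """One origin-destination matrix per calendar quarter of ``year``.

    The four quarterly matrices sum (cell-wise) to the annual matrix built
    from the same records.
    """
    recs = records[records["date"].dt.year == year]
    out = {}
    for q in (1, 2, 3, 4):
        sub = recs[recs["date"].dt.quarter == q]
        out[q] = build_matrix(sub, premises, regions=regions,
                              exclude_slaughter=exclude_slaughter)
    return out


def matrix_long_format(matrix: pd.DataFrame, period: str) -> pd.DataFrame:
    """Long-format export: one row per region pair with both normalizations
    and the quartile bin."""
    pct_dep = normalize(matrix, MODE_DEPARTURE)
    pct_dst = normalize(matrix, MODE_DESTINATION)
    bins, _ = quartile_bins(matrix)
    rows = []
    for dep in matrix.index:
        for dst in matrix.columns:
            rows.append({
                "departure": dep, "destination": dst, "period": period,
                "sheep": int(matrix.loc[dep, dst]),
                "pct_departure": pct_dep.loc[dep, dst],
                "pct_destination": pct_dst.loc[dep, dst],
                "quartile_bin": bins.loc[dep, dst],
            })
    return pd.DataFrame(rows)
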
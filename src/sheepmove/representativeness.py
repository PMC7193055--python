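"""Survey-coverage assessment of a slaughterhouse catchment area.

Given the holdings sampled by a slaughterhouse-based survey and the holdings
that make up the slaughterhouse's catchment, each hexagonal grid cell of the
catchment is scored with a chi-square statistic (O - E)^2 / E, where E is the
number of sampled holdings the cell would receive if the sample had been
allocated proportionately to the spatial distribution of supplying holdings.
Cells with a statistic at or below a cut-off (default 2, a pragmatic
significance point for a large-df chi-square treated as approximately
normal) are deemed adequately sampled; unsampled and over-represented cells
are reported separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ingest_classify import SCOTLAND, registry_index

CAT_NOT_SAMPLED = "not_sampled"
CAT_ADEQUATE = "adequate"
CAT_OVERSAMPLED = "oversampled"
CAT_UNDERSAMPLED = "undersampled"


def expected_counts(catchment_holdings_per_cell: pd.Series,
                    n_sampled_total: int) -> pd.Series:
    """Expected sampled holdings per cell under proportional allocation.

    E_i = n * h_i / sum(h); the expectations sum to ``n_sampled_total``
    exactly (up to floating tolerance).
    """
    h = pd.Series(catchment_holdings_per_cell, dtype=float)
    total = h.sum()
    if total <= 0:
        raise ValueError("catchment has no holdings: cannot allocate "
                         "expected counts")
    if n_sampled_total <= 0:
        raise ValueError("n_sampled_total must be positive")
    return n_sampled_total * h / total


def categorize_cells(observed: pd.Series, expected: pd.Series,
                     threshold: float = 2.0,
                     merge_undersampled: bool = False) -> pd.DataFrame:
    """Per-cell chi-square statistic and sampling category.

    Categories: observed 0 -> ``not_sampled``; chi2 <= threshold ->
    ``adequate``; above threshold with O > E -> ``oversampled``, with O < E
    -> ``undersampled``.  ``merge_undersampled`` folds undersampled into
    oversampled, giving the two-way adequate-vs-over scheme some surveys
    report.  A cell with E = 0 but O > 0 has an undefined statistic; it is
    categorized oversampled by convention and flagged.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    obs = pd.Series(observed, dtype=float)
    exp = pd.Series(expected, dtype=float).reindex(obs.index)
    if exp.isna().any():
        raise ValueError("observed and expected must align by cell")

    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (obs - exp) ** 2 / exp
    undefined = (exp == 0) & (obs > 0)
    chi2 = chi2.where(~undefined)

    category = pd.Series(CAT_ADEQUATE, index=obs.index, dtype=object)
    category[(obs == 0) & (exp > 0)] = CAT_NOT_SAMPLED
    over = (obs > 0) & (chi2 > threshold) & (obs > exp)
    under = (obs > 0) & (chi2 > threshold) & (obs < exp)
    category[over] = CAT_OVERSAMPLED
    category[under] = (CAT_OVERSAMPLED if merge_undersampled
                       else CAT_UNDERSAMPLED)
    category[undefined] = CAT_OVERSAMPLED

    return pd.DataFrame({
        "observed": obs, "expected": exp, "chi2": chi2,
        "category": category, "chi2_undefined": undefined,
    })


def coverage_summary(cells: pd.DataFrame) -> pd.DataFrame:
    """Percentage of catchment cells per sampling category (sums to 100)."""
    counts = cells["category"].value_counts()
    n = len(cells)
    order = [CAT_ADEQUATE, CAT_NOT_SAMPLED, CAT_OVERSAMPLED, CAT_UNDERSAMPLED]
    rows = [{"category": c, "n_cells": int(counts.get(c, 0)),
             "pct_of_cells": 100.0 * counts.get(c, 0) / n if n else np.nan}
            for c in order if c in counts or c in order[:3]]
    return pd.DataFrame(rows).set_index("category")


def sample_ingest(samples: pd.DataFrame,
                  premises: pd.DataFrame) -> dict:
    """Distinct-holding counts and exclusions from a sampled-specimen table.

    ``samples`` columns: sample_id, holding_cph, date.  Samples without a
    CPH are excluded and counted; holdings resolving outside the study
    country are excluded and counted.  Returns per-holding sample counts and
    a multiplicity summary (min/quartiles/mean/max).
    """
    reg = registry_index(premises)
    s = samples.copy()
    no_cph = s["holding_cph"].isna() | (s["holding_cph"].astype(str).str.strip()
                                        == "")
    s = s[~no_cph]
    country = s["holding_cph"].map(reg["country"])
    outside = country.notna() & (country != SCOTLAND)
    excluded_outside = s.loc[outside, "holding_cph"].nunique()
    s = s[~outside]

    per_holding = s.groupby("holding_cph").size().rename("n_samples")
    mult = per_holding.describe()
    return {
        "n_samples": int(len(samples)),
        "n_samples_no_cph": int(no_cph.sum()),
        "n_holdings_outside_country": int(excluded_outside),
        "n_holdings": int(per_holding.size),
        "per_holding_counts": per_holding,
        "multiplicity": {
            "min": float(mult["min"]) if len(per_holding) else np.nan,
            "q1": float(per_holding.quantile(0.25)) if len(per_holding) else np.nan,
            "median": float(per_holding.median()) if len(per_holding) else np.nan,
            "mean": float(per_holding.mean()) if len(per_holding) else np.nan,
            "q3": float(per_holding.quantile(0.75)) if len(per_holding) else np.nan,
            "max": float(mult["max"]) if len(per_holding) else np.nan,
        },
    }


def assess_representativeness(catchment_holdings_per_cell: pd.Series,
                              sampled_holdings_per_cell: pd.Series,
                              threshold: float = 2.0,
                              merge_undersampled: bool = False
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end coverage assessment of a catchment.

    Only cells with at least one supplying holding (the catchment cells)
    are categorized; cells outside the catchment are never scored.  Returns
    ``(per_cell_table, summary)``.
    """
    h = pd.Series(catchment_holdings_per_cell, dtype=float)
    h = h[h > 0]
    obs = (pd.Series(sampled_holdings_per_cell, dtype=float)
           .reindex(h.index, fill_value=0.0))
    exp = expected_counts(h, int(obs.sum())) if obs.sum() > 0 else h * 0.0
    if obs.sum() == 0:
        cells = pd.DataFrame({"observed": obs, "expected": exp,
                              "chi2": np.nan, "category": CAT_NOT_SAMPLED,
                              "chi2_undefined": False})
    else:
        cells = categorize_cells(obs, exp, threshold=threshold,
                                 merge_undersampled=merge_undersampled)
    return cells, coverage_summary(cells)
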
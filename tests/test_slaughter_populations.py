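import numpy as np
import pandas as pd
import pytest

import sheepmove as sm
from sheepmove.slaughter_populations import (
    MATCH_COUNT,
    MATCH_EID,
    POP_POP4,
    POP_SISP,
    POP_SOSP,
)


def _registry():
    return pd.DataFrame({
        "cph": ["1/1/1", "1/1/2", "55/1/1", "50/1/1", "95/1/1", "91/1/1"],
        "ptype": ["farm", "farm", "market", "slaughterhouse",
                  "slaughterhouse", "farm"],
        "country": ["Scotland", "Scotland", "Scotland", "Scotland",
                    "rest-of-GB", "rest-of-GB"],
        "region": ["Highland", "Grampian", "Fife", "Fife", None, None],
        "parish_id": ["P1", "P2", "P3", "P3", None, None],
        "easting": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "northing": [1.0] * 6,
    })


def _rec(rid, dep, read, dst, date, n, n_reads=0):
    return {"record_id": rid, "departure_cph": dep, "read_cph": read,
            "destination_cph": dst, "date": pd.Timestamp(date),
            "n_animals": n, "n_reads": n_reads}


_EMPTY_READS = pd.DataFrame(columns=["tag_id", "ccp_cph", "date", "batch_ref"])


class TestIdentifySlaughterMoves:
    def test_only_slaughterhouse_destinations(self):
        recs = pd.DataFrame([
            _rec("a", "1/1/1", None, "50/1/1", "2017-05-01", 10),
            _rec("b", "1/1/1", None, "55/1/1", "2017-05-01", 10),  # market
            _rec("c", "1/1/1", None, "1/1/2", "2017-05-01", 10),   # farm
        ])
        out = sm.identify_slaughter_moves(recs, _registry())
        assert list(out["record_id"]) == ["a"]

    def test_empty_input(self):
        out = sm.identify_slaughter_moves(
            pd.DataFrame(columns=["record_id", "departure_cph", "read_cph",
                                  "destination_cph", "date", "n_animals",
                                  "n_reads"]), _registry())
        assert out.empty


class TestDedup:
    def test_dual_record_pattern_removed_once(self):
        # farm -> [market] -> abattoir plus market -> abattoir, equal heads
        recs = pd.DataFrame([
            _rec("r1", "1/1/1", "55/1/1", "50/1/1", "2017-05-01", 40),
            _rec("r2", "55/1/1", "50/1/1", "50/1/1", "2017-05-01", 40),
        ])
        result = sm.deduplicate_market_legs(recs, _EMPTY_READS, _registry())
        assert list(result.kept["record_id"]) == ["r1"]
        assert result.removed["match_basis"].iloc[0] == MATCH_COUNT
        assert result.kept["n_animals"].sum() == 40

    def test_eid_overlap_beats_count_equality(self):
        recs = pd.DataFrame([
            _rec("r1", "1/1/1", "55/1/1", "50/1/1", "2017-05-01", 40),
            _rec("r2", "55/1/1", "50/1/1", "50/1/1", "2017-05-01", 40),
        ])
        reads = pd.DataFrame({
            "tag_id": ["UK1", "UK1"], "ccp_cph": ["55/1/1", "50/1/1"],
            "date": [pd.Timestamp("2017-05-01")] * 2,
            "batch_ref": ["r1", "r2"],
        })
        result = sm.deduplicate_market_legs(recs, reads, _registry())
        assert result.removed["match_basis"].iloc[0] == MATCH_EID

    def test_direct_move_is_kept(self):
        recs = pd.DataFrame([
            _rec("r1", "1/1/1", "50/1/1", "50/1/1", "2017-05-01", 12),
        ])
        result = sm.deduplicate_market_legs(recs, _EMPTY_READS, _registry())
        assert len(result.kept) == 1 and result.removed.empty

    def test_outside_window_not_matched(self):
        recs = pd.DataFrame([
            _rec("r1", "1/1/1", "55/1/1", "50/1/1", "2017-05-01", 40),
            _rec("r2", "55/1/1", "50/1/1", "50/1/1", "2017-05-10", 40),
        ])
        result = sm.deduplicate_market_legs(recs, _EMPTY_READS, _registry(),
                                            window_days=1)
        assert result.removed.empty

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError, match="window_days"):
            sm.deduplicate_market_legs(
                pd.DataFrame(columns=["record_id", "departure_cph",
                                      "read_cph", "destination_cph", "date",
                                      "n_animals", "n_reads"]),
                _EMPTY_READS, _registry(), window_days=-1)

    def test_idempotent(self, small_dataset):
        premises, _, _, batch, reads, _ = small_dataset
        sl = sm.identify_slaughter_moves(batch, premises)
        once = sm.deduplicate_market_legs(sl, reads, premises)
        twice = sm.deduplicate_market_legs(once.kept, reads, premises)
        assert twice.removed.empty
        assert list(twice.kept["record_id"]) == list(once.kept["record_id"])

    def test_matches_ground_truth_without_misreads(self, clean_dataset):
        premises, _, _, batch, reads, truth = clean_dataset
        sl = sm.identify_slaughter_moves(batch, premises)
        result = sm.deduplicate_market_legs(sl, reads, premises)
        removed = set(zip(result.removed["matched_first_leg_record_id"],
                          result.removed["market_leg_record_id"]))
        assert removed == truth.duplicated_record_pairs
        kept = result.kept.copy()
        kept["year"] = kept["date"].dt.year
        totals = kept.groupby(["destination_cph", "year"])["n_animals"].sum()
        assert {k: int(v) for k, v in totals.items()} == \
            truth.true_slaughter_count


class TestPopulations:
    @pytest.mark.parametrize("dep,dst,expected", [
        ("1/1/1", "50/1/1", POP_SISP),   # Scottish farm -> Scottish abattoir
        ("1/1/1", "95/1/1", POP_SOSP),   # Scottish farm -> English abattoir
        ("91/1/1", "50/1/1", POP_POP4),  # English farm -> Scottish abattoir
    ])
    def test_population_assignment(self, dep, dst, expected):
        recs = pd.DataFrame([_rec("r", dep, None, dst, "2017-05-01", 5)])
        assert sm.classify_population(recs, _registry()).iloc[0] == expected

    def test_neither_endpoint_scottish_rejected(self):
        recs = pd.DataFrame([_rec("r", "91/1/1", None, "95/1/1",
                                  "2017-05-01", 5)])
        with pytest.raises(ValueError, match="out-of-scope"):
            sm.classify_population(recs, _registry())

    def test_summary_percentages(self):
        counts = pd.DataFrame(
            {2015: [1_107_763, 1_146_499]},
            index=[POP_SISP, POP_SOSP])
        census = pd.Series({2015: 6_701_376})
        table = sm.population_summary_from_counts(counts, census)
        assert table.loc[2015, "sssp_sheep"] == 2_254_262
        assert table.loc[2015, "sssp_pct_of_census"] == 33.6
        assert table.loc[2015, "sisp_pct_of_sssp"] == 49.1
        # SISP + SOSP partition SSSP
        assert (table.loc[2015, "sisp_sheep"] + table.loc[2015, "sosp_sheep"]
                == table.loc[2015, "sssp_sheep"])
        assert (table.loc[2015, "sisp_pct_of_sssp"]
                + table.loc[2015, "sosp_pct_of_sssp"]) == pytest.approx(
                    100.0, abs=0.1)

    def test_missing_census_year_reports_absent(self):
        counts = pd.DataFrame({2017: [10, 10]}, index=[POP_SISP, POP_SOSP])
        table = sm.population_summary_from_counts(counts, pd.Series(dtype=float))
        assert np.isnan(table.loc[2017, "sssp_pct_of_census"])


class TestRanking:
    def _deduped(self):
        rows = []
        shares = {"50/1/1": 40, "50/1/2": 15}
        reg = _registry().copy()
        reg = pd.concat([reg, pd.DataFrame({
            "cph": ["50/1/2"], "ptype": ["slaughterhouse"],
            "country": ["Scotland"], "region": ["Fife"],
            "parish_id": ["P3"], "easting": [9.0], "northing": [1.0]})],
            ignore_index=True)
        for sh, n in shares.items():
            rows.append(_rec(f"r{sh}", "1/1/1", None, sh, "2017-05-01", n))
        return pd.DataFrame(rows), reg

    def test_descending_order_and_shares(self):
        recs, reg = self._deduped()
        ranking = sm.rank_slaughterhouses(recs, reg, 2017, by="sheep")
        assert list(ranking["slaughterhouse_cph"]) == ["50/1/1", "50/1/2"]
        assert ranking["share_pct"].iloc[0] == pytest.approx(100 * 40 / 55)
        assert ranking["cumulative_share_pct"].iloc[-1] == pytest.approx(100.0)

    def test_unknown_year_empty(self):
        recs, reg = self._deduped()
        assert sm.rank_slaughterhouses(recs, reg, 1999).empty

    def test_sheep_vs_batch_ranking_can_invert(self):
        # many small batches to one abattoir, few large to another
        reg = self._deduped()[1]
        rows = [_rec(f"s{i}", "1/1/1", None, "50/1/1", "2017-05-01", 2)
                for i in range(10)]
        rows.append(_rec("big", "1/1/1", None, "50/1/2", "2017-05-01", 100))
        recs = pd.DataFrame(rows)
        by_sheep = sm.rank_slaughterhouses(recs, reg, 2017, by="sheep")
        by_batches = sm.rank_slaughterhouses(recs, reg, 2017, by="batches")
        assert by_sheep["slaughterhouse_cph"].iloc[0] == "50/1/2"
        assert by_batches["slaughterhouse_cph"].iloc[0] == "50/1/1"


class TestSupplierOverlap:
    def test_both_category_and_shares_sum(self):
        recs = pd.DataFrame([
            _rec("a", "1/1/1", None, "50/1/1", "2017-05-01", 5),
            _rec("b", "1/1/1", None, "95/1/1", "2017-06-01", 5),
            _rec("c", "1/1/2", None, "50/1/1", "2017-06-01", 5),
        ])
        table = sm.supplier_overlap(recs, _registry())
        assert table.loc["pooled", "both"] == 1
        assert table.loc["pooled", "scotland_only"] == 1
        shares = table.loc["pooled", ["scotland_only_pct",
                                      "rest_of_gb_only_pct", "both_pct"]]
        assert shares.sum() == pytest.approx(100.0, abs=0.1)

    def test_against_ground_truth_supply(self, clean_dataset):
        premises, _, _, batch, reads, truth = clean_dataset
        sl = sm.identify_slaughter_moves(batch, premises)
        dd = sm.deduplicate_market_legs(sl, reads, premises)
        table = sm.supplier_overlap(dd.kept, premises)
        # truth: holding -> set of slaughterhouse countries
        reg = premises.set_index("cph")
        seen = {}
        for (h, s, y, q) in truth.per_holding_supply:
            if reg.loc[h, "country"] != "Scotland":
                continue
            seen.setdefault(h, set()).add(reg.loc[s, "country"])
        n_both = sum(1 for v in seen.values() if len(v) == 2)
        n_scot = sum(1 for v in seen.values() if v == {"Scotland"})
        assert table.loc["pooled", "both"] == n_both
        assert table.loc["pooled", "scotland_only"] == n_scot


class TestMonthlySeries:
    def test_single_month_carries_all(self):
        recs = pd.DataFrame([_rec("a", "1/1/1", None, "1/1/2",
                                  "2017-09-15", 30)])
        series = sm.monthly_series(recs)
        assert series.loc[2017, 9] == 30
        assert series.loc[2017].sum() == 30

    def test_monthly_sums_match_annual_total(self, small_dataset):
        _, _, _, batch, _, _ = small_dataset
        series = sm.monthly_series(batch)
        for year, group in batch.groupby(batch["date"].dt.year):
            assert series.loc[year].sum() == group["n_animals"].sum()

    def test_september_argmax_on_default_profile(self, small_dataset):
        _, _, _, batch, _, _ = small_dataset
        series = sm.monthly_series(batch)
        assert series.sum(axis=0).idxmax() == 9
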
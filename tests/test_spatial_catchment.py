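import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Point, Polygon

import sheepmove as sm
from sheepmove.spatial_catchment import FLAT_TOP, OUTSIDE_GRID, POINTY_TOP


def brute_force_assign(points, grid):
    """O(points x cells) containment oracle: lowest incident cell id."""
    polys = grid.polygons()
    out = np.full(len(points), OUTSIDE_GRID, dtype=int)
    pts = [Point(x, y) for x, y in points]
    for cid, poly in sorted(zip(grid.cell_ids, polys), reverse=True):
        mask = shapely.covers(poly, pts)
        out[mask] = cid  # later (lower) ids overwrite, giving the minimum
    return out


class TestGridConstruction:
    def test_circumradius_closed_form(self):
        r = sm.circumradius_for_area(115.0)
        assert r == pytest.approx(np.sqrt(2 * 115e6 / (3 * np.sqrt(3))))
        assert r == pytest.approx(6653, abs=1)

    def test_cell_area_exact(self):
        grid = sm.build_hex_grid((0, 0, 50000, 50000), 115.0)
        for poly in grid.polygons()[:10]:
            assert poly.area == pytest.approx(115e6, rel=1e-6)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sm.build_hex_grid((0, 0, 1000, 1000), 0.0)

    def test_tiny_extent_still_covered(self):
        grid = sm.build_hex_grid((0, 0, 100, 100), 115.0)
        assert len(grid) >= 1
        assert (sm.assign_points(np.array([[50.0, 50.0]]), grid)[0]
                != OUTSIDE_GRID)

    def test_union_covers_extent(self):
        grid = sm.build_hex_grid((0, 0, 30000, 30000), 115.0)
        union = shapely.unary_union(grid.polygons())
        assert union.area >= 30000 * 30000
        uncovered = shapely.box(0, 0, 30000, 30000).difference(union)
        assert uncovered.area < 1e-6  # m^2; floating slivers only

    def test_clip_polygon_drops_outside_cells(self):
        full = sm.build_hex_grid((0, 0, 60000, 60000), 115.0)
        clipped = sm.build_hex_grid((0, 0, 60000, 60000), 115.0,
                                    clip_polygon=shapely.box(0, 0, 20000,
                                                             20000))
        assert 0 < len(clipped) < len(full)


class TestAssignPoints:
    @pytest.mark.parametrize("orientation", [FLAT_TOP, POINTY_TOP])
    def test_agrees_with_brute_force(self, orientation):
        grid = sm.build_hex_grid((0, 0, 60000, 60000), 115.0,
                                 orientation=orientation)
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 60000, size=(2000, 2))
        fast = sm.assign_points(pts, grid)
        slow = brute_force_assign(pts, grid)
        assert (fast == slow).all()

    def test_cell_center_maps_to_itself(self):
        grid = sm.build_hex_grid((0, 0, 40000, 40000), 115.0)
        ids = sm.assign_points(grid.centers, grid)
        assert (ids == grid.cell_ids).all()

    def test_shared_edge_midpoint_takes_lowest_id(self):
        grid = sm.build_hex_grid((0, 0, 40000, 40000), 115.0)
        # adjacent cells in the same column are sqrt(3) R apart vertically
        c0 = grid.centers[0]
        neighbour_offsets = grid.centers - c0
        d = np.hypot(*neighbour_offsets.T)
        j = np.argsort(d)[1]
        mid = (c0 + grid.centers[j]) / 2.0
        got = sm.assign_points(mid.reshape(1, 2), grid)[0]
        assert got == min(grid.cell_ids[0], grid.cell_ids[j])

    def test_assignment_is_a_function_and_totals_conserved(self):
        grid = sm.build_hex_grid((0, 0, 50000, 50000), 115.0)
        rng = np.random.default_rng(8)
        pts = rng.uniform(-10000, 60000, size=(10000, 2))
        ids = sm.assign_points(pts, grid)
        inside = ids != OUTSIDE_GRID
        assert inside.sum() + (~inside).sum() == 10000
        # within the extent every point lands in exactly one cell
        in_extent = ((pts[:, 0] >= 0) & (pts[:, 0] <= 50000)
                     & (pts[:, 1] >= 0) & (pts[:, 1] <= 50000))
        assert (ids[in_extent] != OUTSIDE_GRID).all()

    def test_translation_invariance(self):
        rng = np.random.default_rng(15)
        pts = rng.uniform(0, 30000, size=(500, 2))
        grid_a = sm.build_hex_grid((0, 0, 30000, 30000), 115.0)
        shift = np.array([123456.0, -98765.0])
        grid_b = sm.build_hex_grid((shift[0], shift[1], 30000 + shift[0],
                                    30000 + shift[1]), 115.0)
        counts_a = np.bincount(sm.assign_points(pts, grid_a) + 1)
        counts_b = np.bincount(sm.assign_points(pts + shift, grid_b) + 1)
        assert sorted(counts_a[counts_a > 0]) == sorted(counts_b[counts_b > 0])

    def test_nan_points_flagged_outside(self):
        grid = sm.build_hex_grid((0, 0, 30000, 30000), 115.0)
        ids = sm.assign_points(np.array([[np.nan, 5.0], [5.0, 5.0]]), grid)
        assert ids[0] == OUTSIDE_GRID and ids[1] != OUTSIDE_GRID


class TestParishDensity:
    def test_density_definition(self):
        census = pd.DataFrame({"year": [2017, 2017], "parish_id": ["P1", "P2"],
                               "region": ["A", "A"], "n_sheep": [800, 0]})
        parishes = pd.DataFrame({"parish_id": ["P1", "P2"],
                                 "region": ["A", "A"],
                                 "area_ha": [400.0, 100.0],
                                 "centroid_easting": [0.0, 0.0],
                                 "centroid_northing": [0.0, 0.0]})
        table = sm.parish_density(census, parishes)
        assert table.loc[0, "density_sheep_per_ha"] == pytest.approx(2.0)
        assert table.loc[1, "density_sheep_per_ha"] == 0.0

    def test_zero_area_warns_and_reports_absent(self):
        census = pd.DataFrame({"year": [2017], "parish_id": ["P1"],
                               "region": ["A"], "n_sheep": [10]})
        parishes = pd.DataFrame({"parish_id": ["P1"], "region": ["A"],
                                 "area_ha": [0.0],
                                 "centroid_easting": [0.0],
                                 "centroid_northing": [0.0]})
        with pytest.warns(UserWarning, match="area"):
            table = sm.parish_density(census, parishes)
        assert np.isnan(table.loc[0, "density_sheep_per_ha"])

    def test_density_range_on_synthetic_census(self, small_dataset):
        _, parishes, census, _, _, _ = small_dataset
        table = sm.parish_density(census, parishes)
        dens = table["density_sheep_per_ha"].dropna()
        assert (dens >= 0).all() and dens.max() <= 8.5


@pytest.fixture(scope="module")
def catchment_setup():
    cfg = sm.SimConfig(moves_per_year=1500, years=(2017,), seed=17)
    premises, parishes, census, batch, reads, truth = sm.generate_dataset(cfg)
    sl = sm.identify_slaughter_moves(batch, premises)
    deduped = sm.deduplicate_market_legs(sl, reads, premises).kept
    grid = sm.build_hex_grid(cfg.extent, 115.0)
    return cfg, premises, parishes, deduped, truth, grid


class TestCatchment:
    def test_unknown_slaughterhouse_rejected(self, catchment_setup):
        _, premises, parishes, deduped, _, grid = catchment_setup
        with pytest.raises(KeyError, match="unknown slaughterhouse"):
            sm.compute_catchment("0/0/0", deduped, premises, parishes,
                                 grid, 2017)

    def test_cell_percentage_arithmetic(self, catchment_setup):
        _, premises, parishes, deduped, _, grid = catchment_setup
        sh = deduped["destination_cph"].iloc[0]
        if premises.set_index("cph").loc[sh, "country"] != "Scotland":
            sh = [s for s in deduped["destination_cph"]
                  if premises.set_index("cph").loc[s, "country"]
                  == "Scotland"][0]
        catch = sm.compute_catchment(sh, deduped, premises, parishes,
                                     grid, 2017, reference="SISP")
        pct = catch.cells["pct_of_reference"]
        np.testing.assert_allclose(
            pct, 100.0 * catch.cells["n_sheep"] / catch.reference_total)

    def test_conservation_and_nesting(self, catchment_setup):
        _, premises, parishes, deduped, _, grid = catchment_setup
        reg = premises.set_index("cph")
        pops = sm.classify_population(deduped, premises)
        sisp = deduped[pops == "SISP"]
        for sh in sisp["destination_cph"].unique()[:3]:
            catch = sm.compute_catchment(sh, deduped, premises, parishes,
                                         grid, 2017, reference="SISP")
            throughput = sisp.loc[sisp["destination_cph"] == sh,
                                  "n_animals"].sum()
            assert (catch.cells["n_sheep"].sum() + catch.unmappable_sheep
                    == throughput)
            assert catch.cells["n_sheep"].sum() <= catch.reference_total

    def test_per_cell_sheep_matches_truth_supply(self, catchment_setup):
        cfg, premises, parishes, deduped, truth, grid = catchment_setup
        resolved = sm.resolve_locations(premises, parishes).set_index("cph")
        reg = premises.set_index("cph")
        sh = next(s for (h, s, y, q) in truth.per_holding_supply
                  if reg.loc[s, "country"] == "Scotland"
                  and reg.loc[h, "country"] == "Scotland")
        catch = sm.compute_catchment(sh, deduped, premises, parishes,
                                     grid, 2017, reference="SISP")
        # aggregate ground truth through the same point assignment
        expected: dict[int, int] = {}
        for (h, s, y, q), v in truth.per_holding_supply.items():
            if s != sh or y != 2017 or reg.loc[h, "country"] != "Scotland":
                continue
            xy = resolved.loc[h, ["x", "y"]].to_numpy(float)
            cid = sm.assign_points(xy.reshape(1, 2), grid)[0]
            if cid != OUTSIDE_GRID:
                expected[cid] = expected.get(cid, 0) + v
        got = dict(zip(catch.cells["cell_id"], catch.cells["n_sheep"]))
        assert got == expected


class TestQuarterlyCatchment:
    def test_layers_sum_to_100_of_mappable(self, catchment_setup):
        _, premises, parishes, deduped, _, grid = catchment_setup
        pops = sm.classify_population(deduped, premises)
        sh = deduped[pops == "SISP"]["destination_cph"].iloc[0]
        layers = sm.quarterly_catchment(sh, deduped, premises, parishes,
                                        grid, 2017)
        total = sum(layer["pct_of_annual"].sum() for layer in layers.values())
        assert total == pytest.approx(100.0, abs=0.1)

    def test_region_quarter_gating(self):
        cfg = sm.SimConfig(moves_per_year=1500, years=(2017,), seed=19,
                           quarter_gate={"Shetland": 3},
                           p_missing_coords=0.0)
        premises, parishes, _, batch, reads, _ = sm.generate_dataset(cfg)
        sl = sm.identify_slaughter_moves(batch, premises)
        deduped = sm.deduplicate_market_legs(sl, reads, premises).kept
        reg = premises.set_index("cph")
        dep_region = deduped["departure_cph"].map(reg["region"])
        gated = deduped[dep_region == "Shetland"]
        assert len(gated) > 0
        assert (gated["date"].dt.quarter == 3).all()


def test_geojson_round_trip(tmp_path):
    grid = sm.build_hex_grid((0, 0, 20000, 20000), 115.0)
    values = pd.DataFrame({"cell_id": grid.cell_ids[:2],
                           "n_sheep": [5, 7]})
    gj = sm.grid_to_geojson(grid, values)
    assert gj["type"] == "FeatureCollection"
    assert len(gj["features"]) == len(grid)
    assert gj["metadata"]["cell_area_km2"] == 115.0
    props = {f["properties"]["cell_id"]: f["properties"]
             for f in gj["features"]}
    assert props[int(grid.cell_ids[0])]["n_sheep"] == 5
    import json
    sm.write_geojson(tmp_path / "g.geojson", gj)
    assert json.loads((tmp_path / "g.geojson").read_text()) == gj
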
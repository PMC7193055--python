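"""Fixed-area hexagonal tessellation, point binning and catchment areas.

Holdings are plotted on a planar national grid (precise coordinates where
known, parish centroids otherwise) and aggregated into a tessellation of
congruent hexagons of a configurable area (115 km^2 by default, a cell size
commonly used for national livestock density maps).  A slaughterhouse's
catchment area is the spatial distribution of the holdings from which it
receives its annual throughput; cells carry holding counts, sheep counts and
each cell's percentage of a reference slaughter population.

A hexagonal tessellation is the Voronoi diagram of its cell centers, so
point-in-cell assignment reduces to a nearest-center query (KD-tree) plus an
exact point-in-hexagon check for points beyond the grid edge.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .ingest_classify import (
    PROV_UNMAPPABLE,
    registry_index,
    resolve_locations,
)
from .slaughter_populations import POP_SISP, POP_SOSP, classify_population

FLAT_TOP = "flat-top"
POINTY_TOP = "pointy-top"

OUTSIDE_GRID = -1


def circumradius_for_area(cell_area_km2: float) -> float:
    """Circumradius R (meters) of a regular hexagon of the given area.

    area = (3*sqrt(3)/2) * R^2, so R = sqrt(2*area / (3*sqrt(3))).
    """
    if cell_area_km2 <= 0:
        raise ValueError(f"cell area must be positive, got {cell_area_km2}")
    area_m2 = cell_area_km2 * 1e6
    return float(np.sqrt(2.0 * area_m2 / (3.0 * np.sqrt(3.0))))


@dataclass
class HexGrid:
    """Congruent-hexagon tessellation covering a rectangular extent.

    Cells are identified by consecutive integer ids in construction order;
    ``centers[i]`` is the center of cell id ``i``.  All cells share one
    circumradius ``r`` so every cell has area ``cell_area_km2`` exactly.
    """

    cell_area_km2: float
    orientation: str
    origin: tuple[float, float]
    extent: tuple[float, float, float, float]
    r: float
    centers: np.ndarray  # (n_cells, 2)
    cell_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.cell_ids is None:
            self.cell_ids = np.arange(len(self.centers))
        self._tree = cKDTree(self.centers)

    def __len__(self) -> int:
        return len(self.centers)

    def cell_polygon(self, cell_id: int) -> Polygon:
        cx, cy = self.centers[np.searchsorted(self.cell_ids, cell_id)]
        return Polygon(zip(*_hex_vertices(cx, cy, self.r, self.orientation)))

    def polygons(self) -> list[Polygon]:
        return [Polygon(zip(*_hex_vertices(cx, cy, self.r, self.orientation)))
                for cx, cy in self.centers]


def _hex_vertices(cx: float, cy: float, r: float, orientation: str
                  ) -> tuple[np.ndarray, np.ndarray]:
    phase = 0.0 if orientation == FLAT_TOP else np.pi / 6.0
    ang = phase + np.arange(6) * np.pi / 3.0
    return cx + r * np.cos(ang), cy + r * np.sin(ang)


def build_hex_grid(extent: Sequence[float], cell_area_km2: float = 115.0,
                   orientation: str = FLAT_TOP,
                   clip_polygon: Polygon | None = None) -> HexGrid:
    """Tessellate ``extent`` with regular hexagons of the given area.

    The grid origin is the extent's lower-left corner; cells extend one ring
    beyond every edge so the rectangle is covered without gaps.  If
    ``clip_polygon`` is given, cells wholly outside it are dropped (an
    optional stand-in for trimming a national grid to the coastline).
    """
    if orientation not in (FLAT_TOP, POINTY_TOP):
        raise ValueError(f"unknown orientation {orientation!r}")
    r = circumradius_for_area(cell_area_km2)
    x0, y0, x1, y1 = map(float, extent)
    if not (x1 > x0 and y1 > y0):
        raise ValueError(f"degenerate extent {tuple(extent)}")

    s3 = np.sqrt(3.0)
    if orientation == FLAT_TOP:
        # columns 1.5R apart in x, rows sqrt(3)R apart in y,
        # odd columns shifted up half a row
        ncols = int(np.ceil((x1 - x0) / (1.5 * r))) + 2
        nrows = int(np.ceil((y1 - y0) / (s3 * r))) + 2
        cols = np.arange(-1, ncols)
        rows = np.arange(-1, nrows)
        ii, jj = np.meshgrid(cols, rows, indexing="ij")
        cx = x0 + 1.5 * r * ii
        cy = y0 + s3 * r * jj + (ii % 2) * (s3 * r / 2.0)
    else:
        nrows = int(np.ceil((y1 - y0) / (1.5 * r))) + 2
        ncols = int(np.ceil((x1 - x0) / (s3 * r))) + 2
        cols = np.arange(-1, ncols)
        rows = np.arange(-1, nrows)
        ii, jj = np.meshgrid(cols, rows, indexing="ij")
        cx = x0 + s3 * r * ii + (jj % 2) * (s3 * r / 2.0)
        cy = y0 + 1.5 * r * jj
    centers = np.column_stack([cx.ravel(), cy.ravel()])

    # keep cells that can touch the extent (or the clip polygon)
    near = ((centers[:, 0] >= x0 - 2 * r) & (centers[:, 0] <= x1 + 2 * r)
            & (centers[:, 1] >= y0 - 2 * r) & (centers[:, 1] <= y1 + 2 * r))
    centers = centers[near]
    order = np.lexsort((centers[:, 0], centers[:, 1]))
    centers = centers[order]

    grid = HexGrid(cell_area_km2=float(cell_area_km2),
                   orientation=orientation, origin=(x0, y0),
                   extent=(x0, y0, x1, y1), r=r, centers=centers)
    if clip_polygon is not None:
        keep = np.array([poly.intersects(clip_polygon)
                         for poly in grid.polygons()])
        grid = HexGrid(cell_area_km2=float(cell_area_km2),
                       orientation=orientation, origin=(x0, y0),
                       extent=(x0, y0, x1, y1), r=r,
                       centers=centers[keep],
                       cell_ids=grid.cell_ids[keep])
    return grid


def _in_hexagon(dx: np.ndarray, dy: np.ndarray, r: float, orientation: str,
                eps: float) -> np.ndarray:
    """Exact containment of local offsets in a regular hexagon (boundary
    inclusive up to eps)."""
    s3 = np.sqrt(3.0)
    if orientation == POINTY_TOP:
        dx, dy = dy, dx
    return ((np.abs(dy) <= s3 / 2.0 * r + eps)
            & (s3 * np.abs(dx) + np.abs(dy) <= s3 * r + eps))


def assign_points(points: np.ndarray, grid: HexGrid) -> np.ndarray:
    """Map each planar point to the id of the cell containing it.

    Because the tessellation is the Voronoi diagram of the cell centers, the
    containing cell is the nearest center; boundary points (equidistant from
    several centers) go to the lowest incident cell id.  Points beyond the
    grid get ``OUTSIDE_GRID`` (-1) and are excluded from tallies but counted
    by callers in a data-quality report.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, 2)
    out = np.full(len(pts), OUTSIDE_GRID, dtype=int)
    finite = np.isfinite(pts).all(axis=1)
    if not finite.any():
        return out
    p = pts[finite]
    # k=3 captures every center tied for nearest at an edge or vertex
    dist, idx = grid._tree.query(p, k=min(3, len(grid)))
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    tol = 1e-9 * grid.r
    tied = dist <= (dist[:, [0]] + tol)
    # lowest cell id among tied nearest centers
    ids = grid.cell_ids[idx]
    ids_masked = np.where(tied, ids, np.iinfo(np.int64).max)
    chosen_pos = np.argmin(ids_masked, axis=1)
    chosen_idx = idx[np.arange(len(p)), chosen_pos]
    centers = grid.centers[chosen_idx]
    inside = _in_hexagon(p[:, 0] - centers[:, 0], p[:, 1] - centers[:, 1],
                         grid.r, grid.orientation, eps=tol)
    res = np.where(inside, grid.cell_ids[chosen_idx], OUTSIDE_GRID)
    out[finite] = res
    return out


# ---------------------------------------------------------------------------
# Parish densities


def parish_density(census: pd.DataFrame, parishes: pd.DataFrame
                   ) -> pd.DataFrame:
    """Sheep per hectare per parish per year.

    Parishes with zero or missing area report an absent density with a
    warning rather than failing.
    """
    merged = census.merge(parishes[["parish_id", "area_ha"]], on="parish_id",
                          how="left")
    bad = merged["area_ha"].isna() | (merged["area_ha"] <= 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} census rows have zero or missing "
                      "parish area; density reported absent", stacklevel=2)
    merged["density_sheep_per_ha"] = np.where(
        bad, np.nan, merged["n_sheep"] / merged["area_ha"])
    return merged[["year", "parish_id", "region", "n_sheep", "area_ha",
                   "density_sheep_per_ha"]]


# ---------------------------------------------------------------------------
# Catchment areas


@dataclass
class Catchment:
    """Spatial distribution of one slaughterhouse's annual supply."""

    slaughterhouse: str
    year: int
    reference: str  # SISP or SSSP
    cells: pd.DataFrame  # cell_id, n_holdings, n_sheep, pct_of_reference
    holdings: set
    reference_total: int
    mappable_sheep: int
    unmappable_sheep: int
    unmappable_holdings: int


def _reference_populations(reference: str) -> list[str]:
    if reference == "SISP":
        return [POP_SISP]
    if reference == "SSSP":
        return [POP_SISP, POP_SOSP]
    raise ValueError(f"reference must be 'SISP' or 'SSSP', got {reference!r}")


def compute_catchment(slaughterhouse: str, deduped: pd.DataFrame,
                      premises: pd.DataFrame, parishes: pd.DataFrame,
                      grid: HexGrid, year: int,
                      reference: str = "SISP") -> Catchment:
    """Per-cell holding and sheep counts for one slaughterhouse's suppliers.

    ``pct_of_reference`` is each cell's sheep as a percentage of the total
    reference population (SISP or SSSP) for that year, so catchments of
    different slaughterhouses are directly comparable.  Holdings that cannot
    be mapped (no coordinates and no parish centroid) are tallied separately,
    never silently dropped.
    """
    reg = registry_index(premises)
    if slaughterhouse not in reg.index or \
            reg.loc[slaughterhouse, "ptype"] != "slaughterhouse":
        raise KeyError(f"unknown slaughterhouse {slaughterhouse!r}")
    wanted = _reference_populations(reference)
    recs = deduped.copy()
    recs["population"] = classify_population(recs, premises)
    recs["year"] = recs["date"].dt.year
    recs = recs[(recs["year"] == year) & recs["population"].isin(wanted)]
    reference_total = int(recs["n_animals"].sum())
    supply = recs[recs["destination_cph"] == slaughterhouse]

    resolved = resolve_locations(premises, parishes).set_index("cph")
    dep = supply.groupby("departure_cph")["n_animals"].sum()
    xy = resolved.loc[dep.index, ["x", "y"]].to_numpy(dtype=float)
    prov = resolved.loc[dep.index, "provenance"]
    mappable = (prov != PROV_UNMAPPABLE).to_numpy()

    cell_of = np.full(len(dep), OUTSIDE_GRID, dtype=int)
    if mappable.any():
        cell_of[mappable] = assign_points(xy[mappable], grid)
    in_grid = cell_of != OUTSIDE_GRID

    per_cell = pd.DataFrame({
        "cell_id": cell_of[in_grid],
        "holding": dep.index.to_numpy()[in_grid],
        "n_sheep": dep.to_numpy()[in_grid],
    })
    cells = (per_cell.groupby("cell_id")
             .agg(n_holdings=("holding", "nunique"), n_sheep=("n_sheep", "sum"))
             .reset_index())
    cells["pct_of_reference"] = (100.0 * cells["n_sheep"] / reference_total
                                 if reference_total else np.nan)
    return Catchment(
        slaughterhouse=slaughterhouse, year=year, reference=reference,
        cells=cells, holdings=set(dep.index),
        reference_total=reference_total,
        mappable_sheep=int(per_cell["n_sheep"].sum()),
        unmappable_sheep=int(dep.to_numpy()[~in_grid].sum()),
        unmappable_holdings=int((~in_grid).sum()),
    )


def quarterly_catchment(slaughterhouse: str, deduped: pd.DataFrame,
                        premises: pd.DataFrame, parishes: pd.DataFrame,
                        grid: HexGrid, year: int,
                        reference: str = "SISP") -> dict[int, pd.DataFrame]:
    """Seasonal decomposition of a catchment: one cell layer per quarter.

    Each layer reports sheep per cell as a percentage of the slaughterhouse's
    ANNUAL mappable throughput, so the four layers' grand totals sum to 100.
    """
    reg = registry_index(premises)
    if slaughterhouse not in reg.index or \
            reg.loc[slaughterhouse, "ptype"] != "slaughterhouse":
        raise KeyError(f"unknown slaughterhouse {slaughterhouse!r}")
    wanted = _reference_populations(reference)
    recs = deduped.copy()
    recs["population"] = classify_population(recs, premises)
    recs["year"] = recs["date"].dt.year
    recs = recs[(recs["year"] == year) & recs["population"].isin(wanted)
                & (recs["destination_cph"] == slaughterhouse)].copy()
    recs["quarter"] = recs["date"].dt.quarter

    resolved = resolve_locations(premises, parishes).set_index("cph")
    xy = resolved.reindex(recs["departure_cph"])[["x", "y"]].to_numpy(float)
    recs["cell_id"] = assign_points(xy, grid)
    mappable = recs[recs["cell_id"] != OUTSIDE_GRID]
    annual_mappable = mappable["n_animals"].sum()

    layers: dict[int, pd.DataFrame] = {}
    for q in (1, 2, 3, 4):
        sub = mappable[mappable["quarter"] == q]
        layer = (sub.groupby("cell_id")
                 .agg(n_holdings=("departure_cph", "nunique"),
                      n_sheep=("n_animals", "sum"))
                 .reset_index())
        layer["pct_of_annual"] = (100.0 * layer["n_sheep"] / annual_mappable
                                  if annual_mappable else np.nan)
        layers[q] = layer
    return layers


# ---------------------------------------------------------------------------
# GeoJSON export


def grid_to_geojson(grid: HexGrid,
                    cell_values: pd.DataFrame | None = None) -> dict:
    """GeoJSON FeatureCollection of the grid's hexagons.

    ``cell_values`` (indexed or keyed by ``cell_id``) contributes extra
    per-cell properties (counts, percentages).  Grid metadata (cell area,
    orientation, origin) is recorded on the collection so a tiling is
    reproducible from its export.
    """
    props_by_cell: dict[int, dict] = {}
    if cell_values is not None:
        cv = cell_values.set_index("cell_id") if "cell_id" in cell_values \
            else cell_values
        props_by_cell = {int(k): {c: (v if pd.notna(v) else None)
                                  for c, v in row.items()}
                         for k, row in cv.iterrows()}
    features = []
    for cid, (cx, cy) in zip(grid.cell_ids, grid.centers):
        xs, ys = _hex_vertices(cx, cy, grid.r, grid.orientation)
        ring = [[float(x), float(y)] for x, y in zip(xs, ys)]
        ring.append(ring[0])
        props = {"cell_id": int(cid)}
        props.update(props_by_cell.get(int(cid), {}))
        features.append({"type": "Feature",
                         "geometry": {"type": "Polygon",
                                      "coordinates": [ring]},
                         "properties": props})
    return {
        "type": "FeatureCollection",
        "features": features,
        "metadata": {"cell_area_km2": grid.cell_area_km2,
                     "orientation": grid.orientation,
                     "origin": list(grid.origin),
                     "extent": list(grid.extent)},
    }


def write_geojson(path: str | Path, collection: dict) -> None:
    Path(path).write_text(json.dumps(collection))
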
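"""Voronoi quadrats and tumor-component typing.

The colocalization analysis bins cells into Voronoi polygons ("quadrats")
whose number is the cube root of the cell count in the region of interest.
Seeds are placed at k-means centroids of the cell coordinates, so the
tessellation adapts to tissue density while remaining deterministic for a
fixed random seed.  In mixed invasive/in-situ sections each polygon is then
typed by its content — synchronous DCIS (cancer cells confined to ducts),
IDC (predominantly invasive cancer cells), mixed (the duct/invasive
interface) or excluded (no cancer cells, negligible duct area) — and the
per-component statistics are computed over the polygons of each type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import voronoi_diagram

from .cells import EPITHELIAL_CLASSES, CellMap, DuctMask

RegionType = Literal["synchronous_DCIS", "IDC", "mixed", "excluded"]

#: default duct-content thresholds: "only ducts" mapped to >= 0.9,
#: "predominantly invasive" to <= 0.1, to tolerate boundary noise.
T_LOW_DEFAULT = 0.1
T_HIGH_DEFAULT = 0.9
#: a component with fewer cells than this yields a flagged null result
MIN_COMPONENT_CELLS = 50
#: default ROI: convex hull of all cells buffered by this margin (um)
ROI_BUFFER_UM = 50.0


class DegenerateInputError(ValueError):
    """Too few cells (or zero-area ROI) to build a tessellation."""


def seed_count(n_cells: int) -> int:
    """Number of Voronoi seeds for a region containing ``n_cells`` cells.

    The seed count is the cube root of the cell count, rounded to the
    nearest integer (half away from zero) with a floor of 2; fewer than
    two cells cannot be partitioned and yield 0.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if n_cells < 2:
        return 0
    return max(2, int(math.floor(np.cbrt(float(n_cells)) + 0.5)))


@dataclass
class RegionPolygon:
    """One Voronoi quadrat, its component type and its assigned cells."""

    polygon_id: int
    geometry: Polygon
    region_type: RegionType | None = None
    duct_area_fraction: float | None = None
    in_duct_epithelial_fraction: float | None = None
    cell_ids: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class RegionPartition:
    """Voronoi tessellation of a region of interest, clipped to the ROI."""

    polygons: list[RegionPolygon]
    seed_points: np.ndarray
    roi: Polygon
    section_id: str

    @property
    def n_seeds(self) -> int:
        return len(self.seed_points)

    def polygons_of_type(self, region_type: RegionType) -> list[RegionPolygon]:
        return [p for p in self.polygons if p.region_type == region_type]

    def total_area(self) -> float:
        return float(sum(p.geometry.area for p in self.polygons))

    def cell_assignment(self) -> dict:
        """Mapping cell_id -> polygon_id over all polygons."""
        out = {}
        for poly in self.polygons:
            for cid in poly.cell_ids:
                out[cid] = poly.polygon_id
        return out


def default_roi(cells: CellMap, buffer_um: float = ROI_BUFFER_UM) -> Polygon:
    """Convex hull of all cells, buffered outward (fallback tissue outline)."""
    hull = MultiPoint(cells.coords()).convex_hull.buffer(buffer_um)
    return hull


def tessellate(
    cells: CellMap,
    roi: Polygon | None = None,
    rng_seed: int = 0,
    n_seeds: int | None = None,
) -> RegionPartition:
    """Voronoi-partition the ROI using k-means centroids of cells as seeds.

    ``n_seeds`` defaults to :func:`seed_count` of the number of cells inside
    the ROI.  Every cell inside the ROI is assigned to exactly one polygon
    (nearest seed; boundary ties go to the lowest polygon_id).  The clipped
    polygons partition the ROI: their areas sum to the ROI area.
    """
    if roi is None:
        roi = default_roi(cells)
    if roi.is_empty or roi.area <= 0:
        raise DegenerateInputError("ROI has zero area")
    xy = cells.coords()
    inside = shapely.covers(roi, shapely.points(xy))
    xy_in = xy[inside]
    ids_in = cells.df["cell_id"].to_numpy()[inside]
    k = n_seeds if n_seeds is not None else seed_count(len(xy_in))
    if k < 2:
        raise DegenerateInputError(
            f"{len(xy_in)} cells in ROI give {k} seeds; need at least 2"
        )
    seeds = _kmeans_seeds(xy_in, k, rng_seed)
    # stable polygon ids: seeds sorted lexicographically by (x, y)
    order = np.lexsort((seeds[:, 1], seeds[:, 0]))
    seeds = seeds[order]

    cells_geom = voronoi_diagram(MultiPoint(seeds), envelope=roi)
    # match each Voronoi cell to the seed it contains
    raw = list(cells_geom.geoms)
    clipped: list[Polygon] = []
    seed_pts = shapely.points(seeds)
    for i, pt in enumerate(seed_pts):
        hits = [g for g in raw if g.covers(pt)]
        if not hits:  # pragma: no cover - voronoi_diagram always covers seeds
            raise RuntimeError(f"no Voronoi cell found for seed {i}")
        geom = hits[0].intersection(roi)
        if geom.geom_type == "MultiPolygon":  # non-convex ROI can split a cell
            geom = max(geom.geoms, key=lambda g: g.area)
        clipped.append(geom)

    assignment = _assign_nearest(seeds, xy_in)
    polygons = []
    for i, geom in enumerate(clipped):
        cell_ids = ids_in[assignment == i].tolist()
        polygons.append(RegionPolygon(polygon_id=i, geometry=geom, cell_ids=cell_ids))
    return RegionPartition(
        polygons=polygons,
        seed_points=seeds,
        roi=roi,
        section_id=cells.section_id,
    )


def _kmeans_seeds(xy: np.ndarray, k: int, rng_seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, random_state=int(rng_seed) % (2**31), n_init=4)
    km.fit(xy)
    return np.asarray(km.cluster_centers_, dtype=float)


def _assign_nearest(seeds: np.ndarray, xy: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Nearest-seed assignment; equidistant ties go to the lower seed index."""
    if len(xy) == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(seeds)
    kq = min(2, len(seeds))
    dist, idx = tree.query(xy, k=kq)
    if kq == 1:
        return np.atleast_1d(idx)
    tied = np.abs(dist[:, 0] - dist[:, 1]) <= tol
    out = idx[:, 0].copy()
    out[tied] = np.minimum(idx[tied, 0], idx[tied, 1])
    return out


def classify_polygons(
    partition: RegionPartition,
    ducts: DuctMask,
    cells: CellMap,
    t_low: float = T_LOW_DEFAULT,
    t_high: float = T_HIGH_DEFAULT,
) -> RegionPartition:
    """Type each quadrat as synchronous_DCIS / IDC / mixed / excluded.

    A polygon containing epithelial cells is typed by where its epithelium
    lies: if at least ``t_high`` of its epithelial cells fall inside duct
    polygons its cancer content is ductal only (synchronous DCIS); if at
    most ``t_low`` do — and the duct area fraction is also at most
    ``t_low`` — it is predominantly invasive (IDC); anything in between is
    the duct/invasive interface (mixed).  Polygons without epithelial cells
    are typed by duct area alone: excluded below ``t_low`` (stroma, fat,
    artifacts), synchronous DCIS above ``t_high``, mixed otherwise.
    Raising a polygon's duct area fraction can never move it from
    synchronous DCIS toward IDC.
    """
    if not (0 <= t_low < t_high <= 1):
        raise ValueError("thresholds must satisfy 0 <= t_low < t_high <= 1")
    if partition.section_id != cells.section_id or (
        ducts.section_id != cells.section_id
    ):
        raise ValueError(
            "section_id mismatch between partition "
            f"({partition.section_id!r}), ducts ({ducts.section_id!r}) and "
            f"cells ({cells.section_id!r})"
        )
    duct_union = ducts.union

    epi = cells.subset(EPITHELIAL_CLASSES)
    epi_ids = set(epi.df["cell_id"])
    in_duct = ducts.contains_points(epi.coords())
    in_duct_by_id = dict(zip(epi.df["cell_id"], in_duct))

    typed = []
    for poly in partition.polygons:
        area = poly.geometry.area
        d = 0.0
        if area > 0 and not duct_union.is_empty:
            d = float(poly.geometry.intersection(duct_union).area / area)
        d = min(max(d, 0.0), 1.0)
        epi_in_poly = [cid for cid in poly.cell_ids if cid in epi_ids]
        if epi_in_poly:
            s = float(np.mean([in_duct_by_id[cid] for cid in epi_in_poly]))
            if s >= t_high or d >= t_high:
                rtype: RegionType = "synchronous_DCIS"
            elif s <= t_low and d <= t_low:
                rtype = "IDC"
            else:
                rtype = "mixed"
        else:
            s = None
            if d <= t_low:
                rtype = "excluded"
            elif d >= t_high:
                rtype = "synchronous_DCIS"
            else:
                rtype = "mixed"
        typed.append(
            replace(
                poly,
                region_type=rtype,
                duct_area_fraction=d,
                in_duct_epithelial_fraction=s,
            )
        )
    return RegionPartition(
        polygons=typed,
        seed_points=partition.seed_points,
        roi=partition.roi,
        section_id=partition.section_id,
    )


@dataclass
class ComponentCells:
    """Cells of one tumor component, with the insufficiency flag."""

    cells: CellMap
    component: str
    n_polygons: int
    insufficient: bool


def component_cells(
    cells: CellMap,
    partition: RegionPartition,
    component: RegionType,
    min_cells: int = MIN_COMPONENT_CELLS,
) -> ComponentCells:
    """Sub-table of cells assigned to polygons of the requested component.

    Components backed by no polygons, or by fewer than ``min_cells`` cells,
    are flagged insufficient (the caller reports a null index rather than
    an error) — this is how sections lacking synchronous DCIS regions are
    dropped from group comparisons instead of contributing zeros.
    """
    if component not in ("synchronous_DCIS", "IDC"):
        raise ValueError("component must be 'synchronous_DCIS' or 'IDC'")
    polys = partition.polygons_of_type(component)
    ids: list = []
    for p in polys:
        ids.extend(p.cell_ids)
    sub = cells.select_ids(ids)
    insufficient = len(polys) < 1 or len(sub) < min_cells
    sub.metadata["component"] = component
    sub.metadata["insufficient_component"] = insufficient
    return ComponentCells(
        cells=sub,
        component=component,
        n_polygons=len(polys),
        insufficient=insufficient,
    )
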
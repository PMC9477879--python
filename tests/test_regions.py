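"""Cube-root seeding, Voronoi partition properties and component typing."""

import numpy as np
import pytest
from shapely.geometry import box

from dcispatial import (
    CellClass,
    CellMap,
    DuctMask,
    SampleType,
    classify_polygons,
    component_cells,
    seed_count,
    tessellate,
)
from dcispatial.regions import DegenerateInputError, RegionPartition


class TestSeedCount:
    @pytest.mark.parametrize(
        "n,k",
        [(1000, 10), (27, 3), (100, 5), (8, 2), (2, 2), (1, 0), (0, 0), (64, 4)],
    )
    def test_cube_root_rounding(self, n, k):
        assert seed_count(n) == k

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            seed_count(-1)


def _grid_cells(xy, classes=None, section_id="s", **kwargs):
    xy = np.asarray(xy, dtype=float)
    classes = classes or [CellClass.STROMA] * len(xy)
    return CellMap.from_arrays(
        xy[:, 0], xy[:, 1], classes, section_id=section_id, **kwargs
    )


class TestTessellate:
    def test_two_separated_squares_split_evenly(self):
        left = [(0, 0), (0, 10), (10, 0), (10, 10)]
        right = [(100, 0), (100, 10), (110, 0), (110, 10)]
        cells = _grid_cells(left + right)
        part = tessellate(cells, roi=box(-5, -5, 115, 15), n_seeds=2)
        assert len(part.polygons) == 2
        assert sorted(p.n_cells for p in part.polygons) == [4, 4]

    def test_partition_conserves_area_and_cells(self):
        rng = np.random.default_rng(3)
        cells = _grid_cells(rng.uniform(0, 500, size=(1000, 2)))
        part = tessellate(cells, rng_seed=0)
        assert part.total_area() == pytest.approx(part.roi.area, rel=1e-6)
        assert sum(p.n_cells for p in part.polygons) == 1000

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        cells = _grid_cells(rng.uniform(0, 300, size=(200, 2)))
        p1 = tessellate(cells, rng_seed=42)
        p2 = tessellate(cells, rng_seed=42)
        np.testing.assert_array_equal(p1.seed_points, p2.seed_points)
        assert p1.cell_assignment() == p2.cell_assignment()

    def test_too_few_cells_degenerate(self):
        cells = _grid_cells([(0.0, 0.0)])
        with pytest.raises(DegenerateInputError):
            tessellate(cells)


def _manual_partition(cells, polys):
    """Partition from explicit polygons, cells assigned by containment."""
    import shapely

    from dcispatial.regions import RegionPolygon

    region_polys = []
    ids = cells.df["cell_id"].to_numpy()
    pts = shapely.points(cells.coords())
    for i, geom in enumerate(polys):
        inside = shapely.covers(geom, pts)
        region_polys.append(
            RegionPolygon(polygon_id=i, geometry=geom, cell_ids=ids[inside].tolist())
        )
    from shapely.ops import unary_union

    return RegionPartition(
        polygons=region_polys,
        seed_points=np.zeros((len(polys), 2)),
        roi=unary_union(polys),
        section_id=cells.section_id,
    )


class TestClassifyPolygons:
    def setup_method(self):
        # left polygon sits entirely inside a duct; right has no duct overlap
        self.ducts = DuctMask(polygons=[box(0, 0, 12, 10)], section_id="s")
        self.cells = _grid_cells(
            [(2, 2), (4, 4), (20, 2), (24, 8)],
            classes=[
                CellClass.CA9_NEG_EPITHELIAL,
                CellClass.CA9_POS_EPITHELIAL,
                CellClass.CA9_NEG_EPITHELIAL,
                CellClass.CA9_NEG_EPITHELIAL,
            ],
        )

    def test_duct_covered_polygon_is_synchronous(self):
        part = _manual_partition(self.cells, [box(0, 0, 10, 10), box(10, 0, 30, 10)])
        typed = classify_polygons(part, self.ducts, self.cells)
        assert typed.polygons[0].region_type == "synchronous_DCIS"
        assert typed.polygons[0].duct_area_fraction == pytest.approx(1.0)

    def test_ductfree_epithelial_polygon_is_idc(self):
        part = _manual_partition(self.cells, [box(0, 0, 12, 10), box(15, 0, 30, 10)])
        typed = classify_polygons(part, self.ducts, self.cells)
        assert typed.polygons[1].region_type == "IDC"
        assert typed.polygons[1].duct_area_fraction == 0.0

    def test_halfway_epithelial_free_polygon_is_mixed(self):
        cells = _grid_cells([(40, 5)], classes=[CellClass.STROMA])
        ducts = DuctMask(polygons=[box(0, 0, 10, 10)], section_id="s")
        part = _manual_partition(cells, [box(5, 0, 15, 10), box(30, 0, 50, 10)])
        typed = classify_polygons(part, ducts, cells)
        assert typed.polygons[0].duct_area_fraction == pytest.approx(0.5)
        assert typed.polygons[0].region_type == "mixed"
        # no epithelium and no duct -> excluded from analysis
        assert typed.polygons[1].region_type == "excluded"

    def test_interface_polygon_is_mixed(self):
        # one polygon holding both in-duct and invasive epithelium
        cells = _grid_cells(
            [(2, 2), (20, 2)],
            classes=[CellClass.CA9_NEG_EPITHELIAL, CellClass.CA9_NEG_EPITHELIAL],
        )
        ducts = DuctMask(polygons=[box(0, 0, 10, 10)], section_id="s")
        part = _manual_partition(cells, [box(0, 0, 30, 10)])
        typed = classify_polygons(part, ducts, cells)
        assert typed.polygons[0].region_type == "mixed"

    def test_typing_monotone_in_duct_area(self):
        # growing the duct under an IDC polygon can only move it toward mixed/sync
        cells = _grid_cells([(25, 5)], classes=[CellClass.CA9_NEG_EPITHELIAL])
        part = _manual_partition(cells, [box(0, 0, 30, 10)])
        order = {"IDC": 0, "mixed": 1, "synchronous_DCIS": 2}
        last = -1
        for duct_w in [1.0, 12.0, 29.0]:
            ducts = DuctMask(polygons=[box(0, 0, duct_w, 10)], section_id="s")
            typed = classify_polygons(part, ducts, cells)
            rank = order[typed.polygons[0].region_type]
            assert rank >= last
            last = rank

    def test_section_mismatch_rejected(self):
        part = _manual_partition(self.cells, [box(0, 0, 30, 10)])
        ducts = DuctMask(polygons=[box(0, 0, 10, 10)], section_id="other")
        with pytest.raises(ValueError, match="section_id"):
            classify_polygons(part, ducts, self.cells)


class TestComponentCells:
    def test_accounting_and_flags(self, idc_section):
        cells, ducts = idc_section.cells, idc_section.ducts
        part = classify_polygons(tessellate(cells, rng_seed=0), ducts, cells)
        sync = component_cells(cells, part, "synchronous_DCIS")
        idc = component_cells(cells, part, "IDC")
        assert sync.cells.n_cells + idc.cells.n_cells <= cells.n_cells
        assert not idc.insufficient

    def test_missing_component_flagged_not_raised(self, pure_section):
        cells, ducts = pure_section.cells, pure_section.ducts
        part = classify_polygons(tessellate(cells, rng_seed=0), ducts, cells)
        idc = component_cells(cells, part, "IDC")  # pure DCIS: no invasive cells
        assert idc.insufficient
        assert idc.cells.n_cells < 50

    def test_pure_dcis_epithelial_polygons_mostly_ductal(self, pure_section):
        cells, ducts = pure_section.cells, pure_section.ducts
        part = classify_polygons(tessellate(cells, rng_seed=0), ducts, cells)
        epi_polys = [
            p for p in part.polygons if p.in_duct_epithelial_fraction is not None
        ]
        ok = [p for p in epi_polys if p.region_type in ("synchronous_DCIS", "mixed")]
        assert len(ok) >= 0.9 * len(epi_polys)
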
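"""Morisita–Horn colocalization and cell-type abundance.

The Morisita–Horn index quantifies spatial overlap between two cell
populations from their per-quadrat counts x_i, y_i (quadrats here are the
Voronoi polygons of :mod:`dcispatial.regions`):

    MH = 2 * sum_i(x_i * y_i) / [ (sum_i x_i^2 / X^2 + sum_i y_i^2 / Y^2) * X * Y ]

with X = sum_i x_i and Y = sum_i y_i.  MH ranges from 0 (complete spatial
segregation — the two types never share a quadrat) to 1 (maximal
colocalization — proportional counts in every quadrat).

Abundances are simple fractions within a lineage: FOXP3+ lymphocyte
abundance = |FOXP3+| / (|FOXP3+| + |FOXP3-|) and CA9+ epithelial
abundance = |CA9+| / (|CA9+| + |CA9-|).

Whole-tumor sections of pure DCIS get a single index per cell-type pair;
sections with both invasive and in-situ disease get one index per pair for
the synchronous-DCIS component and one for the IDC component, computed over
the quadrats typed to each component by :func:`regions.classify_polygons`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .cells import (
    EPITHELIAL_CLASSES,
    LYMPHOCYTE_CLASSES,
    CellClass,
    CellMap,
    DuctMask,
    SampleType,
)
from .regions import (
    MIN_COMPONENT_CELLS,
    T_HIGH_DEFAULT,
    T_LOW_DEFAULT,
    RegionPartition,
    classify_polygons,
    component_cells,
    tessellate,
)

#: the four lymphocyte/epithelial pairs compared across sample groups
DEFAULT_PAIRS: tuple[tuple[CellClass, CellClass], ...] = (
    (CellClass.FOXP3_POS_LYMPHOCYTE, CellClass.CA9_POS_EPITHELIAL),
    (CellClass.FOXP3_NEG_LYMPHOCYTE, CellClass.CA9_POS_EPITHELIAL),
    (CellClass.FOXP3_POS_LYMPHOCYTE, CellClass.CA9_NEG_EPITHELIAL),
    (CellClass.FOXP3_NEG_LYMPHOCYTE, CellClass.CA9_NEG_EPITHELIAL),
)


@dataclass
class QuadratCounts:
    """Aligned per-quadrat counts of two cell types."""

    x: np.ndarray
    y: np.ndarray
    polygon_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D vectors of equal length")
        if np.any(self.x < 0) or np.any(self.y < 0):
            raise ValueError("quadrat counts must be non-negative")

    @property
    def X(self) -> float:
        return float(self.x.sum())

    @property
    def Y(self) -> float:
        return float(self.y.sum())


def morisita_horn(x, y=None) -> float:
    """Morisita–Horn overlap of two count vectors; NaN when undefined.

    Accepts either a :class:`QuadratCounts` or two array-likes.  Returns
    NaN (null index, insufficient data) when either population is absent
    (X = 0 or Y = 0); symmetric in its arguments and bounded in [0, 1].
    """
    if isinstance(x, QuadratCounts) and y is None:
        q = x
    else:
        q = QuadratCounts(np.asarray(x), np.asarray(y))
    X, Y = q.X, q.Y
    if X == 0 or Y == 0:
        return float("nan")
    # cleared-denominator form of 2*sum(xy) / ((sum(x^2)/X^2 + sum(y^2)/Y^2)*X*Y):
    # exact for integer counts and symmetric under x <-> y
    num = 2.0 * float(np.dot(q.x, q.y)) * (X * Y)
    den = float(np.dot(q.x, q.x)) * Y**2 + float(np.dot(q.y, q.y)) * X**2
    return num / den


@dataclass
class ColocalizationResult:
    """Morisita–Horn index for one class pair in one tumor component."""

    section_id: str
    pair: tuple[str, str]
    component: str  # whole_section | synchronous_DCIS | IDC
    mh_index: float | None
    n_polygons: int
    X: int
    Y: int
    insufficient_data: bool

    def as_dict(self) -> dict:
        return {
            "section_id": self.section_id,
            "component": self.component,
            "class_a": self.pair[0],
            "class_b": self.pair[1],
            "mh_index": self.mh_index,
            "n_polygons": self.n_polygons,
            "X": self.X,
            "Y": self.Y,
            "insufficient_data": self.insufficient_data,
        }


@dataclass
class AbundanceResult:
    """FOXP3+ and CA9+ abundance fractions for one component."""

    section_id: str
    component: str
    foxp3_pos_abundance: float | None
    ca9_pos_abundance: float | None
    n_lymphocytes: int
    n_epithelial: int
    insufficient_lymphocytes: bool
    insufficient_epithelial: bool

    def as_dict(self) -> dict:
        return {
            "section_id": self.section_id,
            "component": self.component,
            "foxp3_pos_abundance": self.foxp3_pos_abundance,
            "ca9_pos_abundance": self.ca9_pos_abundance,
            "n_lymphocytes": self.n_lymphocytes,
            "n_epithelial": self.n_epithelial,
        }


def abundance(cells: CellMap, component: str = "whole_section") -> AbundanceResult:
    """FOXP3+ / lymphocyte and CA9+ / epithelial fractions for a cell table.

    A zero denominator (no lymphocytes, or no epithelial cells) yields a
    null fraction with the corresponding insufficiency flag set.
    """
    counts = cells.class_counts()
    n_lym = (
        counts[CellClass.FOXP3_POS_LYMPHOCYTE.value]
        + counts[CellClass.FOXP3_NEG_LYMPHOCYTE.value]
    )
    n_epi = (
        counts[CellClass.CA9_POS_EPITHELIAL.value]
        + counts[CellClass.CA9_NEG_EPITHELIAL.value]
    )
    foxp3 = (
        counts[CellClass.FOXP3_POS_LYMPHOCYTE.value] / n_lym if n_lym else None
    )
    ca9 = counts[CellClass.CA9_POS_EPITHELIAL.value] / n_epi if n_epi else None
    return AbundanceResult(
        section_id=cells.section_id,
        component=component,
        foxp3_pos_abundance=foxp3,
        ca9_pos_abundance=ca9,
        n_lymphocytes=n_lym,
        n_epithelial=n_epi,
        insufficient_lymphocytes=n_lym == 0,
        insufficient_epithelial=n_epi == 0,
    )


def quadrat_counts(
    partition: RegionPartition,
    cells: CellMap,
    cell_class: CellClass,
    polygon_ids: list[int] | None = None,
) -> np.ndarray:
    """Per-polygon count of one cell class, over all or selected polygons."""
    wanted = CellClass(cell_class).value
    cls_by_id = dict(zip(cells.df["cell_id"], cells.df["cell_class"]))
    polys = partition.polygons
    if polygon_ids is not None:
        keep = set(polygon_ids)
        polys = [p for p in polys if p.polygon_id in keep]
    return np.array(
        [sum(cls_by_id.get(cid) == wanted for cid in p.cell_ids) for p in polys],
        dtype=float,
    )


@dataclass
class SectionAnalysis:
    """Full spatial read-out of one section: indices, abundances, partition."""

    section_id: str
    sample_type: SampleType
    colocalization: list[ColocalizationResult]
    abundances: list[AbundanceResult]
    partition: RegionPartition | None = None


def _pair_results(
    partition: RegionPartition,
    cells: CellMap,
    pairs,
    component: str,
    polygon_ids: list[int] | None,
    insufficient: bool,
) -> list[ColocalizationResult]:
    results = []
    n_polys = (
        len(polygon_ids)
        if polygon_ids is not None
        else len(partition.polygons)
    )
    for a, b in pairs:
        a, b = CellClass(a), CellClass(b)
        if insufficient or n_polys < 2:
            results.append(
                ColocalizationResult(
                    section_id=cells.section_id,
                    pair=(a.value, b.value),
                    component=component,
                    mh_index=None,
                    n_polygons=n_polys,
                    X=0,
                    Y=0,
                    insufficient_data=True,
                )
            )
            continue
        x = quadrat_counts(partition, cells, a, polygon_ids)
        y = quadrat_counts(partition, cells, b, polygon_ids)
        mh = morisita_horn(x, y)
        null = bool(np.isnan(mh))
        results.append(
            ColocalizationResult(
                section_id=cells.section_id,
                pair=(a.value, b.value),
                component=component,
                mh_index=None if null else float(mh),
                n_polygons=n_polys,
                X=int(x.sum()),
                Y=int(y.sum()),
                insufficient_data=null,
            )
        )
    return results


def colocalize_section(
    cells: CellMap,
    ducts: DuctMask | None = None,
    pairs=DEFAULT_PAIRS,
    roi: Polygon | None = None,
    t_low: float = T_LOW_DEFAULT,
    t_high: float = T_HIGH_DEFAULT,
    min_cells: int = MIN_COMPONENT_CELLS,
    rng_seed: int = 0,
) -> list[ColocalizationResult]:
    """Morisita–Horn indices for the requested class pairs of one section.

    Pure-DCIS sections are tessellated once over the whole ROI and yield
    one ``whole_section`` index per pair.  IDC/DCIS sections require a duct
    mask: the section is tessellated, polygons are typed, and each pair is
    evaluated separately over the synchronous-DCIS and the IDC quadrats
    (two results per pair).  Components failing the minimum-data rule
    (< ``min_cells`` cells or no polygons) yield flagged null indices.
    """
    return analyze_section(
        cells,
        ducts=ducts,
        pairs=pairs,
        roi=roi,
        t_low=t_low,
        t_high=t_high,
        min_cells=min_cells,
        rng_seed=rng_seed,
    ).colocalization


def analyze_section(
    cells: CellMap,
    ducts: DuctMask | None = None,
    pairs=DEFAULT_PAIRS,
    roi: Polygon | None = None,
    t_low: float = T_LOW_DEFAULT,
    t_high: float = T_HIGH_DEFAULT,
    min_cells: int = MIN_COMPONENT_CELLS,
    rng_seed: int = 0,
) -> SectionAnalysis:
    """Tessellate, type and score one section; returns indices + abundances."""
    if cells.sample_type is None:
        raise ValueError("cells.sample_type must be set for section analysis")
    sample_type = SampleType(cells.sample_type)
    partition = tessellate(cells, roi=roi, rng_seed=rng_seed)

    if sample_type is SampleType.PURE_DCIS:
        coloc = _pair_results(partition, cells, pairs, "whole_section", None, False)
        abund = [abundance(cells, "whole_section")]
        return SectionAnalysis(
            section_id=cells.section_id,
            sample_type=sample_type,
            colocalization=coloc,
            abundances=abund,
            partition=partition,
        )

    if ducts is None:
        raise ValueError("IDC_DCIS sections require a duct mask")
    partition = classify_polygons(partition, ducts, cells, t_low=t_low, t_high=t_high)
    coloc: list[ColocalizationResult] = []
    abund: list[AbundanceResult] = []
    for component in ("synchronous_DCIS", "IDC"):
        comp = component_cells(cells, partition, component, min_cells=min_cells)
        ids = [p.polygon_id for p in partition.polygons_of_type(component)]
        coloc.extend(
            _pair_results(partition, cells, pairs, component, ids, comp.insufficient)
        )
        if comp.insufficient:
            abund.append(
                AbundanceResult(
                    section_id=cells.section_id,
                    component=component,
                    foxp3_pos_abundance=None,
                    ca9_pos_abundance=None,
                    n_lymphocytes=0,
                    n_epithelial=0,
                    insufficient_lymphocytes=True,
                    insufficient_epithelial=True,
                )
            )
        else:
            abund.append(abundance(comp.cells, component))
    return SectionAnalysis(
        section_id=cells.section_id,
        sample_type=sample_type,
        colocalization=coloc,
        abundances=abund,
        partition=partition,
    )


def results_to_frame(results: list[ColocalizationResult]) -> pd.DataFrame:
    """Tidy DataFrame of colocalization results (one row per pair/component)."""
    return pd.DataFrame([r.as_dict() for r in results])


def abundances_to_frame(results: list[AbundanceResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])
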
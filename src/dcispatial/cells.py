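"""Core data containers for single-cell maps and duct masks.

A tissue section is represented by two objects: a :class:`CellMap` holding
one row per detected cell (micron coordinates plus one of five marker
classes) and a :class:`DuctMask` holding the DCIS duct outlines as simple
polygons in the same micron frame.  Coordinates follow the image
convention: origin at the top-left of the section, x to the right, y
downward, units of microns (sections are scanned at 0.5 um/pixel).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union


class CellClass(str, enum.Enum):
    """The five marker-defined cell classes of the dual CA9/FOXP3 stain."""

    CA9_POS_EPITHELIAL = "CA9_pos_epithelial"
    CA9_NEG_EPITHELIAL = "CA9_neg_epithelial"
    FOXP3_POS_LYMPHOCYTE = "FOXP3_pos_lymphocyte"
    FOXP3_NEG_LYMPHOCYTE = "FOXP3_neg_lymphocyte"
    STROMA = "stroma"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: epithelial subset (denominator of CA9+ abundance)
EPITHELIAL_CLASSES = frozenset(
    {CellClass.CA9_POS_EPITHELIAL, CellClass.CA9_NEG_EPITHELIAL}
)
#: lymphocyte subset (denominator of FOXP3+ abundance)
LYMPHOCYTE_CLASSES = frozenset(
    {CellClass.FOXP3_POS_LYMPHOCYTE, CellClass.FOXP3_NEG_LYMPHOCYTE}
)

VALID_CLASS_VALUES = frozenset(c.value for c in CellClass)


class SampleType(str, enum.Enum):
    """Histological sample category of a whole section."""

    PURE_DCIS = "pure_DCIS"
    IDC_DCIS = "IDC_DCIS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CELL_COLUMNS = ["cell_id", "x_um", "y_um", "cell_class"]


@dataclass
class CellMap:
    """Per-cell table for one tissue section (or one component of it).

    Parameters
    ----------
    df
        DataFrame with columns ``cell_id`` (unique identifier), ``x_um``,
        ``y_um`` (micron coordinates, finite and non-negative) and
        ``cell_class`` (one of the five :class:`CellClass` values).
    section_id
        Non-empty identifier of the tissue section.
    sample_type
        ``pure_DCIS`` or ``IDC_DCIS``; optional for derived sub-tables.
    pixel_size
        Scan resolution in um/pixel (default 0.5, the x20 setting).
    metadata
        Free-form section metadata (ER status, grade, flags).
    """

    df: pd.DataFrame
    section_id: str
    sample_type: SampleType | None = None
    pixel_size: float = 0.5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.section_id:
            raise ValueError("section_id must be non-empty")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.sample_type is not None:
            self.sample_type = SampleType(self.sample_type)
        missing = [c for c in CELL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cell table is missing required columns: {missing}")
        df = self.df.loc[:, CELL_COLUMNS].reset_index(drop=True).copy()
        df["cell_class"] = df["cell_class"].map(
            lambda v: v.value if isinstance(v, CellClass) else str(v)
        )
        unknown = sorted(set(df["cell_class"]) - VALID_CLASS_VALUES)
        if unknown:
            raise ValueError(
                f"unknown cell_class labels {unknown}; expected one of "
                f"{sorted(VALID_CLASS_VALUES)}"
            )
        xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("cell coordinates must be finite")
        if xy.size and xy.min() < 0:
            raise ValueError("cell coordinates must be non-negative")
        if df["cell_id"].duplicated().any():
            raise ValueError("cell_id values must be unique")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_cells(self) -> int:
        return len(self.df)

    def coords(self, classes: Iterable[CellClass] | None = None) -> np.ndarray:
        """(n, 2) array of micron coordinates, optionally for a class subset."""
        df = self.df if classes is None else self._subset_df(classes)
        return df[["x_um", "y_um"]].to_numpy(dtype=float)

    def class_counts(self) -> dict[str, int]:
        counts = self.df["cell_class"].value_counts()
        return {c.value: int(counts.get(c.value, 0)) for c in CellClass}

    def _subset_df(self, classes: Iterable[CellClass]) -> pd.DataFrame:
        values = {CellClass(c).value for c in classes}
        return self.df[self.df["cell_class"].isin(values)]

    def subset(self, classes: Iterable[CellClass]) -> "CellMap":
        """New CellMap restricted to the given classes."""
        return self.replace(df=self._subset_df(classes))

    def select_ids(self, cell_ids: Sequence) -> "CellMap":
        """New CellMap restricted to the given cell_id values."""
        keep = self.df[self.df["cell_id"].isin(set(cell_ids))]
        return self.replace(df=keep)

    def replace(self, **kwargs) -> "CellMap":
        base = dict(
            df=self.df,
            section_id=self.section_id,
            sample_type=self.sample_type,
            pixel_size=self.pixel_size,
            metadata=dict(self.metadata),
        )
        base.update(kwargs)
        return CellMap(**base)

    @classmethod
    def from_arrays(
        cls,
        x: np.ndarray,
        y: np.ndarray,
        cell_class: Sequence,
        section_id: str,
        sample_type: SampleType | None = None,
        cell_ids: Sequence | None = None,
        **kwargs,
    ) -> "CellMap":
        n = len(x)
        if cell_ids is None:
            cell_ids = [f"c{i:06d}" for i in range(n)]
        df = pd.DataFrame(
            {
                "cell_id": list(cell_ids),
                "x_um": np.asarray(x, dtype=float),
                "y_um": np.asarray(y, dtype=float),
                "cell_class": [
                    c.value if isinstance(c, CellClass) else str(c)
                    for c in cell_class
                ],
            }
        )
        return cls(df=df, section_id=section_id, sample_type=sample_type, **kwargs)


@dataclass
class DuctMask:
    """Collection of DCIS duct outlines (simple polygons, um coordinates)."""

    polygons: list[Polygon]
    section_id: str = "section"

    def __post_init__(self) -> None:
        polys = []
        for i, p in enumerate(self.polygons):
            if not isinstance(p, Polygon):
                raise ValueError(f"duct {i} is not a polygon: {p.geom_type}")
            if not p.is_valid:
                raise ValueError(f"duct polygon {i} is not a valid simple polygon")
            if not p.area > 0:
                raise ValueError(f"duct polygon {i} has zero area")
            polys.append(shapely.geometry.polygon.orient(p, sign=1.0))
        self.polygons = polys

    def __len__(self) -> int:
        return len(self.polygons)

    @property
    def union(self):
        """Union geometry of all ducts (empty geometry when duct-free)."""
        if not self.polygons:
            return Polygon()
        return unary_union(self.polygons)

    @property
    def total_area(self) -> float:
        return float(self.union.area)

    def contains_points(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask: which of the (n, 2) points lie inside any duct."""
        xy = np.asarray(xy, dtype=float)
        if xy.size == 0 or not self.polygons:
            return np.zeros(len(xy), dtype=bool)
        u = self.union
        return shapely.covers(u, shapely.points(xy))
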
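"""Reading and writing the pipeline's file formats.

Cell tables travel as UTF-8 CSV with a required header
(``cell_id,x_um,y_um,cell_class``); duct masks travel either as GeoJSON
FeatureCollections of polygons (canonical, coordinates in microns, image
y-down frame) or as 8-bit label images (import convenience, requires a
um/pixel scale).  All readers validate and fail loudly with the offending
column, label or feature named.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Polygon, mapping, shape
from shapely.ops import unary_union
from shapely.validation import make_valid

from .cells import CELL_COLUMNS, VALID_CLASS_VALUES, CellMap, DuctMask, SampleType

# --------------------------------------------------------------------------
# cell tables


def read_cells(
    path,
    dialect: str = "csv",
    section_id: str | None = None,
    sample_type: SampleType | str | None = None,
    pixel_size: float = 0.5,
) -> CellMap:
    """Read a per-cell CSV table into a :class:`CellMap`.

    Coordinates may be given in microns (``x_um``/``y_um``) or in pixels
    (``x_px``/``y_px``), in which case they are converted using
    ``pixel_size`` (um/pixel).  Unknown class labels are rejected with the
    offending labels listed.
    """
    if dialect != "csv":
        raise ValueError(f"unsupported cell-table dialect: {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path)
    if "x_px" in df.columns and "x_um" not in df.columns:
        df["x_um"] = df["x_px"].astype(float) * pixel_size
        df["y_um"] = df["y_px"].astype(float) * pixel_size
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    unknown = sorted(set(df["cell_class"].astype(str)) - VALID_CLASS_VALUES)
    if unknown:
        raise ValueError(
            f"{path.name}: unknown cell_class label(s) {unknown}; expected "
            f"{sorted(VALID_CLASS_VALUES)}"
        )
    return CellMap(
        df=df,
        section_id=section_id or path.stem,
        sample_type=sample_type,
        pixel_size=pixel_size,
    )


def write_cells(cells: CellMap, path) -> Path:
    """Write a CellMap as CSV (columns cell_id, x_um, y_um, cell_class)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cells.df.to_csv(path, index=False)
    return path


# --------------------------------------------------------------------------
# duct masks


def _normalise_polygon(geom, index: int) -> list[Polygon]:
    """Validate/repair one GeoJSON geometry into a list of simple polygons."""
    if not geom.is_valid:
        geom = make_valid(geom)
        if not geom.is_valid:
            raise ValueError(f"feature {index}: invalid geometry, not repairable")
    polys: list[Polygon] = []
    if geom.geom_type == "Polygon":
        polys = [geom]
    elif geom.geom_type == "MultiPolygon":
        polys = list(geom.geoms)
    elif geom.geom_type == "GeometryCollection":
        polys = [g for g in geom.geoms if g.geom_type == "Polygon"]
    if not polys or any(p.area <= 0 for p in polys):
        raise ValueError(
            f"feature {index}: geometry of type {geom.geom_type} does not "
            "yield polygons of positive area"
        )
    return polys


def read_duct_mask(
    path,
    dialect: str = "geojson",
    pixel_size: float | None = None,
    section_id: str | None = None,
) -> DuctMask:
    """Read duct outlines from GeoJSON or from an 8-bit label image.

    For ``dialect="label_image"`` a ``pixel_size`` (um/pixel) is required;
    non-zero pixels are grouped into 8-connected components and converted
    to polygons as unions of pixel squares, so the polygon area equals the
    pixel count times ``pixel_size**2`` exactly and holes are preserved.
    """
    path = Path(path)
    if dialect == "geojson":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("type") != "FeatureCollection":
            raise ValueError(f"{path.name}: expected a GeoJSON FeatureCollection")
        polys: list[Polygon] = []
        for i, feat in enumerate(doc.get("features", [])):
            geom = shape(feat["geometry"])
            polys.extend(_normalise_polygon(geom, i))
        return DuctMask(polygons=polys, section_id=section_id or path.stem)
    if dialect == "label_image":
        if pixel_size is None:
            raise ValueError("label_image dialect requires a pixel_size (um/pixel)")
        img = _read_image(path)
        return DuctMask(
            polygons=label_image_to_polygons(img, pixel_size),
            section_id=section_id or path.stem,
        )
    raise ValueError(f"unsupported duct-mask dialect: {dialect!r}")


def _read_image(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def label_image_to_polygons(img: np.ndarray, pixel_size: float) -> list[Polygon]:
    """Vectorise a label image: one polygon (with holes) per 8-connected blob.

    Pixel (row r, col c) maps to the square [c, c+1] x [r, r+1] in pixel
    units, scaled by ``pixel_size``; foreground area is conserved exactly.
    """
    img = np.asarray(img)
    if img.ndim == 3:  # RGB(A) export of a binary mask
        img = img[..., :3].max(axis=-1)
    binary = img > 0
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    polys: list[Polygon] = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        boxes = [
            shapely.box(c * pixel_size, r * pixel_size, (c + 1) * pixel_size, (r + 1) * pixel_size)
            for r, c in zip(rows, cols)
        ]
        merged = unary_union(boxes)
        if merged.geom_type == "Polygon":
            polys.append(merged)
        else:  # 8-connected blobs touching only at corners may split
            polys.extend(g for g in merged.geoms if g.geom_type == "Polygon")
    return polys


def write_duct_mask_geojson(mask: DuctMask, path) -> Path:
    """Write ducts as a GeoJSON FeatureCollection (micron, y-down frame)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features = [
        {
            "type": "Feature",
            "properties": {"duct_id": i},
            "geometry": mapping(poly),
        }
        for i, poly in enumerate(mask.polygons)
    ]
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "section_id": mask.section_id,
            "coordinate_frame": "micron, image convention (y down), no CRS",
        },
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return path


def rasterize_mask(
    mask: DuctMask, shape_px: tuple[int, int], pixel_size: float
) -> np.ndarray:
    """Rasterise duct polygons onto a (rows, cols) boolean grid.

    A pixel is foreground when its centre lies inside the duct union —
    the inverse of :func:`label_image_to_polygons` up to half-pixel
    boundary effects.
    """
    rows, cols = shape_px
    u = mask.union
    if u.is_empty:
        return np.zeros(shape_px, dtype=bool)
    cx = (np.arange(cols) + 0.5) * pixel_size
    cy = (np.arange(rows) + 0.5) * pixel_size
    gx, gy = np.meshgrid(cx, cy)
    pts = shapely.points(np.column_stack([gx.ravel(), gy.ravel()]))
    return shapely.covers(u, pts).reshape(rows, cols)


def write_label_image(mask: DuctMask, path, shape_px, pixel_size: float) -> Path:
    """Write the mask as an 8-bit label image (0 background, 255 duct)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = (rasterize_mask(mask, shape_px, pixel_size) * 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    return path
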
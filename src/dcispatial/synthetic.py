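"""Synthetic tissue sections with controllable spatial structure.

The generator emulates a dual CA9/FOXP3-stained breast tissue section at
the micron scale: elliptical (optionally lobed) duct outlines, epithelial
cells confined to ducts (pure DCIS) or split between ducts and a
contiguous invasive mass (IDC/DCIS), CA9+ epithelium clustered into a
small number of hypoxic foci, lymphocytes and stroma in the inter-duct
compartment, and a tunable attraction that draws FOXP3+ lymphocytes
toward CA9+ epithelial cells.  At ``attraction=0`` the FOXP3+ placement
is conditionally independent of CA9 status; increasing it raises the
expected Morisita-Horn overlap of the FOXP3+/CA9+ pair monotonically.

A separate degradation step turns a ground-truth cell map into simulated
detector output (dropped cells, positional jitter, spurious detections,
label confusion) for exercising the evaluation metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from .cells import CellClass, CellMap, DuctMask, SampleType


class ConfigurationError(ValueError):
    """Parameter combination that admits no valid section."""


@dataclass
class SimulationParams:
    """Knobs of the synthetic section generator.

    Defaults follow the annotated class proportions of the stain
    (epithelium ~46% of cells with ~26% CA9+, lymphocytes ~47% with ~8.7%
    FOXP3+, stroma ~7%) scaled to ~3600 cells over a 2x2 mm field.
    """

    rng_seed: int = 0
    field_width: float = 2000.0  # um
    field_height: float = 2000.0
    n_ducts: int = 6
    duct_radius_range: tuple[float, float] = (100.0, 250.0)
    duct_shape: str = "ellipse"  # ellipse | lobed
    invasive_fraction: float = 0.5  # of epithelial cells, IDC/DCIS only
    n_epithelial: int = 1650
    n_lymphocyte: int = 1690
    n_stroma: int = 260
    ca9_pos_fraction: float = 0.257
    foxp3_pos_fraction: float = 0.087
    hypoxia_focality: int = 3
    attraction: float = 0.0
    attraction_bandwidth: float = 50.0  # um, kernel s.d. around CA9+ cells
    invasive_spread: float = 250.0  # um, s.d. of the invasive mass
    invasive_margin: float = 150.0  # um, min gap between mass centre and ducts
    jitter_sd: float = 2.0  # um, detector degradation defaults
    drop_rate: float = 0.1
    spurious_rate: float = 0.05

    def __post_init__(self) -> None:
        counts = {
            "n_ducts": self.n_ducts,
            "n_epithelial": self.n_epithelial,
            "n_lymphocyte": self.n_lymphocyte,
            "n_stroma": self.n_stroma,
            "hypoxia_focality": self.hypoxia_focality,
        }
        for name, v in counts.items():
            if v < 0 or int(v) != v:
                raise ConfigurationError(f"{name} must be a non-negative integer")
        fractions = {
            "invasive_fraction": self.invasive_fraction,
            "ca9_pos_fraction": self.ca9_pos_fraction,
            "foxp3_pos_fraction": self.foxp3_pos_fraction,
            "drop_rate": self.drop_rate,
            "spurious_rate": self.spurious_rate,
        }
        for name, v in fractions.items():
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        rmin, rmax = self.duct_radius_range
        if not (0 < rmin <= rmax):
            raise ConfigurationError("duct_radius_range must satisfy 0 < min <= max")
        if self.field_width <= 0 or self.field_height <= 0:
            raise ConfigurationError("field dimensions must be positive")
        if self.duct_shape not in ("ellipse", "lobed"):
            raise ConfigurationError("duct_shape must be 'ellipse' or 'lobed'")
        if self.attraction < 0:
            raise ConfigurationError("attraction must be non-negative")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be non-negative")


@dataclass
class SyntheticSection:
    """Ground-truth cell map + duct mask for one simulated section."""

    cells: CellMap
    ducts: DuctMask
    sample_type: SampleType
    params: SimulationParams

    def __post_init__(self) -> None:
        field_poly = box(0, 0, self.params.field_width, self.params.field_height)
        for i, p in enumerate(self.ducts.polygons):
            if not field_poly.covers(p):
                raise ValueError(f"duct {i} extends outside the field")
        for i in range(len(self.ducts.polygons)):
            for j in range(i + 1, len(self.ducts.polygons)):
                inter = self.ducts.polygons[i].intersection(self.ducts.polygons[j])
                if inter.area > 0:
                    raise ValueError(f"ducts {i} and {j} overlap")


def simulate_section(
    params: SimulationParams,
    sample_type: SampleType | str = SampleType.PURE_DCIS,
    section_id: str | None = None,
) -> SyntheticSection:
    """Generate one synthetic section; deterministic given ``params.rng_seed``.

    Pure-DCIS sections force ``invasive_fraction`` to 0 (all epithelium in
    ducts); IDC/DCIS sections place the invasive epithelium as a Gaussian
    mass around a focus kept clear of the ducts.  Exactly the requested
    number of cells per class is produced.
    """
    sample_type = SampleType(sample_type)
    if sample_type is SampleType.PURE_DCIS:
        params = replace(params, invasive_fraction=0.0)
    rng = np.random.default_rng(params.rng_seed)
    field_poly = box(0, 0, params.field_width, params.field_height)

    n_invasive = int(np.floor(params.invasive_fraction * params.n_epithelial + 0.5))
    n_in_duct = params.n_epithelial - n_invasive
    if n_in_duct > 0 and params.n_ducts == 0:
        raise ConfigurationError(
            "n_ducts=0 leaves no place for in-duct epithelial cells "
            f"({n_in_duct} requested)"
        )

    ducts = _sample_ducts(params, rng)
    duct_union = unary_union(ducts) if ducts else Polygon()

    epi_xy = np.zeros((0, 2))
    if n_in_duct:
        epi_xy = _uniform_in_ducts(rng, ducts, n_in_duct)
    if n_invasive:
        inv_xy = _invasive_mass(rng, params, field_poly, duct_union, n_invasive)
        epi_xy = np.vstack([epi_xy, inv_xy])
    in_duct_flag = np.zeros(len(epi_xy), dtype=bool)
    in_duct_flag[:n_in_duct] = True

    ca9_pos = _pick_hypoxic(rng, params, epi_xy, in_duct_flag)

    stroma_xy = _uniform_outside(rng, field_poly, duct_union, params.n_stroma)

    n_fox = int(np.floor(params.foxp3_pos_fraction * params.n_lymphocyte + 0.5))
    n_foxneg = params.n_lymphocyte - n_fox
    foxneg_xy = _uniform_outside(rng, field_poly, duct_union, n_foxneg)
    fox_xy = _place_foxp3_pos(
        rng, params, field_poly, duct_union, epi_xy[ca9_pos], n_fox
    )

    xs, ys, classes, flags = [], [], [], []
    for (x, y), pos, ind in zip(epi_xy, ca9_pos, in_duct_flag):
        xs.append(x)
        ys.append(y)
        classes.append(
            CellClass.CA9_POS_EPITHELIAL if pos else CellClass.CA9_NEG_EPITHELIAL
        )
        flags.append(bool(ind))
    for x, y in fox_xy:
        xs.append(x)
        ys.append(y)
        classes.append(CellClass.FOXP3_POS_LYMPHOCYTE)
        flags.append(False)
    for x, y in foxneg_xy:
        xs.append(x)
        ys.append(y)
        classes.append(CellClass.FOXP3_NEG_LYMPHOCYTE)
        flags.append(False)
    for x, y in stroma_xy:
        xs.append(x)
        ys.append(y)
        classes.append(CellClass.STROMA)
        flags.append(False)

    sid = section_id or f"sim_{sample_type.value}_{params.rng_seed}"
    cells = CellMap.from_arrays(
        np.asarray(xs),
        np.asarray(ys),
        classes,
        section_id=sid,
        sample_type=sample_type,
        metadata={
            "field_width": params.field_width,
            "field_height": params.field_height,
            "in_duct": flags,
        },
    )
    mask = DuctMask(polygons=ducts, section_id=sid)
    return SyntheticSection(cells=cells, ducts=mask, sample_type=sample_type, params=params)


# --------------------------------------------------------------------------
# placement helpers


def _sample_ducts(params: SimulationParams, rng: np.random.Generator) -> list[Polygon]:
    """Rejection-sample non-overlapping duct outlines inside the field."""
    rmin, rmax = params.duct_radius_range
    gap = 5.0  # um clearance so ducts stay pairwise disjoint
    ducts: list[Polygon] = []
    attempts = 0
    max_attempts = 5000 * max(params.n_ducts, 1)
    while len(ducts) < params.n_ducts:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigurationError(
                f"could not place {params.n_ducts} non-overlapping ducts of "
                f"radius {params.duct_radius_range} in a "
                f"{params.field_width}x{params.field_height} field"
            )
        a = rng.uniform(rmin, rmax)
        b = rng.uniform(rmin, rmax)
        theta = rng.uniform(0, 180.0)
        r_eff = max(a, b)
        cx = rng.uniform(r_eff, params.field_width - r_eff)
        cy = rng.uniform(r_eff, params.field_height - r_eff)
        if params.duct_shape == "ellipse":
            duct = Point(cx, cy).buffer(1.0, quad_segs=24)
            duct = affinity.scale(duct, a, b)
        else:
            duct = _lobed_polygon(rng, cx, cy, (a + b) / 2.0)
        duct = affinity.rotate(duct, theta, origin=(cx, cy))
        if not box(0, 0, params.field_width, params.field_height).covers(duct):
            continue
        if any(duct.distance(d) < gap for d in ducts):
            continue
        ducts.append(duct)
    return ducts


def _lobed_polygon(rng, cx: float, cy: float, r0: float) -> Polygon:
    """Radially perturbed circle, mimicking lobular duct outlines."""
    m = int(rng.integers(3, 7))
    phase = rng.uniform(0, 2 * np.pi)
    amp = rng.uniform(0.1, 0.25)
    theta = np.linspace(0, 2 * np.pi, 96, endpoint=False)
    r = r0 * (1.0 + amp * np.sin(m * theta + phase))
    return Polygon(np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)]))


def _uniform_in_ducts(rng, ducts: list[Polygon], n: int) -> np.ndarray:
    areas = np.array([d.area for d in ducts])
    choice = rng.choice(len(ducts), size=n, p=areas / areas.sum())
    pts = np.zeros((n, 2))
    for i, duct_idx in enumerate(choice):
        pts[i] = _rejection_point(rng, ducts[duct_idx])
    return pts


def _rejection_point(rng, poly: Polygon) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    while True:
        p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
        if poly.covers(Point(p)):
            return p


def _uniform_outside(rng, field_poly: Polygon, duct_union, n: int) -> np.ndarray:
    """Uniform points in the stromal compartment (field minus ducts)."""
    pts = np.zeros((n, 2))
    minx, miny, maxx, maxy = field_poly.bounds
    for i in range(n):
        while True:
            p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
            if duct_union.is_empty or not duct_union.covers(Point(p)):
                pts[i] = p
                break
    return pts


def _invasive_mass(
    rng, params: SimulationParams, field_poly: Polygon, duct_union, n: int
) -> np.ndarray:
    """Contiguous invasive mass: truncated-Gaussian cluster clear of ducts.

    Draws are truncated at 2.5 s.d. so the mass stays a coherent region
    rather than scattering stray cells across the whole section.
    """
    minx, miny, maxx, maxy = field_poly.bounds
    centre = None
    for _ in range(2000):
        c = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
        d = 0.0 if duct_union.is_empty else Point(c).distance(duct_union)
        if duct_union.is_empty or d >= params.invasive_margin:
            centre = c
            break
    if centre is None:
        raise ConfigurationError(
            "no room for an invasive mass at the requested margin from ducts"
        )
    pts = np.zeros((n, 2))
    r_max = 2.5 * params.invasive_spread
    for i in range(n):
        while True:
            offset = rng.normal(0.0, params.invasive_spread, size=2)
            if np.hypot(*offset) > r_max:
                continue
            p = centre + offset
            inside = (minx <= p[0] <= maxx) and (miny <= p[1] <= maxy)
            if inside and (duct_union.is_empty or not duct_union.covers(Point(p))):
                pts[i] = p
                break
    return pts


def _pick_hypoxic(
    rng, params: SimulationParams, epi_xy: np.ndarray, in_duct: np.ndarray
) -> np.ndarray:
    """Mark the CA9+ epithelial subset, clustered into hypoxic foci.

    Focus centres are drawn from in-duct epithelium when present (CA9
    expression is focal within ducts); the requested number of CA9+ cells
    are those nearest to any focus.
    """
    n_epi = len(epi_xy)
    n_ca9 = int(np.floor(params.ca9_pos_fraction * n_epi + 0.5))
    mask = np.zeros(n_epi, dtype=bool)
    if n_ca9 == 0 or n_epi == 0:
        return mask
    n_foci = max(1, min(params.hypoxia_focality, n_epi))
    pool = np.flatnonzero(in_duct) if in_duct.any() else np.arange(n_epi)
    foci_idx = rng.choice(pool, size=min(n_foci, len(pool)), replace=False)
    foci = epi_xy[foci_idx]
    d = np.min(
        np.linalg.norm(epi_xy[:, None, :] - foci[None, :, :], axis=2), axis=1
    )
    mask[np.argsort(d, kind="stable")[:n_ca9]] = True
    return mask


def _place_foxp3_pos(
    rng,
    params: SimulationParams,
    field_poly: Polygon,
    duct_union,
    ca9_xy: np.ndarray,
    n: int,
) -> np.ndarray:
    """FOXP3+ lymphocytes: uniform/attracted mixture in the stroma.

    With weight w = attraction / (1 + attraction) a FOXP3+ cell is placed
    by a Gaussian kernel (s.d. ``attraction_bandwidth``) around a random
    CA9+ epithelial cell — attracted cells may infiltrate ducts, as Tregs
    recruited to hypoxic epithelium do; with weight 1 - w it is uniform in
    the stroma like any other lymphocyte.  attraction = 0 (w = 0) makes
    the placement independent of CA9 locations.
    """
    if n == 0:
        return np.zeros((0, 2))
    w = params.attraction / (1.0 + params.attraction)
    minx, miny, maxx, maxy = field_poly.bounds
    pts = np.zeros((n, 2))
    for i in range(n):
        attracted = len(ca9_xy) > 0 and rng.random() < w
        if not attracted:
            pts[i] = _uniform_outside(rng, field_poly, duct_union, 1)[0]
            continue
        placed = False
        for _ in range(200):
            anchor = ca9_xy[rng.integers(len(ca9_xy))]
            p = anchor + rng.normal(0.0, params.attraction_bandwidth, size=2)
            if (minx <= p[0] <= maxx) and (miny <= p[1] <= maxy):
                pts[i] = p
                placed = True
                break
        if not placed:  # pathological geometry; keep the count exact
            pts[i] = _uniform_outside(rng, field_poly, duct_union, 1)[0]
    return pts


# --------------------------------------------------------------------------
# detector degradation


def degrade_detections(
    cells: CellMap,
    jitter_sd: float = 2.0,
    drop_rate: float = 0.1,
    spurious_rate: float = 0.05,
    rng_seed: int = 0,
    confusion_rate: float = 0.0,
) -> CellMap:
    """Simulated detector output from a ground-truth cell map.

    Each true cell is dropped independently with ``drop_rate``; survivors
    are displaced by isotropic Gaussian noise of s.d. ``jitter_sd`` um
    (clipped into the non-negative quadrant); ``Binomial(n, spurious_rate)``
    spurious detections are added uniformly over the occupied extent; with
    ``confusion_rate`` a surviving cell's label is reassigned to a
    different class uniformly.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    for name, v in [
        ("drop_rate", drop_rate),
        ("spurious_rate", spurious_rate),
        ("confusion_rate", confusion_rate),
    ]:
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    df = cells.df
    n = len(df)
    keep = rng.random(n) >= drop_rate
    xy = df[["x_um", "y_um"]].to_numpy(float)[keep]
    labels = df["cell_class"].to_numpy()[keep].tolist()
    if jitter_sd > 0 and len(xy):
        xy = np.clip(xy + rng.normal(0.0, jitter_sd, size=xy.shape), 0.0, None)
    if confusion_rate > 0:
        all_classes = [c.value for c in CellClass]
        for i in range(len(labels)):
            if rng.random() < confusion_rate:
                others = [c for c in all_classes if c != labels[i]]
                labels[i] = others[rng.integers(len(others))]
    n_spurious = int(rng.binomial(n, spurious_rate)) if n else 0
    if n_spurious:
        width = cells.metadata.get("field_width")
        height = cells.metadata.get("field_height")
        if width is None or height is None:
            full = df[["x_um", "y_um"]].to_numpy(float)
            width = full[:, 0].max() if len(full) else 1.0
            height = full[:, 1].max() if len(full) else 1.0
        sx = rng.uniform(0, width, size=n_spurious)
        sy = rng.uniform(0, height, size=n_spurious)
        freq = df["cell_class"].value_counts(normalize=True)
        s_labels = rng.choice(freq.index.to_numpy(), size=n_spurious, p=freq.to_numpy())
        xy = np.vstack([xy, np.column_stack([sx, sy])]) if len(xy) else np.column_stack([sx, sy])
        labels = labels + list(s_labels)
    return CellMap.from_arrays(
        xy[:, 0] if len(xy) else np.zeros(0),
        xy[:, 1] if len(xy) else np.zeros(0),
        labels,
        section_id=cells.section_id,
        sample_type=cells.sample_type,
        cell_ids=[f"p{i:06d}" for i in range(len(labels))],
        pixel_size=cells.pixel_size,
        metadata={
            **{k: v for k, v in cells.metadata.items() if k != "in_duct"},
            "degraded": True,
        },
    )
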
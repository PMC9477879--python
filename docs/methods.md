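# Methods

## Problem and data model

A dual CA9/FOXP3 immunohistochemistry section is reduced to two objects:
a per-cell table (micron coordinates, one of five classes: CA9+ / CA9−
epithelial, FOXP3+ / FOXP3− lymphocyte, stroma) and a duct mask (simple
polygons outlining DCIS ducts). Coordinates use the image convention —
origin top-left, y down, microns — matching slides scanned at 0.5 µm/px.
Sections are either *pure DCIS* (all cancer confined to ducts) or
*IDC/DCIS* (ducts plus an invasive component in the same section).

## Colocalization index

Spatial overlap of two cell types is the Morisita–Horn index over quadrat
counts,

    MH = 2·Σᵢxᵢyᵢ / [(Σᵢxᵢ²/X² + Σᵢyᵢ²/Y²)·X·Y],   X=Σxᵢ, Y=Σyᵢ,

bounded in [0, 1]: 0 iff the two types never share a quadrat, 1 when
per-quadrat counts are exactly proportional. The implementation evaluates
the cleared-denominator form `2·Σxy·XY / (Σx²·Y² + Σy²·X²)`, which is
exact for integer counts (products stay below 2⁵³ for any realistic
section) and symmetric in its arguments to the last bit. An absent
population (X=0 or Y=0) or fewer than two quadrats yields a flagged null,
never an exception.

## Quadrats: Voronoi tessellation with cube-root seeding

The number of Voronoi seeds is the cube root of the cell count in the
region of interest, rounded half away from zero with a floor of 2 (the
rounding rule and floor are implementation choices; only the cube-root
scaling is prescribed by the method). Seed *placement* is not prescribed
either; we use k-means centroids of the cell coordinates (fixed
`random_state`, 4 restarts) so the tessellation adapts to tissue density
and is deterministic. The diagram is clipped to the ROI — by default the
convex hull of all cells buffered by 50 µm when no tissue outline is
supplied — and cells are assigned to their nearest seed, boundary ties
going to the lowest polygon id. Polygon areas sum to the ROI area
(relative tolerance 1e-6) and every in-ROI cell lands in exactly one
polygon.

## Component typing

IDC/DCIS polygons are typed by their *cancer content* with thresholds
t_low = 0.1 and t_high = 0.9:

- with epithelial cells present, let s = fraction of the polygon's
  epithelial cells lying inside duct polygons and d = duct area fraction:
  **synchronous DCIS** if s ≥ t_high or d ≥ t_high (cancer content is
  ductal only); **IDC** if s ≤ t_low and d ≤ t_low (predominantly
  invasive); **mixed** otherwise (the duct/invasive interface);
- without epithelial cells: **excluded** if d ≤ t_low (stroma, fat,
  artifacts — these polygons enter no component), **synchronous DCIS** if
  d ≥ t_high, **mixed** otherwise.

A cell-content rule rather than a pure area rule is used because Voronoi
quadrats at cube-root seed counts are much larger than individual ducts:
a quadrat whose cancer is entirely ductal still contains surrounding
stroma, so its duct *area* fraction rarely approaches 1 even when it is
unambiguously a ductal region. Typing is monotone in d: increasing a
polygon's duct area can never move it from synchronous DCIS toward IDC.
Mixed and excluded polygons contribute to neither component's statistics
(switchable in principle, but the default mirrors treating the interface
as unassignable).

Each class pair's index is computed once per component over that
component's quadrats, from a single whole-section tessellation (polygon
identity stays consistent with the component map; per-component
re-tessellation is not performed by default). A component backed by no
polygons or by fewer than 50 cells yields flagged nulls for all its pairs
— the minimum-data rule that operationalizes dropping sections without
sufficient synchronous DCIS, which the source method leaves unquantified.
Nulls are dropped, not zero-filled, in group statistics.

## Abundance

FOXP3+ abundance = FOXP3+ / (FOXP3+ + FOXP3−) lymphocytes; CA9+ abundance
= CA9+ / (CA9+ + CA9−) epithelial cells, per section or per component.
Zero denominators yield flagged nulls.

## Group statistics

Pairwise Wilcoxon rank-sum tests compare an index across the three groups
(pure DCIS, synchronous DCIS, IDC). The test is exact for combined n ≤ 50
without ties, tie-corrected asymptotic otherwise. The Holm step-down
adjustment is applied within one cell-class pair's family of group
contrasts (three tests), not across all pairs jointly. Covariate
adjustment fits an ordinary linear model `index ~ C(group) + covariates`
and reports the group coefficient's p-value; a rank-based variant can be
obtained by rank-transforming the outcome first. Rank-deficient designs
are rejected with the collinear terms named.

## Validation metrics

- **Detection**: minimum-cost one-to-one matching (Hungarian algorithm)
  between predicted and true points with a 10 µm default radius (~one
  nucleus diameter at 0.5 µm/px; the matching rule is an implementation
  choice — greedy matching was rejected for order dependence). Matched =
  TP; precision, recall, F1 computed exactly from counts, rounded only
  for presentation (half away from zero, 2 d.p.).
- **Segmentation**: pixelwise Dice = 2TP/(2TP+FP+FN), precision, recall
  (= sensitivity) and specificity between same-shape binary masks; vector
  masks are rasterized at a declared resolution first.
- **Classification**: 5×5 confusion matrix (true × predicted),
  per-predicted-class correct percentage (diagonal / column sum) and
  overall accuracy (trace / total).
- **CA9 cross-tab**: per-section CA9+ abundance binned on the percent
  scale into [0, 1], (1, 5], (5, 100] — half-open upward so boundary
  values fall in the lower bin — cross-tabulated against the slide-level
  pathologist score groups (Negative: 100 % of DCIS epithelium graded
  CA9-negative; Positive: any positivity), with nearest-integer row
  percentages.

## Synthetic tissue generator

The generator emulates the statistical structure of a stained section,
not its pixel appearance:

- **Field**: 2000 × 2000 µm continuous coordinates (a ×20 tile
  neighborhood); whole slides are larger, but all statistics here scale
  with cell counts, not physical extent.
- **Ducts**: 6 random ellipses (optionally lobed, i.e. radially perturbed)
  with semi-axes 100–250 µm, rejection-sampled to pairwise disjointness
  (5 µm clearance) inside the field. Duct size/density distributions of
  real cohorts are unreported; these defaults are plausibility choices.
- **Cell counts**: 1650 epithelial, 1690 lymphocytes, 260 stroma —
  the class proportions of the stain's annotation set (≈46 % epithelial
  of which 25.7 % CA9+, ≈47 % lymphocytes of which 8.7 % FOXP3+, ≈7 %
  stroma) scaled to ~3600 cells. Requested counts are met exactly.
- **Placement**: in-duct epithelium uniform within ducts; for IDC/DCIS,
  half the epithelium (configurable) forms a contiguous invasive mass — a
  Gaussian cluster (s.d. 250 µm, truncated at 2.5 s.d. so the mass stays
  coherent) around a focus kept ≥ 150 µm from duct boundaries, since
  invasive carcinoma grows as a mass adjacent to ducts rather than as
  uniform scatter. Lymphocytes and stroma occupy the inter-duct
  compartment. CA9+ epithelium is the subset nearest to a small number of
  hypoxic foci (3 by default, drawn from in-duct cells), giving the focal
  expression pattern seen in DCIS.
- **Attraction**: each FOXP3+ lymphocyte is, with probability
  w = attraction/(1+attraction), placed by a Gaussian kernel (s.d. 50 µm)
  around a random CA9+ cell (attracted Tregs may infiltrate ducts);
  otherwise uniformly in the stroma. At attraction = 0 the FOXP3+
  placement is independent of CA9 locations; the expected FOXP3+/CA9+
  index is monotone in the attraction weight.
- **Degradation** (`degrade_detections`): independent dropout, isotropic
  positional jitter, binomially many uniform spurious detections and
  optional label confusion turn ground truth into simulated detector
  output for the evaluation metrics.

What the generator does **not** model: nucleus-level morphology, stain
intensity, imaging artifacts, duct architecture subtypes (cribriform /
solid / comedo / papillary), lymphocyte aggregates, or spatially varying
cell density beyond the duct/stroma/mass structure. Passing tests
therefore demonstrate correctness of the statistical machinery under a
controlled point-process model, not performance on real slides.

## Problem sizes and runtime choices

Tests and the acceptance suite run sections of ~900 cells (1.2 × 1.2 mm,
3 ducts) for replicated experiments and ~3600 cells (the defaults) for
single-section checks; these sizes were chosen so that replicated Monte
Carlo suites (100 paired sections, 3-level attraction grids, 400-sim
calibration checks) complete in tens of seconds while keeping ≥ 8
quadrats per section. KMeans uses 4 restarts; all randomness flows from
explicit integer seeds, and identical seeds reproduce outputs bit for
bit.

## Known limitations

- The duct/invasive interface genuinely mixes: with cube-root seed
  counts, quadrats are ~500 µm across, so ducts adjacent to the invasive
  mass shed a share (~15 % at defaults) of their in-duct epithelium into
  mixed interface polygons rather than synchronous-DCIS polygons. This is
  a property of coarse quadrats, not a bug; finer seeding (a config
  choice) sharpens routing at the cost of sparser per-quadrat counts.
- The Morisita–Horn index ignores within-quadrat structure; two types can
  be segregated at scales below the quadrat size yet score near 1.
- The covariate-adjusted test assumes an additive linear model on the
  index scale; indices near the 0/1 boundary may violate homoscedasticity.
- Sections with fewer than ~50 cells per component return nulls by
  design; the 50-cell floor is a judgment call, exposed as `min_cells`.
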
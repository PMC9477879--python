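# dcispatial

Spatial statistics for the tumor microenvironment of ductal carcinoma in
situ (DCIS): how tissue hypoxia (CA9+ epithelium) and T-cell regulation
(FOXP3+ lymphocytes, i.e. Tregs) colocalize within breast tumor sections,
and how that colocalization differs between pure DCIS, synchronous DCIS
(ducts inside invasive sections) and invasive (IDC) components.

The package is aimed at computational pathology groups working with
single-cell read-outs of immunohistochemistry (IHC) whole-slide images:
it takes per-cell coordinates with a five-way class label (CA9± epithelial,
FOXP3± lymphocyte, stroma) plus duct outlines, and produces per-component
colocalization indices, abundance fractions and group statistics. A
synthetic tissue generator with a tunable Treg–hypoxia attraction makes the
whole pipeline testable end to end without slide data.

## The statistic at the core

Colocalization of two cell types is quantified by the **Morisita–Horn
index** over quadrat counts $x_i$, $y_i$ (with $X=\sum_i x_i$,
$Y=\sum_i y_i$):

$$\mathrm{MH} = \frac{2\sum_i x_i y_i}{\left(\sum_i x_i^2/X^2 + \sum_i y_i^2/Y^2\right) X Y}$$

MH ranges from 0 (complete spatial segregation) to 1 (maximal
colocalization: proportional counts in every quadrat). Quadrats are
**Voronoi polygons** seeded at k-means centroids of the cell coordinates,
with the seed count set to the **cube root of the number of cells** in the
region of interest. In mixed IDC/DCIS sections, each polygon is typed as
*synchronous DCIS* (its cancer cells confined to ducts), *IDC*
(predominantly invasive cancer cells), *mixed* (the duct/invasive
interface) or *excluded* (no cancer content), and every index is computed
separately over the synchronous-DCIS and IDC quadrats. Abundances are
simple lineage fractions, e.g. FOXP3+ abundance
$= |{\rm FOXP3^+}| / (|{\rm FOXP3^+}| + |{\rm FOXP3^-}|)$.

Group differences (pure DCIS vs synchronous DCIS vs IDC) are tested with
pairwise Wilcoxon rank-sum tests, Holm-adjusted within each cell-pair
family, with optional covariate adjustment (ER status, grade, abundances)
via a linear model. Validation metrics for upstream detectors are also
provided: point-detection precision/recall/F1 by Hungarian matching,
pixelwise Dice/precision/recall/sensitivity/specificity for duct masks,
five-class confusion summaries, and the CA9-abundance-bin vs
pathologist-score cross-tab.

## Worked example

```python
from dcispatial import (SimulationParams, SampleType, simulate_section,
                        colocalize_section, abundance)

params = SimulationParams(rng_seed=42, attraction=4.0)   # Tregs drawn to CA9+ cells
section = simulate_section(params, SampleType.IDC_DCIS)
for r in colocalize_section(section.cells, section.ducts, rng_seed=0):
    print(r.component, r.pair, r.mh_index, r.n_polygons)
```

prints (abridged):

```
synchronous_DCIS  FOXP3_pos_lymphocyte vs CA9_pos_epithelial  MH=0.977  quadrats=8
synchronous_DCIS  FOXP3_neg_lymphocyte vs CA9_pos_epithelial  MH=0.539  quadrats=8
synchronous_DCIS  FOXP3_pos_lymphocyte vs CA9_neg_epithelial  MH=0.181  quadrats=8
synchronous_DCIS  FOXP3_neg_lymphocyte vs CA9_neg_epithelial  MH=0.458  quadrats=8
IDC               FOXP3_pos_lymphocyte vs CA9_pos_epithelial  MH=null   quadrats=1
...
```

With a planted attraction of 4, the FOXP3+/CA9+ index (0.977) stands far
above the FOXP3−/CA9+ control (0.539): regulatory T cells track the
hypoxic epithelium while other lymphocytes do not. For this seed the IDC
component collapses into a single quadrat, so its indices are returned as
flagged nulls rather than numbers — the same mechanism that excludes real
sections lacking sufficient synchronous DCIS from group comparisons.
Whole-section abundances come out at their configured values
(`abundance(section.cells)` → FOXP3+ 0.087, CA9+ 0.257).

The same stages are available from the shell:

```bash
dcispatial simulate --seed 42 --out sim/           # cells.csv + ducts.geojson
dcispatial colocalize --cells sim/cells.csv --ducts sim/ducts.geojson \
    --sample-type IDC_DCIS --out coloc.csv
dcispatial run --seed 5 --out run/                 # full multi-section pipeline
```

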
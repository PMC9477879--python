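"""Group comparisons of per-section spatial indices.

Colocalization indices and abundances are compared across the three tumor
groups (pure DCIS sections, synchronous-DCIS components, IDC components)
with pairwise Wilcoxon rank-sum tests, Holm-adjusted within each
cell-class pair's family of group contrasts.  Covariate-adjusted
differences (ER status, grade, abundance terms) use an ordinary linear
model of the index on the group indicator plus covariates, reporting the
group coefficient's p-value as the adjusted test of independence.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: below this per-group size a contrast is skipped with a warning
MIN_GROUP_SIZE = 2


@dataclass
class GroupedMeasurements:
    """Per-section values labelled by group, nulls dropped and counted."""

    data: pd.DataFrame  # columns: value, group (+ optional covariates)
    value_col: str = "value"
    group_col: str = "group"
    n_dropped: int = 0

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, value_col: str = "value", group_col: str = "group"
    ) -> "GroupedMeasurements":
        keep = df[value_col].notna() & np.isfinite(
            df[value_col].astype(float, errors="ignore")
        )
        return cls(
            data=df[keep].reset_index(drop=True),
            value_col=value_col,
            group_col=group_col,
            n_dropped=int((~keep).sum()),
        )

    def group_sizes(self) -> dict[str, int]:
        return self.data.groupby(self.group_col, observed=True).size().to_dict()


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact for small tie-free samples, tie-corrected normal approximation
    otherwise (scipy chooses per its standard rules).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    method = "exact" if (len(a) + len(b) <= 50 and _tie_free(a, b)) else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def _tie_free(a, b) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) == len(pooled)


def pairwise_wilcoxon_holm(
    data: GroupedMeasurements, min_group_size: int = MIN_GROUP_SIZE
) -> pd.DataFrame:
    """All pairwise group contrasts with Holm-adjusted rank-sum p-values.

    Returns a tidy table (group_a, group_b, n_a, n_b, p_raw, p_holm).
    Contrasts involving a group below ``min_group_size`` are skipped with
    a warning; the Holm family is the set of contrasts actually tested.
    """
    df = data.data
    groups = sorted(df[data.group_col].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups with non-null values")
    sizes = {g: int((df[data.group_col].astype(str) == g).sum()) for g in groups}
    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        if sizes[ga] < min_group_size or sizes[gb] < min_group_size:
            warnings.warn(
                f"skipping contrast {ga} vs {gb}: group below "
                f"{min_group_size} non-null values"
            )
            continue
        va = df.loc[df[data.group_col].astype(str) == ga, data.value_col].to_numpy(float)
        vb = df.loc[df[data.group_col].astype(str) == gb, data.value_col].to_numpy(float)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "n_a": sizes[ga],
                "n_b": sizes[gb],
                "p_raw": rank_sum_test(va, vb),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = holm_adjust(out["p_raw"])
    else:
        out["p_holm"] = pd.Series(dtype=float)
    return out


def adjusted_difference(
    data: GroupedMeasurements,
    outcome: str | None = None,
    group_factor: str | None = None,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted group difference via an ordinary linear model.

    Fits ``outcome ~ C(group) + covariates`` by OLS and returns the
    coefficient table; the group-indicator p-value is the adjusted test of
    whether the group difference is independent of the covariates.
    Rank-deficient designs are rejected with the collinear terms named.
    """
    import statsmodels.formula.api as smf

    outcome = outcome or data.value_col
    group_factor = group_factor or data.group_col
    covariates = list(covariates or [])
    df = data.data.copy()
    for col in [outcome, group_factor, *covariates]:
        if col not in df.columns:
            raise ValueError(f"column {col!r} not present in data")
    terms = [f"C({group_factor})"] + covariates
    formula = f"{outcome} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        collinear = _collinear_terms(exog, model.exog_names)
        raise ValueError(f"design matrix is rank-deficient; collinear terms: {collinear}")
    fit = model.fit()
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "std_err": fit.bse,
            "t": fit.tvalues,
            "p_value": fit.pvalues,
        }
    )
    table.index.name = "term"
    return table


def _collinear_terms(exog: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns linearly dependent on their predecessors."""
    bad = []
    for j in range(1, exog.shape[1]):
        sub = exog[:, : j + 1]
        if np.linalg.matrix_rank(sub) < sub.shape[1]:
            bad.append(names[j])
    return bad
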
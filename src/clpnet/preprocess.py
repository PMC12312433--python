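"""Missing-data imputation, standardization, and group descriptives.

Imputation follows the iterative random-forest ("missForest") scheme: missing
cells start at their column means; columns are visited in order of ascending
missingness; each pass refits a random-forest regressor per incomplete column
on all other columns and re-predicts its missing cells; iteration stops when
the normalized change between successive imputations first increases (the
previous iteration's values are returned) or when the iteration cap is hit.
A single completed dataset results — no multiple-imputation pooling.

Standardization z-scores every construct-wave column and age (sample SD,
n-1), and centers 0/1 covariates without rescaling so their coefficients stay
on the per-category scale. The recorded centers/scales allow exact inversion.

Group descriptives use Welch's unequal-variance t-test, a robust default for
two-group comparisons of questionnaire totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .panel import InputError, PanelDataset


# ---------------------------------------------------------------------------
# Random-forest imputation
# ---------------------------------------------------------------------------


def impute_random_forest(
    data: PanelDataset,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
) -> PanelDataset:
    """Single iterative random-forest imputation of construct columns.

    Observed cells are never altered. Covariate and group columns must be
    complete (they are used as predictors). Deterministic under a fixed seed.
    """
    out = data.copy()
    node_cols = data.node_columns()
    mask = data.mask[node_cols].to_numpy()
    if not mask.any():
        return out
    for c in data.covariates:
        if data.frame[c].isna().any():
            raise InputError(f"covariate column {c!r} has missing values")
    fully_missing = [c for c, m in zip(node_cols, mask.T) if m.all()]
    if fully_missing:
        raise InputError(f"column(s) fully missing, cannot impute: {fully_missing}")

    predictor_cols = list(node_cols) + list(data.covariates)
    if data.group_col is not None:
        codes = pd.Categorical(out.frame[data.group_col]).codes.astype(float)
        group_num = "_group_code_"
        out.frame[group_num] = codes
        predictor_cols.append(group_num)

    work = out.frame[predictor_cols].to_numpy(dtype=float)
    n_nodes = len(node_cols)
    col_mask = [mask[:, j] for j in range(n_nodes)]
    # mean initialization
    for j in range(n_nodes):
        if col_mask[j].any():
            work[col_mask[j], j] = np.nanmean(data.frame[node_cols[j]].to_numpy(dtype=float))
    # visit order: ascending missingness
    order = sorted(
        (j for j in range(n_nodes) if col_mask[j].any()),
        key=lambda j: (col_mask[j].sum(), j),
    )

    prev = work.copy()
    prev_change = np.inf
    rng = np.random.default_rng(seed)
    for _ in range(max_iter):
        for j in order:
            m = col_mask[j]
            others = [k for k in range(work.shape[1]) if k != j]
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(work[~m][:, others], work[~m, j])
            work[m, j] = rf.predict(work[m][:, others])
        # missForest stopping rule: normalized squared change over imputed cells
        num = den = 0.0
        for j in range(n_nodes):
            m = col_mask[j]
            if m.any():
                num += float(((work[m, j] - prev[m, j]) ** 2).sum())
                den += float((work[m, j] ** 2).sum())
        change = num / den if den > 0 else 0.0
        if change >= prev_change:
            work = prev  # revert to the previous, better iteration
            break
        prev = work.copy()
        prev_change = change

    for j, col in enumerate(node_cols):
        out.frame[col] = work[:, j]
    if data.group_col is not None:
        out.frame = out.frame.drop(columns=[group_num])
    # mask keeps recording which cells were originally missing
    return out


def mean_impute(data: PanelDataset) -> PanelDataset:
    """Column-mean imputation baseline (used for benchmarking)."""
    out = data.copy()
    for col in data.node_columns():
        m = data.mask[col].to_numpy()
        if m.any():
            vals = data.frame[col].to_numpy(dtype=float)
            if np.isnan(vals[~m]).any() or (~m).sum() == 0:
                raise InputError(f"column {col!r} has no observed values")
            out.frame.loc[m, col] = vals[~m].mean()
    return out


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass
class ScalingRecord:
    """Per-column affine transform applied: x -> (x - center) / scale."""

    centers: dict
    scales: dict

    def invert(self, data: PanelDataset) -> PanelDataset:
        out = data.copy()
        for col, center in self.centers.items():
            out.frame[col] = out.frame[col] * self.scales[col] + center
        return out


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return u.size <= 2


def standardize(data: PanelDataset) -> tuple[PanelDataset, ScalingRecord]:
    """Z-score construct and continuous covariate columns; center binary ones.

    Requires complete construct columns (impute first). Sample SD (n-1).
    """
    node_cols = data.node_columns()
    out = data.copy()
    centers, scales = {}, {}
    cols = node_cols + [c for c in data.covariates]
    for col in cols:
        vals = out.frame[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise InputError(f"column {col!r} has missing values; impute before standardizing")
        center = vals.mean()
        if col in data.covariates and _is_binary(vals):
            scale = 1.0  # centered, not rescaled
        else:
            scale = vals.std(ddof=1)
            if scale == 0:
                raise InputError(f"column {col!r} has zero variance; cannot standardize")
        out.frame[col] = (vals - center) / scale
        centers[col] = float(center)
        scales[col] = float(scale)
    return out, ScalingRecord(centers=centers, scales=scales)


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------


def descriptive_table(data: PanelDataset, group_col: str | None = None) -> pd.DataFrame:
    """Group means/SDs and Welch two-sample t-tests per variable.

    Returns a long-format table: variable, group, mean, sd, n, statistic, p
    (statistic/p repeated across the two group rows of a variable). Degenerate
    zero-variance-in-both-groups cases use the convention p = 1 when the
    means agree and p = 0 otherwise.
    """
    gcol = group_col or data.group_col
    if gcol is None:
        raise InputError("no group column available for descriptives")
    levels = sorted(data.frame[gcol].unique().tolist())
    if len(levels) != 2:
        raise InputError(f"descriptives need exactly two groups, found {levels}")
    variables = data.node_columns() + [c for c in data.covariates]
    rows = []
    for var in variables:
        samples = []
        for g in levels:
            v = data.frame.loc[data.frame[gcol] == g, var].to_numpy(dtype=float)
            v = v[~np.isnan(v)]
            if v.size < 2:
                raise InputError(f"group {g!r} has n < 2 observed values for {var!r}")
            samples.append(v)
        a, b = samples
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t, p = 0.0, 1.0
            if a.mean() != b.mean():
                t, p = np.inf, 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        for g, v in zip(levels, samples):
            rows.append(
                {
                    "variable": var,
                    "group": g,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1),
                    "n": v.size,
                    "statistic": float(t),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows, columns=["variable", "group", "mean", "sd", "n", "statistic", "p"])
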
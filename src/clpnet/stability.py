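"""Case-drop bootstrap stability of centrality orderings.

Repeatedly drops an increasing fraction of participants, re-estimates the
network on each subsample with the same penalty-selection procedure as the
full-sample fit, and correlates (Spearman) the subsample centralities with
the full-sample ones. The correlation-stability (CS) coefficient summarizes
the curves: the largest drop proportion at which at least 95% of replicates
keep a correlation of 0.7 or higher. By the usual reading, CS > 0.25 is
acceptable and CS > 0.50 excellent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import centrality_table
from .estimation import CLPNetwork, EstimationOptions, estimate_network
from .panel import InputError, PanelDataset
from .preprocess import standardize

DEFAULT_DROP_GRID = (0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75)
DEFAULT_N_BOOT = 1000

INDICES = ("out_ei", "in_ei")


@dataclass
class StabilityResult:
    """Bootstrap correlation curves over the case-drop grid.

    ``correlations[index]`` has shape (len(drop_proportions), n_boot); cells
    are NaN when a replicate was skipped (subsample below the minimum fit
    size) or a correlation was undefined (constant centrality vector).
    """

    drop_proportions: np.ndarray
    correlations: Dict[str, np.ndarray]
    n_boot: int
    seed: int
    warnings: list[str] = field(default_factory=list)
    cs: Optional[Dict[str, float]] = None

    def long_frame(self) -> pd.DataFrame:
        rows = []
        for index in INDICES:
            arr = self.correlations[index]
            for di, d in enumerate(self.drop_proportions):
                for b in range(self.n_boot):
                    rows.append(
                        {
                            "index": index,
                            "drop_proportion": float(d),
                            "replicate": b,
                            "correlation": arr[di, b],
                        }
                    )
        return pd.DataFrame(rows, columns=["index", "drop_proportion", "replicate", "correlation"])

    def median_curve(self, index: str) -> np.ndarray:
        return np.nanmedian(self.correlations[index], axis=1)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(stats.spearmanr(a, b).statistic)


def case_drop_bootstrap(
    data: PanelDataset,
    options: Optional[EstimationOptions] = None,
    drop_grid: Sequence[float] = DEFAULT_DROP_GRID,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    covariate_names: Optional[Sequence[str]] = None,
    include_self: bool = False,
) -> StabilityResult:
    """Case-drop bootstrap of out-/in-EI rank stability.

    Each replicate draws floor(n * (1 - d)) participants without replacement,
    re-standardizes the subsample, re-estimates the network (penalty
    re-selected by the same CV rule), and records the Spearman correlation of
    each centrality vector with the full-sample one. Replicates are seeded
    individually from ``seed`` so results do not depend on execution order or
    worker count.
    """
    if options is None:
        options = EstimationOptions()
    if n_boot < 1:
        raise InputError("n_boot must be >= 1")
    drop_grid = np.asarray(sorted(drop_grid), dtype=float)
    if ((drop_grid < 0) | (drop_grid > 0.95)).any():
        raise InputError("drop proportions must lie in [0, 0.95]")
    covs = list(covariate_names) if covariate_names is not None else list(data.covariates)

    full_net = estimate_network(data, covs, options)
    full_tab = centrality_table(full_net, include_self)
    n = data.n
    min_fit = max(data.p + len(covs) + 2, options.n_folds)

    corr = {idx: np.full((drop_grid.size, n_boot), np.nan) for idx in INDICES}
    warnings: list[str] = []
    for di, d in enumerate(drop_grid):
        m = int(np.floor(n * (1.0 - d)))
        if m < min_fit:
            warnings.append(
                f"drop {d:.2f}: subsample size {m} below minimum fit size {min_fit}; skipped"
            )
            continue
        for b in range(n_boot):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(di, b)))
            idx = rng.choice(n, size=m, replace=False)
            sub = data.subset(np.sort(idx))
            try:
                sub_std, _ = standardize(sub)
                rep_options = EstimationOptions(
                    lambda_grid=options.lambda_grid,
                    n_folds=options.n_folds,
                    lambda_rule=options.lambda_rule,
                    penalize_covariates=options.penalize_covariates,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                net = estimate_network(sub_std, covs, rep_options)
            except InputError as exc:
                warnings.append(f"drop {d:.2f} replicate {b}: {exc}")
                continue
            tab = centrality_table(net, include_self)
            corr["out_ei"][di, b] = _spearman(tab.out_ei, full_tab.out_ei)
            corr["in_ei"][di, b] = _spearman(tab.in_ei, full_tab.in_ei)
    return StabilityResult(
        drop_proportions=drop_grid,
        correlations=corr,
        n_boot=n_boot,
        seed=seed,
        warnings=warnings,
    )


def cs_coefficient(
    result: StabilityResult,
    cor_threshold: float = 0.7,
    prob: float = 0.95,
) -> Dict[str, float]:
    """Correlation-stability coefficient per centrality index.

    The largest drop proportion in the grid at which at least ``prob`` of the
    replicates have correlation >= ``cor_threshold``; 0 when no grid point
    qualifies. NaN replicates (skipped or undefined) count as failures.
    """
    cs: Dict[str, float] = {}
    for index in INDICES:
        arr = result.correlations.get(index)
        if arr is None or arr.size == 0:
            raise InputError(f"no replicates recorded for index {index!r}")
        value = 0.0
        for di, d in enumerate(result.drop_proportions):
            ok = np.nan_to_num(arr[di], nan=-np.inf) >= cor_threshold
            if ok.mean() >= prob:
                value = float(d)
        cs[index] = value
    result.cs = cs
    return cs
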
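"""Permutation variable importance (RVIS) and partial dependence.

RVIS permutes one feature column at a time (default 10 permutations),
measures the mean drop in the ensemble score's AUROC, floors negative
drops at zero and rescales so the top variable scores exactly 100.
Partial dependence replaces a variable with each grid value across the
whole table and averages the resulting 0-100 score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import log_loss, roc_auc_score

from .model import IdarModel


def rvis(
    model: IdarModel,
    features: pd.DataFrame,
    labels: np.ndarray,
    n_perm: int = 10,
    seed: int = 0,
    metric: str = "auroc",
) -> pd.DataFrame:
    """Relative variable importance on a 100-point scale.

    Returns a DataFrame (registry order) with columns ``variable``,
    ``raw`` (mean metric drop, floored at 0), ``rvis`` (rescaled so the
    maximum is exactly 100) and ``rank`` (ties broken by registry order).
    """
    if not model.boosters:
        raise ValueError("model is not fitted")
    y = np.asarray(labels, dtype=int)
    x = features[model.feature_names].reset_index(drop=True)

    def perf(tbl: pd.DataFrame) -> float:
        s = model.score(tbl)
        if metric == "auroc":
            return roc_auc_score(y, s)
        if metric == "logloss":
            return -log_loss(y, np.clip(s / 100.0, 1e-9, 1 - 1e-9))
        raise ValueError(f"unknown metric {metric}")

    base = perf(x)
    rng = np.random.default_rng(seed)
    raw = np.zeros(len(model.feature_names))
    for j, name in enumerate(model.feature_names):
        drops = np.empty(n_perm)
        for k in range(n_perm):
            perm = rng.permutation(len(x))
            shuffled = x.copy()
            shuffled[name] = x[name].to_numpy()[perm]
            drops[k] = base - perf(shuffled)
        raw[j] = max(0.0, float(drops.mean()))
    mx = raw.max()
    rescaled = 100.0 * raw / mx if mx > 0 else raw
    order = np.lexsort((np.arange(len(raw)), -rescaled))
    rank = np.empty(len(raw), dtype=int)
    rank[order] = np.arange(1, len(raw) + 1)
    return pd.DataFrame({
        "variable": model.feature_names,
        "raw": raw,
        "rvis": rescaled,
        "rank": rank,
    })


@dataclass
class PartialDependenceCurve:
    variable: str
    grid: np.ndarray
    idar: np.ndarray  # mean 0-100 score at each grid value

    def trend(self) -> float:
        """Spearman-style direction: sign of corr(grid, idar)."""
        return float(np.corrcoef(self.grid, self.idar)[0, 1])


def partial_dependence(
    model: IdarModel,
    features: pd.DataFrame,
    variable: str,
    grid_size: int = 25,
) -> PartialDependenceCurve:
    """Standard partial dependence of the 0-100 score on one variable."""
    if variable not in model.feature_names:
        raise ValueError(f"{variable} not in the feature registry")
    x = features[model.feature_names].reset_index(drop=True)
    col = x[variable].to_numpy(dtype=float)
    finite = col[np.isfinite(col)]
    if len(finite) == 0:
        raise ValueError(f"{variable} is entirely MISSING")
    grid = np.linspace(finite.min(), finite.max(), grid_size)
    means = np.empty(grid_size)
    for i, g in enumerate(grid):
        tbl = x.copy()
        tbl[variable] = g
        means[i] = model.score(tbl).mean()
    return PartialDependenceCurve(variable=variable, grid=grid, idar=means)
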
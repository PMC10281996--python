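"""Collinearity-driven predictor selection: iterative VIF, then pairwise |r|.

The candidate predictor set (19 bioclim + soil layers in the full design) is
reduced in two stages on the pooled presence + pseudo-absence extraction:

1. iteratively drop the single predictor with the largest variance inflation
   factor until all VIF <= 8;
2. while any pair of survivors has |Pearson r| > 0.7, drop the lower-priority
   member of the worst pair.

Priority stands in for expert ecological ranking: user-supplied, or by
default the variable with the lower mean |r| against all others is preferred
(it carries the most independent information).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

VIF_THRESHOLD = 8.0
R_MAX = 0.7


@dataclass
class SelectionResult:
    """Outcome of a selection stage (or the combined cascade)."""

    kept: list[str]
    dropped: list[tuple[str, str, float]] = field(default_factory=list)  # (name, stage, statistic)
    priority: dict[str, int] = field(default_factory=dict)

    @property
    def dropped_names(self) -> list[str]:
        return [d[0] for d in self.dropped]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": n, "status": "kept", "stage": "", "statistic": np.nan}
                for n in self.kept]
        rows += [{"variable": n, "status": "dropped", "stage": s, "statistic": v}
                 for n, s, v in self.dropped]
        return pd.DataFrame(rows)


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.isna().any().any():
        raise ValueError("predictor matrix contains missing values")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if matrix.shape[0] <= matrix.shape[1] + 1:
        raise ValueError("need more rows than predictors + 1")
    const = matrix.columns[matrix.std(ddof=0) == 0]
    if len(const):
        raise ValueError(f"constant predictor columns: {list(const)}")


def compute_vif(matrix: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2) from regressing
    the column on all others (with intercept). Perfect collinearity gives
    +inf rather than an exception."""
    _check_matrix(matrix)
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    vifs = {}
    for j, name in enumerate(matrix.columns):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot
        vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vifs)


def default_priority(matrix: pd.DataFrame) -> dict[str, int]:
    """Rank variables by mean |r| to all others; rank 0 = most independent,
    i.e. preferentially kept."""
    corr = matrix.corr().abs()
    np.fill_diagonal(corr.values, np.nan)
    mean_r = corr.mean(axis=1, skipna=True)
    order = mean_r.sort_values(kind="stable").index
    return {name: rank for rank, name in enumerate(order)}


def vif_filter(matrix: pd.DataFrame, threshold: float = VIF_THRESHOLD,
               priority: dict[str, int] | None = None) -> SelectionResult:
    """Iteratively drop the worst-VIF column until all VIF <= threshold.

    Ties at the maximum are broken by dropping the lower-priority (larger
    rank) name. Stops with a warning when only 2 columns remain.
    """
    prio = priority if priority is not None else default_priority(matrix)
    current = matrix.copy()
    dropped: list[tuple[str, str, float]] = []
    while True:
        vifs = compute_vif(current)
        worst = vifs.max()
        if worst <= threshold:
            break
        candidates = vifs.index[vifs == worst]
        victim = max(candidates, key=lambda n: (prio.get(n, len(prio)), n))
        dropped.append((victim, "vif", float(worst)))
        current = current.drop(columns=[victim])
        if current.shape[1] < 2:
            warnings.warn("VIF filter stopped: fewer than 2 predictors remain",
                          stacklevel=2)
            break
    return SelectionResult(kept=list(current.columns), dropped=dropped, priority=prio)


def correlation_filter(matrix: pd.DataFrame, r_max: float = R_MAX,
                       priority: dict[str, int] | None = None) -> SelectionResult:
    """While any pair has |r| > r_max, drop the lower-priority member of the
    worst (largest |r|) pair."""
    prio = priority if priority is not None else default_priority(matrix)
    current = matrix.copy()
    dropped: list[tuple[str, str, float]] = []
    while current.shape[1] >= 2:
        corr = current.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.values.max()
        if worst <= r_max:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        victim = max((a, b), key=lambda n: (prio.get(n, len(prio)), n))
        dropped.append((victim, "correlation", float(worst)))
        current = current.drop(columns=[victim])
    return SelectionResult(kept=list(current.columns), dropped=dropped, priority=prio)


def select_predictors(matrix: pd.DataFrame, vif_threshold: float = VIF_THRESHOLD,
                      r_max: float = R_MAX,
                      priority: dict[str, int] | None = None) -> SelectionResult:
    """Full two-stage cascade; the final set satisfies both thresholds."""
    prio = priority if priority is not None else default_priority(matrix)
    stage1 = vif_filter(matrix, threshold=vif_threshold, priority=prio)
    stage2 = correlation_filter(matrix[stage1.kept], r_max=r_max, priority=prio)
    result = SelectionResult(kept=stage2.kept,
                             dropped=stage1.dropped + stage2.dropped,
                             priority=prio)
    # safety: recompute both statistics on the final set
    if len(result.kept) >= 2:
        final = matrix[result.kept]
        if final.shape[0] > final.shape[1] + 1:
            assert compute_vif(final).replace(np.inf, np.nan).max() <= vif_threshold + 1e-9 \
                or not np.isfinite(compute_vif(final).max())
        corr = final.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        assert corr.values.max() <= r_max + 1e-12
    return result
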
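"""Mann-Whitney U feature screening.

Features are kept when the two-sided U-test p-value falls below ``alpha``
(default 0.01).  No multiple-testing correction is applied: this step is a
screening device for dimensionality reduction, not inference, so the
selected count under the null is expected to be roughly ``alpha`` times the
number of candidates.

Placement matters for validity.  ``per_fold`` (the default) reruns the
screen inside every outer training split of the cross-validation, which is
leakage-safe.  ``global`` screens the whole sample once before
cross-validation; it mimics a whole-sample screening workflow but lets test
subjects influence the candidate set and therefore risks optimistic AUC
estimates.  Both can be computed and reported side by side.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_N = 16  # pooled sample size up to which the exact p is used


def mann_whitney_u(x, y) -> tuple[float, float]:
    """U statistic (pairs where x > y, ties counted 1/2) and two-sided p.

    Exact enumeration when the pooled size is <= 16 and tie-free, otherwise
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SelectionResult:
    """Per-feature U statistics, p-values and selection flags."""

    table: pd.DataFrame           # columns: U, p, selected (bool)
    alpha: float
    placement: str                # "per_fold" or "global"

    @property
    def selected_features(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature")


def select_from_arrays(values: pd.DataFrame, y: np.ndarray,
                       alpha: float = 0.01,
                       placement: str = "per_fold") -> SelectionResult:
    """Screen every column of ``values`` for a group difference (y=1 vs y=0)."""
    if placement not in ("per_fold", "global"):
        raise ValueError("placement must be 'per_fold' or 'global'")
    y = np.asarray(y)
    if (y == 1).sum() < 1 or (y == 0).sum() < 1:
        raise ValueError("both groups must be present")
    x1 = values.to_numpy()[y == 1]
    x0 = values.to_numpy()[y == 0]
    if len(x1) + len(x0) <= EXACT_MAX_N:
        stats_p = [mann_whitney_u(x1[:, j], x0[:, j])
                   for j in range(values.shape[1])]
        u_vals = np.array([s[0] for s in stats_p])
        p_vals = np.array([s[1] for s in stats_p])
    else:
        res = stats.mannwhitneyu(x1, x0, alternative="two-sided",
                                 method="asymptotic", use_continuity=True, axis=0)
        u_vals = np.asarray(res.statistic, float)
        p_vals = np.asarray(res.pvalue, float)
    table = pd.DataFrame({"U": u_vals, "p": p_vals},
                         index=pd.Index(values.columns, name="feature"))
    table["selected"] = table["p"] < alpha
    return SelectionResult(table=table, alpha=alpha, placement=placement)


def select_features(table, alpha: float = 0.01,
                    placement: str = "per_fold") -> SelectionResult:
    """Screen a FeatureTable (MDD vs HC) at the ``alpha`` level.

    With ``per_fold`` placement this function is invoked inside each outer
    training split by the modeling module; calling it on the full table with
    ``placement='global'`` reproduces whole-sample screening.
    """
    n1, n0 = (table.y == 1).sum(), (table.y == 0).sum()
    if min(n1, n0) < 2:
        raise ValueError("need at least 2 subjects per group")
    return select_from_arrays(table.values, table.y, alpha=alpha,
                              placement=placement)
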
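"""Permutation importance on held-out folds, plus post hoc group statistics.

Importance of a feature is the drop in held-out AUC when that feature's
column is shuffled (10 repeats by default), computed on each outer test fold
of a nested cross-validation result and averaged over folds.  The top-20
lists of the best linear models (LDA, LR, SVM) are intersected to find the
features all of them rely on.

Group statistics: one-way ANCOVA of a feature on group with age as the
covariate (F test of the group term, df = (1, n-3)), and Spearman rank
correlations of features against clinical scores within each group.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.inspection import permutation_importance as _sk_permutation_importance

from .features import FeatureTable
from .modeling import EvaluationResult


def permutation_importance(model_fit, X_test: np.ndarray, y_test: np.ndarray,
                           n_repeats: int = 10, seed: int = 0) -> np.ndarray:
    """Per-feature mean AUC drop on one held-out set.

    ``importance(f) = baseline AUC - mean over repeats of AUC with column f
    permuted``.  Constant columns get importance 0 with a warning.
    """
    X_test = np.asarray(X_test, float)
    res = _sk_permutation_importance(
        model_fit, X_test, y_test, scoring="roc_auc",
        n_repeats=n_repeats, random_state=seed,
    )
    imp = res.importances_mean.copy()
    const = np.ptp(X_test, axis=0) == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant column(s): importance forced to 0",
                      RuntimeWarning, stacklevel=2)
        imp[const] = 0.0
    return imp


@dataclass
class ImportanceReport:
    """Mean permutation importance per feature for one evaluated model."""

    model_id: str
    table: pd.DataFrame           # columns: mean_importance, sd, n_folds_present

    def top_k(self, k: int = 20) -> list[str]:
        return list(self.table["mean_importance"].nlargest(k).index)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature")


def importance_from_evaluation(result: EvaluationResult, table: FeatureTable,
                               n_repeats: int = 10, seed: int = 0) -> ImportanceReport:
    """Aggregate per-fold held-out permutation importance over outer folds.

    A feature not selected in some fold contributes 0 for that fold (the
    fold's model does not rely on it); the mean is taken over all folds.
    """
    if not result.fold_models:
        raise ValueError("evaluation result carries no fitted fold models "
                         "(rerun nested_cv_evaluate with keep_models=True)")
    sub = table.subset(result.combination)
    X_all = sub.values.to_numpy()
    names = list(sub.values.columns)
    y = sub.y
    n_folds = len(result.fold_models)
    acc: dict[str, list[float]] = {}
    for model, (te, cols), selected in zip(result.fold_models,
                                           result.fold_test_idx,
                                           result.fold_selected):
        imp = permutation_importance(model, X_all[np.ix_(te, cols)], y[te],
                                     n_repeats=n_repeats, seed=seed)
        for f, v in zip(selected, imp):
            acc.setdefault(f, []).append(float(v))
    rows = []
    for f, vals in acc.items():
        padded = vals + [0.0] * (n_folds - len(vals))
        rows.append((f, float(np.mean(padded)), float(np.std(padded, ddof=1))
                     if n_folds > 1 else 0.0, len(vals)))
    tab = (pd.DataFrame(rows, columns=["feature", "mean_importance", "sd",
                                       "n_folds_present"])
           .set_index("feature")
           .sort_values("mean_importance", ascending=False))
    return ImportanceReport(model_id=result.model_id, table=tab)


def top_k_intersection(reports: dict[str, ImportanceReport], k: int = 20) -> list[str]:
    """Features common to every model's top-k list (sorted for determinism)."""
    if not reports:
        raise ValueError("no importance reports")
    sets = [set(r.top_k(k)) for r in reports.values()]
    common = set.intersection(*sets)
    return sorted(common)


# ---------------------------------------------------------------------------
# post hoc statistics
# ---------------------------------------------------------------------------

def ancova_group(feature_values, group_labels, age) -> tuple[float, int, int, float]:
    """One-way ANCOVA: feature ~ group + age; F test of the group term.

    Returns (F, df1, df2, p) with df = (1, n - 3).
    """
    values = np.asarray(feature_values, float)
    age = np.asarray(age, float)
    groups = np.asarray(group_labels)
    if len(values) < 4:
        raise ValueError("need at least 4 subjects")
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    g = (groups == uniq[-1]).astype(float)
    X_full = sm.add_constant(np.column_stack([g, age]))
    X_red = sm.add_constant(age)
    fit_full = sm.OLS(values, X_full).fit()
    fit_red = sm.OLS(values, X_red).fit()
    df1 = 1
    df2 = int(fit_full.df_resid)
    f = float((fit_red.ssr - fit_full.ssr) / df1 / (fit_full.ssr / df2))
    p = float(stats.f.sf(f, df1, df2))
    return f, df1, df2, p


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with t-approximation p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def group_stats_report(table: FeatureTable, features: list[str]) -> pd.DataFrame:
    """ANCOVA (group, age covariate) and within-group Spearman correlations
    against MADRS / STAI / MMSE for the given features."""
    rows = []
    age = table.covariates["age"]
    for f in features:
        vals = table.values[f]
        F, df1, df2, p = ancova_group(vals, table.labels, age)
        row = {"feature": f, "ancova_F": F, "df1": df1, "df2": df2, "ancova_p": p}
        for group in ("MDD", "HC"):
            mask = (table.labels == group).to_numpy()
            for score in ("MADRS", "STAI_trait", "STAI_state", "MMSE"):
                rho, sp = spearman_corr(vals[mask], table.covariates[score][mask])
                row[f"rho_{group}_{score}"] = rho
                row[f"p_{group}_{score}"] = sp
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
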
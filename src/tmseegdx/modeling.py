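"""Nested double cross-validation of nine classifiers with averaged ROC/AUC.

The outer 5-fold stratified loop estimates generalization; inside every outer
training split the features are (optionally) re-screened with the
Mann-Whitney U test, z-scored, and the hyperparameters are tuned by a random
grid search scored with inner 10-fold mean AUC.  The tuned pipeline is refit
on the full training split and scored on the held-out fold with continuous
decision scores (positive class = MDD).  Fold ROC curves are averaged
vertically on a common 101-point FPR grid; the reported AUC is the
arithmetic mean of the fold AUCs with its sample standard deviation.

Model ids: LR, LDA, SVM, KNN, NB, DT, RF, ET, LG (lightGBM).
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import ParameterSampler, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable
from .montage import FEATURE_SETS
from .selection import SelectionResult, select_from_arrays

logger = logging.getLogger(__name__)

# harmless name-tracking mismatch between sklearn pipelines and lightgbm
warnings.filterwarnings("ignore", message="X does not have valid feature names")

MODEL_IDS = ("LR", "LDA", "SVM", "KNN", "NB", "DT", "RF", "ET", "LG")


@dataclass(frozen=True)
class ModelSpec:
    """A classifier with its random-search hyperparameter grid."""

    id: str
    estimator: object
    grid: dict
    budget: int = 25              # random draws per outer fold

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError(f"model {self.id}: empty hyperparameter grid")
        if self.budget < 1:
            raise ValueError("tuning budget must be >= 1")


@dataclass(frozen=True)
class CVConfig:
    outer_k: int = 5
    inner_k: int = 10
    seed: int = 0
    selection_alpha: float = 0.01
    selection_placement: str = "per_fold"   # or "global" or "none"

    def __post_init__(self) -> None:
        if self.outer_k < 2 or self.inner_k < 2:
            raise ValueError("outer_k and inner_k must be >= 2")
        if self.selection_placement not in ("per_fold", "global", "none"):
            raise ValueError("selection_placement must be per_fold/global/none")


def default_model_registry(budget: int = 25, seed: int = 0,
                           n_estimators: tuple[int, ...] = (50, 100, 200)) -> dict[str, ModelSpec]:
    """The nine classifiers with log-spaced / small-integer grids."""
    trees = list(n_estimators)
    specs = {
        "LR": ModelSpec("LR", LogisticRegression(max_iter=2000),
                        {"clf__C": np.logspace(-3, 2, 11).tolist()}, budget),
        "LDA": ModelSpec("LDA", LinearDiscriminantAnalysis(solver="lsqr"),
                         {"clf__shrinkage": [0.0, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0, "auto"]},
                         budget),
        "SVM": ModelSpec("SVM", SVC(kernel="rbf", random_state=seed),
                         {"clf__C": np.logspace(-2, 3, 8).tolist(),
                          "clf__gamma": ["scale"] + np.logspace(-4, 0, 6).tolist()},
                         budget),
        "KNN": ModelSpec("KNN", KNeighborsClassifier(),
                         {"clf__n_neighbors": list(range(3, 16))}, budget),
        "NB": ModelSpec("NB", GaussianNB(),
                        {"clf__var_smoothing": np.logspace(-12, -3, 10).tolist()},
                        budget),
        "DT": ModelSpec("DT", DecisionTreeClassifier(random_state=seed),
                        {"clf__max_depth": [2, 3, 4, 6, 8, None],
                         "clf__min_samples_leaf": [1, 2, 4, 8]}, budget),
        "RF": ModelSpec("RF", RandomForestClassifier(random_state=seed),
                        {"clf__n_estimators": trees,
                         "clf__max_depth": [None, 4, 8],
                         "clf__min_samples_leaf": [1, 2, 4],
                         "clf__max_features": ["sqrt", 0.5]}, budget),
        "ET": ModelSpec("ET", ExtraTreesClassifier(random_state=seed),
                        {"clf__n_estimators": trees,
                         "clf__max_depth": [None, 4, 8],
                         "clf__min_samples_leaf": [1, 2, 4],
                         "clf__max_features": ["sqrt", 0.5]}, budget),
    }
    from lightgbm import LGBMClassifier

    specs["LG"] = ModelSpec(
        "LG",
        LGBMClassifier(random_state=seed, verbose=-1, min_child_samples=5),
        {"clf__n_estimators": trees,
         "clf__num_leaves": [3, 7, 15, 31],
         "clf__learning_rate": [0.01, 0.05, 0.1]},
        budget,
    )
    return specs


@dataclass
class ROCCurve:
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    per_fold_tpr: np.ndarray      # (folds, grid points)
    fold_aucs: np.ndarray
    mean_auc: float
    sd_auc: float


@dataclass
class EvaluationResult:
    combination: tuple[str, ...]
    model_id: str
    roc: ROCCurve
    fold_selected: list[list[str]]        # selected feature names per fold
    fold_best_params: list[dict]
    seed: int
    fold_models: list = field(default_factory=list, repr=False)
    fold_test_idx: list = field(default_factory=list, repr=False)

    @property
    def mean_auc(self) -> float:
        return self.roc.mean_auc


def enumerate_combinations() -> list[tuple[str, ...]]:
    """All 15 non-empty subsets of {RST, PRE, PST, DIF}, ordered by subset
    size then lexically."""
    sets = sorted(FEATURE_SETS)
    combos = []
    for k in range(1, len(sets) + 1):
        combos.extend(itertools.combinations(sets, k))
    return combos


def _decision_scores(model, X) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X))
    return np.asarray(model.predict_proba(X))[:, 1]


def average_roc(fold_curves: list[tuple[np.ndarray, np.ndarray]],
                n_grid: int = 101) -> ROCCurve:
    """Vertical averaging of fold ROC curves on a common FPR grid.

    ``fold_curves`` is a list of (fpr, tpr) arrays.  Each fold's TPR is
    linearly interpolated onto the grid (with the (0, 0) anchor enforced);
    the mean AUC is the arithmetic mean of the fold AUCs, not the area under
    the averaged curve.
    """
    if not fold_curves:
        raise ValueError("need at least one fold curve")
    grid = np.linspace(0.0, 1.0, n_grid)
    per_fold, aucs = [], []
    for fpr, tpr in fold_curves:
        fpr = np.concatenate([[0.0], np.asarray(fpr, float)])
        tpr = np.concatenate([[0.0], np.asarray(tpr, float)])
        per_fold.append(np.interp(grid, fpr, tpr))
        aucs.append(auc(fpr, tpr))
    per_fold = np.vstack(per_fold)
    aucs = np.asarray(aucs)
    mean_tpr = per_fold.mean(axis=0)
    mean_tpr[0] = 0.0
    mean_tpr[-1] = 1.0
    sd = float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0
    return ROCCurve(fpr_grid=grid, mean_tpr=mean_tpr, per_fold_tpr=per_fold,
                    fold_aucs=aucs, mean_auc=float(aucs.mean()), sd_auc=sd)


def _tune(pipe: Pipeline, grid: dict, budget: int, X: np.ndarray, y: np.ndarray,
          inner_k: int, rng_seed: int) -> tuple[dict, float]:
    """Random grid search scored by inner stratified k-fold mean AUC."""
    n_min = min(np.bincount(y))
    k = min(inner_k, n_min)
    inner = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    sampler = ParameterSampler(grid, n_iter=min(budget, _grid_size(grid)),
                               random_state=rng_seed)
    best_params, best_score = {}, -np.inf
    for params in sampler:
        model = clone(pipe).set_params(**params)
        scores = []
        try:
            for tr, va in inner.split(X, y):
                m = clone(model).fit(X[tr], y[tr])
                s = _decision_scores(m, X[va])
                fpr, tpr, _ = roc_curve(y[va], s)
                scores.append(auc(fpr, tpr))
        except ValueError:
            continue            # infeasible draw for this training size
        score = float(np.mean(scores))
        if score > best_score:
            best_score, best_params = score, params
    if best_score == -np.inf:
        raise ValueError("no hyperparameter draw could be fit on this fold")
    return best_params, best_score


def _grid_size(grid: dict) -> int:
    size = 1
    for v in grid.values():
        size *= len(v)
    return size


def nested_cv_evaluate(table: FeatureTable, combo, model: ModelSpec,
                       cv: CVConfig, keep_models: bool = True) -> EvaluationResult:
    """Evaluate one (feature-set combination, model) cell.

    Deterministic given ``cv.seed``: the outer/inner fold assignments, the
    random-search draws and any stochastic estimator all derive from it.
    """
    combo = tuple(sorted(combo))
    if not combo:
        raise ValueError("combination must be non-empty")
    sub = table.subset(combo)
    X_all = sub.values.to_numpy()
    names = list(sub.values.columns)
    y = sub.y
    if min(np.bincount(y)) < cv.outer_k:
        raise ValueError("too few subjects per class for stratified outer folds")

    outer = StratifiedKFold(n_splits=cv.outer_k, shuffle=True, random_state=cv.seed)
    global_sel: SelectionResult | None = None
    if cv.selection_placement == "global":
        global_sel = select_from_arrays(sub.values, y, alpha=cv.selection_alpha,
                                        placement="global")

    fold_curves, fold_selected, fold_params = [], [], []
    fold_models, fold_test_idx = [], []
    for fold_i, (tr, te) in enumerate(outer.split(X_all, y)):
        if cv.selection_placement == "per_fold":
            sel = select_from_arrays(sub.values.iloc[tr], y[tr],
                                     alpha=cv.selection_alpha, placement="per_fold")
        elif cv.selection_placement == "global":
            sel = global_sel
        else:
            sel = None
        if sel is not None:
            chosen = sel.selected_features
            if len(chosen) < 2:
                chosen = list(sel.table["p"].nsmallest(2).index)
                logger.warning("fold %d: fewer than 2 features selected; "
                               "falling back to the top-2 smallest p", fold_i)
        else:
            chosen = names
        cols = [names.index(c) for c in chosen]
        X = X_all[:, cols]

        pipe = Pipeline([("scaler", StandardScaler()),
                         ("clf", clone(model.estimator))])
        params, _ = _tune(pipe, model.grid, model.budget, X[tr], y[tr],
                          cv.inner_k, rng_seed=cv.seed * 1000 + fold_i)
        fitted = clone(pipe).set_params(**params).fit(X[tr], y[tr])
        scores = _decision_scores(fitted, X[te])
        fpr, tpr, _ = roc_curve(y[te], scores)
        fold_curves.append((fpr, tpr))
        fold_selected.append(chosen)
        fold_params.append(params)
        if keep_models:
            fold_models.append(fitted)
            fold_test_idx.append((te, cols))

    return EvaluationResult(
        combination=combo, model_id=model.id, roc=average_roc(fold_curves),
        fold_selected=fold_selected, fold_best_params=fold_params,
        seed=cv.seed, fold_models=fold_models, fold_test_idx=fold_test_idx,
    )


def rank_models(results: list[EvaluationResult]) -> pd.DataFrame:
    """Mean AUC +- SD matrix over (combination, model) with the arg-max cell.

    Returns a tidy DataFrame indexed by combination tag (e.g. ``DIF+RST``)
    with one column per model id holding the mean AUC, plus matching
    ``<id>_sd`` columns; the best cell is stored in ``df.attrs['best']``.
    """
    if not results:
        raise ValueError("no evaluation results")
    rows: dict[str, dict[str, float]] = {}
    for r in results:
        tag = "+".join(r.combination)
        rows.setdefault(tag, {})[r.model_id] = r.roc.mean_auc
        rows[tag][f"{r.model_id}_sd"] = r.roc.sd_auc
    df = pd.DataFrame.from_dict(rows, orient="index")
    best = max(results, key=lambda r: r.roc.mean_auc)
    df.attrs["best"] = {"combination": "+".join(best.combination),
                        "model": best.model_id, "mean_auc": best.roc.mean_auc,
                        "sd_auc": best.roc.sd_auc}
    return df
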
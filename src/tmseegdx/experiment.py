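"""End-to-end orchestration: cohort -> preprocessing -> features -> screening
-> nested CV grid -> permutation importance -> group statistics."""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .cohort import CohortSpec, SubjectRecord, generate_cohort
from .config import RunConfig
from .features import (
    FeatureTable,
    compute_dif_features,
    compute_rst_features,
    compute_window_features,
)
from .importance import group_stats_report, importance_from_evaluation, top_k_intersection
from .modeling import (
    default_model_registry,
    enumerate_combinations,
    nested_cv_evaluate,
    rank_models,
)
from .preprocess import PreprocConfig, extract_windows, preprocess_resting, preprocess_tms
from .selection import select_features

logger = logging.getLogger(__name__)


def subject_features(record: SubjectRecord, cfg: PreprocConfig) -> pd.Series:
    """All 2456 features (RST + PRE + PST + DIF) of one subject."""
    rest_epochs, _ = preprocess_resting(record.resting, cfg)
    tms_epochs, _ = preprocess_tms(record.tms, cfg)
    windows = extract_windows(tms_epochs)
    rst = compute_rst_features(rest_epochs)
    pre = compute_window_features(windows["pre"], "PRE")
    pst = compute_window_features(windows["post"], "PST")
    dif = compute_dif_features(pre, pst)
    return pd.concat([rst, pre, pst, dif])


def build_feature_table(records: list[SubjectRecord], cfg: PreprocConfig) -> FeatureTable:
    """FeatureTable over a cohort; logs shape transitions."""
    vectors, labels, covs = {}, {}, {}
    for rec in records:
        vectors[rec.subject_id] = subject_features(rec, cfg)
        labels[rec.subject_id] = rec.group
        covs[rec.subject_id] = {
            "age": rec.age, "MADRS": rec.madrs, "STAI_state": rec.stai_state,
            "STAI_trait": rec.stai_trait, "MMSE": rec.mmse,
        }
    values = pd.DataFrame(vectors).T
    n_missing = int(values.isna().sum().sum())
    if n_missing:
        # features lost to channel rejection in some subjects: impute with
        # the column mean so screening and modeling stay well defined
        logger.warning("imputing %d missing feature values with column means",
                       n_missing)
        values = values.fillna(values.mean())
    logger.info("feature table: %d subjects x %d features", *values.shape)
    return FeatureTable(values, pd.Series(labels), pd.DataFrame(covs).T)


def cohort_feature_table(spec: CohortSpec, cfg: PreprocConfig) -> FeatureTable:
    return build_feature_table(generate_cohort(spec), cfg)


def run_experiment(config: RunConfig, out_dir) -> dict:
    """Run the full experiment and write the artifact files.

    Writes the (combinations x models) AUC grid, per-cell ROC curves, the
    selection report, importance reports with the cross-model top-20
    intersection, group statistics for those common features, and a run
    manifest.  Returns the in-memory artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "status": "running", "stages": []}

    def _stage(name: str) -> None:
        manifest["stages"].append(name)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    try:
        _stage("simulate")
        records = generate_cohort(config.cohort)
        _stage("features")
        table = build_feature_table(records, config.preproc)
        table.to_tsv(out / "features.tsv")

        _stage("select")
        global_sel = select_features(table, alpha=config.cv.selection_alpha,
                                     placement="global")
        global_sel.to_tsv(out / "selection_global.tsv")

        _stage("train")
        registry = default_model_registry(budget=config.tuning_budget,
                                          seed=config.seed,
                                          n_estimators=config.tree_sizes)
        combos = [c for c in enumerate_combinations()
                  if config.combos is None or "+".join(c) in config.combos]
        results = []
        for combo in combos:
            for mid in config.models:
                res = nested_cv_evaluate(table, combo, registry[mid], config.cv)
                results.append(res)
                logger.info("%s / %s: AUC %.3f +- %.3f", "+".join(combo), mid,
                            res.roc.mean_auc, res.roc.sd_auc)
        grid = rank_models(results)
        grid.to_csv(out / "auc_grid.tsv", sep="\t")
        (out / "auc_best.json").write_text(json.dumps(grid.attrs["best"], indent=1))
        roc_dir = out / "roc"
        roc_dir.mkdir(exist_ok=True)
        for res in results:
            pd.DataFrame({"fpr": res.roc.fpr_grid, "mean_tpr": res.roc.mean_tpr}).to_csv(
                roc_dir / f"{'+'.join(res.combination)}_{res.model_id}.tsv",
                sep="\t", index=False)

        _stage("importance")
        full = tuple(sorted(("RST", "PRE", "PST", "DIF")))
        imp_models = [m for m in ("LDA", "LR", "SVM") if m in config.models]
        reports = {}
        for res in results:
            if res.combination == full and res.model_id in imp_models:
                rep = importance_from_evaluation(res, table, seed=config.seed)
                rep.to_tsv(out / f"importance_{res.model_id}.tsv")
                reports[res.model_id] = rep
        common = top_k_intersection(reports, k=20) if reports else []
        (out / "importance_common_top20.json").write_text(json.dumps(common, indent=1))

        _stage("stats")
        if common:
            group_stats_report(table, common).to_csv(out / "group_stats.tsv", sep="\t")

        manifest["status"] = "ok"
        manifest["best"] = grid.attrs["best"]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return {"table": table, "results": results, "grid": grid,
                "importance": reports, "common_top20": common}
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise
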
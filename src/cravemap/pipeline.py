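"""End-to-end orchestration: simulate/load -> exclude -> split -> evaluate
-> permutation inference -> signature -> reports.

Every artifact is stamped with the config hash and master seed (in
``run_info.json``); the plain-text log records each stage's sample counts
and timing.  Given the same config and seed the TSV/JSON outputs are
byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, inference, signature as sig_mod
from .config import RunConfig
from .dataio import Cohort, ParcellationVolume, load_parcellation, read_dataset
from .evaluation import (
    SplitPlan,
    classification_metrics,
    make_split,
    pearson_metric,
    repeat_cv,
    roc_curve_table,
    stratified_metric,
)
from .models import Candidate, RegressorSpec, default_candidate_grid, fit_pipeline, grid_search
from .synthetic import SyntheticTruth, apply_exclusions, generate_cohort, synthetic_parcellation

__all__ = ["run_pipeline", "PreparedData", "prepare_data"]

log = logging.getLogger("cravemap")

# metric columns reported per task (observed/null column names coincide)
TASK_METRICS = {
    "regress": ("rmse", "mae", "pearson_r"),
    "classify_craving": ("rmse", "accuracy", "auc_roc"),
    "classify_cue": ("accuracy", "precision", "auc_roc", "auc_pr"),
}

_CLS_TASK = {"classify_craving": "craving", "classify_cue": "cue"}


@dataclass
class PreparedData:
    cohort: Cohort  # after exclusions
    fitting: Cohort
    holdout: Cohort
    plan: SplitPlan
    truth: SyntheticTruth | None


def prepare_data(config: RunConfig, seed: int | None = None) -> PreparedData:
    """Simulate or load, apply exclusions, then carve out the hold-out set."""
    if seed is not None:
        config = config.with_seed(seed)
    if config.paths.volume is not None:
        cohort = read_dataset(
            config.paths.volume, config.paths.metadata, config.paths.mask
        )
        truth = None
        log.info("loaded %d samples from %s", len(cohort), config.paths.volume)
    else:
        cohort, truth = generate_cohort(config.synthetic)
        log.info(
            "simulated %d subjects x %d blocks (%d voxels)",
            config.synthetic.n_subjects,
            len(cohort) // config.synthetic.n_subjects,
            cohort.stack.n_voxels,
        )
        cohort = apply_exclusions(cohort, truth)
        log.info(
            "exclusions applied: %d subjects remain", len(cohort.subjects)
        )
    ev = config.evaluation
    plan = make_split(
        cohort.subjects,
        holdout_fraction=ev.holdout_fraction,
        k=ev.k,
        seed=ev.seed,
    )
    fitting = cohort.select_subjects(plan.fitting_subjects)
    holdout = (
        cohort.select_subjects(plan.holdout_subjects)
        if plan.holdout_subjects
        else cohort.select(np.zeros(len(cohort), dtype=bool))
    )
    log.info(
        "split: %d hold-out / %d fitting subjects (k=%d)",
        len(plan.holdout_subjects),
        len(plan.fitting_subjects),
        ev.k,
    )
    return PreparedData(
        cohort=cohort, fitting=fitting, holdout=holdout, plan=plan, truth=truth
    )


def _observed_distribution(task, fitting, config, spec, seed) -> pd.DataFrame:
    reps = config.evaluation.repetitions
    k = config.evaluation.k
    if task == "regress":
        return repeat_cv(
            fitting, config.reducer_config, spec=spec,
            n_repetitions=reps, k=k, seed=seed,
        )
    df = classify.repeat_classification(
        fitting,
        _CLS_TASK[task],
        n_repetitions=reps,
        k=k,
        seed=seed,
        n_components=config.n_components,
        spec=spec,
    )
    return df.rename(columns={"rmse_stratified": "rmse"})


def _null_distribution(task, fitting, config, spec, seed) -> pd.DataFrame:
    null_task = {"regress": "regress"} | _CLS_TASK
    return inference.permutation_null(
        fitting,
        config.reducer_config,
        spec=spec,
        task=null_task[task],
        n_perm=config.inference.n_perm,
        k=config.evaluation.k,
        seed=seed,
        within_subject=config.inference.within_subject,
    )


def _final_fit(task, fitting, config, spec, seed):
    """Fit one pipeline on all fitting subjects; returns (pipeline, threshold)."""
    if task == "classify_craving":
        ext = classify.binarize_craving(fitting)
        data = fitting.select(ext.indices)
        y = data.ratings
    elif task == "classify_cue":
        data = fitting
        y = fitting.cue_types.astype(float)
    else:
        data = fitting
        y = fitting.ratings
    pipe = fit_pipeline(
        data.X, y, config.reducer_config, spec=spec, seed=seed,
        train_subjects=data.subjects,
    )
    threshold = None
    if task == "classify_craving":
        ext = classify.binarize_craving(fitting)
        threshold = classify.optimize_threshold(
            pipe.predict(data.X), ext.labels
        ).threshold
    elif task == "classify_cue":
        threshold = 0.5
    return pipe, threshold, data


def _holdout_eval(task, pipe, threshold, holdout) -> tuple[dict, pd.DataFrame | None]:
    """Out-of-sample metrics on the untouched hold-out subjects."""
    if len(holdout) == 0:
        return {}, None
    if task == "regress":
        yhat = pipe.predict(holdout.X)
        y = holdout.ratings
        return {
            "rmse": stratified_metric(y, yhat, "rmse").value,
            "mae": stratified_metric(y, yhat, "mae").value,
            "pearson_r": pearson_metric(y, yhat).value,
        }, None
    if task == "classify_craving":
        ext = classify.binarize_craving(holdout)
        data = holdout.select(ext.indices)
        yhat = pipe.predict(data.X)
        m = classification_metrics(ext.labels, yhat, threshold=threshold)
        out = {
            "rmse": stratified_metric(data.ratings, yhat, "rmse").value,
            "accuracy": m["accuracy"].value,
            "auc_roc": m["auc_roc"].value,
        }
        return out, roc_curve_table(ext.labels, yhat)
    yhat = pipe.predict(holdout.X)
    labels = holdout.cue_types
    m = classification_metrics(labels, yhat, threshold=threshold)
    out = {k: m[k].value for k in ("accuracy", "precision", "auc_roc", "auc_pr")}
    return out, roc_curve_table(labels, yhat)


def run_pipeline(
    config: RunConfig, out_dir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Execute the full analysis for ``config.task``; returns artifact paths.

    Any stage failure is re-raised annotated with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = seed if seed is not None else config.evaluation.seed
    config = config.with_seed(master_seed)
    task = config.task
    spec = RegressorSpec(config.models.family, config.models.hyperparameters)
    artifacts: dict[str, Path] = {}
    stage = "prepare"
    t_all = time.perf_counter()
    try:
        data = prepare_data(config)

        if config.models.grid_enabled:
            stage = "grid-search"
            t0 = time.perf_counter()
            cands = default_candidate_grid(
                components=config.models.grid_components,
                families=config.models.grid_families,
            )
            gr = grid_search(
                cands, data.fitting, k=config.evaluation.k, seed=master_seed
            )
            artifacts["grid"] = out / "grid_search.tsv"
            gr.to_frame().to_csv(artifacts["grid"], sep="\t", index=False)
            win = gr.winning_candidate()
            spec = win.spec
            log.info(
                "grid search: winner %s (%.1f s)",
                win.label(), time.perf_counter() - t0,
            )

        stage = "cross-validation"
        t0 = time.perf_counter()
        observed = _observed_distribution(task, data.fitting, config, spec, master_seed)
        artifacts["observed"] = out / "observed_metrics.tsv"
        observed.to_csv(artifacts["observed"], sep="\t", index=False)
        log.info(
            "repeated CV: %d repetitions (%.1f s)",
            len(observed), time.perf_counter() - t0,
        )

        stage = "permutation"
        t0 = time.perf_counter()
        null = _null_distribution(task, data.fitting, config, spec, master_seed)
        artifacts["null"] = out / "null_metrics.tsv"
        null.to_csv(artifacts["null"], sep="\t", index=False)
        log.info(
            "permutation null: %d permutations (%.1f s)",
            len(null), time.perf_counter() - t0,
        )

        stage = "final-fit"
        pipe, threshold, _ = _final_fit(task, data.fitting, config, spec, master_seed)
        if threshold is not None:
            log.info("decision threshold: %.4f", threshold)

        stage = "hold-out"
        oos, roc = _holdout_eval(task, pipe, threshold, data.holdout)
        if roc is not None:
            artifacts["roc"] = out / "holdout_roc.tsv"
            roc.to_csv(artifacts["roc"], sep="\t", index=False)

        stage = "report"
        reports = []
        for metric in TASK_METRICS[task]:
            dist = inference.MetricDistribution(
                metric=metric,
                observed=observed[metric].to_numpy(),
                null=null[metric].to_numpy(),
            )
            reports.append(
                inference.report(
                    dist,
                    out_of_sample=oos.get(metric, float("nan")),
                    alpha=config.inference.alpha,
                    n_boot=config.inference.n_boot,
                    seed=master_seed,
                )
            )
        artifacts["stats"] = inference.write_stat_table(reports, out / "stat_report.tsv")

        stage = "signature"
        if spec.is_linear and config.features.method == "pca":
            sig = sig_mod.back_project(pipe)
            sig = sig_mod.normalize_for_display(sig, data.fitting.mean_beta_map())
            artifacts.update(sig_mod.write_signature(sig, data.fitting.stack, out))
            parc = _get_parcellation(config, data.fitting)
            regional = sig_mod.summarize_by_atlas(sig, parc, data.fitting.stack)
            artifacts["regional"] = out / "regional_summary.tsv"
            regional.to_csv(artifacts["regional"], sep="\t", index=False)

        stage = "stamp"
        info = {
            "task": task,
            "seed": master_seed,
            "config_hash": config.config_hash(),
            "n_subjects_analyzed": len(data.cohort.subjects),
            "n_holdout": len(data.plan.holdout_subjects),
            "n_fitting": len(data.plan.fitting_subjects),
            "regressor": spec.family,
            "n_components": config.n_components,
            "threshold": threshold,
            "out_of_sample": oos,
        }
        artifacts["run_info"] = out / "run_info.json"
        artifacts["run_info"].write_text(json.dumps(info, indent=2, sort_keys=True))
        log.info("pipeline done in %.1f s", time.perf_counter() - t_all)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return artifacts


def _get_parcellation(config: RunConfig, cohort: Cohort) -> ParcellationVolume:
    if config.paths.parcellation is not None:
        return load_parcellation(
            config.paths.parcellation, config.paths.parcellation_names
        )
    n_regions = min(config.paths.atlas_regions, cohort.stack.n_in_mask)
    return synthetic_parcellation(cohort.stack, n_regions=n_regions, seed=0)
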
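"""Binary readouts of the regression pipeline.

Two derived tasks share every upstream stage with the craving regression:

* high/low craving — per subject, only the first-occurrence minimum and
  maximum rating blocks are kept (low = 0, high = 1); the regressor is still
  trained on the raw 1-4 ratings and its continuous output is mapped to a
  label with a threshold re-optimized for F1 on each iteration's training
  predictions (50 PCA components by default, the sample count being halved
  to two blocks per subject);
* cue type — the regression target is the 0/1 cue code and the output is
  thresholded at a fixed 0.5 (100 PCA components by default).

Thresholds maximize F1 and are methodological, not clinical, cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .evaluation import (
    MetricValue,
    SplitPlan,
    classification_metrics,
    extract_extremes,
    make_split,
    prepare_fold_scores,
    stratified_metric,
)
from .models import RegressorSpec, build_estimator

__all__ = [
    "ThresholdResult",
    "ExtremeSet",
    "binarize_craving",
    "optimize_threshold",
    "classify_cue",
    "run_craving_classification",
    "run_cue_classification",
    "repeat_classification",
]

LABEL_LOW = 0
LABEL_HIGH = 1


@dataclass(frozen=True)
class ThresholdResult:
    """An F1-optimal decision threshold and the grid it was searched over."""

    threshold: float
    f1_at_threshold: float
    search_grid: np.ndarray = field(repr=False, default=None)


@dataclass
class ExtremeSet:
    """Per-subject extreme blocks: two samples per non-degenerate subject."""

    indices: np.ndarray  # rows into the source cohort
    labels: np.ndarray  # 0 = that subject's min-rating block, 1 = max
    dropped_subjects: tuple[str, ...]  # degenerate (constant-rating) subjects


def binarize_craving(cohort) -> ExtremeSet:
    """Reduce a cohort to first-occurrence min/max blocks per subject.

    Subjects whose ratings are constant carry no high/low contrast and are
    dropped.  Over the remaining subjects the classes are exactly balanced
    by construction.
    """
    indices: list[int] = []
    labels: list[int] = []
    dropped: list[str] = []
    meta = cohort.meta
    for sid in cohort.subjects:
        rows = np.flatnonzero(meta["subject_id"].astype(str) == sid)
        pair = extract_extremes(
            meta["rating"].to_numpy()[rows], meta["block_index"].to_numpy()[rows]
        )
        if pair.degenerate:
            dropped.append(sid)
            continue
        indices.extend([rows[pair.min_index], rows[pair.max_index]])
        labels.extend([LABEL_LOW, LABEL_HIGH])
    if not indices:
        raise ValueError("all subjects are degenerate (constant ratings)")
    return ExtremeSet(
        indices=np.asarray(indices),
        labels=np.asarray(labels),
        dropped_subjects=tuple(dropped),
    )


def optimize_threshold(yhat: np.ndarray, labels: np.ndarray) -> ThresholdResult:
    """Threshold maximizing F1 (positive class 1; predict = yhat >= t).

    Candidates are the midpoints between consecutive sorted unique
    predictions plus one value below the minimum and one above the maximum;
    ties resolve to the lowest threshold.
    """
    yhat = np.asarray(yhat, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("threshold optimization needs both classes present")
    u = np.unique(yhat)
    candidates = np.concatenate(
        ([u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0])
    )
    best_t, best_f1 = candidates[0], -1.0
    for t in candidates:
        pred = yhat >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1 + 1e-15:  # strict improvement keeps the lowest tie
            best_t, best_f1 = float(t), float(f1)
    return ThresholdResult(
        threshold=best_t, f1_at_threshold=best_f1, search_grid=candidates
    )


def classify_cue(yhat: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Map regression output to cue labels; boundary goes to drug (>= 0.5)."""
    return (np.asarray(yhat, dtype=float) >= threshold).astype(int)


# ---------------------------------------------------------------------------
# cross-validated task runners
# ---------------------------------------------------------------------------

@dataclass
class ClassificationCVResult:
    """Per-fold table plus pooled out-of-fold scores/labels for one task."""

    task: str
    fold_metrics: pd.DataFrame
    oof_scores: np.ndarray
    oof_labels: np.ndarray
    oof_targets: np.ndarray  # raw regression targets for the RMSE column
    thresholds: list[float]
    pooled: dict[str, MetricValue]


def _pooled_metrics(
    task: str,
    labels: np.ndarray,
    scores: np.ndarray,
    targets: np.ndarray,
    threshold: float,
) -> dict[str, MetricValue]:
    out = classification_metrics(labels, scores, threshold=threshold)
    # RMSE of the raw regression output against the raw targets (1-4 extreme
    # ratings for high/low, 0/1 codes for cue), stratified over target levels
    out["rmse_stratified"] = stratified_metric(targets, scores, "rmse")
    return out


def run_craving_classification(
    cohort,
    plan: SplitPlan | None = None,
    n_components: int = 50,
    spec: RegressorSpec | None = None,
    seed: int = 0,
) -> ClassificationCVResult:
    """Subject-level CV of the high/low craving readout.

    Per fold: train the regressor on the raw extreme ratings of the training
    subjects, pick the F1-optimal threshold on the training predictions, and
    apply it to the held-out fold (optimizing on test would leak).
    """
    spec = spec or RegressorSpec()
    ext = binarize_craving(cohort)
    sub = cohort.select(ext.indices)
    if plan is None:
        plan = make_split(sub.subjects, holdout_fraction=0.0, k=5, seed=seed)
    reducer_config = {"method": "pca", "n_components": n_components}
    folds = prepare_fold_scores(sub, plan, reducer_config)
    y_raw = sub.ratings
    labels = ext.labels
    oof_scores = np.full(len(sub), np.nan)
    rows, thresholds = [], []
    for fs in folds:
        est = build_estimator(spec, seed=seed + fs.fold)
        est.fit(fs.S_train, y_raw[fs.train_idx])
        thr = optimize_threshold(
            est.predict(fs.S_train), labels[fs.train_idx]
        ).threshold
        yhat = est.predict(fs.S_test)
        oof_scores[fs.test_idx] = yhat
        m = _pooled_metrics(
            "craving", labels[fs.test_idx], yhat, y_raw[fs.test_idx], thr
        )
        rows.append(
            {"fold": fs.fold, "threshold": thr}
            | {k: v.value for k, v in m.items()}
        )
        thresholds.append(thr)
    seen = ~np.isnan(oof_scores)
    pooled = _pooled_metrics(
        "craving",
        labels[seen],
        oof_scores[seen],
        y_raw[seen],
        float(np.median(thresholds)),
    )
    return ClassificationCVResult(
        task="craving",
        fold_metrics=pd.DataFrame(rows),
        oof_scores=oof_scores,
        oof_labels=labels,
        oof_targets=y_raw,
        thresholds=thresholds,
        pooled=pooled,
    )


def run_cue_classification(
    cohort,
    plan: SplitPlan | None = None,
    n_components: int = 100,
    spec: RegressorSpec | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> ClassificationCVResult:
    """Subject-level CV of the drug/neutral cue readout (fixed 0.5 cut)."""
    spec = spec or RegressorSpec()
    if plan is None:
        plan = make_split(cohort.subjects, holdout_fraction=0.0, k=5, seed=seed)
    reducer_config = {"method": "pca", "n_components": n_components}
    folds = prepare_fold_scores(cohort, plan, reducer_config)
    y = cohort.cue_types.astype(float)
    labels = cohort.cue_types
    oof_scores = np.full(len(cohort), np.nan)
    rows = []
    for fs in folds:
        est = build_estimator(spec, seed=seed + fs.fold)
        est.fit(fs.S_train, y[fs.train_idx])
        yhat = est.predict(fs.S_test)
        oof_scores[fs.test_idx] = yhat
        m = _pooled_metrics("cue", labels[fs.test_idx], yhat, y[fs.test_idx], threshold)
        rows.append(
            {"fold": fs.fold, "threshold": threshold}
            | {k: v.value for k, v in m.items()}
        )
    seen = ~np.isnan(oof_scores)
    pooled = _pooled_metrics("cue", labels[seen], oof_scores[seen], y[seen], threshold)
    return ClassificationCVResult(
        task="cue",
        fold_metrics=pd.DataFrame(rows),
        oof_scores=oof_scores,
        oof_labels=labels,
        oof_targets=y,
        thresholds=[threshold] * len(folds),
        pooled=pooled,
    )


def repeat_classification(
    cohort,
    task: str,
    n_repetitions: int = 100,
    k: int = 5,
    seed: int = 0,
    n_components: int | None = None,
    spec: RegressorSpec | None = None,
) -> pd.DataFrame:
    """Repeated-CV metric distribution for one classification task."""
    if task not in ("craving", "cue"):
        raise ValueError("task must be 'craving' or 'cue'")
    runner = run_craving_classification if task == "craving" else run_cue_classification
    kwargs = {}
    if n_components is not None:
        kwargs["n_components"] = n_components
    children = np.random.SeedSequence(seed).spawn(n_repetitions)
    rows = []
    for rep, child in enumerate(children):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        subjects = (
            cohort.select(binarize_craving(cohort).indices).subjects
            if task == "craving"
            else cohort.subjects
        )
        plan = make_split(subjects, holdout_fraction=0.0, k=k, seed=rep_seed)
        res = runner(cohort, plan=plan, seed=rep_seed, spec=spec, **kwargs)
        rows.append(
            {"repetition": rep} | {name: mv.value for name, mv in res.pooled.items()}
        )
    return pd.DataFrame(rows)
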
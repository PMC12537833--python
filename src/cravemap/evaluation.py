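"""Subject-level splitting, stratified metrics, extremes, and CV evaluation.

All splitting is by participant: every sample of a subject shares its
assignment, so no subject contributes to both the train and test side of
any fold.  Error metrics (RMSE/MAE) are stratified: computed within each
observed rating level and then averaged without weights, which neutralizes
rating imbalance.  Pearson r is pooled over all pairs, because a
within-level correlation is undefined when the level's ratings are
constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    roc_auc_score,
    roc_curve,
)

from .features import FeatureReducer

__all__ = [
    "SplitPlan",
    "MetricValue",
    "make_split",
    "stratified_metric",
    "pearson_metric",
    "classification_metrics",
    "roc_curve_table",
    "extract_extremes",
    "run_cv",
    "repeat_cv",
    "CVResult",
    "prepare_fold_scores",
]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Hold-out subjects plus a k-fold partition of the fitting subjects.

    ``folds`` is a tuple of subject tuples; :func:`make_split` guarantees
    disjointness and balance, while :func:`run_cv` re-checks for subject
    leakage at the sample level on every run.
    """

    holdout_subjects: tuple[str, ...]
    folds: tuple[tuple[str, ...], ...]
    k: int
    seed: int

    @property
    def fitting_subjects(self) -> tuple[str, ...]:
        return tuple(s for fold in self.folds for s in fold)


def make_split(
    subjects: Sequence[str],
    holdout_fraction: float = 0.2,
    k: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Shuffle subjects, set aside ceil(fraction * n) as hold-out, deal the
    rest into k balanced folds (sizes differ by at most one).

    Rounding up reproduces the reference split: 51 subjects at 20% give 11
    held out and 40 fitting.
    """
    subjects = list(dict.fromkeys(map(str, subjects)))
    if not subjects:
        raise ValueError("no subjects to split")
    if not 0 <= holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    shuffled = [subjects[i] for i in rng.permutation(len(subjects))]
    n_hold = math.ceil(holdout_fraction * len(subjects))
    holdout = tuple(shuffled[:n_hold])
    fitting = shuffled[n_hold:]
    if k > len(fitting):
        raise ValueError(
            f"k={k} folds but only {len(fitting)} fitting subjects remain"
        )
    folds = tuple(tuple(fitting[i::k]) for i in range(k))
    return SplitPlan(holdout_subjects=holdout, folds=folds, k=k, seed=seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricValue:
    name: str
    value: float
    stratified: bool = False
    n: int = 0


def _level_error(y: np.ndarray, yhat: np.ndarray, metric: str) -> float:
    err = yhat - y
    if metric == "rmse":
        return float(np.sqrt(np.mean(err**2)))
    if metric == "mae":
        return float(np.mean(np.abs(err)))
    raise ValueError(f"unknown metric {metric!r}")


def stratified_metric(
    y: np.ndarray, yhat: np.ndarray, metric: str = "rmse"
) -> MetricValue:
    """Error within each observed rating level, averaged without weights."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("y and yhat must be equal-length and non-empty")
    levels = np.unique(y)
    per_level = [_level_error(y[y == lv], yhat[y == lv], metric) for lv in levels]
    return MetricValue(
        name=metric, value=float(np.mean(per_level)), stratified=True, n=y.size
    )


def pearson_metric(y: np.ndarray, yhat: np.ndarray) -> MetricValue:
    """Pooled Pearson r; NaN when either vector is constant (undefined)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 2 or y.shape != yhat.shape:
        raise ValueError("need >= 2 aligned pairs")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        return MetricValue(name="pearson_r", value=float("nan"), n=y.size)
    r = stats.pearsonr(y, yhat).statistic
    return MetricValue(name="pearson_r", value=float(r), n=y.size)


def classification_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict[str, MetricValue]:
    """Threshold metrics plus ROC/PR areas for binary labels.

    Predictions are ``scores >= threshold`` (boundary goes to the positive
    class).  AUCs are NaN when only one class is present.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(int)
    n = labels.size
    single_class = np.unique(labels).size < 2
    out = {
        "accuracy": MetricValue("accuracy", float(accuracy_score(labels, pred)), n=n),
        "precision": MetricValue(
            "precision", float(precision_score(labels, pred, zero_division=0)), n=n
        ),
        "f1": MetricValue("f1", float(f1_score(labels, pred, zero_division=0)), n=n),
    }
    if single_class:
        out["auc_roc"] = MetricValue("auc_roc", float("nan"), n=n)
        out["auc_pr"] = MetricValue("auc_pr", float("nan"), n=n)
    else:
        out["auc_roc"] = MetricValue(
            "auc_roc", float(roc_auc_score(labels, scores)), n=n
        )
        out["auc_pr"] = MetricValue(
            "auc_pr", float(average_precision_score(labels, scores)), n=n
        )
    return out


def roc_curve_table(labels: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold), exportable for plotting."""
    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------------
# per-subject extremes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtremePair:
    """Positional indices of a subject's first minimum and first maximum."""

    min_index: int
    max_index: int
    degenerate: bool  # min rating == max rating


def extract_extremes(
    ratings: Sequence[int], block_indices: Sequence[int] | None = None
) -> ExtremePair:
    """First occurrence (in block order) of the min and the max rating.

    Returns positions into the given sequences.  ``degenerate`` is set when
    the subject's ratings are constant (single sample included).
    """
    ratings = np.asarray(ratings)
    if ratings.size == 0:
        raise ValueError("subject has no samples")
    if block_indices is None:
        order = np.arange(ratings.size)
    else:
        order = np.argsort(np.asarray(block_indices), kind="stable")
    r_sorted = ratings[order]
    min_pos = int(order[np.argmin(r_sorted)])
    max_pos = int(order[np.argmax(r_sorted)])
    return ExtremePair(
        min_index=min_pos,
        max_index=max_pos,
        degenerate=bool(ratings[min_pos] == ratings[max_pos]),
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldScores:
    """Cached per-fold reduced-space design matrices (label-independent)."""

    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    S_train: np.ndarray
    S_test: np.ndarray
    reducer: FeatureReducer


def _fold_sample_indices(cohort, plan: SplitPlan):
    """Yield (fold id, train rows, test rows) with a subject-leakage check."""
    sid = cohort.subject_ids
    holdout = set(plan.holdout_subjects)
    for f, fold_subjects in enumerate(plan.folds):
        test_set = set(fold_subjects)
        train_set = {
            s for g, fs in enumerate(plan.folds) if g != f for s in fs
        }
        assert not (train_set & test_set), (
            f"subject leakage in fold {f}: {sorted(train_set & test_set)}"
        )
        assert not (train_set & holdout) and not (test_set & holdout), (
            "hold-out subjects leaked into cross-validation"
        )
        test_mask = np.isin(sid, list(test_set))
        train_mask = np.isin(sid, list(train_set))
        yield f, np.flatnonzero(train_mask), np.flatnonzero(test_mask)


def prepare_fold_scores(
    cohort,
    plan: SplitPlan,
    reducer_config: Mapping[str, Any],
    anova_groups: np.ndarray | None = None,
) -> list[FoldScores]:
    """Fit the reducer per fold (train rows only) and cache the transforms.

    For PCA the reducer depends only on the features, so the cache can be
    reused across label permutations; for ANOVA the grouping labels enter
    the fit and the cache is valid only for the given ``anova_groups``.
    """
    folds = []
    for f, tr, te in _fold_sample_indices(cohort, plan):
        groups = None
        if dict(reducer_config).get("method") == "anova":
            base = anova_groups if anova_groups is not None else cohort.ratings
            groups = np.asarray(base)[tr]
        red = FeatureReducer(**reducer_config).fit(cohort.X[tr], groups)
        folds.append(
            FoldScores(
                fold=f,
                train_idx=tr,
                test_idx=te,
                S_train=red.transform(cohort.X[tr]),
                S_test=red.transform(cohort.X[te]),
                reducer=red,
            )
        )
    return folds


@dataclass
class CVResult:
    """Per-fold metric table plus pooled out-of-fold predictions."""

    fold_metrics: pd.DataFrame
    oof_pred: np.ndarray  # aligned with the cohort rows; NaN where not predicted
    pooled: dict[str, MetricValue] = field(default_factory=dict)


def _target_vector(cohort, target: str) -> np.ndarray:
    if target == "rating":
        return cohort.ratings
    if target == "cue":
        return cohort.cue_types.astype(float)
    raise ValueError(f"unknown target {target!r}")


def run_cv(
    cohort,
    reducer_config: Mapping[str, Any],
    spec=None,
    plan: SplitPlan | None = None,
    seed: int = 0,
    target: str = "rating",
    folds: list[FoldScores] | None = None,
) -> CVResult:
    """Subject-level k-fold CV: fit on in-fold-train, predict out-of-fold.

    Hold-out subjects in ``plan`` are never touched.  Returns per-fold
    stratified RMSE/MAE and pooled metrics over the out-of-fold
    predictions.  ``folds`` may pass pre-computed :class:`FoldScores`.
    """
    from .models import RegressorSpec, build_estimator  # lazy: module cycle

    spec = spec or RegressorSpec()
    if plan is None:
        plan = make_split(cohort.subjects, holdout_fraction=0.0, k=5, seed=seed)
    y_all = _target_vector(cohort, target)
    if folds is None:
        folds = prepare_fold_scores(cohort, plan, reducer_config)
    oof = np.full(len(cohort), np.nan)
    rows = []
    for fs in folds:
        est = build_estimator(spec, seed=seed + fs.fold)
        est.fit(fs.S_train, y_all[fs.train_idx])
        yhat = est.predict(fs.S_test)
        oof[fs.test_idx] = yhat
        y_te = y_all[fs.test_idx]
        rows.append(
            {
                "fold": fs.fold,
                "n_test": len(fs.test_idx),
                "rmse_stratified": stratified_metric(y_te, yhat, "rmse").value,
                "mae_stratified": stratified_metric(y_te, yhat, "mae").value,
                "pearson_r": pearson_metric(y_te, yhat).value,
            }
        )
    seen = ~np.isnan(oof)
    pooled = {
        "rmse_stratified": stratified_metric(y_all[seen], oof[seen], "rmse"),
        "mae_stratified": stratified_metric(y_all[seen], oof[seen], "mae"),
        "pearson_r": pearson_metric(y_all[seen], oof[seen]),
    }
    return CVResult(fold_metrics=pd.DataFrame(rows), oof_pred=oof, pooled=pooled)


def repeat_cv(
    cohort,
    reducer_config: Mapping[str, Any],
    spec=None,
    n_repetitions: int = 100,
    k: int = 5,
    seed: int = 0,
    target: str = "rating",
) -> pd.DataFrame:
    """Repeat k-fold CV with fresh fold assignments; one metric row per run.

    This builds the observed metric distribution (the histogram of repeated
    cross-validation values) from which inference summaries are computed.
    """
    children = np.random.SeedSequence(seed).spawn(n_repetitions)
    rows = []
    for rep, child in enumerate(children):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        plan = make_split(cohort.subjects, holdout_fraction=0.0, k=k, seed=rep_seed)
        res = run_cv(
            cohort, reducer_config, spec=spec, plan=plan, seed=rep_seed, target=target
        )
        rows.append(
            {
                "repetition": rep,
                "rmse": res.pooled["rmse_stratified"].value,
                "mae": res.pooled["mae_stratified"].value,
                "pearson_r": res.pooled["pearson_r"].value,
            }
        )
    return pd.DataFrame(rows)
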
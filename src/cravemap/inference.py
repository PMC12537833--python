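"""Permutation-null inference and the statistical summary columns.

The null distribution of every metric is built by repeatedly shuffling the
prediction targets across all fitting samples (features untouched) and
re-running the full cross-validated evaluation.  Significance and power use
counting definitions: the add-one permutation p-value, and power as the
fraction of the observed metric distribution beyond the null's 5% critical
value.  Effect sizes are gated by a Shapiro-Wilk normality test of the
observed distribution: Cohen's d with a Student-t CI when normal, Cliff's
delta with a percentile-bootstrap CI otherwise.

Because the PCA reducer never sees the targets, fold transforms are fitted
once and reused across permutations; for the plain least-squares family all
permuted targets are solved in a single multi-RHS least-squares call per
fold.  This is algebraically identical to re-fitting per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import binarize_craving, optimize_threshold
from .evaluation import (
    SplitPlan,
    classification_metrics,
    make_split,
    pearson_metric,
    prepare_fold_scores,
    stratified_metric,
)
from .models import RegressorSpec, build_estimator

__all__ = [
    "MetricDistribution",
    "StatReport",
    "permutation_null",
    "p_value",
    "power",
    "cliffs_delta",
    "cohens_d",
    "normality_gate",
    "bootstrap_ci",
    "report",
    "write_stat_table",
]

LOWER_BETTER = frozenset({"rmse", "mae", "rmse_stratified", "mae_stratified"})


def better_direction(metric: str) -> str:
    return "lower" if metric in LOWER_BETTER else "higher"


@dataclass
class MetricDistribution:
    """Observed repeated-CV values paired with a permutation-null sample."""

    metric: str
    observed: np.ndarray
    null: np.ndarray
    direction: str = ""

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.null = np.asarray(self.null, dtype=float)
        if self.observed.size == 0 or self.null.size == 0:
            raise ValueError("observed and null must be non-empty")
        if not self.direction:
            self.direction = better_direction(self.metric)
        if self.direction not in ("lower", "higher"):
            raise ValueError("direction must be 'lower' or 'higher'")


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _permuted_targets(
    y: np.ndarray,
    n_perm: int,
    seed: int,
    subject_ids: np.ndarray | None = None,
) -> np.ndarray:
    """(n, n_perm) matrix of shuffled targets, one child seed per permutation.

    With ``subject_ids`` given, shuffling happens within each subject's rows
    (the alternative scheme); otherwise across all samples.  The label
    multiset is preserved exactly either way.
    """
    n = y.shape[0]
    out = np.empty((n, n_perm), dtype=float)
    for j, child in enumerate(np.random.SeedSequence(seed).spawn(n_perm)):
        rng = np.random.default_rng(child)
        if subject_ids is None:
            out[:, j] = y[rng.permutation(n)]
        else:
            perm = np.arange(n)
            for sid in np.unique(subject_ids):
                rows = np.flatnonzero(subject_ids == sid)
                perm[rows] = rows[rng.permutation(rows.size)]
            out[:, j] = y[perm]
    return out


def _batched_oof(folds, Y: np.ndarray) -> np.ndarray:
    """Out-of-fold OLS predictions for every target column at once."""
    n = Y.shape[0]
    P = np.full_like(Y, np.nan)
    for fs in folds:
        A = np.column_stack([np.ones(len(fs.train_idx)), fs.S_train])
        coefs, *_ = np.linalg.lstsq(A, Y[fs.train_idx], rcond=None)
        At = np.column_stack([np.ones(len(fs.test_idx)), fs.S_test])
        P[fs.test_idx] = At @ coefs
    assert not np.isnan(P).any(), "folds do not cover every sample"
    return P


def _looped_oof(folds, Y: np.ndarray, spec: RegressorSpec, seed: int) -> np.ndarray:
    P = np.full_like(Y, np.nan)
    for j in range(Y.shape[1]):
        for fs in folds:
            est = build_estimator(spec, seed=seed + fs.fold)
            est.fit(fs.S_train, Y[fs.train_idx, j])
            P[fs.test_idx, j] = est.predict(fs.S_test)
    return P


def _regression_metric_rows(Y: np.ndarray, P: np.ndarray) -> pd.DataFrame:
    rows = []
    for j in range(Y.shape[1]):
        y, p = Y[:, j], P[:, j]
        rows.append(
            {
                "rmse": stratified_metric(y, p, "rmse").value,
                "mae": stratified_metric(y, p, "mae").value,
                "pearson_r": pearson_metric(y, p).value,
            }
        )
    return pd.DataFrame(rows)


def _classification_metric_rows(
    labels_perm: np.ndarray,
    P: np.ndarray,
    folds,
    thresholds: str | float,
    targets_perm: np.ndarray,
) -> pd.DataFrame:
    """Per-permutation classification metrics on out-of-fold scores.

    ``thresholds`` is either a fixed cut or "f1", in which case the
    F1-optimal threshold is re-derived per fold from that permutation's
    training predictions — mirroring the observed algorithm exactly.
    """
    rows = []
    for j in range(P.shape[1]):
        scores = P[:, j]
        labels = labels_perm[:, j].astype(int)
        if thresholds == "f1":
            pred = np.zeros_like(scores, dtype=bool)
            for fs in folds:
                A = np.column_stack([np.ones(len(fs.train_idx)), fs.S_train])
                coefs, *_ = np.linalg.lstsq(
                    A, targets_perm[fs.train_idx, j], rcond=None
                )
                train_pred = A @ coefs
                thr = optimize_threshold(
                    train_pred, labels_perm[fs.train_idx, j].astype(int)
                ).threshold
                pred[fs.test_idx] = scores[fs.test_idx] >= thr
            m = classification_metrics(labels, scores, threshold=np.inf)
            acc = float(np.mean(pred == labels))
            tp = int(np.sum(pred & (labels == 1)))
            fp = int(np.sum(pred & (labels == 0)))
            prec = tp / (tp + fp) if (tp + fp) else 0.0
            row = {
                "accuracy": acc,
                "precision": prec,
                "auc_roc": m["auc_roc"].value,
                "auc_pr": m["auc_pr"].value,
            }
        else:
            m = classification_metrics(labels, scores, threshold=float(thresholds))
            row = {k: m[k].value for k in ("accuracy", "precision", "auc_roc", "auc_pr")}
        row["rmse"] = stratified_metric(targets_perm[:, j], scores, "rmse").value
        rows.append(row)
    return pd.DataFrame(rows)


def permutation_null(
    cohort,
    reducer_config: Mapping[str, object],
    spec: RegressorSpec | None = None,
    task: str = "regress",
    n_perm: int = 1000,
    k: int = 5,
    seed: int = 0,
    within_subject: bool = False,
    plan: SplitPlan | None = None,
) -> pd.DataFrame:
    """Null metric sample: shuffle targets, re-run the CV, record metrics.

    Returns one row per permutation.  Tasks: ``regress`` (rating target),
    ``craving`` (extreme blocks, per-fold F1 thresholds), ``cue`` (cue
    target, fixed 0.5 threshold).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    spec = spec or RegressorSpec()

    if task == "craving":
        ext = binarize_craving(cohort)
        data = cohort.select(ext.indices)
        y = data.ratings
        labels = ext.labels.astype(float)
    elif task == "cue":
        data = cohort
        y = data.cue_types.astype(float)
        labels = y.copy()
    elif task == "regress":
        data = cohort
        y = data.ratings
        labels = None
    else:
        raise ValueError(f"unknown task {task!r}")

    if plan is None:
        plan = make_split(data.subjects, holdout_fraction=0.0, k=k, seed=seed)
    folds = prepare_fold_scores(data, plan, reducer_config)

    sid = data.subject_ids if within_subject else None
    # one shared shuffle index matrix keeps (target, label) pairs aligned
    n = len(data)
    idx = np.arange(n, dtype=float)
    I = _permuted_targets(idx, n_perm, seed, subject_ids=sid).astype(int)
    Y = np.take(y, I)

    use_fast = spec.family == "ols" and dict(reducer_config).get("method") == "pca"
    if task == "craving" and not use_fast:
        raise ValueError(
            "the high/low-craving null (per-fold F1 thresholds) is defined "
            "for the PCA + OLS configuration"
        )
    P = _batched_oof(folds, Y) if use_fast else _looped_oof(folds, Y, spec, seed)

    if task == "regress":
        return _regression_metric_rows(Y, P)
    L = np.take(labels, I)
    thresholds = "f1" if task == "craving" else 0.5
    return _classification_metric_rows(L, P, folds, thresholds, Y)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def p_value(dist: MetricDistribution) -> float:
    """Add-one permutation p: fraction of null values at least as good as
    the observed mean, in the metric's better direction."""
    obs = float(np.mean(dist.observed))
    if dist.direction == "lower":
        hits = int(np.sum(dist.null <= obs))
    else:
        hits = int(np.sum(dist.null >= obs))
    return (1 + hits) / (1 + dist.null.size)


def power(dist: MetricDistribution, alpha: float = 0.05) -> float:
    """Counting power: share of observed values beyond the null's
    alpha-tail critical value (in the better direction)."""
    if dist.direction == "lower":
        crit = float(np.quantile(dist.null, alpha))
        return float(np.mean(dist.observed < crit))
    crit = float(np.quantile(dist.null, 1 - alpha))
    return float(np.mean(dist.observed > crit))


def cliffs_delta(a: Sequence[float], b: Sequence[float]) -> float:
    """delta = (#{a > b} - #{a < b}) / (|a|·|b|) over all pairs, in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = a[:, None] - b[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (a.size * b.size))


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Mean difference over the (n-1)-weighted pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("both samples need >= 2 values")
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ZeroDivisionError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def normality_gate(x: Sequence[float], alpha: float = 0.05) -> str:
    """Shapiro-Wilk gate: 'parametric' when normality is not rejected."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("normality test needs at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for a constant vector")
    return "parametric" if stats.shapiro(x).pvalue >= alpha else "nonparametric"


def bootstrap_ci(
    x: Sequence[float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile interval of the resampled mean; deterministic per seed."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("bootstrap needs >= 2 values")
    rng = np.random.default_rng(seed)
    means = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


@dataclass
class StatReport:
    """One summary row: the statistical columns for a single metric."""

    metric: str
    mean: float
    sd: float
    ci95: tuple[float, float]
    p: float
    effect_size: float
    effect_type: str
    power: float
    out_of_sample: float

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "mean": self.mean,
            "sd": self.sd,
            "ci95_lo": self.ci95[0],
            "ci95_hi": self.ci95[1],
            "p_value": self.p,
            "effect_size": self.effect_size,
            "effect_type": self.effect_type,
            "power": self.power,
            "out_of_sample": self.out_of_sample,
        }


def report(
    dist: MetricDistribution,
    out_of_sample: float = float("nan"),
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> StatReport:
    """Assemble mean, SD, CI, p, gated effect size and power for one metric.

    The effect size compares the observed distribution to the null one and
    is oriented so that "better than null" is positive regardless of the
    metric's direction.
    """
    obs = dist.observed
    gate = normality_gate(obs) if np.ptp(obs) > 0 and obs.size >= 3 else "degenerate"
    sign = -1.0 if dist.direction == "lower" else 1.0
    if gate == "parametric":
        effect = sign * cohens_d(obs, dist.null)
        effect_type = "cohens_d"
        m, s = obs.mean(), obs.std(ddof=1)
        half = stats.t.ppf(1 - alpha / 2, obs.size - 1) * s / np.sqrt(obs.size)
        ci = (float(m - half), float(m + half))
    elif gate == "nonparametric":
        effect = sign * cliffs_delta(obs, dist.null)
        effect_type = "cliffs_delta"
        ci = bootstrap_ci(obs, n_boot=n_boot, seed=seed)
    else:  # constant observed vector: CI collapses, effect via Cliff's delta
        effect = sign * cliffs_delta(obs, dist.null)
        effect_type = "cliffs_delta"
        ci = (float(obs[0]), float(obs[0]))
    return StatReport(
        metric=dist.metric,
        mean=float(obs.mean()),
        sd=float(obs.std(ddof=1)) if obs.size > 1 else 0.0,
        ci95=ci,
        p=p_value(dist),
        effect_size=float(effect),
        effect_type=effect_type,
        power=power(dist, alpha=alpha),
        out_of_sample=float(out_of_sample),
    )


def write_stat_table(reports: Sequence[StatReport], path) -> Path:
    """TSV table mirroring the statistical summary layout."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([r.to_row() for r in reports]).to_csv(path, sep="\t", index=False)
    return path
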
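"""Regression estimators and the candidate grid search.

The menu mirrors the selection experiment: ordinary least squares, ridge,
lasso, elastic net, random forest and gradient-boosted trees, each fit on
reduced feature scores.  "Gradient boosting" stands in for the extreme
gradient boosting family; the winning configuration is PCA + OLS, and the
menu exists to reproduce the selection, not any one library's tree
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge

from .features import FeatureReducer

__all__ = [
    "FAMILIES",
    "RegressorSpec",
    "FittedPipeline",
    "GridResult",
    "build_estimator",
    "fit_pipeline",
    "grid_search",
]

# family order doubles as the tie-break order (simpler families first)
FAMILIES = ("ols", "ridge", "lasso", "elastic_net", "random_forest",
            "gradient_boosting")

_LINEAR_FAMILIES = frozenset({"ols", "ridge", "lasso", "elastic_net"})


@dataclass(frozen=True)
class RegressorSpec:
    """One regressor family plus its hyperparameters."""

    family: str = "ols"
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        hp = dict(self.hyperparameters)
        if hp.get("alpha", 0) < 0:
            raise ValueError("penalty strength must be >= 0")
        if not 0 <= hp.get("l1_ratio", 0.5) <= 1:
            raise ValueError("l1_ratio must be in [0, 1]")
        if hp.get("n_estimators", 1) < 1:
            raise ValueError("tree count must be >= 1")
        object.__setattr__(self, "hyperparameters", hp)

    @property
    def is_linear(self) -> bool:
        return self.family in _LINEAR_FAMILIES


def build_estimator(spec: RegressorSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator for a spec.

    Tree families get ``random_state`` derived from ``seed``; linear
    families are deterministic.
    """
    hp = dict(spec.hyperparameters)
    if spec.family == "ols":
        return LinearRegression(**hp)
    if spec.family == "ridge":
        return Ridge(alpha=hp.pop("alpha", 1.0), **hp)
    if spec.family == "lasso":
        return Lasso(alpha=hp.pop("alpha", 1.0), **hp)
    if spec.family == "elastic_net":
        return ElasticNet(
            alpha=hp.pop("alpha", 1.0), l1_ratio=hp.pop("l1_ratio", 0.5), **hp
        )
    if spec.family == "random_forest":
        hp.setdefault("n_estimators", 200)
        return RandomForestRegressor(random_state=seed, **hp)
    if spec.family == "gradient_boosting":
        hp.setdefault("n_estimators", 200)
        return GradientBoostingRegressor(random_state=seed, **hp)
    raise ValueError(spec.family)  # unreachable


@dataclass
class FittedPipeline:
    """Everything needed to predict from raw voxels and to back-project.

    For linear families ``B`` (coefficients in reduced space) and ``b0``
    (intercept) are exposed; tree families predict through the estimator
    only and cannot be back-projected.
    """

    reducer: FeatureReducer
    estimator: Any
    spec: RegressorSpec
    train_subjects: frozenset[str] = frozenset()

    @property
    def B(self) -> np.ndarray:
        if not self.spec.is_linear:
            raise AttributeError("B is defined for linear families only")
        return np.asarray(self.estimator.coef_, dtype=float)

    @property
    def b0(self) -> float:
        if not self.spec.is_linear:
            raise AttributeError("b0 is defined for linear families only")
        return float(self.estimator.intercept_)

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        """Raw voxel samples -> predicted target (no clipping to [1, 4])."""
        scores = self.reducer.transform(X_raw)
        yhat = self.estimator.predict(scores)
        if not np.all(np.isfinite(yhat)):
            raise FloatingPointError("non-finite predictions")
        return np.asarray(yhat, dtype=float)


def fit_pipeline(
    X_raw: np.ndarray,
    y: np.ndarray,
    reducer: FeatureReducer | Mapping[str, Any],
    spec: RegressorSpec = RegressorSpec(),
    seed: int = 0,
    train_subjects: Sequence[str] = (),
    anova_groups: np.ndarray | None = None,
) -> FittedPipeline:
    """Fit reducer (training data only) + regressor into one pipeline.

    ``anova_groups`` supplies the grouping labels for ANOVA selection
    (defaults to ``y`` rounded, i.e., rating levels).
    """
    y = np.asarray(y, dtype=float)
    if X_raw.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if isinstance(reducer, Mapping):
        reducer = FeatureReducer(**reducer)
    if not reducer.is_fitted:
        groups = anova_groups if anova_groups is not None else np.rint(y)
        reducer.fit(X_raw, groups)
    scores = reducer.transform(X_raw)
    est = build_estimator(spec, seed=seed)
    est.fit(scores, y)
    if spec.family == "ols" and scores.shape[1] >= scores.shape[0]:
        raise ValueError(
            "exact OLS with p >= n: the reducer must leave fewer components "
            "than training samples"
        )
    return FittedPipeline(
        reducer=reducer,
        estimator=est,
        spec=spec,
        train_subjects=frozenset(map(str, train_subjects)),
    )


@dataclass(frozen=True)
class Candidate:
    """One (reducer configuration, regressor spec) grid-search entry."""

    reducer_config: Mapping[str, Any]
    spec: RegressorSpec

    def label(self) -> str:
        cfg = dict(self.reducer_config)
        hp = ",".join(f"{k}={v}" for k, v in sorted(self.spec.hyperparameters.items()))
        return (
            f"{cfg.get('method', 'pca')}-{cfg.get('n_components', '?')}"
            f"+{self.spec.family}" + (f"({hp})" if hp else "")
        )


@dataclass
class GridResult:
    """Scored candidate table; ``winner`` indexes the minimum CV RMSE."""

    candidates: list[Candidate]
    cv_rmse: list[float]  # NaN for failed candidates
    fold_rmse: list[list[float]]
    failures: dict[int, str]
    winner: int

    def winning_candidate(self) -> Candidate:
        return self.candidates[self.winner]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "candidate": [c.label() for c in self.candidates],
                "mean_cv_rmse": self.cv_rmse,
                "fold_rmse": [
                    " ".join(f"{v:.6g}" for v in fr) for fr in self.fold_rmse
                ],
                "failed": [i in self.failures for i in range(len(self.candidates))],
                "reason": [self.failures.get(i, "") for i in range(len(self.candidates))],
                "winner": [i == self.winner for i in range(len(self.candidates))],
            }
        )


def _tie_break_key(idx: int, cand: Candidate) -> tuple:
    n_comp = int(dict(cand.reducer_config).get("n_components", 10**9))
    return (n_comp, FAMILIES.index(cand.spec.family), idx)


def grid_search(
    candidates: Sequence[Candidate | tuple],
    cohort,
    k: int = 5,
    seed: int = 0,
    target: str = "rating",
) -> GridResult:
    """Score each candidate by subject-level k-fold CV stratified RMSE.

    Candidates that are invalid for the data size are marked failed with a
    reason rather than silently dropped.  Ties on mean RMSE break toward
    fewer components, then the simpler family, deterministically.
    """
    from .evaluation import make_split, run_cv  # lazy: avoids module cycle

    cands = [c if isinstance(c, Candidate) else Candidate(*c) for c in candidates]
    if not cands:
        raise ValueError("no candidates given")
    plan = make_split(cohort.subjects, holdout_fraction=0.0, k=k, seed=seed)
    cv_rmse: list[float] = []
    fold_rmse: list[list[float]] = []
    failures: dict[int, str] = {}
    for i, cand in enumerate(cands):
        try:
            res = run_cv(
                cohort,
                reducer_config=dict(cand.reducer_config),
                spec=cand.spec,
                plan=plan,
                seed=seed,
                target=target,
            )
            per_fold = res.fold_metrics["rmse_stratified"].tolist()
            cv_rmse.append(float(np.mean(per_fold)))
            fold_rmse.append(per_fold)
        except (ValueError, RuntimeError) as exc:
            failures[i] = str(exc)
            cv_rmse.append(float("nan"))
            fold_rmse.append([])
    ok = [i for i in range(len(cands)) if i not in failures]
    if not ok:
        raise RuntimeError("every grid-search candidate failed")
    best = min(cv_rmse[i] for i in ok)
    tied = [i for i in ok if cv_rmse[i] <= best + 1e-12]
    winner = min(tied, key=lambda i: _tie_break_key(i, cands[i]))
    return GridResult(
        candidates=cands,
        cv_rmse=cv_rmse,
        fold_rmse=fold_rmse,
        failures=failures,
        winner=winner,
    )


def default_candidate_grid(
    components: Sequence[int] = (50, 100),
    families: Sequence[str] = FAMILIES,
) -> list[Candidate]:
    """The default selection grid (penalties, l1 ratios, tree depths)."""
    out: list[Candidate] = []
    for n_comp in components:
        red = {"method": "pca", "n_components": int(n_comp)}
        for fam in families:
            if fam == "ols":
                out.append(Candidate(red, RegressorSpec("ols")))
            elif fam in ("ridge", "lasso"):
                for a in (0.01, 0.1, 1.0, 10.0):
                    out.append(Candidate(red, RegressorSpec(fam, {"alpha": a})))
            elif fam == "elastic_net":
                for a in (0.01, 0.1, 1.0, 10.0):
                    for l1 in (0.25, 0.5, 0.75):
                        out.append(
                            Candidate(
                                red, RegressorSpec(fam, {"alpha": a, "l1_ratio": l1})
                            )
                        )
            else:
                for depth in (3, None):
                    out.append(
                        Candidate(
                            red,
                            RegressorSpec(
                                fam, {"n_estimators": 200, "max_depth": depth}
                            ),
                        )
                    )
    return out
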
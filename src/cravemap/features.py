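"""Feature reduction: variance filter, standardization, PCA / ANOVA selection.

The reducer is fit on training data only and is strictly stateless at
transform time.  Order of operations: drop columns with sample variance
(ddof=1) below the threshold, standardize the survivors ((x - mu) / sigma),
then either project onto PCA components or keep the top-k columns by the
one-way ANOVA F statistic grouped by rating level.

PCA component signs are fixed by forcing the largest-magnitude loading of
each component to be positive; without this the back-projected signature map
would flip arbitrarily between otherwise identical fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif

__all__ = ["FeatureReducer", "fit_variance_filter", "fit_reducer"]

_FORMAT_VERSION = 1


def fit_variance_filter(X: np.ndarray, threshold: float = 0.001) -> np.ndarray:
    """Indices of columns whose unbiased sample variance is >= threshold."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("variance filter needs at least 2 samples")
    var = X.var(axis=0, ddof=1)
    return np.flatnonzero(var >= threshold)


@dataclass
class FeatureReducer:
    """Variance filter + standard scaler + PCA or ANOVA selection.

    Parameters
    ----------
    method : {"pca", "anova"}
    n_components : components kept (PCA) or k best columns (ANOVA).
    variance_threshold : minimum unbiased sample variance to keep a column.

    Fitted state: ``kept_columns_`` (into the original full voxel layout),
    ``mean_`` / ``scale_`` (per kept column), and ``components_`` (PCA,
    n_components x n_kept, rows orthonormal) or ``selected_`` (ANOVA,
    indices into kept columns).
    """

    method: str = "pca"
    n_components: int = 100
    variance_threshold: float = 0.001

    kept_columns_: np.ndarray | None = field(default=None, repr=False)
    mean_: np.ndarray | None = field(default=None, repr=False)
    scale_: np.ndarray | None = field(default=None, repr=False)
    components_: np.ndarray | None = field(default=None, repr=False)
    explained_variance_: np.ndarray | None = field(default=None, repr=False)
    selected_: np.ndarray | None = field(default=None, repr=False)
    f_scores_: np.ndarray | None = field(default=None, repr=False)
    n_features_in_: int | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.method not in ("pca", "anova"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")

    @property
    def is_fitted(self) -> bool:
        return self.kept_columns_ is not None

    @property
    def n_features_out(self) -> int:
        return self.n_components

    def fit(self, X: np.ndarray, y: np.ndarray | None = None) -> "FeatureReducer":
        """Fit on training data; ``y`` (rating levels) is required for ANOVA."""
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        self.n_features_in_ = X.shape[1]
        self.kept_columns_ = fit_variance_filter(X, self.variance_threshold)
        Xk = X[:, self.kept_columns_]
        n_kept = Xk.shape[1]
        if self.n_components > min(n - 1, n_kept):
            raise ValueError(
                f"n_components={self.n_components} exceeds "
                f"min(n_train - 1, kept columns) = {min(n - 1, n_kept)}"
            )
        self.mean_ = Xk.mean(axis=0)
        self.scale_ = Xk.std(axis=0)  # population sd, as a standard scaler uses
        assert np.all(self.scale_ > 0), "zero scale after variance filtering"
        Xs = (Xk - self.mean_) / self.scale_
        if self.method == "pca":
            pca = PCA(n_components=self.n_components, random_state=0)
            pca.fit(Xs)
            comps = pca.components_.copy()
            # sign convention: largest-|loading| entry of each component > 0
            flip = np.sign(comps[np.arange(comps.shape[0]),
                                 np.abs(comps).argmax(axis=1)])
            self.components_ = comps * flip[:, None]
            self.explained_variance_ = pca.explained_variance_.copy()
        else:
            if y is None:
                raise ValueError("ANOVA selection requires y")
            y = np.asarray(y)
            if y.shape[0] != n:
                raise ValueError("ANOVA selection requires y aligned with X")
            _, counts = np.unique(y, return_counts=True)
            if counts.size < 2:
                raise ValueError("ANOVA needs at least two rating levels")
            if counts.min() < 2:
                raise ValueError("every rating level needs >= 2 samples for ANOVA")
            F, _ = f_classif(Xs, y)
            F = np.nan_to_num(F, nan=0.0)
            # deterministic: descending F, ascending column index on ties
            order = np.lexsort((np.arange(F.size), -F))
            self.selected_ = np.sort(order[: self.n_components])
            self.f_scores_ = F
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project raw full-layout samples into the reduced space."""
        if not self.is_fitted:
            raise RuntimeError("reducer is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns; reducer was fit on "
                f"{self.n_features_in_}"
            )
        Xs = (X[:, self.kept_columns_] - self.mean_) / self.scale_
        if self.method == "pca":
            return Xs @ self.components_.T
        return Xs[:, self.selected_]

    def fit_transform(self, X: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    # -- serialization -----------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Serialize to a single .npz archive (format version 1)."""
        if not self.is_fitted:
            raise RuntimeError("cannot save an unfitted reducer")
        path = Path(path)
        arrays = {
            "format_version": np.array(_FORMAT_VERSION),
            "method": np.array(self.method),
            "n_components": np.array(self.n_components),
            "variance_threshold": np.array(self.variance_threshold),
            "n_features_in": np.array(self.n_features_in_),
            "kept_columns": self.kept_columns_,
            "mean": self.mean_,
            "scale": self.scale_,
        }
        if self.method == "pca":
            arrays["components"] = self.components_
            arrays["explained_variance"] = self.explained_variance_
        else:
            arrays["selected"] = self.selected_
            arrays["f_scores"] = self.f_scores_
        np.savez(path, **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FeatureReducer":
        with np.load(path, allow_pickle=False) as z:
            if int(z["format_version"]) != _FORMAT_VERSION:
                raise ValueError("unsupported reducer archive version")
            r = cls(
                method=str(z["method"]),
                n_components=int(z["n_components"]),
                variance_threshold=float(z["variance_threshold"]),
            )
            r.n_features_in_ = int(z["n_features_in"])
            r.kept_columns_ = z["kept_columns"]
            r.mean_ = z["mean"]
            r.scale_ = z["scale"]
            if r.method == "pca":
                r.components_ = z["components"]
                r.explained_variance_ = z["explained_variance"]
            else:
                r.selected_ = z["selected"]
                r.f_scores_ = z["f_scores"]
        return r


def fit_reducer(
    X_train: np.ndarray,
    method: str = "pca",
    size_param: int = 100,
    y: np.ndarray | None = None,
    variance_threshold: float = 0.001,
) -> FeatureReducer:
    """Convenience constructor-and-fit used by the pipeline."""
    return FeatureReducer(
        method=method, n_components=size_param, variance_threshold=variance_threshold
    ).fit(X_train, y)
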
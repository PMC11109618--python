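"""Feature ranking, top-k selection, hybrid-matrix construction, and SMOTE.

Features are ranked per source matrix by the p-value of a two-sided,
two-sample Student t-test with pooled variance (the classic ``ttest2``
default), the top ``k`` features with p < alpha from each of the six
matrices are concatenated, and the result is standardized column-wise
("equal-weight" processing) so every selected feature contributes a
comparable magnitude.  Class imbalance is then removed with the synthetic
minority oversampling technique (SMOTE), which interpolates new minority
rows between existing minority neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors

from .features import FeatureDescriptor, FeatureMatrix

__all__ = [
    "RankedFeature",
    "HybridMatrix",
    "BalanceResult",
    "pooled_ttest_pvalues",
    "rank_by_pvalue",
    "select_top",
    "TTestKBest",
    "HybridBuilder",
    "build_hybrid",
    "Smote",
    "smote_balance",
]


@dataclass(frozen=True)
class RankedFeature:
    """One feature with its between-class p-value and rank (1 = smallest p)."""

    descriptor: FeatureDescriptor
    column: int
    p_value: float
    rank: int


def pooled_ttest_pvalues(values: np.ndarray, y: np.ndarray,
                         equal_var: bool = True) -> np.ndarray:
    """Two-sided two-sample t-test p-value per column.

    ``equal_var=True`` is the pooled-variance Student test; a zero-variance,
    equal-mean column has an undefined statistic and gets p = 1 by
    convention (ranked last).
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    a = values[y == classes[0]]
    b = values[y == classes[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("each class needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = sstats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    p = np.asarray(p, dtype=float)
    p[np.isnan(p)] = 1.0
    return p


def rank_by_pvalue(matrix: FeatureMatrix, y: np.ndarray | None = None,
                   equal_var: bool = True) -> list[RankedFeature]:
    """All features of one matrix, sorted ascending by p (ties: column order)."""
    if y is None:
        y = matrix.binary_labels
    p = pooled_ttest_pvalues(matrix.values, y, equal_var=equal_var)
    order = np.argsort(p, kind="stable")
    return [
        RankedFeature(descriptor=matrix.descriptors[col], column=int(col),
                      p_value=float(p[col]), rank=int(r + 1))
        for r, col in enumerate(order)
    ]


def select_top(ranked: list[RankedFeature], k: int = 10,
               alpha: float = 0.05) -> list[RankedFeature]:
    """Up to ``k`` significant (p < alpha) features, in rank order."""
    chosen = [rf for rf in ranked if rf.p_value < alpha][:k]
    if not chosen:
        warnings.warn("no feature reached the significance threshold",
                      stacklevel=2)
    return chosen


class TTestKBest(BaseEstimator, TransformerMixin):
    """sklearn-style selector: top-k features by pooled-variance t-test p.

    Parameters
    ----------
    k : number of features to keep (fewer if fewer reach ``alpha``).
    alpha : significance threshold on the two-sided p-value.
    equal_var : pooled-variance Student test when True, Welch when False.
    """

    def __init__(self, k: int = 10, alpha: float = 0.05,
                 equal_var: bool = True):
        self.k = k
        self.alpha = alpha
        self.equal_var = equal_var

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.pvalues_ = pooled_ttest_pvalues(X, y, equal_var=self.equal_var)
        order = np.argsort(self.pvalues_, kind="stable")
        significant = order[self.pvalues_[order] < self.alpha]
        self.selected_ = np.asarray(significant[: self.k], dtype=int)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        return X[:, self.selected_]


@dataclass
class HybridMatrix:
    """The standardized hybrid feature table built from six matrices."""

    values: np.ndarray
    columns: list[RankedFeature]
    source_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    per_source_counts: dict[str, int] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def report(self) -> pd.DataFrame:
        """Selected-feature table (descriptor, p-value, rank, source)."""
        return pd.DataFrame({
            "feature": [c.descriptor.name for c in self.columns],
            "p_value": [c.p_value for c in self.columns],
            "rank": [c.rank for c in self.columns],
            "source_matrix": self.source_names,
        })


class HybridBuilder(BaseEstimator):
    """Fits per-matrix top-k selection plus equal-weight standardization.

    ``fit`` consumes the six feature matrices (with labels) and learns the
    selected columns and per-column center/scale; ``transform`` applies them
    to held-out rows of the same matrices without touching their labels.
    """

    def __init__(self, k: int = 10, alpha: float = 0.05,
                 equal_var: bool = True):
        self.k = k
        self.alpha = alpha
        self.equal_var = equal_var

    def fit(self, matrices: list[FeatureMatrix], y: np.ndarray):
        ns = {m.shape[0] for m in matrices}
        if len(ns) != 1:
            raise ValueError(f"matrices disagree on sample count: {sorted(ns)}")
        self.selected_: list[list[RankedFeature]] = []
        blocks = []
        for m in matrices:
            ranked = rank_by_pvalue(m, y, equal_var=self.equal_var)
            chosen = select_top(ranked, k=self.k, alpha=self.alpha)
            self.selected_.append(chosen)
            if chosen:
                blocks.append(m.values[:, [c.column for c in chosen]])
        if not blocks:
            raise ValueError("no matrix produced a significant feature")
        raw = np.hstack(blocks)
        self.center_ = raw.mean(axis=0)
        scale = raw.std(axis=0, ddof=0)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        self.source_names_ = [
            m.name for m, chosen in zip(matrices, self.selected_)
            for _ in chosen
        ]
        return self

    def transform(self, matrices: list[FeatureMatrix]) -> np.ndarray:
        blocks = [
            m.values[:, [c.column for c in chosen]]
            for m, chosen in zip(matrices, self.selected_) if chosen
        ]
        raw = np.hstack(blocks)
        return (raw - self.center_) / self.scale_

    def fit_transform_matrix(self, matrices: list[FeatureMatrix],
                             y: np.ndarray) -> HybridMatrix:
        self.fit(matrices, y)
        values = self.transform(matrices)
        columns = [c for chosen in self.selected_ for c in chosen]
        counts = {m.name: len(chosen)
                  for m, chosen in zip(matrices, self.selected_)}
        return HybridMatrix(values=values, columns=columns,
                            source_names=list(self.source_names_),
                            center=self.center_, scale=self.scale_,
                            per_source_counts=counts)


def build_hybrid(matrices: list[FeatureMatrix], y: np.ndarray | None = None,
                 k: int = 10, alpha: float = 0.05) -> HybridMatrix:
    """Top-k per matrix, concatenated and z-scored (60 columns at defaults)."""
    if y is None:
        y = matrices[0].binary_labels
    return HybridBuilder(k=k, alpha=alpha).fit_transform_matrix(matrices, y)


@dataclass
class BalanceResult:
    """Outcome of SMOTE balancing; original rows come first, verbatim."""

    X: np.ndarray
    y: np.ndarray
    n_synthetic: int
    k_neighbors: int
    seed: int | None
    #: per synthetic row: (parent row index, neighbor row index, u in (0,1))
    provenance: list[tuple[int, int, float]] = field(default_factory=list)


class Smote(BaseEstimator):
    """Synthetic minority oversampling by convex interpolation.

    Each synthetic row is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0, 1)``,
    ``x_i`` a minority row and ``x_nn`` one of its ``k_neighbors`` nearest
    minority neighbors.  All classes are oversampled up to the majority
    count; original rows are preserved verbatim.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int | None = None,
                 strict: bool = False):
        self.k_neighbors = k_neighbors
        self.random_state = random_state
        self.strict = strict

    def fit_resample(self, X, y) -> BalanceResult:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        target = counts.max()
        rng = np.random.default_rng(self.random_state)
        new_rows, new_labels, provenance = [], [], []
        for cls, count in zip(classes, counts):
            deficit = target - count
            if deficit == 0:
                continue
            idx = np.flatnonzero(y == cls)
            if count == 1:
                if self.strict:
                    raise ValueError(
                        f"class {cls!r} has a single row; cannot interpolate")
                warnings.warn(
                    f"class {cls!r} has a single row; oversampling by "
                    "duplication", stacklevel=2)
                for _ in range(deficit):
                    new_rows.append(X[idx[0]].copy())
                    new_labels.append(cls)
                    provenance.append((int(idx[0]), int(idx[0]), 0.0))
                continue
            k = self.k_neighbors
            if count <= k:
                if self.strict:
                    raise ValueError(
                        f"class {cls!r} has {count} rows <= k_neighbors={k}")
                k = count - 1
                warnings.warn(
                    f"class {cls!r}: k_neighbors reduced to {k} "
                    f"(only {count} minority rows)", stacklevel=2)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(X[idx])
            neighbors = nn.kneighbors(X[idx], return_distance=False)[:, 1:]
            for _ in range(deficit):
                i = int(rng.integers(len(idx)))
                j = int(neighbors[i, rng.integers(k)])
                u = float(rng.random())
                new_rows.append(X[idx[i]] + u * (X[idx[j]] - X[idx[i]]))
                new_labels.append(cls)
                provenance.append((int(idx[i]), int(idx[j]), u))
        if new_rows:
            X_out = np.vstack([X, np.vstack(new_rows)])
            y_out = np.concatenate([y, np.asarray(new_labels)])
        else:
            X_out, y_out = X.copy(), y.copy()
        return BalanceResult(X=X_out, y=y_out, n_synthetic=len(new_rows),
                             k_neighbors=self.k_neighbors,
                             seed=self.random_state, provenance=provenance)


def smote_balance(X, y, k_neighbors: int = 5,
                  seed: int | None = None) -> BalanceResult:
    """Functional wrapper over :class:`Smote`."""
    return Smote(k_neighbors=k_neighbors, random_state=seed).fit_resample(X, y)
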
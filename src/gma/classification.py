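"""Classifier zoo, hold-out/cross-validation protocol, metrics, and the
feature-dimension sweep.

The evaluation protocol is repeated stratified 80/20 hold-out: in each round
feature selection and standardization are fitted on the training split only
(unless the whole-dataset "pre_split" SMOTE mode is requested), class
imbalance is removed with SMOTE, a 5-fold cross-validation accuracy on the
training split is recorded for model assessment, and precision, recall,
accuracy and F1 are computed on the untouched test split.  Metrics are
averaged over rounds (and optional repeats) with their SD.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (AdaBoostClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB, MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix
from .selection import HybridBuilder, Smote, rank_by_pvalue

__all__ = [
    "MODEL_ZOO",
    "ConfusionMatrix",
    "Metrics",
    "EvaluationReport",
    "make_model",
    "train_model",
    "metrics_from_confusion",
    "evaluate",
    "evaluate_pipeline",
    "evaluate_multiclass",
    "dimension_sweep",
]

#: The nine-model zoo (MNB is wrapped with a [0, 1] rescaler because it
#: requires non-negative inputs).
MODEL_ZOO: tuple[str, ...] = (
    "LR", "SVM", "MNB", "KNN", "DT", "RF", "GNB", "AdaBoost", "GBDT",
)


def make_model(name: str, seed: int | None = 0):
    """Instantiate a zoo model with a fixed seed where the fit is stochastic."""
    if name == "LR":
        return LogisticRegression(max_iter=5000, random_state=seed)
    if name == "SVM":
        return SVC(random_state=seed)
    if name == "MNB":
        return Pipeline([("rescale", MinMaxScaler()), ("mnb", MultinomialNB())])
    if name == "KNN":
        return KNeighborsClassifier()
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "GNB":
        return GaussianNB()
    if name == "AdaBoost":
        return AdaBoostClassifier(random_state=seed)
    if name == "GBDT":
        return GradientBoostingClassifier(random_state=seed)
    raise ValueError(f"unknown model {name!r}; the zoo is {list(MODEL_ZOO)}")


def train_model(name: str, X, y, seed: int | None = 0):
    """Fit one zoo model; deterministic under a fixed seed."""
    model = make_model(name, seed=seed)
    model.fit(np.asarray(X, dtype=float), np.asarray(y))
    return model


# ---------------------------------------------------------------------------
# confusion matrix and metrics


@dataclass
class ConfusionMatrix:
    """C x C counts (rows = true class, columns = predicted class)."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be square in the class order")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred,
                         classes: list[str] | None = None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if classes is None:
            classes = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, classes=list(classes))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def binary_cells(self, positive: str) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) treating ``positive`` as the positive class."""
        i = self.classes.index(positive)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, tn, fn

    def row_normalized(self) -> np.ndarray:
        """Per-true-class recall view of the counts."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(totals > 0, self.counts / totals, 0.0)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass(frozen=True)
class Metrics:
    """Precision, recall, accuracy and F1, each in [0, 1]."""

    precision: float
    recall: float
    accuracy: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"precision": self.precision, "recall": self.recall,
                "accuracy": self.accuracy, "f1": self.f1}


def _binary_metrics(tp: int, fp: int, tn: int, fn: int) -> Metrics:
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return Metrics(precision=precision, recall=recall, accuracy=accuracy, f1=f1)


def metrics_from_confusion(cm: ConfusionMatrix,
                           positive: str | None = None) -> Metrics:
    """Precision/recall/accuracy/F1 from a confusion matrix.

    Binary matrices use the standard TP/FP/TN/FN formulas with ``positive``
    as the positive class (default: 'Risky' if present, else the second
    class).  Multiclass matrices use macro-averaged one-vs-rest precision,
    recall and F1, with accuracy = trace / total.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if len(cm.classes) == 2:
        if positive is None:
            positive = "Risky" if "Risky" in cm.classes else cm.classes[1]
        return _binary_metrics(*cm.binary_cells(positive))
    per_class = [_binary_metrics(*cm.binary_cells(c)) for c in cm.classes]
    accuracy = float(np.trace(cm.counts)) / cm.total
    return Metrics(
        precision=float(np.mean([m.precision for m in per_class])),
        recall=float(np.mean([m.recall for m in per_class])),
        accuracy=accuracy,
        f1=float(np.mean([m.f1 for m in per_class])),
    )


# ---------------------------------------------------------------------------
# evaluation protocol


@dataclass
class EvaluationReport:
    """Per-round metrics plus protocol record; fully reproducible."""

    model_name: str
    round_metrics: list[Metrics]
    cv_accuracies: list[float]
    confusion: ConfusionMatrix
    protocol: dict = field(default_factory=dict)

    @property
    def mean(self) -> dict[str, float]:
        keys = ("precision", "recall", "accuracy", "f1")
        return {k: float(np.mean([getattr(m, k) for m in self.round_metrics]))
                for k in keys}

    @property
    def sd(self) -> dict[str, float]:
        keys = ("precision", "recall", "accuracy", "f1")
        return {k: float(np.std([getattr(m, k) for m in self.round_metrics],
                                ddof=1)) if len(self.round_metrics) > 1 else 0.0
                for k in keys}

    @property
    def mean_accuracy(self) -> float:
        return self.mean["accuracy"]

    def per_class_recall(self) -> dict[str, float]:
        norm = self.confusion.row_normalized()
        return {c: float(norm[i, i]) for i, c in enumerate(self.confusion.classes)}

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "mean": self.mean,
            "sd": self.sd,
            "cv_accuracy_mean": float(np.mean(self.cv_accuracies))
            if self.cv_accuracies else None,
            "rounds": [m.as_dict() for m in self.round_metrics],
            "confusion": {"classes": self.confusion.classes,
                          "counts": self.confusion.counts.tolist()},
            "per_class_recall": self.per_class_recall(),
            "protocol": self.protocol,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _stratified_split(y: np.ndarray, subject_ids: np.ndarray | None,
                      split: float, granularity: str,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test row indices at frame or subject granularity.

    Every class keeps at least one row on each side of the split.
    """
    y = np.asarray(y)
    n = len(y)
    if granularity == "frame":
        train, test = [], []
        for cls in np.unique(y):
            idx = rng.permutation(np.flatnonzero(y == cls))
            n_test = min(max(1, int(round((1 - split) * len(idx)))), len(idx) - 1)
            test.extend(idx[:n_test])
            train.extend(idx[n_test:])
        return np.sort(np.asarray(train)), np.sort(np.asarray(test))
    if granularity == "subject":
        if subject_ids is None:
            raise ValueError("subject granularity needs subject_ids")
        subject_ids = np.asarray(subject_ids)
        subjects = pd.unique(subject_ids)
        sub_label = {s: y[subject_ids == s][0] for s in subjects}
        test_subjects = set()
        for cls in np.unique(y):
            subs = [s for s in subjects if sub_label[s] == cls]
            if len(subs) < 2:
                raise ValueError(
                    f"class {cls!r} has {len(subs)} subject(s); subject-level "
                    "splitting needs at least 2 per class")
            order = rng.permutation(len(subs))
            n_test = min(max(1, int(round((1 - split) * len(subs)))),
                         len(subs) - 1)
            test_subjects.update(subs[i] for i in order[:n_test])
        mask = np.isin(subject_ids, list(test_subjects))
        return np.flatnonzero(~mask), np.flatnonzero(mask)
    raise ValueError(f"unknown granularity {granularity!r}")


def _inner_cv_accuracy(model, X, y, folds: int, seed: int) -> float:
    _, counts = np.unique(y, return_counts=True)
    k = min(folds, counts.min())
    if k < 2:
        return float("nan")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = cross_val_score(clone(model), X, y, cv=cv, scoring="accuracy")
    return float(scores.mean())


def _run_rounds(get_split_data, model_name: str, classes: list[str],
                rounds: int, repeats: int, folds: int, seed: int,
                protocol: dict) -> EvaluationReport:
    round_metrics, cv_accs = [], []
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    for rep in range(repeats):
        for rnd in range(rounds):
            round_seed = int(
                np.random.SeedSequence([seed, rep, rnd]).generate_state(1)[0]
                % (2 ** 31))
            rng = np.random.default_rng(round_seed)
            X_tr, y_tr, X_te, y_te = get_split_data(rng, round_seed)
            model = make_model(model_name, seed=round_seed)
            cv_accs.append(_inner_cv_accuracy(model, X_tr, y_tr, folds,
                                              round_seed))
            model.fit(X_tr, y_tr)
            y_pred = model.predict(X_te)
            cm = ConfusionMatrix.from_predictions(y_te, y_pred, classes=classes)
            pooled += cm.counts
            round_metrics.append(metrics_from_confusion(cm))
    report = EvaluationReport(
        model_name=model_name,
        round_metrics=round_metrics,
        cv_accuracies=cv_accs,
        confusion=ConfusionMatrix(counts=pooled, classes=classes),
        protocol=protocol,
    )
    return report


def evaluate(X, y, model_name: str, split: float = 0.8, rounds: int = 50,
             folds: int = 5, repeats: int = 1, seed: int = 0,
             smote_mode: str = "train_only", granularity: str = "frame",
             subject_ids=None, smote_k: int = 5) -> EvaluationReport:
    """Repeated stratified hold-out evaluation of one model on a fixed
    feature table.

    ``smote_mode``: ``"train_only"`` balances the training split of each
    round; ``"pre_split"`` balances the whole table once before splitting
    (whole-dataset protocol; frame granularity only); ``"off"`` disables
    balancing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    if smote_mode not in ("train_only", "pre_split", "off"):
        raise ValueError(f"unknown smote_mode {smote_mode!r}")
    if smote_mode == "pre_split":
        if granularity != "frame":
            raise ValueError("pre_split SMOTE has no subject identity for "
                             "synthetic rows; use frame granularity")
        bal = Smote(k_neighbors=smote_k, random_state=seed).fit_resample(X, y)
        X, y, subject_ids = bal.X, bal.y, None
    classes = sorted(np.unique(y).tolist())
    subs = np.asarray(subject_ids) if subject_ids is not None else None

    def get_split_data(rng, round_seed):
        tr, te = _stratified_split(y, subs, split, granularity, rng)
        X_tr, y_tr = X[tr], y[tr]
        if smote_mode == "train_only":
            bal = Smote(k_neighbors=smote_k,
                        random_state=round_seed).fit_resample(X_tr, y_tr)
            X_tr, y_tr = bal.X, bal.y
        return X_tr, y_tr, X[te], y[te]

    protocol = {"split": split, "rounds": rounds, "folds": folds,
                "repeats": repeats, "seed": seed, "smote_mode": smote_mode,
                "granularity": granularity, "smote_k": smote_k,
                "classes": classes}
    return _run_rounds(get_split_data, model_name, classes, rounds, repeats,
                       folds, seed, protocol)


def evaluate_pipeline(matrices: list[FeatureMatrix], model_name: str,
                      multiclass: bool = False, split: float = 0.8,
                      rounds: int = 50, folds: int = 5, repeats: int = 1,
                      seed: int = 0, smote_mode: str = "train_only",
                      granularity: str = "frame", k: int | list[int] = 10,
                      alpha: float = 0.05, smote_k: int = 5) -> EvaluationReport:
    """Leakage-aware evaluation from the six raw feature matrices.

    In ``train_only`` mode feature ranking/selection and standardization are
    re-fitted inside every round on the training rows only, then applied to
    the held-out rows; in ``pre_split`` mode the hybrid matrix and SMOTE use
    all rows before splitting (whole-dataset protocol).
    """
    ref = matrices[0]
    y = (ref.multiclass_labels if multiclass else ref.binary_labels).astype(str)
    # the t-test ranking is defined between the two clinical groups; the
    # classifier may still be trained on the three-label view
    y_select = ref.binary_labels.astype(str)
    subs = np.asarray(ref.subject_ids)
    ks = list(k) if isinstance(k, (list, tuple, np.ndarray)) else [k] * len(matrices)

    if smote_mode in ("pre_split", "off"):
        builder = _fit_builder(matrices, y_select, ks, alpha)
        X = builder.transform(matrices)
        return evaluate(X, y, model_name, split=split, rounds=rounds,
                        folds=folds, repeats=repeats, seed=seed,
                        smote_mode=smote_mode, granularity=granularity,
                        subject_ids=subs, smote_k=smote_k)

    classes = sorted(np.unique(y).tolist())

    def get_split_data(rng, round_seed):
        tr, te = _stratified_split(y, subs, split, granularity, rng)
        train_mats = [m.subset_rows(tr) for m in matrices]
        builder = _fit_builder(train_mats, y_select[tr], ks, alpha)
        X_tr = builder.transform(train_mats)
        X_te = builder.transform([m.subset_rows(te) for m in matrices])
        bal = Smote(k_neighbors=smote_k,
                    random_state=round_seed).fit_resample(X_tr, y[tr])
        return bal.X, bal.y, X_te, y[te]

    protocol = {"split": split, "rounds": rounds, "folds": folds,
                "repeats": repeats, "seed": seed, "smote_mode": smote_mode,
                "granularity": granularity, "k": ks, "alpha": alpha,
                "smote_k": smote_k, "classes": classes,
                "multiclass": multiclass}
    return _run_rounds(get_split_data, model_name, classes, rounds, repeats,
                       folds, seed, protocol)


def _fit_builder(matrices: list[FeatureMatrix], y: np.ndarray,
                 ks: list[int], alpha: float) -> HybridBuilder:
    """Fit a HybridBuilder with a (possibly different) k per matrix."""
    builder = HybridBuilder(k=max(ks), alpha=alpha)
    # fit per matrix with its own k by fitting at max(k) then truncating
    builder.fit(matrices, y)
    builder.selected_ = [chosen[:ki] for chosen, ki
                         in zip(builder.selected_, ks)]
    raw = np.hstack([
        m.values[:, [c.column for c in chosen]]
        for m, chosen in zip(matrices, builder.selected_) if chosen
    ])
    builder.center_ = raw.mean(axis=0)
    scale = raw.std(axis=0, ddof=0)
    builder.scale_ = np.where(scale > 0, scale, 1.0)
    builder.source_names_ = [m.name for m, chosen
                             in zip(matrices, builder.selected_)
                             for _ in chosen]
    return builder


def evaluate_multiclass(matrices: list[FeatureMatrix], model_name: str,
                        **kwargs) -> EvaluationReport:
    """Three-class (Normal / LowRisk / HighRisk) evaluation.

    Returns the report with a pooled confusion matrix; metrics are
    macro-averaged one-vs-rest, and ``per_class_recall`` exposes the
    row-normalized diagonal.
    """
    return evaluate_pipeline(matrices, model_name, multiclass=True, **kwargs)


def allocate_features(matrices: list[FeatureMatrix], y: np.ndarray,
                      dim: int, alpha: float = 0.05) -> list[int]:
    """Per-matrix selection counts summing to ``dim``.

    An equal base of ``dim // 6`` goes to every matrix; any remainder is
    assigned round-robin by global p-rank, i.e. to the matrices whose next
    candidate feature has the smallest p-value.
    """
    n_mat = len(matrices)
    base, extra = divmod(dim, n_mat)
    counts = [base] * n_mat
    if extra:
        next_p = []
        for m in matrices:
            ranked = rank_by_pvalue(m, y)
            next_p.append(ranked[base].p_value if base < len(ranked)
                          else np.inf)
        for i in np.argsort(next_p, kind="stable")[:extra]:
            counts[int(i)] += 1
    return counts


def dimension_sweep(matrices: list[FeatureMatrix], model_names=("LR",),
                    dims=(60, 50, 40, 30, 20, 10), **kwargs) -> pd.DataFrame:
    """Mean hold-out accuracy per model as the hybrid dimension shrinks.

    Each dimension allocates ``dim // 6`` features per matrix (remainder by
    global p-rank) and re-runs the full protocol.
    """
    ref = matrices[0]
    y = ref.binary_labels
    records = []
    for dim in dims:
        ks = allocate_features(matrices, y, dim, alpha=kwargs.get("alpha", 0.05))
        for name in model_names:
            report = evaluate_pipeline(matrices, name, k=ks, **kwargs)
            records.append({"dim": dim, "model": name,
                            "accuracy": report.mean_accuracy,
                            "accuracy_sd": report.sd["accuracy"]})
    return pd.DataFrame.from_records(records)
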
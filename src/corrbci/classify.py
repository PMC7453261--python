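"""10-fold cross-validated classification of feature sets.

Classifiers are k-nearest-neighbours (Euclidean, majority vote), a Gini
decision tree, and linear discriminant analysis for the binary
rest-vs-movement comparison protocol. Folds are stratified by class where
counts permit and the headline metric is plain multiclass accuracy in
percent, averaged over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ClassifierSpec", "CVResult", "GridResult", "kfold_split", "fit_predict",
    "cross_validate", "evaluate_grid", "binary_protocol", "DEFAULT_SPECS",
    "pivot_hybrid",
]

ALGORITHMS = ("knn", "decision_tree", "lda")


@dataclass(frozen=True)
class ClassifierSpec:
    algorithm: str
    params: tuple = ()          # sorted (key, value) pairs, hashable
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; valid: {ALGORITHMS}")
        p = dict(self.params)
        if self.algorithm == "knn" and p.get("n_neighbors", 5) < 1:
            raise ValueError("knn needs n_neighbors >= 1")

    @classmethod
    def make(cls, algorithm: str, seed: int = 0, **params) -> "ClassifierSpec":
        return cls(algorithm=algorithm, params=tuple(sorted(params.items())),
                   seed=seed)

    @property
    def label(self) -> str:
        if not self.params:
            return self.algorithm
        inner = ",".join(f"{k}={v}" for k, v in self.params)
        return f"{self.algorithm}({inner})"

    def build(self):
        p = dict(self.params)
        if self.algorithm == "knn":
            return KNeighborsClassifier(
                n_neighbors=p.get("n_neighbors", 5),
                metric=p.get("metric", "euclidean"))
        if self.algorithm == "decision_tree":
            return DecisionTreeClassifier(
                criterion=p.get("criterion", "gini"),
                max_depth=p.get("max_depth"), random_state=self.seed)
        shrinkage = p.get("shrinkage")
        if shrinkage is not None:
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
        return LinearDiscriminantAnalysis()


DEFAULT_SPECS = (ClassifierSpec.make("knn", n_neighbors=5),
                 ClassifierSpec.make("decision_tree"))


@dataclass
class CVResult:
    fold_accuracies: list[float]        # percent, one per fold
    mean_accuracy: float                # percent
    confusion: pd.DataFrame             # rows true class, cols predicted
    feature_set_id: str
    spec: ClassifierSpec
    folds: int
    seed: int

    def __post_init__(self) -> None:
        assert all(0.0 <= a <= 100.0 for a in self.fold_accuracies)


def kfold_split(n_trials: int, k: int = 10, seed: int = 0,
                labels: np.ndarray | None = None,
                stratified: bool = True) -> np.ndarray:
    """Fold assignment (length ``n_trials``, values 0..k-1), shuffled by seed.

    Folds are stratified by class when every class has at least ``k``
    members; otherwise plain shuffled folds are used.
    """
    if n_trials < k:
        raise ValueError(f"cannot make {k} folds from {n_trials} trials")
    assign = np.empty(n_trials, dtype=int)
    if stratified and labels is not None:
        labels = np.asarray(labels)
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() >= k:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            for f, (_, test) in enumerate(splitter.split(np.zeros(n_trials), labels)):
                assign[test] = f
            return assign
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (_, test) in enumerate(splitter.split(np.zeros(n_trials))):
        assign[test] = f
    return assign


def _split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cols = [c for c in table.columns if c != "label"]
    if not cols:
        raise ValueError("feature table has no feature columns")
    return table[cols].to_numpy(dtype=float), table["label"].to_numpy()


def fit_predict(spec: ClassifierSpec, x_train: np.ndarray, y_train: np.ndarray,
                x_test: np.ndarray) -> np.ndarray:
    if len(x_train) == 0:
        raise ValueError("empty training set")
    est = spec.build()
    if spec.algorithm == "knn":
        est.set_params(n_neighbors=min(dict(spec.params).get("n_neighbors", 5),
                                       len(x_train)))
    try:
        est.fit(x_train, y_train)
    except np.linalg.LinAlgError as exc:  # degenerate LDA covariance
        raise np.linalg.LinAlgError(
            f"{exc}; consider ClassifierSpec.make('lda', shrinkage='auto')")
    return est.predict(x_test)


def cross_validate(table: pd.DataFrame, spec: ClassifierSpec, k: int = 10,
                   seed: int = 0, feature_set_id: str = "",
                   stratified: bool = True,
                   normalize_within_folds: bool = False) -> CVResult:
    """k-fold CV accuracy of one classifier on one feature table.

    With ``normalize_within_folds`` the min-max rescaling is re-fit on each
    training fold and applied to its test fold (leakage-safe variant).
    """
    x, y = _split_xy(table)
    assign = kfold_split(len(y), k=k, seed=seed, labels=y, stratified=stratified)
    classes = np.unique(y)
    fold_acc: list[float] = []
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for f in range(k):
        test = assign == f
        xtr, xte = x[~test], x[test]
        if normalize_within_folds:
            lo, hi = xtr.min(axis=0), xtr.max(axis=0)
            span = np.where(hi > lo, hi - lo, 1.0)
            xtr = (xtr - lo) / span
            xte = np.clip((xte - lo) / span, 0.0, 1.0)
        missing = set(classes) - set(y[~test])
        if missing:
            raise ValueError(f"fold {f}: class(es) {sorted(missing)} absent from training")
        pred = fit_predict(spec, xtr, y[~test], xte)
        fold_acc.append(100.0 * float(np.mean(pred == y[test])))
        conf += confusion_matrix(y[test], pred, labels=classes)
    confusion = pd.DataFrame(conf, index=classes, columns=classes)
    return CVResult(fold_accuracies=fold_acc,
                    mean_accuracy=float(np.mean(fold_acc)),
                    confusion=confusion, feature_set_id=feature_set_id,
                    spec=spec, folds=k, seed=seed)


@dataclass
class GridResult:
    """Mean CV accuracies: rows = feature-set ids, columns = classifiers."""

    grid: pd.DataFrame
    results: dict[tuple[str, str], CVResult] = field(repr=False, default_factory=dict)

    @property
    def best(self) -> tuple[str, str, float]:
        col = self.grid.max().idxmax()
        row = self.grid[col].idxmax()
        return row, col, float(self.grid.loc[row, col])


def evaluate_grid(feature_sets: list[tuple[str, pd.DataFrame]],
                  specs: tuple[ClassifierSpec, ...] = DEFAULT_SPECS,
                  k: int = 10, seed: int = 0, **cv_kwargs) -> GridResult:
    if not feature_sets or not specs:
        raise ValueError("need at least one feature set and one classifier")
    results: dict[tuple[str, str], CVResult] = {}
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("classifier specs must have distinct labels")
    grid = pd.DataFrame(index=[sid for sid, _ in feature_sets],
                        columns=labels, dtype=float)
    for sid, table in feature_sets:
        for spec in specs:
            res = cross_validate(table, spec, k=k, seed=seed,
                                 feature_set_id=sid, **cv_kwargs)
            results[(sid, spec.label)] = res
            grid.loc[sid, spec.label] = res.mean_accuracy
    return GridResult(grid=grid, results=results)


def pivot_hybrid(grid: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Reshape a 36-row hybrid grid into per-classifier 6x6 tables
    (rows = fNIRS pair, columns = EEG pair)."""
    out: dict[str, pd.DataFrame] = {}
    parts = [sid.split("|") for sid in grid.index]
    if any(len(p) != 2 for p in parts):
        raise ValueError("grid index is not hybrid ('eeg|fnirs') ids")
    eeg_ids = list(dict.fromkeys(p[0] for p in parts))
    fnirs_ids = list(dict.fromkeys(p[1] for p in parts))
    for algo in grid.columns:
        tab = pd.DataFrame(index=fnirs_ids, columns=eeg_ids, dtype=float)
        for (e, f), val in zip(parts, grid[algo]):
            tab.loc[f, e] = val
        out[algo] = tab
    return out


def binary_protocol(table: pd.DataFrame, class_a: str, class_b: str,
                    k: int = 10, seed: int = 0,
                    feature_set_id: str = "") -> CVResult:
    """LDA cross-validation restricted to two classes (e.g. rest vs right_hand)."""
    if class_a == class_b:
        raise ValueError("the two classes must differ")
    present = set(table["label"])
    missing = {class_a, class_b} - present
    if missing:
        raise ValueError(f"class(es) {sorted(missing)} not in feature table")
    sub = table[table["label"].isin([class_a, class_b])].reset_index(drop=True)
    return cross_validate(sub, ClassifierSpec.make("lda"), k=k, seed=seed,
                          feature_set_id=feature_set_id or f"{class_a}-vs-{class_b}")
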
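"""Random-forest classification of whistles into ecotypes.

The forest itself is scikit-learn's; everything reported around it is
implemented here so the numbers are fully specified: the Pearson
correlation screen, the stratified 67/33 split, mtry tuning by
cross-validated ROC AUC, the confusion matrix (rows = prediction, columns =
reference, classes alphabetical), exact Clopper-Pearson confidence
intervals, Cohen's kappa, out-of-bag permutation importance (MDA), impurity
importance (MDG) and one-dimensional partial dependence on the
class-probability scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .contours import FEATURE_NAMES


@dataclass
class ConfusionMatrix2x2:
    """2x2 counts with rows = predicted class, columns = reference class."""

    counts: np.ndarray
    classes: tuple[str, str] = ("coastal", "offshore")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 2x2 with non-negative counts")
        if self.counts.sum() == 0:
            raise ValueError("empty confusion matrix")

    @classmethod
    def from_flat(cls, flat, classes=("coastal", "offshore")) -> "ConfusionMatrix2x2":
        """Row-major counts (pred0/ref0, pred0/ref1, pred1/ref0, pred1/ref1)."""
        return cls(np.asarray(flat).reshape(2, 2), classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def correct(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.classes, name="Prediction"),
            columns=pd.Index(self.classes, name="Reference"),
        )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes out of n."""
    if n == 0:
        raise ValueError("n must be > 0")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def cohen_kappa(cm: ConfusionMatrix2x2) -> float:
    """Chance-corrected agreement from the confusion-matrix marginals."""
    n = cm.total
    p_o = cm.correct / n
    rows = cm.counts.sum(axis=1) / n
    cols = cm.counts.sum(axis=0) / n
    p_e = float(rows @ cols)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def accuracy_ci_kappa(cm: ConfusionMatrix2x2, level: float = 0.95) -> dict:
    """Accuracy with exact Clopper-Pearson CI, plus Cohen's kappa."""
    acc = cm.correct / cm.total
    lo, hi = clopper_pearson(cm.correct, cm.total, level)
    return {"accuracy": acc, "ci": (lo, hi), "kappa": cohen_kappa(cm)}


# ---------------------------------------------------------------------------
# Screening and splitting
# ---------------------------------------------------------------------------


def correlation_screen(features: pd.DataFrame, threshold: float = 0.8) -> dict:
    """Pairwise Pearson correlations among predictor columns.

    Returns the correlation matrix and the list of flagged pairs with
    |r| > threshold.  Features are flagged, never silently dropped — the
    analyst decides.  A zero-variance feature is an error (its correlation
    is undefined).
    """
    cols = list(features.columns)
    if len(cols) < 2:
        raise ValueError("need >= 2 features")
    for c in cols:
        if float(features[c].std(ddof=0)) == 0.0:
            raise ValueError(f"zero-variance feature: {c!r}")
    corr = features.corr(method="pearson")
    flagged = [
        (cols[i], cols[j], float(corr.iloc[i, j]))
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
        if abs(corr.iloc[i, j]) > threshold
    ]
    return {"correlation": corr, "flagged": flagged}


def stratified_split(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    train_frac: float = 0.67,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Per-class split with ceil(train_frac * n_class) whistles in training.

    Returns (X_train, y_train, X_test, y_test) with positional indexing
    preserved from the input frame.
    """
    labels = pd.Series(np.asarray(labels), index=features.index)
    rng = np.random.default_rng(seed)
    train_idx: list = []
    test_idx: list = []
    for cls, sub in labels.groupby(labels):
        idx = np.array(sub.index)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_train = math.ceil(train_frac * len(idx))
        if n_train >= len(idx):
            raise ValueError(f"class {cls!r}: split leaves an empty test set")
        perm = rng.permutation(len(idx))
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return (
        features.loc[train_idx],
        labels.loc[train_idx],
        features.loc[test_idx],
        labels.loc[test_idx],
    )


# ---------------------------------------------------------------------------
# Fitting and native evaluation
# ---------------------------------------------------------------------------


@dataclass
class RfReport:
    accuracy: float
    ci95: tuple[float, float]
    kappa: float
    oob_error: float
    importance: pd.DataFrame  # columns MDA, MDG
    pdp: dict = field(default_factory=dict)  # feature -> (grid, prob of classes[0])
    tuned_mtry: int = 2
    n_trees: int = 300
    cv_auc: dict = field(default_factory=dict)


def _oob_permutation_importance(
    forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray, seed: int
) -> np.ndarray:
    """Mean decrease in accuracy over each tree's out-of-bag sample."""
    rng = np.random.default_rng(seed)
    n = len(X)
    n_boot = _get_n_samples_bootstrap(n, forest.max_samples, None)
    # trees predict encoded class indices, not the original labels
    class_index = {c: i for i, c in enumerate(forest.classes_)}
    y_enc = np.array([class_index[v] for v in y], dtype=float)
    decreases = np.zeros((len(forest.estimators_), X.shape[1]))
    for t, tree in enumerate(forest.estimators_):
        oob = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if len(oob) == 0:
            continue
        Xo, yo = X[oob], y_enc[oob]
        base = np.mean(tree.predict(Xo) == yo)
        for f in range(X.shape[1]):
            Xp = Xo.copy()
            Xp[:, f] = Xp[rng.permutation(len(oob)), f]
            decreases[t, f] = base - np.mean(tree.predict(Xp) == yo)
    return decreases.mean(axis=0)


def tune_mtry(
    X: np.ndarray,
    y: np.ndarray,
    mtry_grid,
    n_trees: int = 300,
    cv: tuple[int, int] = (10, 3),
    seed: int = 0,
) -> tuple[int, dict]:
    """Choose mtry by mean ROC AUC over repeated stratified k-fold CV.

    ``cv`` is (folds, repeats).  Ties go to the smaller mtry.
    """
    n_features = X.shape[1]
    for m in mtry_grid:
        if not 1 <= m <= n_features:
            raise ValueError(f"mtry {m} outside [1, {n_features}]")
    if len(set(mtry_grid)) == 1:
        m = int(next(iter(mtry_grid)))
        return m, {m: float("nan")}
    classes = np.unique(y)
    y_bin = (y == classes[1]).astype(int)
    splitter = RepeatedStratifiedKFold(n_splits=cv[0], n_repeats=cv[1], random_state=seed % 2**31)
    aucs: dict[int, float] = {}
    for m in sorted(mtry_grid):
        scores = []
        for fold, (tr, te) in enumerate(splitter.split(X, y_bin)):
            clf = RandomForestClassifier(
                n_estimators=n_trees, max_features=m, random_state=(seed + fold) % 2**31
            )
            clf.fit(X[tr], y_bin[tr])
            scores.append(roc_auc_score(y_bin[te], clf.predict_proba(X[te])[:, 1]))
        aucs[m] = float(np.mean(scores))
    best = max(sorted(aucs), key=lambda m: (aucs[m], -m))
    return best, aucs


def fit_and_evaluate(
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame,
    y_test,
    n_trees: int = 300,
    mtry_grid=None,
    cv: tuple[int, int] = (10, 3),
    seed: int = 0,
    pdp_points: int = 50,
) -> tuple[RfReport, ConfusionMatrix2x2]:
    """Fit the tuned forest and evaluate it natively on the test set."""
    feature_names = list(X_train.columns)
    Xtr, Xte = X_train.to_numpy(float), X_test.to_numpy(float)
    ytr, yte = np.asarray(y_train), np.asarray(y_test)
    classes = tuple(sorted(np.unique(ytr)))
    if mtry_grid is None:
        mtry_grid = list(range(1, len(feature_names) + 1))
    best_mtry, aucs = tune_mtry(Xtr, ytr, mtry_grid, n_trees=n_trees, cv=cv, seed=seed)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=best_mtry,
        oob_score=True,
        random_state=seed % 2**31,
    )
    forest.fit(Xtr, ytr)
    pred = forest.predict(Xte)
    cm = np.zeros((2, 2), dtype=int)
    for p, r in zip(pred, yte):
        cm[classes.index(p), classes.index(r)] += 1
    cm = ConfusionMatrix2x2(cm, classes)
    metrics = accuracy_ci_kappa(cm)
    mda = _oob_permutation_importance(forest, Xtr, ytr, seed=seed + 1)
    mdg = forest.feature_importances_
    importance = pd.DataFrame({"MDA": mda, "MDG": mdg}, index=feature_names)
    pdp = {}
    for f, name in enumerate(feature_names):
        grid = np.linspace(Xte[:, f].min(), Xte[:, f].max(), pdp_points)
        probs = np.empty(pdp_points)
        Xmod = Xte.copy()
        class0_col = list(forest.classes_).index(classes[0])
        for g, val in enumerate(grid):
            Xmod[:, f] = val
            probs[g] = forest.predict_proba(Xmod)[:, class0_col].mean()
        pdp[name] = (grid, probs)
    report = RfReport(
        accuracy=metrics["accuracy"],
        ci95=metrics["ci"],
        kappa=metrics["kappa"],
        oob_error=1.0 - float(forest.oob_score_),
        importance=importance,
        pdp=pdp,
        tuned_mtry=best_mtry,
        n_trees=n_trees,
        cv_auc=aucs,
    )
    return report, cm


__all__ = [
    "ConfusionMatrix2x2",
    "RfReport",
    "FEATURE_NAMES",
    "accuracy_ci_kappa",
    "clopper_pearson",
    "cohen_kappa",
    "correlation_screen",
    "stratified_split",
    "tune_mtry",
    "fit_and_evaluate",
]
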
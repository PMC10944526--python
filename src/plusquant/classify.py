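"""Feature selection, dimensionality reduction and Plus/non-Plus classification.

Pipeline, fitted per training fold to avoid leakage: standardize the feature
columns, weight them with the feature-weighting variant of Neighborhood
Component Analysis (NCA) and keep the top-k, project onto the first three
principal components, and train a soft-margin SVM with a radial-basis-function
kernel (regularization C = 1).  Performance is summarized over repeated
stratified tenfold cross-validation as mean +/- SD of accuracy, sensitivity,
specificity, PPV and NPV, treating "Plus" as the positive class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core_io import PLUS, logger

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Standardizer:
    """Column-wise z-score transform (sample SD), reusable on held-out rows."""

    means: pd.Series
    scales: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return (table[self.means.index] - self.means) / self.scales


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Fit a zero-mean unit-variance transform on the given rows."""
    if len(table) < 2:
        raise ValueError("standardization needs >= 2 rows")
    means = table.mean()
    scales = table.std(ddof=1)
    zero = scales.index[scales == 0].tolist()
    if zero:
        raise ValueError(f"zero-variance feature(s): {zero}")
    fitted = Standardizer(means=means, scales=scales)
    return fitted.transform(table), fitted


# ---------------------------------------------------------------------------
# NCA feature selection (feature-weighting variant)
# ---------------------------------------------------------------------------


def _nca_objective_grad(
    w: np.ndarray, diffs: np.ndarray, same: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """Leave-one-out stochastic-neighbor objective and gradient w.r.t. w.

    Weighted distance d_ij = sum_l w_l^2 |x_il - x_jl|; reference point j is
    picked with probability softmax(-d_ij); the objective is the expected
    count of correctly classified points minus an l2 penalty on w.
    """
    n = diffs.shape[0]
    d = diffs @ (w**2)
    np.fill_diagonal(d, np.inf)
    logits = -d - (-d).max(axis=1, keepdims=True)  # stabilized softmax
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    p_i = (p * same).sum(axis=1)
    objective = float(p_i.sum() - lam * (w**2).sum())
    expected = np.einsum("ij,ijl->il", p, diffs)  # E_j[ d^l_ij ]
    same_term = np.einsum("ij,ijl->il", p * same, diffs)
    grad = 2 * w * (p_i[:, None] * expected - same_term).sum(axis=0) - 2 * lam * w
    return objective, grad


def select_features_nca(
    features: pd.DataFrame,
    labels: np.ndarray,
    k: int = 5,
    regularization: float = 1.0,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[list, np.ndarray]:
    """Nonnegative per-feature NCA weights; the top-k features are selected.

    Maximizes the leave-one-out stochastic-neighbor classification objective
    with an l2 penalty by adaptive-step gradient ascent (tolerance ``tol`` on
    the objective or ``max_iter`` iterations).  Ties in the weight ranking
    are broken by feature order.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n, p = X.shape
    if n < 10:
        raise ValueError("NCA selection needs >= 10 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("NCA selection needs both classes present")
    k = min(k, p)
    diffs = np.abs(X[:, None, :] - X[None, :, :])
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)

    rng = np.random.default_rng(seed)
    w = np.ones(p) + rng.uniform(-1e-3, 1e-3, size=p)
    obj, grad = _nca_objective_grad(w, diffs, same, regularization)
    lr = 0.01
    for _ in range(max_iter):
        w_new = w + lr * grad
        obj_new, grad_new = _nca_objective_grad(w_new, diffs, same, regularization)
        if obj_new > obj:
            if obj_new - obj < tol:
                w, obj, grad = w_new, obj_new, grad_new
                break
            w, obj, grad = w_new, obj_new, grad_new
            lr *= 1.05
        else:
            lr *= 0.5
            if lr < 1e-12:
                break
    weights = np.abs(w)
    order = np.argsort(-weights, kind="stable")
    selected = [features.columns[i] for i in order[:k]]
    return selected, weights


# ---------------------------------------------------------------------------
# PCA and SVM
# ---------------------------------------------------------------------------


def pca_project(
    features: pd.DataFrame, n_components: int = 3
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, PCA]:
    """Principal-component projection with a deterministic sign convention.

    Components are ordered by decreasing explained variance; each loading is
    flipped so its largest-magnitude element is positive.
    """
    if n_components > features.shape[1]:
        raise ValueError(
            f"n_components={n_components} exceeds {features.shape[1]} features"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(np.asarray(features, dtype=float))
    loadings = pca.components_
    for i, row in enumerate(loadings):
        if row[np.argmax(np.abs(row))] < 0:
            loadings[i] = -row
            scores[:, i] = -scores[:, i]
    pca.components_ = loadings
    projected = pd.DataFrame(
        scores, index=features.index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return projected, loadings, pca.explained_variance_ratio_, pca


def train_svm_rbf(
    X: pd.DataFrame | np.ndarray, y: np.ndarray, C: float = 1.0, gamma: float | str = "scale"
) -> SVC:
    """Soft-margin SVM with a Gaussian kernel (deterministic given inputs)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("SVM training needs both classes present")
    clf = SVC(kernel="rbf", C=C, gamma=gamma)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


# ---------------------------------------------------------------------------
# Metrics and cross-validation
# ---------------------------------------------------------------------------


def classification_metrics(tp: int, fn: int, fp: int, tn: int) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity, PPV, NPV from confusion counts.

    Ratios with a zero denominator are reported as None (missing).
    """
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    total = tp + fn + fp + tn
    if total == 0:
        raise ValueError("confusion counts must not all be zero")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


@dataclass(frozen=True)
class ClassificationReport:
    """Repeated-CV performance summary with full per-repeat detail."""

    per_repeat: list[dict]
    mean: dict[str, float]
    sd: dict[str, float]
    folds: int
    repeats: int
    seed: int
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "per_repeat": self.per_repeat,
                    "mean": self.mean,
                    "sd": self.sd,
                    "folds": self.folds,
                    "repeats": self.repeats,
                    "seed": self.seed,
                    "config": self.config,
                },
                fh,
                indent=2,
            )


def cross_validate(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    nca_k: int = 5,
    nca_regularization: float = 1.0,
    C: float = 1.0,
    gamma: float | str = "scale",
    n_components: int = 3,
    legacy_leaky: bool = False,
    config_echo: dict | None = None,
) -> ClassificationReport:
    """Repeated stratified k-fold CV of the standardize->NCA->PCA->SVM pipeline.

    All transforms are fitted on the training rows of each fold only (unless
    ``legacy_leaky``, which fits them once on the full table before
    splitting).  Predictions are pooled per repeat into one confusion matrix;
    the report gives mean and sample SD of each metric over repeats.
    """
    y = np.asarray(pd.Series(labels) == PLUS) if not np.issubdtype(
        np.asarray(labels).dtype, np.bool_
    ) else np.asarray(labels)
    X = features.select_dtypes(include=[np.number])
    if len(X) < folds:
        raise ValueError(f"need >= {folds} rows for {folds}-fold CV")
    per_repeat: list[dict] = []
    for r in range(repeats):
        rep_seed = (seed + 100003 * r) % (2**31)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        tp = fn = fp = tn = 0
        if legacy_leaky:
            X_all_std, fitted_all = standardize(X)
            sel_all, _ = select_features_nca(
                X_all_std, y, k=nca_k, regularization=nca_regularization, seed=rep_seed
            )
            _, _, _, pca_all = pca_project(
                X_all_std[sel_all], n_components=min(n_components, len(sel_all))
            )
        for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            X_train, X_test = X.iloc[train_idx], X.iloc[test_idx]
            y_train, y_test = y[train_idx], y[test_idx]
            if len(np.unique(y_train)) < 2:
                raise ValueError("stratification failed: a training split lost a class")
            if legacy_leaky:
                fitted, selected, pca = fitted_all, sel_all, pca_all
            else:
                _, fitted = standardize(X_train)
                selected, _ = select_features_nca(
                    fitted.transform(X_train),
                    y_train,
                    k=nca_k,
                    regularization=nca_regularization,
                    seed=(rep_seed + fold) % (2**31),
                )
                _, _, _, pca = pca_project(
                    fitted.transform(X_train)[selected],
                    n_components=min(n_components, len(selected)),
                )
            Z_train = pca.transform(np.asarray(fitted.transform(X_train)[selected], dtype=float))
            Z_test = pca.transform(np.asarray(fitted.transform(X_test)[selected], dtype=float))
            clf = train_svm_rbf(Z_train, y_train, C=C, gamma=gamma)
            pred = clf.predict(Z_test)
            tp += int(((pred == 1) & (y_test == 1)).sum())
            fn += int(((pred == 0) & (y_test == 1)).sum())
            fp += int(((pred == 1) & (y_test == 0)).sum())
            tn += int(((pred == 0) & (y_test == 0)).sum())
        metrics = classification_metrics(tp, fn, fp, tn)
        metrics["seed"] = rep_seed
        per_repeat.append(metrics)
    mean = {
        m: float(np.mean([rep[m] for rep in per_repeat if rep[m] is not None]))
        for m in METRIC_NAMES
    }
    sd = {
        m: float(np.std([rep[m] for rep in per_repeat if rep[m] is not None], ddof=1))
        if repeats > 1
        else 0.0
        for m in METRIC_NAMES
    }
    return ClassificationReport(
        per_repeat=per_repeat,
        mean=mean,
        sd=sd,
        folds=folds,
        repeats=repeats,
        seed=seed,
        config=config_echo or {},
    )


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def compare_feature_groups(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_features_tested: int | None = None,
) -> pd.DataFrame:
    """Two-sided rank-sum test per feature, Bonferroni-corrected.

    The rank-sum (Mann-Whitney) test is used because the feature
    distributions are skewed with outliers; p-values are multiplied by the
    number of features tested and clipped at 1.
    """
    y = np.asarray(pd.Series(labels) == PLUS)
    X = features.select_dtypes(include=[np.number])
    if y.sum() < 3 or (~y).sum() < 3:
        raise ValueError("group comparison needs >= 3 samples per group")
    m = n_features_tested if n_features_tested is not None else X.shape[1]
    rows = []
    for col in X.columns:
        stat, p = mannwhitneyu(X.loc[y, col], X.loc[~y, col], alternative="two-sided")
        rows.append(
            {"feature": col, "statistic": float(stat), "p": float(p), "p_bonferroni": min(1.0, p * m)}
        )
    return pd.DataFrame(rows).set_index("feature")


def truncate_2dp(x: float) -> float:
    """Two-decimal truncation (not rounding), as used in the reported tables."""
    return np.trunc(x * 100) / 100
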
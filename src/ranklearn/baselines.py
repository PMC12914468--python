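"""Intensity-based comparator models.

Logistic regression (LR) and random forest (RF) with the feature-selection
strategies used to benchmark the rank-profile classifier: Lasso, rank
product, greedy forward selection by cross-validated AUC, and impurity
importance. The estimators themselves come from scikit-learn; the forward
selection loop and the rank-product statistic are implemented here.

Selection and fitting only ever see development data; missing values are
imputed with per-feature development medians (or means) since LR/RF cannot
consume masked entries directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .evaluation import AUCReport, auc, bootstrap_ci
from .matrix import ExpressionMatrix
from .optimizer import DevelopmentSplit

__all__ = [
    "BaselineSpec",
    "forward_select",
    "rank_product_select",
    "fit_baseline",
]

_VALID_COMBOS = {
    ("logistic_regression", "lasso"),
    ("logistic_regression", "rank_product"),
    ("logistic_regression", "forward"),
    ("logistic_regression", "none"),
    ("random_forest", "forward"),
    ("random_forest", "importance"),
    ("random_forest", "none"),
}


@dataclass(frozen=True)
class BaselineSpec:
    model: str = "logistic_regression"
    selection: str = "forward"
    cv_folds: int = 5
    selection_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.model, self.selection) not in _VALID_COMBOS:
            raise ValueError(
                f"unsupported baseline combination ({self.model}, {self.selection})"
            )


def _impute(values: np.ndarray, fill: np.ndarray) -> np.ndarray:
    out = values.copy()
    nan = ~np.isfinite(out)
    out[nan] = np.broadcast_to(fill, out.shape)[nan]
    return out


def _dev_fill(values: np.ndarray, how: str) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        fill = np.nanmedian(values, axis=0) if how == "median" else np.nanmean(values, axis=0)
    return np.where(np.isfinite(fill), fill, 0.0)


def _cv_auc(X: np.ndarray, y: np.ndarray, cols: list[int], cv_folds: int, seed: int) -> float:
    """Out-of-fold AUC of a logistic model on the given feature columns."""
    folds = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    oof = np.empty(y.size)
    for tr, va in folds.split(X, y):
        model = LogisticRegression(max_iter=1000)
        model.fit(X[np.ix_(tr, cols)], y[tr])
        oof[va] = model.decision_function(X[np.ix_(va, cols)])
    return auc(oof, y)


def forward_select(
    data: ExpressionMatrix,
    cv_folds: int = 5,
    rng: np.random.Generator | int | None = None,
    min_gain: float = 1e-4,
    max_features: int | None = None,
) -> list[int]:
    """Greedy forward selection maximizing cross-validated LR AUC.

    Adds the feature giving the largest CV-AUC gain; stops when no candidate
    improves by more than ``min_gain``. Returns indices in selection order.
    """
    data.require_both_classes("forward_select input")
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(2**31 - 1))
    n_per_class = min(data.n_cases, data.n_controls)
    if n_per_class < cv_folds:
        raise ValueError(
            f"cv_folds={cv_folds} exceeds the smaller class size {n_per_class}"
        )
    X = StandardScaler().fit_transform(
        _impute(data.values, _dev_fill(data.values, "median"))
    )
    y = data.labels
    max_features = max_features or data.p

    selected: list[int] = []
    best = 0.5
    while len(selected) < max_features:
        gains = np.full(data.p, -np.inf)
        for f in range(data.p):
            if f in selected:
                continue
            gains[f] = _cv_auc(X, y, selected + [f], cv_folds, seed)
        f_best = int(np.argmax(gains))
        if gains[f_best] <= best + min_gain:
            break
        selected.append(f_best)
        best = gains[f_best]
    return selected


def rank_product_select(
    data: ExpressionMatrix,
    n_features: int,
    rng: np.random.Generator | int | None = None,
    n_perm: int = 100,
    max_comparisons: int = 400,
) -> list[int]:
    """Top features by rank-product significance.

    For each case-control pairing the features are ranked by expression
    difference (descending for up-regulation, ascending for down); the rank
    product is the geometric mean of a feature's ranks across pairings,
    taken direction-wise, and significance is assessed by permuting class
    labels. Returns the ``n_features`` most significant feature indices.
    """
    data.require_both_classes("rank_product_select input")
    if n_features > data.p:
        raise ValueError(f"n_features={n_features} exceeds p={data.p}")
    rng = np.random.default_rng(rng)
    X = _impute(data.values, _dev_fill(data.values, "median"))

    def _log_rp(y: np.ndarray) -> np.ndarray:
        cases = np.flatnonzero(y == 1)
        ctrls = np.flatnonzero(y == 0)
        pairs = [(a, b) for a in cases for b in ctrls]
        if len(pairs) > max_comparisons:
            keep = rng.choice(len(pairs), size=max_comparisons, replace=False)
            pairs = [pairs[k] for k in keep]
        log_up = np.zeros(data.p)
        log_dn = np.zeros(data.p)
        for a, b in pairs:
            diff = X[a] - X[b]
            r_up = np.argsort(np.argsort(-diff)) + 1  # rank 1 = most up
            log_up += np.log(r_up)
            log_dn += np.log(data.p + 1 - r_up)
        k = len(pairs)
        return np.minimum(log_up, log_dn) / k  # best direction, log-geometric-mean

    observed = _log_rp(data.labels)
    exceed = np.ones(data.p)
    for _ in range(n_perm):
        perm = _log_rp(rng.permutation(data.labels))
        exceed += perm <= observed
    pvals = exceed / (n_perm + 1)
    ranking = np.lexsort((observed, pvals))  # significance, then statistic
    return [int(f) for f in ranking[:n_features]]


def _importance_select(
    data: ExpressionMatrix, cv_folds: int, seed: int, candidates=(1, 2, 4, 8, 16)
) -> list[int]:
    """Top-k features by RF impurity importance, k chosen by CV AUC."""
    X = _impute(data.values, _dev_fill(data.values, "median"))
    y = data.labels
    rf = RandomForestClassifier(n_estimators=200, random_state=seed)
    rf.fit(X, y)
    order = np.argsort(rf.feature_importances_)[::-1]
    best_k, best_auc = candidates[0], -np.inf
    folds = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for k in candidates:
        if k > data.p:
            break
        cols = order[:k]
        oof = np.empty(y.size)
        for tr, va in folds.split(X, y):
            m = RandomForestClassifier(n_estimators=200, random_state=seed)
            m.fit(X[np.ix_(tr, cols)], y[tr])
            oof[va] = m.predict_proba(X[np.ix_(va, cols)])[:, 1]
        a = auc(oof, y)
        if a > best_auc:
            best_k, best_auc = k, a
    return [int(f) for f in order[:best_k]]


def fit_baseline(
    spec: BaselineSpec,
    split: DevelopmentSplit,
    test: ExpressionMatrix,
    rng: np.random.Generator | int | None = None,
    impute: str = "median",
    bootstrap: bool = False,
) -> dict:
    """Select features on development data, fit, and score development + test.

    Returns a dict with the selected feature indices and AUC reports for the
    development and test sets (point AUCs, or bootstrap CIs when
    ``bootstrap=True``).
    """
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(2**31 - 1))
    dev_rows = np.concatenate([split.d1.values, split.d2.values])
    dev_labels = np.concatenate([split.d1.labels, split.d2.labels])
    dev = ExpressionMatrix(values=dev_rows, labels=dev_labels,
                           feature_ids=list(split.d1.feature_ids))

    fill = _dev_fill(dev.values, impute)
    X_dev = _impute(dev.values, fill)
    X_test = _impute(test.values, fill)
    y_dev, y_test = dev.labels, test.labels

    if spec.selection == "forward":
        cols = forward_select(dev, cv_folds=spec.cv_folds, rng=rng,
                              **spec.selection_params)
    elif spec.selection == "rank_product":
        cols = rank_product_select(
            dev, n_features=spec.selection_params.get("n_features", 20), rng=rng
        )
    elif spec.selection == "importance":
        cols = _importance_select(dev, spec.cv_folds, seed)
    else:
        cols = list(range(dev.p))

    if not cols:
        warnings.warn("feature selection returned an empty set; using all features")
        cols = list(range(dev.p))

    if spec.model == "logistic_regression":
        scaler = StandardScaler().fit(X_dev[:, cols])
        Xd, Xt = scaler.transform(X_dev[:, cols]), scaler.transform(X_test[:, cols])
        if spec.selection == "lasso":
            model = LogisticRegressionCV(
                penalty="l1", solver="liblinear", cv=spec.cv_folds,
                random_state=seed, max_iter=1000,
            )
        else:
            model = LogisticRegression(max_iter=1000)
        model.fit(Xd, y_dev)
        dev_scores = model.decision_function(Xd)
        test_scores = model.decision_function(Xt)
        if spec.selection == "lasso":  # report the surviving features
            cols = [cols[k] for k in np.flatnonzero(np.abs(model.coef_[0]) > 1e-12)] or cols
    else:
        model = RandomForestClassifier(n_estimators=500, random_state=seed)
        model.fit(X_dev[:, cols], y_dev)
        dev_scores = model.predict_proba(X_dev[:, cols])[:, 1]
        test_scores = model.predict_proba(X_test[:, cols])[:, 1]

    if bootstrap:
        dev_report = bootstrap_ci(dev_scores, y_dev, rng=rng)
        test_report = bootstrap_ci(test_scores, y_test, rng=rng)
    else:
        dev_report = AUCReport(auc(dev_scores, y_dev), np.nan, np.nan, "point", 0)
        test_report = AUCReport(auc(test_scores, y_test), np.nan, np.nan, "point", 0)
    return {
        "spec": spec,
        "selected_features": cols,
        "development": dev_report,
        "test": test_report,
    }
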
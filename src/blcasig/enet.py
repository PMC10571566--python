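"""Elastic-net regularized logistic regression and model evaluation.

The classifier minimizes the penalized average negative log-likelihood

    (1/n) sum_i dev_i + lambda * [ m * sum|b_j| + (1 - m)/2 * sum b_j^2 ]

with mixing weight ``m`` (0.5 by default: an equal LASSO/ridge blend).
Predictors are standardized internally and coefficients are reported on
the input scale, so the penalty treats all genes equally regardless of
their expression range.  The penalty ``lambda`` is chosen by stratified
k-fold cross-validation (k = 10) over a log-spaced grid descending from
``lambda_max`` (the smallest penalty that zeroes every coefficient) to
``lambda_max * 1e-4``, minimizing the mean held-out binomial deviance.

The underlying per-lambda optimization is delegated to scikit-learn's
saga solver; the glmnet-style parameterization, internal scaling, path
warm starts and CV selection are implemented here.

Also provided: stratified train/test splitting, ROC/AUC via the rank
(Mann-Whitney) formulation, an accuracy-maximizing cutpoint search, and
the exact binomial (Clopper-Pearson) confidence interval for accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .exceptions import DomainError

_EPS = 1e-12


@dataclass(frozen=True)
class SplitSpec:
    """A stratified train/test partition of sample IDs."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    ratio: float
    stratify_on: str = "endpoint"


@dataclass
class RocResult:
    """ROC curve with rank-based AUC and an accuracy-optimal cutpoint."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    optimal_cutpoint: float | None = None
    accuracy_at_cutpoint: float | None = None


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(labels: pd.Series, ratio: float = 0.7,
                     seed: int | None = None) -> SplitSpec:
    """Stratified train/test split preserving per-class proportions.

    Each class contributes ``round(class_size * ratio)`` training samples,
    with any remainder against the overall ``round(n * ratio)`` target
    resolved on the largest classes first.  Deterministic given ``seed``.
    """
    labels = pd.Series(labels)
    if labels.nunique() < 2 and ratio < 1.0:
        raise DomainError("endpoint has a single class; cannot stratify")
    rng = np.random.default_rng(seed)
    n = len(labels)
    target = _round_half_up(n * ratio)
    classes = sorted(labels.unique(), key=lambda c: (-int((labels == c).sum()), str(c)))
    alloc = {c: _round_half_up(int((labels == c).sum()) * ratio) for c in classes}
    # reconcile the per-class roundings with the overall target
    i = 0
    while sum(alloc.values()) != target and i < 10 * len(classes):
        c = classes[i % len(classes)]
        size = int((labels == c).sum())
        if sum(alloc.values()) > target and alloc[c] > 0:
            alloc[c] -= 1
        elif sum(alloc.values()) < target and alloc[c] < size:
            alloc[c] += 1
        i += 1
    train, test = [], []
    for c in classes:
        ids = np.asarray(labels.index[labels == c], dtype=object)
        perm = rng.permutation(len(ids))
        k = alloc[c]
        train.extend(ids[perm[:k]])
        test.extend(ids[perm[k:]])
    if not test:
        warnings.warn("ratio leaves an empty test set", stacklevel=2)
    return SplitSpec(train_ids=tuple(train), test_ids=tuple(test), ratio=ratio)


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class ElasticNetLogistic(BaseEstimator, ClassifierMixin):
    """Binary logistic regression with an elastic-net penalty.

    Parameters
    ----------
    lambda_ : penalty strength; ``None`` (default) selects ``lambda_min``
        by stratified k-fold cross-validation on binomial deviance.
    mixing : elastic-net weight m in [0, 1]; 0.5 mixes LASSO and ridge
        equally, 1 is pure LASSO.
    n_lambdas, lambda_min_ratio : geometry of the penalty grid.
    cv : number of CV folds (reduced with a warning if a class is smaller).
    random_state : seed for fold shuffling; fits themselves are
        deterministic.

    Fitted attributes: ``intercept_``, ``coef_`` (input scale),
    ``lambda_min_``, ``lambda_path_``, ``cv_deviance_path_``,
    ``nonzero_genes_``.
    """

    def __init__(self, lambda_: float | None = None, mixing: float = 0.5,
                 n_lambdas: int = 100, lambda_min_ratio: float = 1e-4,
                 cv: int = 10, random_state: int | None = None,
                 tol: float = 1e-3, max_iter: int = 2000):
        self.lambda_ = lambda_
        self.mixing = mixing
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter

    # -- internals ---------------------------------------------------------

    def _standardize(self, X: np.ndarray):
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        return (X - mean) / sd_safe, mean, sd_safe

    def _lambda_grid(self, Xs: np.ndarray, y: np.ndarray) -> np.ndarray:
        n = y.size
        resid = y - y.mean()
        m = max(self.mixing, 1e-3)
        lam_max = np.abs(Xs.T @ resid).max() / (n * m)
        lam_max = max(lam_max, 1e-8)
        return np.geomspace(lam_max, lam_max * self.lambda_min_ratio,
                            self.n_lambdas)

    def _fit_path(self, Xs: np.ndarray, y: np.ndarray, lambdas: np.ndarray):
        """Warm-started descent along a decreasing penalty grid.

        Penalties at or above the data's lambda_max admit the exact null
        solution (all coefficients zero, intercept at the empirical
        log-odds) by the KKT conditions, so those grid points are filled
        in closed form rather than iterated.
        """
        n = y.size
        ybar = y.mean()
        m = max(self.mixing, 1e-3)
        lam_max = max(np.abs(Xs.T @ (y - ybar)).max() / (n * m), 1e-12)
        clf = LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=self.mixing,
            fit_intercept=True, warm_start=True, tol=self.tol,
            max_iter=self.max_iter, C=1.0,
            random_state=0,  # saga epoch shuffling; fits stay deterministic
        )
        coefs = np.zeros((lambdas.size, Xs.shape[1]))
        intercepts = np.full(lambdas.size,
                             np.log(ybar / (1 - ybar)) if 0 < ybar < 1 else 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # saga ConvergenceWarning on path ends
            for i, lam in enumerate(lambdas):
                if lam >= lam_max * (1 - 1e-12):
                    continue  # exact null model already filled in
                clf.set_params(C=1.0 / (n * lam))
                clf.fit(Xs, y)
                coefs[i] = clf.coef_[0]
                intercepts[i] = clf.intercept_[0]
        return coefs, intercepts

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(float)
        values = X.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise DomainError("non-finite expression value passed to fit")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise DomainError("y must contain exactly two classes")
        if counts.min() < 2:
            raise DomainError("fewer than 2 samples in one class")
        self.classes_ = np.array([0, 1])
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]

        Xs, mean, sd = self._standardize(values)
        self._mean_, self._sd_ = mean, sd

        if self.lambda_ is not None and self.lambda_ < 0:
            raise DomainError("lambda must be non-negative")

        if self.lambda_ is None:
            lambdas = self._lambda_grid(Xs, y)
            k = min(self.cv, int(counts.min()))
            if k < self.cv:
                warnings.warn(
                    f"reducing CV folds from {self.cv} to {k}: smallest class "
                    f"has {int(counts.min())} samples", stacklevel=2)
            if k < 2:
                raise DomainError("need at least 2 samples per class for CV")
            folds = StratifiedKFold(n_splits=k, shuffle=True,
                                    random_state=self.random_state)
            dev = np.zeros((k, lambdas.size))
            for f, (tr, va) in enumerate(folds.split(Xs, y)):
                Xtr, mtr, str_ = self._standardize(values[tr])
                coefs, icepts = self._fit_path(Xtr, y[tr], lambdas)
                Xva = (values[va] - mtr) / str_
                eta = Xva @ coefs.T + icepts
                p = 1.0 / (1.0 + np.exp(-eta))
                for i in range(lambdas.size):
                    dev[f, i] = _binomial_deviance(y[va], p[:, i])
            mean_dev = dev.mean(axis=0)
            best = int(np.argmin(mean_dev))  # ties -> largest lambda (first)
            self.lambda_path_ = lambdas
            self.cv_deviance_path_ = mean_dev
            self.lambda_min_ = float(lambdas[best])
            coefs, icepts = self._fit_path(Xs, y, lambdas[: best + 1])
            b_std, a_std = coefs[-1], icepts[-1]
        elif self.lambda_ == 0:
            clf = LogisticRegression(penalty=None, solver="lbfgs",
                                     max_iter=self.max_iter, tol=self.tol)
            clf.fit(Xs, y)
            b_std, a_std = clf.coef_[0], clf.intercept_[0]
            self.lambda_path_ = np.array([0.0])
            self.cv_deviance_path_ = None
            self.lambda_min_ = 0.0
        else:
            lambdas = self._lambda_grid(Xs, y)
            path = lambdas[lambdas > self.lambda_]
            path = np.append(path, self.lambda_)
            coefs, icepts = self._fit_path(Xs, y, path)
            b_std, a_std = coefs[-1], icepts[-1]
            self.lambda_path_ = path
            self.cv_deviance_path_ = None
            self.lambda_min_ = float(self.lambda_)

        # back-transform to the input scale
        self.coef_ = b_std / sd
        self.intercept_ = float(a_std - np.sum(b_std * mean / sd))
        self.nonzero_genes_ = list(self.feature_names_in_[self.coef_ != 0])
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = pd.DataFrame(X)
        if list(X.columns) != list(self.feature_names_in_):
            missing = set(self.feature_names_in_) - set(X.columns)
            if missing:
                raise DomainError(f"missing predictor genes: {sorted(missing)[:5]}")
            X = X[list(self.feature_names_in_)]
        return X.to_numpy(dtype=float) @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        eta = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p1, p1])

    def predict(self, X, boundary: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > boundary).astype(int)


# -- functional wrappers ---------------------------------------------------

def cv_lambda(X, y, k: int = 10, mixing: float = 0.5,
              seed: int | None = None, n_lambdas: int = 100):
    """CV-select the penalty; returns (lambda_min, lambda grid, mean deviances)."""
    if n_lambdas == 1:
        model = ElasticNetLogistic(mixing=mixing, cv=k, random_state=seed,
                                   n_lambdas=2)
        Xs, _, _ = model._standardize(pd.DataFrame(X).to_numpy(dtype=float))
        lam = model._lambda_grid(Xs, np.asarray(y, dtype=float))[:1]
        return float(lam[0]), lam, np.array([np.nan])
    model = ElasticNetLogistic(mixing=mixing, cv=k, random_state=seed,
                               n_lambdas=n_lambdas)
    model.fit(X, y)
    return model.lambda_min_, model.lambda_path_, model.cv_deviance_path_


def fit_enet(X, y, lambda_: float, mixing: float = 0.5) -> ElasticNetLogistic:
    """Fit at a fixed penalty."""
    return ElasticNetLogistic(lambda_=lambda_, mixing=mixing).fit(X, y)


def predict_response(fit: ElasticNetLogistic, x) -> float:
    """Event probability for a single expression vector (sigmoid of a + b.x)."""
    x = pd.Series(x)
    missing = [g for g in fit.feature_names_in_ if g not in x.index]
    if missing:
        raise DomainError(f"missing predictor genes: {missing[:5]}")
    eta = float(np.dot(x[list(fit.feature_names_in_)].to_numpy(dtype=float),
                       fit.coef_) + fit.intercept_)
    return float(1.0 / (1.0 + np.exp(-eta)))


def classify(p: float, boundary: float = 0.5) -> int:
    """Class from a probability: 1 iff p strictly exceeds the boundary."""
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"probability outside [0, 1]: {p}")
    return int(p > boundary)


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC by the rank (Mann-Whitney) formulation.

    Tied scores contribute 1/2, so the AUC equals the probability that a
    random positive outscores a random negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DomainError("both classes must be present for ROC analysis")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    # explicit curve over the distinct score thresholds
    order = np.argsort(-scores, kind="stable")
    s_sorted, l_sorted = scores[order], labels[order]
    distinct = np.r_[True, np.diff(s_sorted) != 0]
    tp = np.cumsum(l_sorted == 1)
    fp = np.cumsum(l_sorted == 0)
    idx = np.flatnonzero(np.r_[distinct[1:], True])
    tpr = np.r_[0.0, tp[idx] / n1]
    fpr = np.r_[0.0, fp[idx] / n0]
    thresholds = np.r_[np.inf, s_sorted[idx]]
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc))


def optimal_cutpoint(scores, labels) -> tuple[float, float]:
    """Accuracy-maximizing probability cutpoint.

    Candidate cutpoints are the midpoints between adjacent distinct sorted
    scores plus -inf/+inf sentinels; a sample is called positive when its
    score is >= the cutpoint.  Ties in accuracy break toward the lowest
    cutpoint.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(set(labels)) < 2:
        raise DomainError("both classes must be present for cutpoint search")
    distinct = np.unique(scores)
    candidates = np.concatenate([
        [-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf],
    ])
    best_c, best_acc = candidates[0], -1.0
    for c in candidates:
        acc = float(np.mean((scores >= c).astype(int) == labels))
        if acc > best_acc:
            best_c, best_acc = c, acc
    return float(best_c), float(best_acc)


def accuracy_ci(correct: int, total: int,
                level: float = 0.95) -> tuple[float, float, float]:
    """Point accuracy with the exact binomial (Clopper-Pearson) interval."""
    if total < 1:
        raise DomainError("total must be at least 1")
    if not 0 <= correct <= total:
        raise DomainError(f"correct ({correct}) outside [0, {total}]")
    a = 1.0 - level
    point = correct / total
    lower = 0.0 if correct == 0 else float(
        stats.beta.ppf(a / 2, correct, total - correct + 1))
    upper = 1.0 if correct == total else float(
        stats.beta.ppf(1 - a / 2, correct + 1, total - correct))
    return point, lower, upper
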
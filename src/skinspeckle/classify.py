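"""Classifiers for sound-skin vs injured-skin discrimination.

Two binary classifiers mirror the two imaging channels: a least-squares
support vector machine (LS-SVM) with RBF kernel for the visible-imaging
feature vectors, and a binary logistic regression fitted by iteratively
reweighted least squares for the scalar biospeckle-activity feature.  Both
are scikit-learn estimators.  Evaluation follows a stratified repeated
random 2:1 train/prediction split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "LSSVMClassifier",
    "BinaryLogisticRegression",
    "EvalReport",
    "fit_lssvm",
    "fit_blr",
    "split_evaluate",
    "tune_lssvm",
]


def _rbf_kernel(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    d2 = cdist(a, b, "sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


class LSSVMClassifier(ClassifierMixin, BaseEstimator):
    """Least-squares SVM with RBF kernel.

    Training solves the LS-SVM KKT system exactly: with labels ``y`` encoded
    as +/-1, kernel matrix ``K`` and regularization ``gamma``,

        [ 0   1^T          ] [ b     ]   [ 0 ]
        [ 1   K + I/gamma  ] [ alpha ] = [ y ]

    and the decision function is ``sign(sum_k alpha_k K(x, x_k) + b)``.
    Unlike the standard SVM there is no sparsity: every training point is a
    support vector.  Features are z-scored with training statistics by
    default (``standardize=True``), which prevents test-set leakage when the
    estimator is cloned inside a resampling loop.

    Attributes
    ----------
    alpha_ : (n_train,) dual weights
    bias_ : float
    kkt_residual_ : relative residual of the solved KKT system
    """

    def __init__(self, gamma: float = 1.0, sigma: float = 1.0, standardize: bool = True):
        self.gamma = gamma
        self.sigma = sigma
        self.standardize = standardize

    def fit(self, X, y) -> "LSSVMClassifier":
        X, y = check_X_y(X, y)
        if self.gamma <= 0 or self.sigma <= 0:
            raise ValueError("gamma and sigma must be positive")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("LSSVMClassifier is strictly binary")
        y_pm = np.where(y == self.classes_[1], 1.0, -1.0)

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_

        n = Xs.shape[0]
        K = _rbf_kernel(Xs, Xs, self.sigma)
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = K + np.eye(n) / self.gamma
        rhs = np.concatenate([[0.0], y_pm])
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
            raise np.linalg.LinAlgError(
                "singular LS-SVM KKT system; try a larger gamma or sigma"
            ) from exc
        self.bias_ = float(sol[0])
        self.alpha_ = sol[1:]
        self.X_fit_ = Xs
        self.kkt_residual_ = float(
            np.linalg.norm(A @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
        )
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "alpha_")
        X = check_array(X)
        Xs = (X - self.mean_) / self.scale_
        return _rbf_kernel(Xs, self.X_fit_, self.sigma) @ self.alpha_ + self.bias_

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores >= 0, self.classes_[1], self.classes_[0])


class BinaryLogisticRegression(ClassifierMixin, BaseEstimator):
    """Maximum-likelihood logistic regression fitted by IRLS.

    Newton/IRLS steps with step-halving keep the log-likelihood monotone
    non-decreasing (history in ``loglik_path_``).  Complete separation is
    detected (margins diverging with every point correctly classified); the
    coefficients are then capped at the current iterate and ``separated_``
    is set — training-set classification remains perfect.  The decision
    threshold is probability 0.5.

    Attributes
    ----------
    intercept_ : float
    coef_ : (n_features,) slopes
    bse_ : asymptotic standard errors (inverse Fisher information)
    converged_, separated_ : flags;  n_iter_ : iterations used
    """

    _MARGIN_CAP = 30.0  # |X beta| beyond this, probabilities are 1 to 1e-13

    def __init__(self, max_iter: int = 100, tol: float = 1e-10):
        self.max_iter = max_iter
        self.tol = tol

    @staticmethod
    def _loglik(eta: np.ndarray, y01: np.ndarray) -> float:
        # log p = -log(1+exp(-eta)) for y=1; -log(1+exp(eta)) for y=0
        return float(-np.logaddexp(0.0, np.where(y01 == 1, -eta, eta)).sum())

    def fit(self, X, y) -> "BinaryLogisticRegression":
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("BinaryLogisticRegression needs exactly 2 classes")
        y01 = (y == self.classes_[1]).astype(float)
        Xd = np.column_stack([np.ones(len(X)), X])

        beta = np.zeros(Xd.shape[1])
        eta = Xd @ beta
        ll = self._loglik(eta, y01)
        self.loglik_path_ = [ll]
        self.converged_ = False
        self.separated_ = False
        it = 0
        for it in range(1, self.max_iter + 1):
            p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
            w = np.clip(p * (1.0 - p), 1e-12, None)
            grad = Xd.T @ (y01 - p)
            hess = Xd.T @ (Xd * w[:, None])
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                break
            # Step-halving guarantees a non-decreasing log-likelihood.
            t = 1.0
            for _ in range(30):
                cand = beta + t * step
                cand_ll = self._loglik(Xd @ cand, y01)
                if cand_ll >= ll:
                    break
                t /= 2.0
            else:  # pragma: no cover - defensive
                break
            beta, new_ll = cand, cand_ll
            eta = Xd @ beta
            self.loglik_path_.append(new_ll)
            correct = np.all((eta >= 0) == (y01 == 1))
            if correct and np.max(np.abs(eta)) > self._MARGIN_CAP:
                self.separated_ = True
                break
            if new_ll - ll < self.tol:
                self.converged_ = True
                ll = new_ll
                break
            ll = new_ll

        self.n_iter_ = it
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        fisher = Xd.T @ (Xd * w[:, None])
        try:
            cov = np.linalg.inv(fisher)
            self.bse_ = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:  # pragma: no cover
            self.bse_ = np.full(Xd.shape[1], np.nan)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X)
        eta = self.intercept_ + X @ self.coef_
        p1 = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p1 = self.predict_proba(X)[:, 1]
        return np.where(p1 >= 0.5, self.classes_[1], self.classes_[0])


@dataclass(frozen=True)
class EvalReport:
    """Accuracy of repeated stratified train/prediction splits."""

    accuracy: float  # mean over repeats, in [0, 1]
    accuracy_sd: float
    per_repeat: tuple[float, ...]
    n_train: int
    n_test: int
    split_ratio: str
    confusion: dict = field(default_factory=dict)  # summed over repeats
    seed: int = 0

    @property
    def accuracy_se(self) -> float:
        return self.accuracy_sd / np.sqrt(max(len(self.per_repeat), 1))


def fit_lssvm(X, y, gamma: float = 1.0, sigma: float = 1.0) -> LSSVMClassifier:
    """Convenience wrapper: fit an RBF LS-SVM on standardized features."""
    return LSSVMClassifier(gamma=gamma, sigma=sigma).fit(X, y)


def fit_blr(X, y) -> BinaryLogisticRegression:
    """Convenience wrapper: fit a binary logistic regression by IRLS."""
    return BinaryLogisticRegression().fit(X, y)


def split_evaluate(
    X,
    y,
    estimator: BaseEstimator | None = None,
    train_fraction: float = 2.0 / 3.0,
    n_repeats: int = 50,
    seed: int = 0,
) -> EvalReport:
    """Repeated stratified random split evaluation (default 2:1, 50 repeats).

    Each repeat refits a clone of ``estimator`` on the training part and
    scores the held-out prediction part; the report carries the mean and SD
    of the per-repeat accuracies plus summed confusion tallies.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if estimator is None:
        estimator = LSSVMClassifier()
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_fraction, random_state=seed % (2**31)
    )
    accs = []
    classes = np.unique(y)
    confusion = {(t, p): 0 for t in classes for p in classes}
    n_train = n_test = 0
    for train_idx, test_idx in splitter.split(X, y):
        model = clone(estimator).fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
        for t, p in zip(y[test_idx], pred):
            confusion[(t, p)] += 1
        n_train, n_test = len(train_idx), len(test_idx)
    accs_arr = np.asarray(accs)
    num, den = (
        np.round(train_fraction / (1 - train_fraction), 2),
        1,
    )
    return EvalReport(
        accuracy=float(accs_arr.mean()),
        accuracy_sd=float(accs_arr.std(ddof=1)) if len(accs) > 1 else 0.0,
        per_repeat=tuple(accs),
        n_train=n_train,
        n_test=n_test,
        split_ratio=f"{num:g}:{den}",
        confusion={f"true_{t}_pred_{p}": c for (t, p), c in confusion.items()},
        seed=seed,
    )


def tune_lssvm(
    X,
    y,
    gamma_grid=(0.1, 1.0, 10.0, 100.0),
    sigma_grid=(0.25, 0.5, 1.0, 2.0, 4.0),
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Cross-validated grid search for (gamma, sigma).

    Ties in mean fold accuracy break deterministically toward the smallest
    gamma, then the smallest sigma.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(gamma_grid) == 0 or len(sigma_grid) == 0:
        raise ValueError("hyperparameter grids must be non-empty")
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed % (2**31))
    splits = list(cv.split(X, y))
    best = None
    best_acc = -np.inf
    for g in sorted(gamma_grid):
        for s in sorted(sigma_grid):
            fold_accs = []
            for train_idx, test_idx in splits:
                model = LSSVMClassifier(gamma=g, sigma=s).fit(X[train_idx], y[train_idx])
                fold_accs.append(np.mean(model.predict(X[test_idx]) == y[test_idx]))
            acc = float(np.mean(fold_accs))
            if acc > best_acc:  # strict: first (smallest g, s) wins ties
                best_acc = acc
                best = (g, s)
    assert best is not None
    return best
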
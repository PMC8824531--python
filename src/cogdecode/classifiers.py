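"""The four binary classifiers behind one train/score/predict contract.

Scores are real-valued per-trial certainties oriented so that larger means
stronger evidence for the positive class (the larger of the two labels);
they feed the multiclass voting scheme.

* ``GaussianDiscriminant`` — the printed "naive Bayes": full per-class
  covariance quadratic discriminant d_i(x) = x'A_i x + b_i'x + c_i.
* ``LogisticClassifier`` — Newton-Raphson MLE with a tiny L2 stabilizer.
* ``LassoClassifier`` — coordinate descent on ||y - Xb||^2 + lam*||b||_1
  with classes coded -1/+1 and inner-CV lambda choice.
* ``LinearSVM`` — soft-margin linear SVM (libsvm dual via scikit-learn),
  margin M = 2/||w|| reported.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit
from sklearn.model_selection import KFold
from sklearn.svm import SVC

__all__ = [
    "GaussianDiscriminant",
    "LogisticClassifier",
    "LassoClassifier",
    "LinearSVM",
    "make_classifier",
    "predict",
    "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = ("naive_bayes", "logistic", "lasso", "linear_svm")


def _check_binary(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes.size}")
    return classes


class _BaseClassifier:
    kind: str = ""
    classes_: np.ndarray

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BaseClassifier":
        raise NotImplementedError

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        scores = self.score_samples(np.asarray(X, dtype=float))
        labels = np.where(scores > 0, self.classes_[1], self.classes_[0])
        return labels, scores

    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"model expects {self.n_features_} features, got {X.shape[1]}"
            )
        return X

    def _params_dict(self) -> dict:
        return {}

    def to_dict(self) -> dict:
        """JSON-serializable snapshot: kind, classes, parameter vectors."""
        return {
            "kind": self.kind,
            "classes": np.asarray(self.classes_).tolist(),
            "n_features": int(self.n_features_),
            **self._params_dict(),
        }


class GaussianDiscriminant(_BaseClassifier):
    """Gaussian class-conditional discriminant with full covariances.

    Supports any number of classes (argmax of d_i); the binary score is
    d_pos(x) - d_neg(x).  Near-singular covariances get a diagonal ridge.
    """

    kind = "naive_bayes"

    def __init__(self, diagonal: bool = False):
        self.diagonal = diagonal

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need >= 2 classes")
        self.n_features_ = X.shape[1]
        n = len(y)
        self.A_, self.b_, self.c_ = [], [], []
        self.mu_, self.sigma_, self.prior_ = [], [], []
        d = X.shape[1]
        for c in self.classes_:
            Xc = X[y == c]
            if len(Xc) < 2:
                raise ValueError(f"class {c!r} needs >= 2 trials")
            mu = Xc.mean(axis=0)
            sigma = np.atleast_2d(np.cov(Xc, rowvar=False))
            if self.diagonal:
                sigma = np.diag(np.diag(sigma))
            evals = np.linalg.eigvalsh(sigma)
            if evals.min() < 1e-10:
                eps = max(1e-6 * np.trace(sigma) / d, 1e-10)
                sigma = sigma + eps * np.eye(d)
            try:
                sigma_inv = np.linalg.inv(sigma)
                _, logdet = np.linalg.slogdet(sigma)
            except np.linalg.LinAlgError as err:
                raise ValueError(
                    f"covariance of class {c!r} singular after ridge"
                ) from err
            prior = len(Xc) / n
            self.mu_.append(mu)
            self.sigma_.append(sigma)
            self.prior_.append(prior)
            self.A_.append(-0.5 * sigma_inv)
            self.b_.append(sigma_inv @ mu)
            self.c_.append(
                -0.5 * mu @ sigma_inv @ mu - 0.5 * logdet + np.log(prior)
            )
        return self

    def _params_dict(self):
        return {
            "mu": [m.tolist() for m in self.mu_],
            "sigma": [s.tolist() for s in self.sigma_],
            "prior": [float(p) for p in self.prior_],
        }

    def discriminants(self, X: np.ndarray) -> np.ndarray:
        """d_i(x) per class, shape (trials, classes)."""
        X = self._validate(X)
        out = np.empty((X.shape[0], self.classes_.size))
        for i in range(self.classes_.size):
            quad = np.einsum("nd,de,ne->n", X, self.A_[i], X)
            out[:, i] = quad + X @ self.b_[i] + self.c_[i]
        return out

    def score_samples(self, X):
        d = self.discriminants(X)
        if self.classes_.size != 2:
            raise ValueError("binary score undefined for > 2 classes")
        return d[:, 1] - d[:, 0]

    def predict(self, X):
        d = self.discriminants(X)
        labels = self.classes_[np.argmax(d, axis=1)]
        scores = d[:, 1] - d[:, 0] if self.classes_.size == 2 else d
        return labels, scores


class LogisticClassifier(_BaseClassifier):
    """Binary logistic regression by damped Newton iterations.

    A small L2 term (default 1e-6, intercept unpenalized) keeps separable
    problems finite.  Convergence: gradient inf-norm < 1e-8 or 200 steps.
    """

    kind = "logistic"

    def __init__(self, l2: float = 1e-6, max_iter: int = 200, tol: float = 1e-8):
        self.l2 = l2
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_ = _check_binary(y)
        self.n_features_ = X.shape[1]
        t = (np.asarray(y) == self.classes_[1]).astype(float)
        n, d = X.shape
        Xb = np.hstack([X, np.ones((n, 1))])
        beta = np.zeros(d + 1)
        reg = np.full(d + 1, self.l2)
        reg[-1] = 0.0  # intercept unpenalized

        def loss_grad(b):
            z = Xb @ b
            # log(1 + e^z) - t z, numerically stabilized
            nll = np.sum(np.logaddexp(0.0, z) - t * z) + 0.5 * np.sum(reg * b * b)
            p = expit(z)
            g = Xb.T @ (p - t) + reg * b
            return nll, g, p

        converged = False
        nll, g, p = loss_grad(beta)
        for _ in range(self.max_iter):
            if np.max(np.abs(g)) < self.tol:
                converged = True
                break
            w = np.maximum(p * (1 - p), 1e-12)
            H = (Xb * w[:, None]).T @ Xb + np.diag(reg + 1e-12)
            step = np.linalg.solve(H, g)
            # backtracking keeps Newton monotone on ill-scaled problems
            alpha = 1.0
            for _ in range(30):
                new_nll, new_g, new_p = loss_grad(beta - alpha * step)
                if new_nll <= nll:
                    break
                alpha /= 2.0
            beta = beta - alpha * step
            nll, g, p = new_nll, new_g, new_p
        if not converged and np.max(np.abs(g)) >= self.tol:
            warnings.warn("logistic fit did not fully converge; best iterate kept")
        self.weights_ = beta[:-1]
        self.intercept_ = float(beta[-1])
        return self

    def _params_dict(self):
        return {"weights": self.weights_.tolist(),
                "intercept": self.intercept_, "l2": self.l2}

    def score_samples(self, X):
        X = self._validate(X)
        return X @ self.weights_ + self.intercept_

    def predict_proba(self, X):
        return expit(self.score_samples(X))


def _soft_threshold(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def lasso_coordinate_descent(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, float]:
    """Minimize ||y - Xb - b0||^2 + lam * ||b||_1; returns (beta, intercept).

    The intercept is unpenalized and handled by centering.  lam = 0 falls
    back to exact least squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    if lam == 0:
        beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        return beta, float(y_mean - x_mean @ beta)
    norms = (Xc**2).sum(axis=0)
    beta = np.zeros(X.shape[1])
    resid = yc.copy()
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(X.shape[1]):
            if norms[j] == 0:
                continue
            rho = Xc[:, j] @ resid + norms[j] * beta[j]
            new = _soft_threshold(rho, lam / 2.0) / norms[j]
            if new != beta[j]:
                resid += Xc[:, j] * (beta[j] - new)
                max_delta = max(max_delta, abs(new - beta[j]))
                beta[j] = new
        if max_delta < tol:
            break
    return beta, float(y_mean - x_mean @ beta)


def lasso_lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lam for which the all-zero coefficient vector is optimal."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return float(2.0 * np.max(np.abs(Xc.T @ yc)))


class LassoClassifier(_BaseClassifier):
    """L1-penalized least squares on -1/+1 class codes.

    ``lam=None`` selects the penalty by inner k-fold CV on squared error
    over a logarithmic grid anchored at lambda_max (min-error rule).
    """

    kind = "lasso"

    def __init__(
        self,
        lam: float | None = None,
        n_grid: int = 20,
        cv_folds: int = 5,
        seed: int = 0,
        tol: float = 1e-8,
    ):
        self.lam = lam
        self.n_grid = n_grid
        self.cv_folds = cv_folds
        self.seed = seed
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_ = _check_binary(y)
        self.n_features_ = X.shape[1]
        yy = np.where(np.asarray(y) == self.classes_[1], 1.0, -1.0)
        if self.lam is not None:
            lam = float(self.lam)
        else:
            lam_max = lasso_lambda_max(X, yy)
            if lam_max == 0:
                lam = 0.0
            else:
                grid = lam_max * np.logspace(-4, 1, self.n_grid)
                kf = KFold(
                    n_splits=min(self.cv_folds, len(yy)),
                    shuffle=True,
                    random_state=self.seed,
                )
                errs = np.zeros(len(grid))
                for tr, te in kf.split(X):
                    for gi, g in enumerate(grid):
                        b, b0 = lasso_coordinate_descent(
                            X[tr], yy[tr], g, tol=max(self.tol, 1e-6)
                        )
                        pred = X[te] @ b + b0
                        errs[gi] += np.sum((yy[te] - pred) ** 2)
                lam = float(grid[int(np.argmin(errs))])
        self.lam_ = lam
        self.coef_, self.intercept_ = lasso_coordinate_descent(
            X, yy, lam, tol=self.tol
        )
        return self

    def _params_dict(self):
        return {"coef": self.coef_.tolist(), "intercept": self.intercept_,
                "lambda": self.lam_}

    def score_samples(self, X):
        X = self._validate(X)
        return X @ self.coef_ + self.intercept_

    def predict(self, X):
        scores = self.score_samples(X)
        # ties at exactly 0 go to the +1-coded class
        labels = np.where(scores >= 0, self.classes_[1], self.classes_[0])
        return labels, scores


class LinearSVM(_BaseClassifier):
    """Soft-margin linear SVM; reports the margin M = 2/||w||."""

    kind = "linear_svm"

    def __init__(self, C: float = 1.0, tol: float = 1e-8):
        self.C = C
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_ = _check_binary(y)
        self.n_features_ = X.shape[1]
        self._svc = SVC(kernel="linear", C=self.C, tol=self.tol)
        self._svc.fit(X, np.asarray(y))
        self.weights_ = self._svc.coef_.ravel().copy()
        self.intercept_ = float(self._svc.intercept_[0])
        norm = np.linalg.norm(self.weights_)
        if norm == 0:
            raise ValueError("degenerate SVM solution with ||w|| = 0")
        self.margin_ = 2.0 / norm
        return self

    def _params_dict(self):
        return {"weights": self.weights_.tolist(), "intercept": self.intercept_,
                "C": self.C, "margin": self.margin_}

    def score_samples(self, X):
        X = self._validate(X)
        return X @ self.weights_ + self.intercept_


def make_classifier(spec: str | dict, seed: int = 0) -> _BaseClassifier:
    """Build a classifier from a spec like ``"lasso"`` or
    ``{"kind": "linear_svm", "C": 10.0}``."""
    if isinstance(spec, str):
        kind, params = spec, {}
    else:
        params = dict(spec)
        kind = params.pop("kind")
    if kind == "naive_bayes":
        return GaussianDiscriminant(**params)
    if kind == "logistic":
        return LogisticClassifier(**params)
    if kind == "lasso":
        params.setdefault("seed", seed)
        return LassoClassifier(**params)
    if kind == "linear_svm":
        return LinearSVM(**params)
    raise ValueError(f"unknown classifier kind {kind!r}")


def predict(model: _BaseClassifier, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unified (labels, scores) contract for any trained model."""
    return model.predict(X)
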
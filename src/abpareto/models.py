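"""Two-class projection models whose 1-D projections act as property metrics.

A projection model classifies a binary property (high/low affinity, high/low
non-specific binding) but its real product is the continuous 1-D projection
p(x): the signed distance along the learned discriminant direction. The sign
convention is fixed so that the positive training class has the higher mean
projection; classification is ``p(x) > threshold_``.

Three models are provided: :class:`LDAProjector` (Fisher discriminant via an
SVD solver, robust to the rank deficiency of one-hot matrices),
:class:`NNProjector` (a small neural network with a single-node bottleneck
whose activation is the projection), and a k-nearest-neighbour baseline used
only for accuracy comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.utils.validation import check_X_y, check_array


def _validate_binary(y):
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    return classes


class LDAProjector(BaseEstimator, ClassifierMixin):
    """Linear discriminant projection model (SVD solver).

    The fitted direction ``coef_`` is the two-class Fisher discriminant
    (proportional to pooled-within-covariance^-1 times the class-mean
    difference), computed by sklearn's SVD route so collinear one-hot
    columns are handled by singular-value cutoff. The projection is the raw
    affine score ``x @ coef_``; ``threshold_`` (= -intercept) is where the
    fitted class posterior flips, and is generally not zero.
    """

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = _validate_binary(y)
        self.lda_ = LinearDiscriminantAnalysis(solver="svd")
        self.lda_.fit(X, y)
        self.coef_ = self.lda_.coef_.ravel().copy()
        self.intercept_ = float(self.lda_.intercept_[0])
        self.threshold_ = -self.intercept_
        self.n_features_in_ = X.shape[1]
        # sklearn's decision function is positive toward classes_[1]; with
        # labels {0, 1} the positive class therefore has the higher mean
        # projection by construction.
        return self

    def project(self, X):
        """Continuous 1-D projection p(x) = x @ w (unstandardized)."""
        X = check_array(X)
        return X @ self.coef_

    def decision_function(self, X):
        return self.project(X) - self.threshold_

    def predict(self, X):
        return np.where(self.project(X) > self.threshold_, self.classes_[1], self.classes_[0])

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


class NNProjector(BaseEstimator, ClassifierMixin):
    """Neural projection model: projector network + prediction layer.

    Architecture: two dense hidden layers (ReLU), then a dense layer with a
    single linear node — the projection — followed by a 2-way softmax
    prediction layer. Trained with categorical cross-entropy and Adam on
    shuffled mini-batches; fully seeded, so identical data and seed give
    identical parameters.

    Because the prediction layer is an affine function of the scalar
    projection, classification is exactly ``projection > threshold_``, where
    the threshold is the projection value at which the two class logits are
    equal.
    """

    def __init__(
        self,
        hidden=(32, 8),
        epochs: int = 50,
        batch_size: int = 50,
        learning_rate: float = 1e-3,
        random_state: int = 0,
    ):
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- forward/backward ---------------------------------------------------

    def _init_params(self, d, rng):
        sizes = [d, *self.hidden, 1, 2]
        params = []
        for a, b in zip(sizes, sizes[1:]):
            params.append(
                {
                    "W": rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)),
                    "b": np.zeros(b),
                }
            )
        return params

    def _forward(self, X, params):
        acts = [X]
        n_hidden = len(self.hidden)
        h = X
        for k, layer in enumerate(params):
            z = h @ layer["W"] + layer["b"]
            if k < n_hidden:
                h = np.maximum(z, 0.0)  # ReLU hidden layers
            else:
                h = z  # linear projection node and logits
            acts.append(h)
        return acts

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = _validate_binary(y)
        yi = (np.asarray(y) == self.classes_[1]).astype(int)
        rng = np.random.default_rng(self.random_state)
        params = self._init_params(X.shape[1], rng)
        mom = [{k: np.zeros_like(v) for k, v in p.items()} for p in params]
        vel = [{k: np.zeros_like(v) for k, v in p.items()} for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(X)
        n_hidden = len(self.hidden)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], yi[idx]
                acts = self._forward(xb, params)
                logits = acts[-1]
                logits = logits - logits.max(axis=1, keepdims=True)
                p = np.exp(logits)
                p /= p.sum(axis=1, keepdims=True)
                if not np.all(np.isfinite(p)):
                    raise FloatingPointError("non-finite loss during training")
                grad = p.copy()
                grad[np.arange(len(yb)), yb] -= 1.0
                grad /= len(yb)
                # backprop
                grads = [None] * len(params)
                delta = grad
                for k in range(len(params) - 1, -1, -1):
                    h_in = acts[k]
                    grads[k] = {"W": h_in.T @ delta, "b": delta.sum(axis=0)}
                    if k > 0:
                        delta = delta @ params[k]["W"].T
                        if k - 1 < n_hidden:
                            delta = delta * (acts[k] > 0)
                step += 1
                for pr, g, m, v in zip(params, grads, mom, vel):
                    for key in ("W", "b"):
                        m[key] = beta1 * m[key] + (1 - beta1) * g[key]
                        v[key] = beta2 * v[key] + (1 - beta2) * g[key] ** 2
                        mhat = m[key] / (1 - beta1**step)
                        vhat = v[key] / (1 - beta2**step)
                        pr[key] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
        self.params_ = params
        self.n_features_in_ = X.shape[1]
        # prediction layer: logits = proj * w + b with w shape (1, 2)
        w = params[-1]["W"][0]
        b = params[-1]["b"]
        slope = w[1] - w[0]
        if slope == 0:
            raise FloatingPointError("degenerate prediction layer (equal logit slopes)")
        self._raw_threshold = (b[0] - b[1]) / slope
        # sign convention: positive class mean projection above the threshold
        self.sign_ = 1.0 if slope > 0 else -1.0
        self.threshold_ = self.sign_ * self._raw_threshold
        return self

    def project(self, X):
        """Activation of the single projection node (sign-normalized)."""
        X = check_array(X)
        acts = self._forward(X, self.params_)
        return self.sign_ * acts[-2].ravel()

    def predict(self, X):
        return np.where(self.project(X) > self.threshold_, self.classes_[1], self.classes_[0])

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


# ---------------------------------------------------------------------------
# Cross-validation harness and kNN baseline


@dataclass
class CVReport:
    """Per-fold accuracies of a 5-fold (by default) cross-validation."""

    train_accuracy: list
    test_accuracy: list
    train_sizes: list
    test_sizes: list
    seed: int
    refit_full: bool = False
    final_model: object = None

    @property
    def mean_test_accuracy(self) -> float:
        return float(np.mean(self.test_accuracy))

    @property
    def mean_train_accuracy(self) -> float:
        return float(np.mean(self.train_accuracy))


def cross_validate(estimator, X, y, folds: int = 5, seed: int = 0, refit: bool = True) -> CVReport:
    """Plain shuffled k-fold CV (unstratified), then refit on the full data.

    With n = 4000 and 5 folds this gives the 3200/800 train/test splits of
    the standard protocol; the final model is refit on all n rows.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if folds > len(X):
        raise ValueError("more folds than samples")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    report = CVReport([], [], [], [], seed)
    for tr, te in kf.split(X):
        m = clone(estimator).fit(X[tr], y[tr])
        report.train_accuracy.append(float(np.mean(m.predict(X[tr]) == y[tr])))
        report.test_accuracy.append(float(np.mean(m.predict(X[te]) == y[te])))
        report.train_sizes.append(len(tr))
        report.test_sizes.append(len(te))
    if refit:
        report.final_model = clone(estimator).fit(X, y)
        report.refit_full = True
    return report


def fit_lda(X, y) -> LDAProjector:
    return LDAProjector().fit(X, y)


def fit_nn_projector(X, y, **config) -> NNProjector:
    return NNProjector(**config).fit(X, y)


def fit_knn_baseline(X, y, k_range=range(1, 26), folds: int = 5, seed: int = 0) -> pd.DataFrame:
    """Mean k-fold CV test accuracy of a Euclidean majority-vote kNN per k.

    Ties in the vote break toward the smaller label index (argmax over class
    probabilities picks the first maximum).
    """
    X = np.asarray(X)
    y = np.asarray(y)
    k_range = list(k_range)
    max_train = len(X) - len(X) // folds
    if max(k_range) > max_train:
        raise ValueError(f"k={max(k_range)} exceeds training-fold size {max_train}")
    rows = []
    for k in k_range:
        rep = cross_validate(
            KNeighborsClassifier(n_neighbors=k, metric="euclidean"),
            X, y, folds=folds, seed=seed, refit=False,
        )
        rows.append({"k": k, "mean_cv_accuracy": rep.mean_test_accuracy})
    return pd.DataFrame(rows)


def pooled_covariance_direction(X, y):
    """Closed-form two-class Fisher direction: Sw^-1 (mu1 - mu0).

    Independent reference for full-rank data; used to validate the SVD-based
    fit, never as the production path.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = _validate_binary(y)
    x0, x1 = X[y == classes[0]], X[y == classes[1]]
    n0, n1 = len(x0), len(x1)
    s0 = np.cov(x0, rowvar=False, bias=False) * (n0 - 1)
    s1 = np.cov(x1, rowvar=False, bias=False) * (n1 - 1)
    sw = (s0 + s1) / (n0 + n1 - 2)
    return np.linalg.solve(sw, x1.mean(axis=0) - x0.mean(axis=0))
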
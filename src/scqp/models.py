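"""From-scratch regression and classification machinery.

All estimators follow the scikit-learn protocol (``fit`` / ``predict``,
``get_params`` / ``set_params``, trailing-underscore fitted attributes) so
they compose with sklearn pipelines and model selection, but every training
loop is implemented here: stochastic gradient descent with a 1/t-decayed
learning rate drives the Lasso-loss linear models (L1 handled by a proximal
soft-threshold step, so exact zeros are reachable), the epsilon-insensitive
linear SVR and the logistic classifier; the regression tree is a
variance-reduction CART limited to depth 3; the small fully connected
network (hidden layers 64-32-16-5, ReLU) trains with plain backprop SGD and
early stopping at patience 15 on a held-out validation split.

Defaults pin the study's hyperparameters: Lasso degree alpha = 0.1 for the
concentration models, SVR C = 1.5 and epsilon = 1, CART depth <= 3, K = 10
cross-validation folds.  Every fit is bit-reproducible given (data, params,
seed).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone

__all__ = [
    "Standardizer",
    "SGDLassoRegressor",
    "PolynomialLassoRegressor",
    "LinearSVRScratch",
    "CartRegressor",
    "TinyMLPRegressor",
    "SGDLogisticClassifier",
    "soft_threshold",
    "kfold_indices",
    "cross_validate",
    "make_model",
    "MODEL_KINDS",
]

DEFAULT_SEED = 20240101


def soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    """Proximal operator of t*|.|: sign(x) * max(|x| - t, 0)."""
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _check_Xy(X, y=None, *, min_rows: int = 1):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be a 2-D array with at least one feature")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if X.shape[0] < min_rows:
        raise ValueError(f"need at least {min_rows} samples, got {X.shape[0]}")
    if y is None:
        return X
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y have different lengths")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    return X, y


class Standardizer(BaseEstimator):
    """Zero-mean unit-variance feature scaling (fit on training folds only).

    Constant features get scale 1 so they pass through centered.
    """

    def fit(self, X, y=None):
        X = _check_Xy(X)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        return self

    def transform(self, X):
        X = _check_Xy(X)
        return (X - self.mean_) / self.scale_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)

    def inverse_transform(self, X):
        return np.asarray(X) * self.scale_ + self.mean_


def _minibatches(n: int, batch_size: int | None, rng: np.random.Generator):
    """Seeded shuffled minibatch index stream for one epoch."""
    if batch_size is None or batch_size >= n:
        yield np.arange(n)
        return
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start:start + batch_size]


class SGDLassoRegressor(RegressorMixin, BaseEstimator):
    """Linear regression with Lasso loss, trained by proximal SGD.

    Minimizes ``0.5 * mean((Xw + b - y)^2) + alpha * ||w||_1``; the
    intercept is not penalized.  The learning rate decays as
    ``lr / (1 + lr_decay * t)`` with t the global step counter.
    ``batch_size=None`` runs full-batch (deterministic) gradient steps,
    which the closed-form checks use; the default minibatch setting is the
    study configuration.
    """

    def __init__(self, alpha: float = 0.1, learning_rate: float = 0.01,
                 lr_decay: float = 0.01, epochs: int = 500,
                 batch_size: int | None = 16, seed: int = DEFAULT_SEED,
                 tol: float = 1e-14):
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.tol = tol

    def _design(self, X: np.ndarray) -> np.ndarray:
        return X

    def fit(self, X, y):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        X, y = _check_Xy(X, y)
        self.n_features_in_ = X.shape[1]
        Z = self._design(X)
        n, m = Z.shape
        if n < m + 2:
            raise ValueError(f"need n >= m+2 samples (n={n}, m={m})")
        rng = np.random.default_rng(self.seed)
        w = np.zeros(m)
        b = float(y.mean())  # start at the intercept-only optimum
        t = 0
        self.loss_curve_ = []
        prev = np.inf
        for _ in range(self.epochs):
            for idx in _minibatches(n, self.batch_size, rng):
                lr = self.learning_rate / (1.0 + self.lr_decay * t)
                r = Z[idx] @ w + b - y[idx]
                gw = Z[idx].T @ r / len(idx)
                gb = float(r.mean())
                w = soft_threshold(w - lr * gw, lr * self.alpha)
                b -= lr * gb
                t += 1
            r_full = Z @ w + b - y
            loss = 0.5 * float(np.mean(r_full**2))
            loss += self.alpha * float(np.abs(w).sum())
            self.loss_curve_.append(loss)
            if abs(prev - loss) < self.tol:
                break
            prev = loss
        self.coef_ = w
        self.intercept_ = b
        self.converged_ = abs(prev - self.loss_curve_[-1]) < max(self.tol, 1e-8)
        return self

    def predict(self, X):
        X = _check_Xy(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return self._design(X) @ self.coef_ + self.intercept_


class PolynomialLassoRegressor(SGDLassoRegressor):
    """Lasso-loss regression on the square-augmented feature map [x, x^2].

    Square features capture the mild curvature of the concentration-signal
    relationship; with L1 regularization the square weights shrink to zero
    when the ground truth is linear.
    """

    def _design(self, X: np.ndarray) -> np.ndarray:
        return np.hstack([X, X**2])

    def fit(self, X, y):
        super().fit(X, y)
        m = self.n_features_in_
        self.coef_linear_ = self.coef_[:m]
        self.coef_square_ = self.coef_[m:]
        return self


class LinearSVRScratch(RegressorMixin, BaseEstimator):
    """Linear epsilon-insensitive support vector regression via subgradient SGD.

    Minimizes ``0.5 * ||w||^2 + C * sum_i max(0, |y_i - (x_i.w + b)| - eps)``
    (slack variables zeta/zeta* for residuals above/below the tube).  The
    study values C = 1.5 and epsilon = 1 are the defaults.

    The regularizer makes the objective 1-strongly convex in ``w``, so the
    step size follows the classic ``1 / (t0 + t)`` schedule for strongly
    convex subgradient methods, and the returned solution averages the tail
    half of the iterates (subgradient descent itself does not converge
    pointwise on piecewise-linear losses).  The unregularized intercept has
    no strong convexity to exploit, so it is instead minimized exactly once
    per epoch: for fixed ``w`` the slack sum is piecewise linear in ``b``
    with breakpoints at ``residual +- epsilon``, and the flat minimizing
    interval is found by direct evaluation.
    """

    def __init__(self, C: float = 1.5, epsilon: float = 1.0,
                 epochs: int = 2000, batch_size: int | None = 16,
                 t0: float = 10.0, average_tail: float = 0.5,
                 seed: int = DEFAULT_SEED):
        self.C = C
        self.epsilon = epsilon
        self.epochs = epochs
        self.batch_size = batch_size
        self.t0 = t0
        self.average_tail = average_tail
        self.seed = seed

    def _objective(self, X, y, w, b):
        r = y - (X @ w + b)
        slack = np.maximum(np.abs(r) - self.epsilon, 0.0)
        return 0.5 * float(w @ w) + self.C * float(slack.sum())

    def _optimal_intercept(self, r: np.ndarray) -> float:
        """Exact minimizer over b of sum_i max(0, |r_i - b| - eps)."""
        cand = np.unique(np.concatenate([r - self.epsilon,
                                         r + self.epsilon]))
        costs = np.maximum(
            np.abs(r[None, :] - cand[:, None]) - self.epsilon, 0.0
        ).sum(axis=1)
        best = costs.min()
        flat = cand[costs <= best + 1e-12]
        return float((flat.min() + flat.max()) / 2.0)

    def fit(self, X, y):
        if self.C <= 0 or self.epsilon < 0:
            raise ValueError("need C > 0 and epsilon >= 0")
        X, y = _check_Xy(X, y)
        self.n_features_in_ = X.shape[1]
        n, m = X.shape
        rng = np.random.default_rng(self.seed)
        w = np.zeros(m)
        b = float(y.mean())
        n_batches = 1 if (self.batch_size is None or self.batch_size >= n) \
            else int(np.ceil(n / self.batch_size))
        total = self.epochs * n_batches
        avg_start = int((1.0 - self.average_tail) * total)
        w_sum, n_avg = np.zeros(m), 0
        t = 0
        self.loss_curve_ = []
        for _ in range(self.epochs):
            for idx in _minibatches(n, self.batch_size, rng):
                lr = 1.0 / (self.t0 + t)
                r = y[idx] - (X[idx] @ w + b)
                sign = np.sign(r) * (np.abs(r) > self.epsilon)
                # subgradient of the full-sum objective, batch-estimated
                scale = self.C * n / len(idx)
                w = w - lr * (w - scale * (X[idx].T @ sign))
                t += 1
                if t > avg_start:
                    w_sum += w
                    n_avg += 1
            b = self._optimal_intercept(y - X @ w)
            self.loss_curve_.append(self._objective(X, y, w, b))
        self.coef_ = w_sum / n_avg
        self.intercept_ = self._optimal_intercept(y - X @ self.coef_)
        self.final_slack_penalty_ = float(
            self.C * np.maximum(
                np.abs(y - (X @ self.coef_ + self.intercept_)) - self.epsilon,
                0.0,
            ).sum()
        )
        return self

    def predict(self, X):
        X = _check_Xy(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return X @ self.coef_ + self.intercept_


class CartRegressor(RegressorMixin, BaseEstimator):
    """Depth-limited CART regression tree with variance-reduction splits.

    Split candidates are midpoints between consecutive sorted unique feature
    values; ties in reduction break to the lowest feature index, then the
    lowest threshold.  Leaves predict the mean target.  Depth never exceeds
    ``max_depth`` (study setting: 3).  Predictions depend only on the
    ordering of samples along each feature, so any strictly monotone feature
    rescaling applied at both fit and predict time leaves them unchanged.
    """

    def __init__(self, max_depth: int = 3, min_samples_split: int = 2,
                 min_samples_leaf: int = 1):
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf

    def fit(self, X, y):
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        X, y = _check_Xy(X, y, min_rows=1)
        self.n_features_in_ = X.shape[1]
        self.tree_ = self._build(X, y, depth=0)
        self.depth_ = self._depth(self.tree_)
        return self

    def _build(self, X, y, depth):
        node = {"n": len(y), "value": float(y.mean())}
        if depth >= self.max_depth or len(y) < self.min_samples_split:
            return node
        sse = float(np.sum((y - y.mean()) ** 2))
        best = None  # (neg_reduction, feature, threshold)
        for j in range(X.shape[1]):
            xs = np.unique(X[:, j])
            if len(xs) < 2:
                continue
            for thr in (xs[:-1] + xs[1:]) / 2.0:
                left = X[:, j] <= thr
                nl = int(left.sum())
                if nl < self.min_samples_leaf or len(y) - nl < self.min_samples_leaf:
                    continue
                yl, yr = y[left], y[~left]
                child_sse = (float(np.sum((yl - yl.mean()) ** 2))
                             + float(np.sum((yr - yr.mean()) ** 2)))
                reduction = sse - child_sse
                cand = (reduction, j, float(thr))
                if best is None or (
                    cand[0] > best[0] + 1e-12
                    or (abs(cand[0] - best[0]) <= 1e-12
                        and (j, thr) < (best[1], best[2]))
                ):
                    best = cand
        if best is None or best[0] <= 1e-12:
            return node
        _, j, thr = best
        left = X[:, j] <= thr
        node.update(
            feature=j, threshold=thr,
            left=self._build(X[left], y[left], depth + 1),
            right=self._build(X[~left], y[~left], depth + 1),
        )
        return node

    def _depth(self, node):
        if "feature" not in node:
            return 0
        return 1 + max(self._depth(node["left"]), self._depth(node["right"]))

    def predict(self, X):
        X = _check_Xy(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = self.tree_
            while "feature" in node:
                node = (node["left"] if row[node["feature"]] <= node["threshold"]
                        else node["right"])
            out[i] = node["value"]
        return out

    def to_dict(self):
        """Serializable tree schema (nested dicts of feature/threshold/value)."""
        return self.tree_


class TinyMLPRegressor(RegressorMixin, BaseEstimator):
    """Small fully connected network: input -> 64 -> 32 -> 16 -> 5 -> 1.

    ReLU hidden activations, squared-error loss, plain SGD with 1/t-decayed
    learning rate, and early stopping when the validation loss has not
    improved for ``patience`` epochs (study setting: 15).  The target is
    internally centered/scaled for conditioning and restored at prediction.
    The input layer is fixed at ``expected_n_features`` (study setting: 5).
    """

    def __init__(self, hidden_layers: tuple[int, ...] = (64, 32, 16, 5),
                 learning_rate: float = 0.01, lr_decay: float = 1e-4,
                 epochs: int = 500, batch_size: int | None = 16,
                 val_fraction: float = 0.2, patience: int = 15,
                 expected_n_features: int = 5, seed: int = DEFAULT_SEED):
        self.hidden_layers = hidden_layers
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.patience = patience
        self.expected_n_features = expected_n_features
        self.seed = seed

    def _forward(self, X, weights, biases):
        acts = [X]
        for i, (W, c) in enumerate(zip(weights, biases)):
            z = acts[-1] @ W + c
            acts.append(np.maximum(z, 0.0) if i < len(weights) - 1 else z)
        return acts

    def fit(self, X, y):
        X, y = _check_Xy(X, y, min_rows=5)
        if X.shape[1] != self.expected_n_features:
            raise ValueError(
                f"expected {self.expected_n_features} input features, "
                f"got {X.shape[1]}"
            )
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        n_val = max(1, int(round(self.val_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        self._y_mean = float(y.mean())
        self._y_scale = float(y.std()) or 1.0
        ys = (y - self._y_mean) / self._y_scale
        Xtr, ytr = X[tr_idx], ys[tr_idx]
        Xva, yva = X[val_idx], ys[val_idx]

        sizes = [X.shape[1], *self.hidden_layers, 1]
        weights = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        biases = [np.zeros(s) for s in sizes[1:]]

        self.loss_curve_, self.val_loss_curve_ = [], []
        best_val, best_state, since_best = np.inf, None, 0
        t = 0
        for epoch in range(self.epochs):
            for idx in _minibatches(len(Xtr), self.batch_size, rng):
                lr = self.learning_rate / (1.0 + self.lr_decay * t)
                acts = self._forward(Xtr[idx], weights, biases)
                delta = (acts[-1].ravel() - ytr[idx])[:, None] / len(idx)
                for layer in range(len(weights) - 1, -1, -1):
                    gW = acts[layer].T @ delta
                    gb = delta.sum(axis=0)
                    if layer > 0:
                        delta = (delta @ weights[layer].T) * (acts[layer] > 0)
                    weights[layer] -= lr * gW
                    biases[layer] -= lr * gb
                t += 1
            tr_loss = float(np.mean(
                (self._forward(Xtr, weights, biases)[-1].ravel() - ytr) ** 2))
            va_loss = float(np.mean(
                (self._forward(Xva, weights, biases)[-1].ravel() - yva) ** 2))
            self.loss_curve_.append(tr_loss)
            self.val_loss_curve_.append(va_loss)
            if va_loss < best_val - 1e-12:
                best_val, since_best = va_loss, 0
                best_state = ([W.copy() for W in weights],
                              [c.copy() for c in biases])
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        self.stopped_epoch_ = len(self.loss_curve_)
        self.converged_ = since_best >= self.patience
        self.weights_, self.biases_ = best_state or (weights, biases)
        return self

    def predict(self, X):
        X = _check_Xy(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        out = self._forward(X, self.weights_, self.biases_)[-1].ravel()
        return out * self._y_scale + self._y_mean


class SGDLogisticClassifier(ClassifierMixin, BaseEstimator):
    """Binary logistic classification trained by minimizing cross-entropy
    ``-[y log p + (1-y) log(1-p)]`` with SGD.

    Probabilities are clipped to (1e-12, 1 - 1e-12) so the loss stays
    finite on separable data.
    """

    PROB_CLIP = 1e-12

    def __init__(self, learning_rate: float = 0.1, lr_decay: float = 0.001,
                 epochs: int = 500, batch_size: int | None = 16,
                 seed: int = DEFAULT_SEED):
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    def fit(self, X, y):
        X = _check_Xy(X)
        y = np.asarray(y).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have different lengths")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"need exactly two classes, got {len(self.classes_)}"
            )
        yb = (y == self.classes_[1]).astype(float)
        self.n_features_in_ = X.shape[1]
        n, m = X.shape
        rng = np.random.default_rng(self.seed)
        w = np.zeros(m)
        b = 0.0
        t = 0
        self.loss_curve_ = []
        for _ in range(self.epochs):
            for idx in _minibatches(n, self.batch_size, rng):
                lr = self.learning_rate / (1.0 + self.lr_decay * t)
                p = _sigmoid(X[idx] @ w + b)
                g = (p - yb[idx]) / len(idx)
                w -= lr * (X[idx].T @ g)
                b -= lr * float(g.sum())
                t += 1
            p_full = np.clip(_sigmoid(X @ w + b),
                             self.PROB_CLIP, 1.0 - self.PROB_CLIP)
            loss = -float(np.mean(
                yb * np.log(p_full) + (1 - yb) * np.log(1 - p_full)))
            self.loss_curve_.append(loss)
        self.coef_ = w
        self.intercept_ = b
        return self

    def predict_proba(self, X):
        X = _check_Xy(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        p1 = np.clip(_sigmoid(X @ self.coef_ + self.intercept_),
                     self.PROB_CLIP, 1.0 - self.PROB_CLIP)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def kfold_indices(
    n: int, k: int = 10, seed: int = DEFAULT_SEED
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded shuffled K-fold partition: disjoint validation folds covering
    all n samples, fold sizes differing by at most one.
    """
    if n < k:
        raise ValueError(f"need n >= K (n={n}, K={k})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i, val in enumerate(folds):
        train = np.concatenate([f for j, f in enumerate(folds) if j != i])
        out.append((np.sort(train), np.sort(val)))
    return out


def cross_validate(
    estimator, X, y, k: int = 10, seed: int = DEFAULT_SEED,
    standardize: bool = True,
) -> dict:
    """K-fold cross-validation (default K = 10) with leakage-free scaling.

    Standardization parameters are learned on each training fold only and
    applied to its validation fold.  Returns per-fold RMSE and the folds.
    """
    X, y = _check_Xy(X, y)
    folds = kfold_indices(X.shape[0], k, seed)
    rmse = []
    for train, val in folds:
        Xtr, Xva = X[train], X[val]
        if standardize:
            sc = Standardizer().fit(Xtr)
            Xtr, Xva = sc.transform(Xtr), sc.transform(Xva)
        est = clone(estimator).fit(Xtr, y[train])
        pred = est.predict(Xva)
        rmse.append(float(np.sqrt(np.mean((pred - y[val]) ** 2))))
    return {"cv_rmse": np.asarray(rmse), "folds": folds, "k": k, "seed": seed}


MODEL_KINDS = {
    "mlr": SGDLassoRegressor,
    "pr": PolynomialLassoRegressor,
    "svr": LinearSVRScratch,
    "dtr": CartRegressor,
    "nn": TinyMLPRegressor,
    "logistic": SGDLogisticClassifier,
}


def make_model(kind: str, **overrides):
    """Factory over the study's model kinds (mlr/pr/svr/dtr/nn/logistic)."""
    try:
        cls = MODEL_KINDS[kind.lower()]
    except KeyError:
        raise ValueError(
            f"unknown model kind {kind!r}; choose from {sorted(MODEL_KINDS)}"
        ) from None
    return cls(**overrides)
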
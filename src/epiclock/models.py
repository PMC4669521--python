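"""Age-prediction regression families behind one fit/predict contract.

Four estimators compete: multivariate linear regression, quadratic
(pure-squares) regression, a single-hidden-layer back-propagation neural
network, and epsilon-insensitive support vector regression with an RBF
kernel solved by SMO. All follow the scikit-learn estimator protocol
(``fit``/``predict``/``get_params``/``set_params``, fitted attributes with
a trailing underscore) without depending on scikit-learn, so they compose
with its pipelines and model-selection tools.

The headline metric throughout is MAD: the mean absolute deviation between
predicted and chronological age, in years.

SVR formulation
---------------
With standardized features X and response y, the dual problem over
z = (alpha, alpha*) in [0, C]^{2n} is

    min  1/2 z' Qbar z + p' z    s.t.  s' z = 0,

where s = (+1,...,+1,-1,...,-1), p = (eps - y, eps + y) and
Qbar = [[K, -K], [-K, K]] for the RBF Gram matrix
K(u, v) = exp(-gamma ||u - v||^2). The fitted function is
f(x) = sum_i beta_i K(x_i, x) + b with beta = alpha - alpha*. The solver is
SMO with maximal-violating-pair working-set selection, run to a KKT gap
tolerance.
"""

from __future__ import annotations

import inspect

import numpy as np
from scipy import linalg as _linalg

from .errors import ConvergenceError, ValidationError

__all__ = [
    "LinearAgeModel",
    "QuadraticAgeModel",
    "BPNNAgeModel",
    "RBFSupportVectorRegression",
    "mad",
    "rbf_kernel",
    "fit_linear",
    "fit_quadratic",
    "fit_bpnn",
    "fit_svr",
    "make_model",
]


def mad(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Mean absolute deviation between predicted and observed ages (years)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValidationError(f"shape mismatch: {predicted.shape} vs {observed.shape}")
    if predicted.size == 0:
        raise ValidationError("empty prediction vector")
    return float(np.mean(np.abs(predicted - observed)))


def rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """K(u, v) = exp(-gamma * ||u - v||^2) for rows of A against rows of B."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    d2 = (
        (A**2).sum(axis=1)[:, None]
        + (B**2).sum(axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.exp(-gamma * np.maximum(d2, 0.0))


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValidationError(f"features must be 2-D (samples x sites), got ndim={X.ndim}")
    if not np.isfinite(X).all():
        raise ValidationError("features contain missing or non-finite values")
    return X


class BaseAgeModel:
    """Minimal scikit-learn-compatible base: parameter introspection only."""

    @classmethod
    def _param_names(cls) -> list[str]:
        sig = inspect.signature(cls.__init__)
        return [p for p in sig.parameters if p != "self"]

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params) -> "BaseAgeModel":
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValidationError(f"unknown parameter {key!r} for {type(self).__name__}")
            setattr(self, key, value)
        return self

    def _check_fitted(self) -> None:
        if not getattr(self, "is_fitted_", False):
            raise ValidationError(f"{type(self).__name__} is not fitted")

    def fit_predict_mad(self, X, y) -> float:
        """Training-set (resubstitution) MAD after fitting on (X, y)."""
        self.fit(X, y)
        return mad(self.predict(X), np.asarray(y, dtype=float))


def _lstsq_with_rank_check(D: np.ndarray, y: np.ndarray, labels: list[str]) -> np.ndarray:
    """Least squares via QR with an explicit rank check.

    Rank deficiency raises, naming the dependent columns (no silent
    pseudo-inverse): the offending columns are those whose pivoted-QR
    diagonal collapses.
    """
    n, p = D.shape
    q, r, piv = _linalg.qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(n, p) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < p:
        bad = [labels[j] for j in piv[rank:]]
        raise ValidationError(f"design matrix is rank-deficient; collinear columns: {bad}")
    coef = np.linalg.solve(r[:p, :p], q.T[:p] @ y)
    out = np.empty(p)
    out[piv] = coef
    return out


class LinearAgeModel(BaseAgeModel):
    """Multivariate linear regression of age on site methylation fractions.

    Ordinary least squares with intercept; requires n > p + 1 and a
    full-rank design.
    """

    def __init__(self) -> None:
        pass

    def fit(self, X, y) -> "LinearAgeModel":
        X = _as_2d(X)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n != y.size:
            raise ValidationError(f"X has {n} rows but y has {y.size} entries")
        if n <= p + 1:
            raise ValidationError(f"need n > p + 1 (n={n}, p={p})")
        D = np.column_stack([np.ones(n), X])
        labels = ["intercept"] + [f"x{j}" for j in range(p)]
        beta = _lstsq_with_rank_check(D, y, labels)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.n_features_in_ = p
        self.is_fitted_ = True
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = _as_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.intercept_ + X @ self.coef_


class QuadraticAgeModel(BaseAgeModel):
    """Quadratic multiple regression: design [1, x_j, x_j^2], pure squares.

    No cross terms — a full second-order model in 11 sites would need more
    parameters than the 49-sample cohort can support. Requires n > 2p + 1.
    """

    def __init__(self) -> None:
        pass

    def fit(self, X, y) -> "QuadraticAgeModel":
        X = _as_2d(X)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n != y.size:
            raise ValidationError(f"X has {n} rows but y has {y.size} entries")
        if n <= 2 * p + 1:
            raise ValidationError(f"need n > 2p + 1 (n={n}, p={p})")
        D = np.column_stack([np.ones(n), X, X**2])
        labels = (
            ["intercept"]
            + [f"x{j}" for j in range(p)]
            + [f"x{j}^2" for j in range(p)]
        )
        beta = _lstsq_with_rank_check(D, y, labels)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1 : p + 1]
        self.coef_sq_ = beta[p + 1 :]
        self.n_features_in_ = p
        self.is_fitted_ = True
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = _as_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.intercept_ + X @ self.coef_ + (X**2) @ self.coef_sq_


class BPNNAgeModel(BaseAgeModel):
    """Back-propagation neural network: one sigmoid hidden layer, linear output.

    Full-batch gradient descent on standardized inputs and response for
    exactly ``max_epochs`` epochs (default 1000 training cycles) unless the
    loss plateaus below ``plateau_tol``; deterministic given ``seed``. The
    recorded ``loss_curve_`` exposes training dynamics.
    """

    def __init__(
        self,
        hidden_units: int = 3,
        max_epochs: int = 1000,
        learning_rate: float = 0.1,
        plateau_tol: float = 0.0,
        seed: int = 0,
    ) -> None:
        self.hidden_units = hidden_units
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.plateau_tol = plateau_tol
        self.seed = seed

    @staticmethod
    def _sigmoid(z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def fit(self, X, y) -> "BPNNAgeModel":
        X = _as_2d(X)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n != y.size:
            raise ValidationError(f"X has {n} rows but y has {y.size} entries")
        self.x_mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.x_scale_ = np.where(sd > 0, sd, 1.0)
        self.y_mean_ = float(y.mean())
        ysd = float(y.std())
        self.y_scale_ = ysd if ysd > 0 else 1.0
        Xs = (X - self.x_mean_) / self.x_scale_
        ys = (y - self.y_mean_) / self.y_scale_

        rng = np.random.default_rng(self.seed)
        h = self.hidden_units
        W1 = rng.normal(0.0, 1.0 / np.sqrt(max(p, 1)), size=(p, h))
        b1 = np.zeros(h)
        W2 = rng.normal(0.0, 1.0 / np.sqrt(h), size=h)
        b2 = 0.0
        lr = self.learning_rate
        losses = []
        for epoch in range(1, self.max_epochs + 1):
            A = self._sigmoid(Xs @ W1 + b1)  # (n, h)
            pred = A @ W2 + b2
            err = pred - ys
            loss = float((err**2).mean()) / 2.0
            if not np.isfinite(loss):
                raise ConvergenceError(f"non-finite loss at epoch {epoch}")
            losses.append(loss)
            # back-propagate the half-MSE loss
            g_pred = err / n
            gW2 = A.T @ g_pred
            gb2 = g_pred.sum()
            g_hidden = np.outer(g_pred, W2) * A * (1 - A)
            gW1 = Xs.T @ g_hidden
            gb1 = g_hidden.sum(axis=0)
            W1 -= lr * gW1
            b1 -= lr * gb1
            W2 -= lr * gW2
            b2 -= lr * gb2
            if (
                self.plateau_tol > 0
                and epoch > 10
                and abs(losses[-2] - losses[-1]) < self.plateau_tol
            ):
                break
        self.W1_, self.b1_, self.W2_, self.b2_ = W1, b1, W2, b2
        self.loss_curve_ = np.asarray(losses)
        self.n_features_in_ = p
        self.is_fitted_ = True
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = _as_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        Xs = (X - self.x_mean_) / self.x_scale_
        A = self._sigmoid(Xs @ self.W1_ + self.b1_)
        return self.y_mean_ + self.y_scale_ * (A @ self.W2_ + self.b2_)


class RBFSupportVectorRegression(BaseAgeModel):
    """epsilon-insensitive SVR with RBF kernel, solved by SMO.

    Defaults follow the published model: C (cost) = 2, gamma = 0.1,
    epsilon = 0.1. Features and response are standardized internally and
    predictions de-standardized — without scaling, a single gamma is
    meaningless across the beta (0-1) and age (years) scales — so epsilon
    lives on the standardized response scale. The dual is solved to a KKT
    gap below ``tol``; non-convergence within ``max_iter`` raises.

    Fitted attributes: ``dual_coef_`` (alpha - alpha* per training sample,
    standardized scale), ``intercept_``, ``support_`` (indices with nonzero
    dual coefficient), ``objective_`` (minimized dual objective),
    ``slack_total_`` (sum of epsilon-tube violations on the standardized
    scale), and the scaling parameters.
    """

    def __init__(
        self,
        C: float = 2.0,
        gamma: float = 0.1,
        epsilon: float = 0.1,
        scale: bool = True,
        tol: float = 1e-6,
        max_iter: int = 100_000,
    ) -> None:
        self.C = C
        self.gamma = gamma
        self.epsilon = epsilon
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y) -> "RBFSupportVectorRegression":
        if self.C <= 0 or self.gamma <= 0 or self.epsilon < 0:
            raise ValidationError("require C > 0, gamma > 0, epsilon >= 0")
        X = _as_2d(X)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n != y.size:
            raise ValidationError(f"X has {n} rows but y has {y.size} entries")
        if n < 2:
            raise ValidationError(f"need at least 2 samples, got {n}")

        if self.scale:
            self.x_mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.x_scale_ = np.where(sd > 0, sd, 1.0)
            self.y_mean_ = float(y.mean())
            ysd = float(y.std())
            self.y_scale_ = ysd if ysd > 0 else 1.0
        else:
            self.x_mean_ = np.zeros(p)
            self.x_scale_ = np.ones(p)
            self.y_mean_ = 0.0
            self.y_scale_ = 1.0
        Xs = (X - self.x_mean_) / self.x_scale_
        ys = (y - self.y_mean_) / self.y_scale_

        self.X_fit_ = Xs
        self.n_features_in_ = p
        if float(np.ptp(ys)) == 0.0:
            # zero response variance: the constant is optimal, no solver call
            self.dual_coef_ = np.zeros(n)
            self.intercept_ = float(ys[0])
            self.support_ = np.array([], dtype=int)
            self.objective_ = 0.0
            self.slack_total_ = 0.0
            self.n_iter_ = 0
            self.is_fitted_ = True
            return self

        K = rbf_kernel(Xs, Xs, self.gamma)
        beta, bias, objective, iters = _smo_svr(
            K, ys, self.C, self.epsilon, self.tol, self.max_iter
        )
        self.dual_coef_ = beta
        self.intercept_ = bias
        self.support_ = np.flatnonzero(np.abs(beta) > 1e-12)
        self.objective_ = objective
        resid = np.abs(K @ beta + bias - ys)
        self.slack_total_ = float(np.maximum(resid - self.epsilon, 0.0).sum())
        self.n_iter_ = iters
        self.is_fitted_ = True
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = _as_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        Xs = (X - self.x_mean_) / self.x_scale_
        if self.support_.size == 0:
            f = np.full(X.shape[0], self.intercept_)
        else:
            Kx = rbf_kernel(Xs, self.X_fit_, self.gamma)
            f = Kx @ self.dual_coef_ + self.intercept_
        return self.y_mean_ + self.y_scale_ * f


def _smo_svr(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    epsilon: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, float, int]:
    """SMO on the 2n-variable SVR dual with maximal-violating-pair selection.

    Returns (beta = alpha - alpha*, bias, minimized dual objective,
    iterations). Raises :class:`ConvergenceError` if the KKT gap does not
    fall below ``tol`` within ``max_iter`` pair updates.
    """
    n = y.size
    s = np.concatenate([np.ones(n), -np.ones(n)])
    p = np.concatenate([epsilon - y, epsilon + y])
    Q = np.block([[K, -K], [-K, K]])  # = outer(s, s) * tile(K)
    z = np.zeros(2 * n)
    G = p.copy()  # gradient of 1/2 z'Qz + p'z at z = 0
    TAU = 1e-12

    it = 0
    while True:
        minus_sG = -s * G
        up = np.where(z < C - 1e-15, True, False)
        up[n:] = z[n:] > 1e-15
        low = np.empty(2 * n, dtype=bool)
        low[:n] = z[:n] > 1e-15
        low[n:] = z[n:] < C - 1e-15
        if not up.any() or not low.any():
            break
        i = int(np.flatnonzero(up)[np.argmax(minus_sG[up])])
        j = int(np.flatnonzero(low)[np.argmin(minus_sG[low])])
        m_val, M_val = minus_sG[i], minus_sG[j]
        if m_val - M_val < tol:
            break
        if it >= max_iter:
            raise ConvergenceError(
                f"SMO did not converge in {max_iter} iterations (gap {m_val - M_val:.3g})"
            )
        a = Q[i, i] + Q[j, j] - 2.0 * s[i] * s[j] * Q[i, j]
        if a <= 0:
            a = TAU
        theta = (m_val - M_val) / a
        # box caps for the direction dz_i = s_i*theta, dz_j = -s_j*theta
        cap_i = (C - z[i]) if s[i] > 0 else z[i]
        cap_j = z[j] if s[j] > 0 else (C - z[j])
        theta = min(theta, cap_i, cap_j)
        dz_i = s[i] * theta
        dz_j = -s[j] * theta
        z[i] += dz_i
        z[j] += dz_j
        G += Q[:, i] * dz_i + Q[:, j] * dz_j
        it += 1

    beta = z[:n] - z[n:]
    objective = float(0.5 * z @ (G + p))  # since G = Qz + p
    # bias from free variables; else midpoint of the feasible interval
    free = (z > 1e-9) & (z < C - 1e-9)
    minus_sG = -s * G
    if free.any():
        bias = float(minus_sG[free].mean())
    else:
        up = np.empty(2 * n, dtype=bool)
        up[:n] = z[:n] < C - 1e-15
        up[n:] = z[n:] > 1e-15
        low = np.empty(2 * n, dtype=bool)
        low[:n] = z[:n] > 1e-15
        low[n:] = z[n:] < C - 1e-15
        hi = minus_sG[up].max() if up.any() else 0.0
        lo = minus_sG[low].min() if low.any() else 0.0
        bias = float((hi + lo) / 2.0)
    return beta, bias, objective, it


# -- thin functional wrappers ------------------------------------------------

def fit_linear(features, ages) -> LinearAgeModel:
    return LinearAgeModel().fit(features, ages)


def fit_quadratic(features, ages) -> QuadraticAgeModel:
    return QuadraticAgeModel().fit(features, ages)


def fit_bpnn(features, ages, **kwargs) -> BPNNAgeModel:
    return BPNNAgeModel(**kwargs).fit(features, ages)


def fit_svr(features, ages, **kwargs) -> RBFSupportVectorRegression:
    return RBFSupportVectorRegression(**kwargs).fit(features, ages)


_FAMILIES = {
    "linear": LinearAgeModel,
    "quadratic": QuadraticAgeModel,
    "bpnn": BPNNAgeModel,
    "svr": RBFSupportVectorRegression,
}


def make_model(family: str, **hyperparameters) -> BaseAgeModel:
    """Instantiate a model family by name: linear, quadratic, bpnn or svr."""
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise ValidationError(
            f"unknown model family {family!r}; choose from {sorted(_FAMILIES)}"
        ) from None
    return cls(**hyperparameters)
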
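"""Discriminative Vector Machine (DVM).

A per-query, representation-based classifier. For a test vector y it:

1. finds the k nearest training samples (Euclidean), X_k;
2. fits y as a linear combination X_k beta of those neighbours by
   minimising a robustly weighted, doubly regularised least squares
   objective

       (y - X_k b)' P (y - X_k b) + delta ||b||^2 + gamma_reg b' L b

   where P = diag(p_i) carries Welsch M-estimator weights
   p_i = exp(-r_i^2 / sigma^2) that downweight outlying feature
   residuals (sigma^2 = theta * r'r / d), and L = D - W is the graph
   Laplacian of the neighbours' cosine-similarity graph, pulling the
   coefficients of similar neighbours together;
3. assigns the class whose neighbours reconstruct y with the smallest
   residual norm ||y - X_{k,i} beta_{k,i}||.

Because P depends on beta, the objective is minimised by half-quadratic
alternation: starting from P = I, repeat [closed-form weighted solve;
Welsch weight update] until the coefficients stabilise. The closed form
for fixed P is

    beta = (X_k' P X_k + delta I + gamma_reg L)^{-1} X_k' P y.

Samples are *columns* of X_k in the algebra above (so X_k beta is a
d-vector and P is d x d); containers store neighbours as rows, the
field's usual layout, and transpose internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DVMParams",
    "DVMModel",
    "NeighborSet",
    "DVMSolution",
    "find_neighbors",
    "welsch_weights",
    "solve_beta",
    "predict_one",
    "predict",
    "residual_margin",
]


@dataclass(frozen=True)
class DVMParams:
    """DVM hyperparameters.

    delta is the ridge weight on ||beta||^2, gamma_reg the manifold
    (Laplacian) weight, theta the Welsch kernel-size constant. The
    defaults delta=1e-3, gamma_reg=1e-4, theta=1 are stable across a
    wide range of problems; k bounds the per-query neighbourhood
    (None = min(n_train, 40)). single_step skips the half-quadratic
    refinement and uses the one-shot P = I solve.
    """

    delta: float = 1e-3
    gamma_reg: float = 1e-4
    theta: float = 1.0
    k: int | None = None
    max_iter: int = 50
    tol: float = 1e-6
    single_step: bool = False

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.gamma_reg <= 0 or self.theta <= 0:
            raise ValueError("delta, gamma_reg and theta must all be > 0")
        if self.k is not None and self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


@dataclass(frozen=True)
class DVMModel:
    """Stored training set: the DVM is instance-based, so 'fitting' is
    retaining the (n x d) feature matrix and integer class labels."""

    train_features: np.ndarray
    train_labels: np.ndarray
    params: DVMParams = field(default_factory=DVMParams)

    def __post_init__(self) -> None:
        X = np.asarray(self.train_features, dtype=float)
        labels = np.asarray(self.train_labels)
        if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError(f"train_features must be n x d, got shape {X.shape}")
        if labels.shape != (X.shape[0],):
            raise ValueError("train_labels length must match feature rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("train_features must be finite")
        object.__setattr__(self, "train_features", X)
        object.__setattr__(self, "train_labels", labels.astype(np.int64))

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.train_labels)

    @property
    def effective_k(self) -> int:
        n = self.train_features.shape[0]
        return min(n, 40) if self.params.k is None else min(n, self.params.k)


@dataclass(frozen=True)
class NeighborSet:
    """The k nearest training rows to one query, plus their similarity
    graph: W (cosine similarity, clipped to [0,1], diagonal 1), degree
    matrix D, and Laplacian L = D - W."""

    indices: np.ndarray
    Xk: np.ndarray        # k x d, rows = neighbours
    labels: np.ndarray
    W: np.ndarray
    D: np.ndarray
    L: np.ndarray


@dataclass(frozen=True)
class DVMSolution:
    """Converged per-query fit: coefficients, final Welsch weights and
    kernel size, per-class reconstruction residuals, predicted class."""

    beta: np.ndarray
    weights: np.ndarray   # diagonal of P, length d
    sigma: float
    residuals: dict[int, float]
    predicted: int
    neighbors: NeighborSet
    n_iter: int


def _cosine_similarity_graph(Xk: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of the neighbour rows, clipped to
    [0, 1] so large w_pq always means 'pull these coefficients together';
    zero-norm rows get similarity 0 to everything, diagonal forced to 1."""
    norms = np.linalg.norm(Xk, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = Xk / safe[:, None]
    W = unit @ unit.T
    W[norms == 0, :] = 0.0
    W[:, norms == 0] = 0.0
    np.clip(W, 0.0, 1.0, out=W)
    np.fill_diagonal(W, 1.0)
    return W


def find_neighbors(model: DVMModel, y: np.ndarray, k: int | None = None) -> NeighborSet:
    """The k training rows nearest to y in Euclidean distance (ties broken
    by training index), with their similarity graph and Laplacian."""
    y = np.asarray(y, dtype=float).ravel()
    X = model.train_features
    if y.shape[0] != X.shape[1]:
        raise ValueError(f"query has dim {y.shape[0]}, model expects {X.shape[1]}")
    k = model.effective_k if k is None else k
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds {X.shape[0]} training samples")

    dists = np.linalg.norm(X - y, axis=1)
    order = np.argsort(dists, kind="stable")[:k]
    Xk = X[order]
    W = _cosine_similarity_graph(Xk)
    D = np.diag(W.sum(axis=1))
    return NeighborSet(
        indices=order,
        Xk=Xk,
        labels=model.train_labels[order],
        W=W,
        D=D,
        L=D - W,
    )


def welsch_weights(
    y: np.ndarray,
    Xk: np.ndarray,
    beta: np.ndarray,
    theta: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Welsch M-estimator weights from the current fit.

    With feature residual r = y - Xk' beta (length d), the kernel size is
    sigma^2 = theta * r'r / d and each weight p_i = exp(-r_i^2 / sigma^2),
    so the largest residual coordinate always gets the smallest weight.
    A perfect fit (r = 0) yields all weights 1 by convention.
    """
    y = np.asarray(y, dtype=float).ravel()
    r = y - np.asarray(Xk, dtype=float).T @ np.asarray(beta, dtype=float)
    ss = float(r @ r)
    d = y.shape[0]
    if ss == 0.0:
        return np.ones(d), 0.0
    sigma_sq = theta * ss / d
    return np.exp(-(r ** 2) / sigma_sq), float(np.sqrt(sigma_sq))


def solve_beta(
    y: np.ndarray,
    Xk: np.ndarray,
    P: np.ndarray,
    L: np.ndarray,
    delta: float = 1e-3,
    gamma_reg: float = 1e-4,
) -> np.ndarray:
    """Closed-form coefficients for fixed Welsch weights.

    Solves (X' P X + delta I + gamma_reg L) beta = X' P y with X = Xk'
    (samples as columns). delta > 0 makes the system positive definite;
    a numerically singular system raises with its condition number.
    """
    y = np.asarray(y, dtype=float).ravel()
    A = np.asarray(Xk, dtype=float).T            # d x k, samples as columns
    p = np.diag(P) if np.ndim(P) == 2 else np.asarray(P, dtype=float)
    PA = A * p[:, None]
    lhs = A.T @ PA + delta * np.eye(A.shape[1]) + gamma_reg * np.asarray(L, dtype=float)
    rhs = A.T @ (p * y)
    try:
        beta = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"DVM inner system singular (cond={np.linalg.cond(lhs):.3e})"
        ) from exc
    resid = np.linalg.norm(lhs @ beta - rhs)
    scale = max(np.linalg.norm(rhs), 1.0)
    if resid / scale > 1e-8:
        warnings.warn(
            f"DVM inner solve inaccurate (relative residual {resid / scale:.2e}; "
            f"cond={np.linalg.cond(lhs):.3e})",
            RuntimeWarning,
        )
    return beta


def _objective(
    y: np.ndarray,
    A: np.ndarray,
    beta: np.ndarray,
    p: np.ndarray,
    L: np.ndarray,
    delta: float,
    gamma_reg: float,
) -> float:
    """Fixed-P objective value (used by the monotonicity diagnostics)."""
    r = y - A @ beta
    return float(r @ (p * r) + delta * beta @ beta + gamma_reg * beta @ L @ beta)


def predict_one(model: DVMModel, y: np.ndarray) -> DVMSolution:
    """Classify one query by half-quadratic DVM fitting.

    Iterates the closed-form solve and the Welsch weight update from
    P = I until the coefficients move less than tol (sup-norm) or
    max_iter is reached (a single solve when params.single_step). The
    per-class residual R_i = ||y - X_{k,i} beta_{k,i}|| uses only the
    neighbour columns of class i; a class absent from the neighbourhood
    gets the empty-dictionary fit R_i = ||y||. Prediction is the argmin
    residual, ties broken toward the smaller class id.
    """
    prm = model.params
    y = np.asarray(y, dtype=float).ravel()
    nb = find_neighbors(model, y)
    A = nb.Xk.T  # d x k

    p = np.ones(y.shape[0])
    sigma = 0.0
    beta = solve_beta(y, nb.Xk, p, nb.L, prm.delta, prm.gamma_reg)
    n_iter = 1
    if not prm.single_step:
        for n_iter in range(2, prm.max_iter + 1):
            p, sigma = welsch_weights(y, nb.Xk, beta, prm.theta)
            beta_new = solve_beta(y, nb.Xk, p, nb.L, prm.delta, prm.gamma_reg)
            step = float(np.max(np.abs(beta_new - beta)))
            beta = beta_new
            if step < prm.tol:
                break

    residuals: dict[int, float] = {}
    y_norm = float(np.linalg.norm(y))
    for cls in model.classes:
        mask = nb.labels == cls
        if not mask.any():
            residuals[int(cls)] = y_norm
        else:
            residuals[int(cls)] = float(np.linalg.norm(y - A[:, mask] @ beta[mask]))
    # ties toward the smaller class id: min over sorted class keys is stable
    predicted = min(sorted(residuals), key=lambda c: residuals[c])
    return DVMSolution(
        beta=beta,
        weights=p,
        sigma=sigma,
        residuals=residuals,
        predicted=predicted,
        neighbors=nb,
        n_iter=n_iter,
    )


def predict(model: DVMModel, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise batch classification.

    Returns (labels, residual matrix) where residuals has one column per
    class in ascending class-id order.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        Y = Y.reshape(-1, model.train_features.shape[1])
    if Y.shape[1] != model.train_features.shape[1] and Y.size > 0:
        raise ValueError(
            f"query width {Y.shape[1]} != model dimension {model.train_features.shape[1]}"
        )
    classes = model.classes
    labels = np.empty(Y.shape[0], dtype=np.int64)
    residuals = np.empty((Y.shape[0], classes.size))
    for i, row in enumerate(Y):
        sol = predict_one(model, row)
        labels[i] = sol.predicted
        residuals[i] = [sol.residuals[int(c)] for c in classes]
    return labels, residuals


def residual_margin(residuals: np.ndarray) -> np.ndarray:
    """Scale-free decision score (R_1 - R_2)/(R_1 + R_2) for two-class
    residuals: positive when class 2 (interacting) reconstructs the query
    better, zero when the two residuals tie or both vanish."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 2 or residuals.shape[1] != 2:
        raise ValueError("residual_margin expects an n x 2 residual matrix")
    r1, r2 = residuals[:, 0], residuals[:, 1]
    denom = r1 + r2
    out = np.zeros_like(denom)
    np.divide(r1 - r2, denom, out=out, where=denom > 0)
    return out
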
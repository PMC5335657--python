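"""Joint multi-task objective and its alternating Sylvester-equation solver.

The model fits one F x C weight matrix per future time point to a shared
baseline design matrix, coupling the tasks through three graph-smoothness
penalties (feature-feature, subject-subject, score-score) and an l2,1
penalty on the row-wise unfolding of all weight matrices:

    sum_t ||Y(t) - X W(t)||_F^2
      + lambda1 * sum_t [ Tr(W(t)' L_f W(t))
                          + Tr((X W(t))' L_s X W(t))
                          + Tr(W(t) L_c(t) W(t)') ]
      + lambda2 * sum_i ||w_i||_2           (rows of the unfolded stack)

Each regularizer is defined BY its trace form; the equivalent explicit
pairwise double-sum equals twice the trace (both orderings of each pair are
summed), a constant absorbed by lambda1.

Minimization alternates between (a) rebuilding the diagonal IRLS matrix for
the l2,1 term from the current unfolded weights and (b) solving, for each
time point, the stationarity condition

    (X'X + lambda1 L_f + lambda1 X' L_s X + lambda2 D) W(t)
        + W(t) (lambda1 L_c(t)) = X' Y(t),

a Sylvester equation solved in closed form.  Because each sweep exactly
minimizes a convex majorizer of the objective, the objective value is
non-increasing across iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_sylvester as _scipy_sylvester

from .datatypes import FeatureMatrix, ScoreTensor, WeightStack
from .graphs import (
    feature_similarity,
    l21_reweight_diag,
    laplacian,
    score_similarity,
    subject_similarity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "RelationGraphs",
    "build_graphs",
    "regularizer_feature",
    "regularizer_subject",
    "regularizer_score",
    "objective",
    "solve_sylvester_step",
    "fit",
]


@dataclass
class FitConfig:
    """Hyperparameters of the joint model and its optimizer.

    lambda1 weighs the three relation regularizers (a single shared weight),
    lambda2 the l2,1 row-sparsity penalty.  ``sigma=None`` uses the plain
    heat kernel exp(-d^2); a positive sigma rescales to exp(-d^2/(2 sigma^2)).
    ``ridge`` adds a small multiple of the identity to the Sylvester A matrix
    for rank-deficient corner cases (off by default).
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    max_iter: int = 50
    tol: float = 1e-6
    epsilon_l21: float = 1e-8
    sigma: float | None = None
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization weights must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.epsilon_l21 <= 0:
            raise ValueError("epsilon_l21 must be positive")


@dataclass
class RelationGraphs:
    """Pre-built Laplacians: L_f (F x F), L_s (S x S), L_c per time (C x C)."""

    feature: np.ndarray
    subject: np.ndarray
    score_per_time: list[np.ndarray]


@dataclass
class FitResult:
    weights: WeightStack
    objective_trace: list[float]
    n_iter: int
    converged: bool
    row_norms: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.row_norms is None:
            self.row_norms = self.weights.row_norms()


def _values(x) -> np.ndarray:
    if isinstance(x, FeatureMatrix):
        return x.values
    return np.asarray(x, dtype=float)


def _score_values(y) -> np.ndarray:
    if isinstance(y, ScoreTensor):
        return y.values
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("scores must be a (T, S, C) array")
    return y


def build_graphs(x, y, sigma: float | None = None) -> RelationGraphs:
    """Construct the three relation Laplacians from the training data.

    L_f and L_s depend on X only; one L_c is built per time point from the
    corresponding score matrix.  None of them depend on the weights, so they
    are built once per fit.
    """
    xv = _values(x)
    yv = _score_values(y)
    l_f = laplacian(feature_similarity(xv, sigma))
    l_s = laplacian(subject_similarity(xv, sigma))
    l_c = [laplacian(score_similarity(yv[t], sigma)) for t in range(yv.shape[0])]
    return RelationGraphs(feature=l_f, subject=l_s, score_per_time=l_c)


def regularizer_feature(w_t: np.ndarray, l_f: np.ndarray) -> float:
    """Feature-smoothness penalty Tr(W' L_f W) over the rows of W."""
    w_t = np.asarray(w_t, dtype=float)
    if l_f.shape[0] != w_t.shape[0]:
        raise ValueError(
            f"L_f is {l_f.shape[0]}x{l_f.shape[1]} but W has {w_t.shape[0]} rows"
        )
    return float(np.trace(w_t.T @ l_f @ w_t))


def regularizer_subject(w_t: np.ndarray, x, l_s: np.ndarray) -> float:
    """Subject-smoothness penalty Tr((XW)' L_s XW) on predicted scores."""
    xv = _values(x)
    w_t = np.asarray(w_t, dtype=float)
    if xv.shape[1] != w_t.shape[0]:
        raise ValueError("X columns must match W rows")
    if l_s.shape[0] != xv.shape[0]:
        raise ValueError("L_s must be S x S")
    xw = xv @ w_t
    return float(np.trace(xw.T @ l_s @ xw))


def regularizer_score(w_t: np.ndarray, l_c_t: np.ndarray) -> float:
    """Score-smoothness penalty Tr(W L_c W') over the columns of W."""
    w_t = np.asarray(w_t, dtype=float)
    if l_c_t.shape[0] != w_t.shape[1]:
        raise ValueError(
            f"L_c is {l_c_t.shape[0]}x{l_c_t.shape[1]} but W has {w_t.shape[1]} columns"
        )
    return float(np.trace(w_t @ l_c_t @ w_t.T))


def objective(x, y, w: WeightStack, cfg: FitConfig, graphs: RelationGraphs) -> float:
    """Full objective value: squared loss + relation penalties + l2,1 norm."""
    xv = _values(x)
    yv = _score_values(y)
    t_pts = yv.shape[0]
    if w.n_timepoints != t_pts:
        raise ValueError("weight stack and score tensor disagree on T")
    if xv.shape[1] != w.n_features:
        raise ValueError("X columns must match weight rows")
    total = 0.0
    for t in range(t_pts):
        w_t = w.per_time[t]
        resid = yv[t] - xv @ w_t
        total += float(np.sum(resid**2))
        if cfg.lambda1 > 0:
            total += cfg.lambda1 * (
                regularizer_feature(w_t, graphs.feature)
                + regularizer_subject(w_t, xv, graphs.subject)
                + regularizer_score(w_t, graphs.score_per_time[t])
            )
    if cfg.lambda2 > 0:
        total += cfg.lambda2 * float(np.sum(w.row_norms()))
    return total


def _factored_solve(
    a_vals: np.ndarray,
    a_vecs: np.ndarray,
    b_vals: np.ndarray,
    b_vecs: np.ndarray,
    q: np.ndarray,
) -> np.ndarray:
    """Solve AW + WB = Q given eigendecompositions of symmetric A and B.

    In the joint eigenbasis the equation is diagonal: each transformed entry
    divides by (alpha_i + beta_j), which must be bounded away from zero.
    """
    denom = a_vals[:, None] + b_vals[None, :]
    scale = max(np.abs(a_vals).max(), np.abs(b_vals).max(), 1.0)
    if np.min(np.abs(denom)) <= 1e-14 * scale:
        raise ValueError(
            "A and -B share an eigenvalue; the Sylvester system is singular "
            "— try a positive ridge"
        )
    qt = a_vecs.T @ q @ b_vecs
    return a_vecs @ (qt / denom) @ b_vecs.T


def _check_and_refine(a, b, q, w, solver) -> np.ndarray:
    """Validate the relative residual, applying up to two refinement solves.

    Badly scaled IRLS loadings (rows clipped at epsilon push diagonal
    entries to ~lambda2 * 5e7) can leave a first-pass residual slightly
    above tolerance even though the system is perfectly solvable.
    """
    denom = max(np.linalg.norm(q), 1.0)
    if not np.all(np.isfinite(w)):
        raise ValueError(
            "Sylvester solution is non-finite; the system is singular — "
            "try a positive ridge"
        )
    resid = np.linalg.norm(a @ w + w @ b - q) / denom
    for _ in range(2):
        if resid <= 1e-8:
            break
        w = w + solver(q - (a @ w + w @ b))
        resid = np.linalg.norm(a @ w + w @ b - q) / denom
    if resid > 1e-8:
        raise ValueError(
            f"Sylvester residual {resid:.3e} exceeds 1e-8; the system is "
            "ill-conditioned — try a positive ridge"
        )
    return w


def solve_sylvester_step(a: np.ndarray, b: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Solve AW + WB = Q for W, validating the residual.

    Symmetric A and B (the only case the optimizer produces: Gram plus
    Laplacians plus diagonal loading) are solved by joint eigendecomposition;
    anything else falls back to scipy's Bartels-Stewart solver.  The solve
    is well-posed iff the spectra of A and -B are disjoint.

    Raises
    ------
    ValueError
        If the computed solution is non-finite or its relative residual
        exceeds 1e-8 (shared eigenvalue / ill-conditioned system); the
        message advises increasing the ridge.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    q = np.asarray(q, dtype=float)
    symmetric = np.allclose(a, a.T, atol=1e-12) and np.allclose(b, b.T, atol=1e-12)
    if symmetric:
        a_vals, a_vecs = np.linalg.eigh(a)
        b_vals, b_vecs = np.linalg.eigh(b)
        solver = lambda rhs: _factored_solve(a_vals, a_vecs, b_vals, b_vecs, rhs)
    else:
        def solver(rhs):
            try:
                return _scipy_sylvester(a, b, rhs)
            except Exception as exc:  # pragma: no cover - scipy failure path
                raise ValueError(
                    "Sylvester solve failed (A and -B may share an "
                    "eigenvalue); try a positive ridge"
                ) from exc
    w = solver(q)
    return _check_and_refine(a, b, q, w, solver)


def _initial_weights(xv: np.ndarray, yv: np.ndarray) -> WeightStack:
    """Ridge-regularized least squares per time point, W0 = (X'X + 1e-3 I)^-1 X'Y."""
    f = xv.shape[1]
    gram = xv.T @ xv + 1e-3 * np.eye(f)
    per_time = np.stack([np.linalg.solve(gram, xv.T @ yv[t]) for t in range(yv.shape[0])])
    return WeightStack(per_time)


def fit(x, y, cfg: FitConfig | None = None) -> FitResult:
    """Minimize the joint objective by alternating Sylvester solves.

    The relation Laplacians are built once from the data; only the diagonal
    l2,1 reweighting matrix is rebuilt each iteration.  Iteration stops when
    the squared Frobenius norm of the change in the unfolded weights drops
    below ``cfg.tol`` or after ``cfg.max_iter`` sweeps.  The recorded
    objective trace (initial value plus one entry per sweep) is
    non-increasing.
    """
    if cfg is None:
        cfg = FitConfig()
    xv = _values(x)
    yv = _score_values(y)
    if xv.ndim != 2:
        raise ValueError("X must be 2-D")
    s, f = xv.shape
    t_pts, s_y, c = yv.shape
    if s_y != s:
        raise ValueError(f"X has {s} subjects but scores have {s_y}")
    if s < 2 or f < 1 or t_pts < 1:
        raise ValueError("need S >= 2, F >= 1, T >= 1")

    graphs = build_graphs(xv, yv, cfg.sigma)
    gram = xv.T @ xv
    a_fixed = gram + cfg.lambda1 * graphs.feature + cfg.lambda1 * (xv.T @ graphs.subject @ xv)
    if cfg.ridge > 0:
        a_fixed = a_fixed + cfg.ridge * np.eye(f)
    q_per_time = [xv.T @ yv[t] for t in range(t_pts)]
    b_per_time = [cfg.lambda1 * graphs.score_per_time[t] for t in range(t_pts)]
    # B is constant across iterations; factor it once per time point.
    b_eigs = [np.linalg.eigh(b) for b in b_per_time]

    weights = _initial_weights(xv, yv)
    trace = [objective(xv, yv, weights, cfg, graphs)]
    converged = False
    n_iter = 0
    for r in range(1, cfg.max_iter + 1):
        n_iter = r
        prev_unfolded = weights.unfolded
        if cfg.lambda2 > 0:
            d = l21_reweight_diag(prev_unfolded, cfg.epsilon_l21)
            a = a_fixed + cfg.lambda2 * d
        else:
            a = a_fixed
        a_vals, a_vecs = np.linalg.eigh(a)
        new_per_time = np.empty_like(weights.per_time)
        for t in range(t_pts):
            b_vals, b_vecs = b_eigs[t]
            solver = lambda rhs: _factored_solve(a_vals, a_vecs, b_vals, b_vecs, rhs)
            w_t = solver(q_per_time[t])
            new_per_time[t] = _check_and_refine(
                a, b_per_time[t], q_per_time[t], w_t, solver
            )
        weights = WeightStack(new_per_time)
        if not np.all(np.isfinite(weights.per_time)):
            raise ValueError(f"non-finite weights at iteration {r}")
        trace.append(objective(xv, yv, weights, cfg, graphs))
        change = np.linalg.norm(weights.unfolded - prev_unfolded)
        logger.debug(
            "iter %d objective=%.6e weight_change=%.3e", r, trace[-1], change
        )
        if change**2 < cfg.tol:
            converged = True
            break
    return FitResult(
        weights=weights,
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
    )
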
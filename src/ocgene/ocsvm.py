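"""From-scratch nu-one-class SVM and SVDD solved in the dual.

The one-class SVM (Schölkopf-style nu formulation) separates the training
class from the origin in feature space with maximum margin.  Its dual is the
box-and-simplex quadratic program

    minimize    1/2 a' K a
    subject to  0 <= a_i <= 1/(nu * l),   sum_i a_i = 1,

where K is the kernel Gram matrix of the l training points.  The offset rho
is recovered from the KKT conditions at the margin support vectors, and the
decision score of a query x is  sum_i a_i k(x_i, x) - rho:  non-negative
scores are inliers, negative scores outliers.

Support vector data description (SVDD) instead encloses the training class
in a minimum-radius hypersphere; its dual is

    maximize    sum_i a_i k(x_i, x_i) - a' K a
    subject to  0 <= a_i <= C,   sum_i a_i = 1.

For kernels with constant diagonal (e.g. RBF) and C = 1/(nu*l) the two duals
coincide up to a constant, so both models predict the same labels.

Both duals are solved by the same SMO-style maximal-violating-pair solver
(`_solve_simplex_box_qp`); `qp_oracle` is an independent generic-solver
route used only for validation at small l.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger("ocgene")

#: default rejection fraction when the caller does not choose one
DEFAULT_NU = 0.05
#: support vectors are points with alpha above this fraction of max(alpha)
SV_REL_TOL = 1e-7
#: convergence tolerance on the maximal KKT violation (bounds the duality gap)
QP_TOL = 1e-8

INLIER = 1
OUTLIER = -1

__version__ = "0.1.0"


class OCSVMError(ValueError):
    """Raised on invalid parameters or inputs to the one-class solvers."""


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice for the one-class models.

    Parameters
    ----------
    kind:
        ``"linear"`` (k(x, y) = x . y) or ``"rbf"``
        (k(x, y) = exp(-gamma ||x - y||^2)).
    gamma:
        RBF width.  ``None`` means "1 / n_features", resolved when the model
        is fitted.  Ignored for the linear kernel.
    """

    kind: str = "linear"
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise OCSVMError(f"unknown kernel kind {self.kind!r}; use 'linear' or 'rbf'")
        if self.kind == "rbf" and self.gamma is not None and not self.gamma > 0:
            raise OCSVMError(f"rbf gamma must be positive, got {self.gamma}")

    def resolve(self, n_features: int) -> "KernelSpec":
        """Return a spec with a concrete gamma (1/d default for RBF)."""
        if self.kind == "rbf" and self.gamma is None:
            return KernelSpec("rbf", 1.0 / n_features)
        return self


def kernel_matrix(X: np.ndarray, Y: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Gram matrix k(X_i, Y_j) for the given kernel.

    ``X`` is l x d and ``Y`` is m x d; the result is l x m.  For ``Y = X``
    the result is symmetric positive semidefinite.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if Y.ndim == 1:
        Y = Y[None, :]
    if X.shape[1] != Y.shape[1]:
        raise OCSVMError(
            f"feature dimension mismatch: X has shape {X.shape}, Y has shape {Y.shape}"
        )
    if kernel.kind == "linear":
        return X @ Y.T
    gamma = kernel.gamma
    if gamma is None:
        gamma = 1.0 / X.shape[1]
    return np.exp(-gamma * cdist(X, Y, "sqeuclidean"))


# ---------------------------------------------------------------------------
# shared dual solver
# ---------------------------------------------------------------------------


def _solve_simplex_box_qp(
    Q: np.ndarray,
    p: np.ndarray,
    ub: float,
    tol: float = QP_TOL,
    max_iter: int | None = None,
) -> np.ndarray:
    """Minimize 1/2 a'Qa + p'a  s.t.  sum a = 1,  0 <= a_i <= ub.

    SMO-style solver: at each step the maximal-violating pair (i, j) is
    selected from the gradient g = Qa + p -- i the best coordinate that can
    still grow, j the worst that can still shrink -- and mass is transferred
    from j to i by the unconstrained-optimal step clipped to the box.  The
    maximal violation g_j - g_i bounds the duality gap (the simplex has unit
    mass), so iteration stops once it falls below ``tol``.
    """
    l = len(p)
    if not ub * l >= 1.0 - 1e-12:
        raise OCSVMError(f"infeasible box: upper bound {ub} with {l} variables cannot sum to 1")
    alpha = np.full(l, 1.0 / l)
    g = Q @ alpha + p
    if max_iter is None:
        max_iter = max(20000, 200 * l)
    eps = 1e-12
    for _ in range(max_iter):
        can_up = alpha < ub - eps
        can_dn = alpha > eps
        gi = np.where(can_up, g, np.inf)
        gj = np.where(can_dn, g, -np.inf)
        i = int(np.argmin(gi))
        j = int(np.argmax(gj))
        viol = gj[j] - gi[i]
        if viol <= tol:
            break
        q = Q[i, i] + Q[j, j] - 2.0 * Q[i, j]
        step = viol / q if q > eps else np.inf
        step = min(step, ub - alpha[i], alpha[j])
        alpha[i] += step
        alpha[j] -= step
        g += step * (Q[:, i] - Q[:, j])
    else:
        logger.warning("QP solver hit max_iter=%d with violation %.3g", max_iter, viol)
    return alpha


def _kkt_interval(g: np.ndarray, alpha: np.ndarray, ub: float, atol: float):
    """KKT-admissible interval for the threshold: [max g over bound-alpha,
    min g over zero-alpha]; either side may be empty."""
    at_ub = alpha >= ub - atol
    at_lo = alpha <= atol
    lo = float(np.max(g[at_ub])) if at_ub.any() else -np.inf
    hi = float(np.min(g[at_lo])) if at_lo.any() else np.inf
    return lo, hi


def _threshold_from_kkt(g: np.ndarray, alpha: np.ndarray, ub: float, atol: float) -> float:
    margin = (alpha > atol) & (alpha < ub - atol)
    if margin.any():
        return float(np.mean(g[margin]))
    lo, hi = _kkt_interval(g, alpha, ub, atol)
    if np.isfinite(lo) and np.isfinite(hi):
        return 0.5 * (lo + hi)
    if np.isfinite(lo):
        return lo
    if np.isfinite(hi):
        return hi
    return float(np.mean(g))


# ---------------------------------------------------------------------------
# nu-one-class SVM
# ---------------------------------------------------------------------------


@dataclass
class OCSVMModel:
    """Fitted nu-one-class SVM.

    ``alphas`` holds all l dual coefficients (most are zero); the implicit
    normal vector is w = sum_i alphas[i] phi(x_i).  ``slacks`` are the solved
    margin violations xi_i = max(0, rho - f_raw(x_i)).
    """

    alphas: np.ndarray
    rho: float
    nu: float
    kernel: KernelSpec
    support_vectors: np.ndarray
    sv_alphas: np.ndarray
    slacks: np.ndarray
    n_features: int
    dual_objective: float = field(default=float("nan"))


def fit_ocsvm(
    X: np.ndarray,
    kernel: KernelSpec = KernelSpec("linear"),
    nu: float = DEFAULT_NU,
) -> OCSVMModel:
    """Fit the nu-one-class SVM by solving its dual QP.

    Parameters
    ----------
    X:
        l x d training matrix (the target class only).
    kernel:
        Kernel specification; RBF gamma defaults to 1/d when unset.
    nu:
        Rejection fraction in (0, 1): an upper bound on the fraction of
        training points scored negative and a lower bound on the fraction of
        support vectors.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not 0.0 < nu < 1.0:
        raise OCSVMError(f"nu must lie in (0, 1), got {nu}")
    if not np.all(np.isfinite(X)):
        raise OCSVMError("training matrix contains non-finite values")
    l, d = X.shape
    if l < 1:
        raise OCSVMError("need at least one training point")
    kernel = kernel.resolve(d)
    K = kernel_matrix(X, X, kernel)
    ub = 1.0 / (nu * l)
    if l == 1:
        alpha = np.array([1.0])
    else:
        alpha = _solve_simplex_box_qp(K, np.zeros(l), ub)
    g = K @ alpha
    atol = max(SV_REL_TOL * alpha.max(), 1e-12)
    rho = _threshold_from_kkt(g, alpha, ub, atol)
    sv_mask = alpha > atol
    slacks = np.maximum(0.0, rho - g)
    return OCSVMModel(
        alphas=alpha,
        rho=rho,
        nu=nu,
        kernel=kernel,
        support_vectors=X[sv_mask].copy(),
        sv_alphas=alpha[sv_mask].copy(),
        slacks=slacks,
        n_features=d,
        dual_objective=float(0.5 * alpha @ K @ alpha),
    )


def decision_function(model: OCSVMModel, X: np.ndarray) -> np.ndarray:
    """Signed score sum_i a_i k(x_i, x) - rho for each row of X.

    Non-negative scores are inliers (members of the trained class),
    negative scores outliers.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise OCSVMError(
            f"query has {X.shape[1]} features but model was trained with {model.n_features}"
        )
    Kq = kernel_matrix(model.support_vectors, X, model.kernel)
    return model.sv_alphas @ Kq - model.rho


def predict(model: OCSVMModel, X: np.ndarray) -> np.ndarray:
    """Labels: +1 (inlier) where score >= 0, -1 (outlier) otherwise.

    A score of exactly zero is an inlier.
    """
    scores = decision_function(model, X)
    return np.where(scores >= 0.0, INLIER, OUTLIER)


# ---------------------------------------------------------------------------
# SVDD
# ---------------------------------------------------------------------------


@dataclass
class SVDDModel:
    """Fitted support vector data description (minimum enclosing hypersphere).

    The sphere center is sum_i alphas[i] phi(x_i); ``radius_sq`` is R^2.
    """

    alphas: np.ndarray
    radius_sq: float
    C: float
    kernel: KernelSpec
    support_vectors: np.ndarray
    sv_alphas: np.ndarray
    n_features: int
    center_sq_norm: float
    dual_objective: float = field(default=float("nan"))


def fit_svdd(
    X: np.ndarray,
    kernel: KernelSpec = KernelSpec("rbf"),
    C: float = 1.0,
) -> SVDDModel:
    """Fit SVDD: the smallest hypersphere in feature space containing the
    target class, with box penalty C on points left outside.

    Requires C >= 1/l, otherwise the constraint sum(alpha) = 1 is
    infeasible.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise OCSVMError("training matrix contains non-finite values")
    l, d = X.shape
    if not C > 0:
        raise OCSVMError(f"C must be positive, got {C}")
    if C * l < 1.0 - 1e-12:
        raise OCSVMError(
            f"C={C} is infeasible for l={l} training points: need C >= 1/l = {1.0 / l:.6g} "
            "so the dual coefficients can sum to 1"
        )
    kernel = kernel.resolve(d)
    K = kernel_matrix(X, X, kernel)
    diag = np.diag(K).copy()
    if l == 1:
        alpha = np.array([1.0])
    else:
        # dual max sum a_i K_ii - a'Ka  ==  min 1/2 a'(2K)a - diag'a
        alpha = _solve_simplex_box_qp(2.0 * K, -diag, C)
    g = K @ alpha
    center_sq = float(alpha @ g)
    dist_sq = diag - 2.0 * g + center_sq
    atol = max(SV_REL_TOL * alpha.max(), 1e-12)
    if l == 1:
        radius_sq = 0.0
    else:
        margin = (alpha > atol) & (alpha < C - atol)
        if margin.any():
            radius_sq = float(np.mean(dist_sq[margin]))
        else:
            # KKT: inside points (alpha=0) have dist^2 <= R^2 <= dist^2 of
            # penalized points (alpha=C); take the midpoint of that interval
            at_lo = alpha <= atol
            at_ub = alpha >= C - atol
            lo = float(np.max(dist_sq[at_lo])) if at_lo.any() else -np.inf
            hi = float(np.min(dist_sq[at_ub])) if at_ub.any() else np.inf
            if np.isfinite(lo) and np.isfinite(hi):
                radius_sq = 0.5 * (lo + hi)
            elif np.isfinite(lo):
                radius_sq = lo
            elif np.isfinite(hi):
                radius_sq = hi
            else:
                radius_sq = float(np.mean(dist_sq))
        radius_sq = max(radius_sq, 0.0)
    sv_mask = alpha > atol
    return SVDDModel(
        alphas=alpha,
        radius_sq=radius_sq,
        C=C,
        kernel=kernel,
        support_vectors=X[sv_mask].copy(),
        sv_alphas=alpha[sv_mask].copy(),
        n_features=d,
        center_sq_norm=center_sq,
        dual_objective=float(alpha @ diag - alpha @ g),
    )


def svdd_decision(model: SVDDModel, X: np.ndarray) -> np.ndarray:
    """Score R^2 - ||phi(x) - center||^2; non-negative means inside the
    sphere (inlier)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise OCSVMError(
            f"query has {X.shape[1]} features but model was trained with {model.n_features}"
        )
    Kq = kernel_matrix(model.support_vectors, X, model.kernel)
    if model.kernel.kind == "linear":
        kxx = np.einsum("ij,ij->i", X, X)
    else:
        kxx = np.ones(X.shape[0])
    dist_sq = kxx - 2.0 * (model.sv_alphas @ Kq) + model.center_sq_norm
    return model.radius_sq - dist_sq


def svdd_predict(model: SVDDModel, X: np.ndarray) -> np.ndarray:
    """Labels from the SVDD score: +1 inside/on the sphere, -1 outside."""
    return np.where(svdd_decision(model, X) >= 0.0, INLIER, OUTLIER)


# ---------------------------------------------------------------------------
# independent QP oracle (tests only)
# ---------------------------------------------------------------------------


def qp_oracle(
    K: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    linear_term: np.ndarray | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """Solve min 1/2 a'Ka + p'a  s.t.  sum a = 1, lower <= a <= upper by a
    generic convex solver (multi-start SLSQP).

    An independent validation route for ``fit_ocsvm``/``fit_svdd`` at
    brute-force scale; refuses problems with more than 12 variables.
    """
    from scipy.optimize import minimize

    K = np.asarray(K, dtype=float)
    l = K.shape[0]
    if l > 12:
        raise OCSVMError(f"qp_oracle is a brute-force validation tool; refusing l={l} > 12")
    lower = np.broadcast_to(np.asarray(lower, dtype=float), (l,))
    upper = np.broadcast_to(np.asarray(upper, dtype=float), (l,))
    p = np.zeros(l) if linear_term is None else np.asarray(linear_term, dtype=float)

    def obj(a):
        return 0.5 * a @ K @ a + p @ a

    def grad(a):
        return K @ a + p

    cons = [{"type": "eq", "fun": lambda a: np.sum(a) - 1.0, "jac": lambda a: np.ones(l)}]
    bounds = list(zip(lower, upper))
    rng = np.random.default_rng(seed)
    best, best_val = None, np.inf
    starts = [np.clip(np.full(l, 1.0 / l), lower, upper)]
    for _ in range(n_starts - 1):
        a0 = rng.dirichlet(np.ones(l))
        starts.append(np.clip(a0, lower, upper))
    for a0 in starts:
        s = a0.sum()
        if s > 0:
            a0 = np.clip(a0 / s, lower, upper)
        res = minimize(
            obj, a0, jac=grad, bounds=bounds, constraints=cons,
            method="SLSQP", options={"ftol": 1e-14, "maxiter": 500},
        )
        if res.fun < best_val and abs(res.x.sum() - 1.0) < 1e-6:
            best, best_val = res.x, res.fun
    if best is None:
        raise OCSVMError("qp_oracle failed to find a feasible solution")
    return np.clip(best, lower, upper)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def model_to_dict(model: OCSVMModel | SVDDModel) -> dict:
    """Self-describing JSON-ready representation of a fitted model."""
    d = {
        "format": "ocgene-model",
        "version": __version__,
        "kernel": {"kind": model.kernel.kind, "gamma": model.kernel.gamma},
        "n_features": model.n_features,
        "alphas": model.alphas.tolist(),
        "support_vectors": model.support_vectors.tolist(),
        "sv_alphas": model.sv_alphas.tolist(),
    }
    if isinstance(model, OCSVMModel):
        d.update(model_type="ocsvm", nu=model.nu, rho=model.rho,
                 slacks=model.slacks.tolist())
    else:
        d.update(model_type="svdd", C=model.C, radius_sq=model.radius_sq,
                 center_sq_norm=model.center_sq_norm)
    return d


def model_from_dict(d: dict) -> OCSVMModel | SVDDModel:
    kernel = KernelSpec(d["kernel"]["kind"], d["kernel"]["gamma"])
    common = dict(
        alphas=np.asarray(d["alphas"], dtype=float),
        kernel=kernel,
        support_vectors=np.asarray(d["support_vectors"], dtype=float),
        sv_alphas=np.asarray(d["sv_alphas"], dtype=float),
        n_features=int(d["n_features"]),
    )
    if d["model_type"] == "ocsvm":
        return OCSVMModel(rho=float(d["rho"]), nu=float(d["nu"]),
                          slacks=np.asarray(d["slacks"], dtype=float), **common)
    if d["model_type"] == "svdd":
        return SVDDModel(radius_sq=float(d["radius_sq"]), C=float(d["C"]),
                         center_sq_norm=float(d["center_sq_norm"]), **common)
    raise OCSVMError(f"unknown model_type {d.get('model_type')!r}")


def save_model(model: OCSVMModel | SVDDModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path) -> OCSVMModel | SVDDModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
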
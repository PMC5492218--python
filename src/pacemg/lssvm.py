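"""Least-squares SVM with O(l^2) insert/delete/replace of support samples.

The binary LS-SVM dual reduces training to one symmetric positive-definite
linear system

    [ 0   1^T ] [ b ]   [ 0 ]
    [ 1    H  ] [ a ] = [ Y ],      H = K + C^{-1} I,

whose solution is

    b = (1^T H^{-1} Y) / (1^T H^{-1} 1),      a = H^{-1} (Y - b 1).

A fresh solve costs O(l^3) through the Cholesky factorization H = R^T R.
The model instead maintains R across edits of the support set: inserting,
deleting or replacing the sample at position p rewrites one row/column of
H, and the factor is repaired by forward substitution for the new column
plus a rank-one Cholesky update (deletion) or downdate (insertion) of the
trailing block — O(l^2) total.  The coefficients (a, b) are then recovered
by two triangular solves against the maintained factor, never by explicit
inversion.

Because every support sample keeps a nonzero coefficient (the model is
full-dense: C xi_i = a_i at the optimum), the support set's size is under
the caller's control — which is exactly what the particle adaptive
classifier exploits by *replacing* particles instead of accumulating them.

A module-level operation counter tallies the dominant floating-point work
of each routine (triangular solves n^2, rank-one factor repair 4m^2,
Cholesky l^3/3, Gram matrix l^2 d) so that scaling behaviour can be
measured deterministically, independent of wall clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky as dense_cholesky
from scipy.linalg.blas import dtrsm, dtrsv

from .kernel import KernelParams, kernel_matrix, kernel_vector

try:  # JIT the rotation sweeps when numba is available; pure numpy otherwise
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco

# tolerance below which a downdated diagonal is treated as a loss of
# positive definiteness rather than rounded through
BREAKDOWN_TOL = 1e-12


class FlopCounter:
    """Deterministic tally of dominant floating-point operations."""

    def __init__(self) -> None:
        self.count = 0.0

    def add(self, n: float) -> None:
        self.count += n

    def reset(self) -> float:
        c, self.count = self.count, 0.0
        return c


FLOPS = FlopCounter()


class FactorBreakdownError(RuntimeError):
    """Positive definiteness lost during a rank-one downdate.

    Cannot occur in exact arithmetic for H = K + C^{-1} I; raised when
    finite precision violates it so callers can fall back to a batch solve.
    """


@dataclass(frozen=True)
class LSSVMModel:
    """Dual LS-SVM state: support set, coefficients, and Cholesky factor.

    ``factor`` is the upper-triangular R with R^T R = K + C^{-1} I over the
    current support samples, in support order.  ``alpha`` sums to zero
    (the equality constraint of the dual), and at every support sample
    the stationarity condition  sum_j a_j k(x_i, x_j) + b + a_i / C = y_i
    holds to solver precision.
    """

    support_samples: np.ndarray  # (l, d)
    support_labels: np.ndarray   # (l,) in {-1, +1}
    alpha: np.ndarray            # (l,)
    b: float
    factor: np.ndarray           # (l, l) upper triangular
    C: float
    kernel: KernelParams

    @property
    def size(self) -> int:
        return self.support_samples.shape[0]


# ---------------------------------------------------------------------------
# rank-one factor repair


@_njit(cache=True)
def _update_sweep(R: np.ndarray, v: np.ndarray) -> None:
    m = R.shape[0]
    for k in range(m):
        r = np.hypot(R[k, k], v[k])
        c = r / R[k, k]
        s = v[k] / R[k, k]
        R[k, k] = r
        for j in range(k + 1, m):
            R[k, j] = (R[k, j] + s * v[j]) / c
            v[j] = c * v[j] - s * R[k, j]


@_njit(cache=True)
def _downdate_sweep(R: np.ndarray, v: np.ndarray, tol: float) -> int:
    m = R.shape[0]
    for k in range(m):
        d = (R[k, k] - v[k]) * (R[k, k] + v[k])
        if d <= tol:
            return k + 1  # breakdown at row k
        r = np.sqrt(d)
        c = r / R[k, k]
        s = v[k] / R[k, k]
        R[k, k] = r
        for j in range(k + 1, m):
            R[k, j] = (R[k, j] - s * v[j]) / c
            v[j] = c * v[j] - s * R[k, j]
    return 0


def cholesky_update(R: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Return upper-triangular R' with R'^T R' = R^T R + v v^T.

    Standard Givens-rotation sweep; O(m^2) for an m x m factor.
    """
    R = np.array(R, dtype=float)
    _update_sweep(R, np.array(v, dtype=float))
    FLOPS.add(4.0 * R.shape[0] ** 2)
    return R


def cholesky_downdate(R: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Return upper-triangular R' with R'^T R' = R^T R - v v^T.

    Hyperbolic-rotation sweep; raises :class:`FactorBreakdownError` when
    the downdated matrix is not numerically positive definite.
    """
    R = np.array(R, dtype=float)
    status = _downdate_sweep(R, np.array(v, dtype=float), BREAKDOWN_TOL)
    if status:
        raise FactorBreakdownError(
            "rank-one downdate lost positive definiteness"
        )
    FLOPS.add(4.0 * R.shape[0] ** 2)
    return R


# ---------------------------------------------------------------------------
# coefficient recovery from the maintained factor


def _solve_spd(R: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve (R^T R) x = rhs by two triangular solves (BLAS trsm)."""
    n = R.shape[0]
    y = dtrsm(1.0, R, rhs, side=0, lower=0, trans_a=1)
    x = dtrsm(1.0, R, y, side=0, lower=0, trans_a=0)
    FLOPS.add(2.0 * n * n * (rhs.shape[1] if rhs.ndim > 1 else 1))
    return x


def _coefficients(R: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Recover (alpha, b) from the factor of H and the labels."""
    rhs = np.empty((y.size, 2))
    rhs[:, 0] = y
    rhs[:, 1] = 1.0
    hinv = _solve_spd(R, rhs)
    hinv_y, hinv_1 = hinv[:, 0], hinv[:, 1]
    b = float(hinv_y.sum() / hinv_1.sum())
    alpha = hinv_y - b * hinv_1
    return alpha, b


# ---------------------------------------------------------------------------
# batch training


def batch_solve(
    samples: np.ndarray,
    labels: np.ndarray,
    C: float,
    kernel: KernelParams,
) -> LSSVMModel:
    """Train an LS-SVM from scratch: factorize H = K + C^{-1} I and solve.

    O(l^3); the resulting factor seeds subsequent O(l^2) edits.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    y = np.asarray(labels, dtype=float).ravel()
    if X.shape[0] == 0:
        raise ValueError("batch_solve requires at least one sample")
    if X.shape[0] != y.shape[0]:
        raise ValueError("samples and labels length mismatch")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be in {-1, +1}")
    if not C > 0:
        raise ValueError("C must be positive")
    l = X.shape[0]
    H = kernel_matrix(X, kernel) + np.eye(l) / C
    FLOPS.add(float(l * l * X.shape[1]))
    R = dense_cholesky(H, lower=False)
    FLOPS.add(l**3 / 3.0)
    alpha, b = _coefficients(R, y)
    return LSSVMModel(X.copy(), y.copy(), alpha, b, R, float(C), kernel)


# ---------------------------------------------------------------------------
# factor surgery


def insert(model: LSSVMModel, x_p: np.ndarray, y_p: float, p: int) -> LSSVMModel:
    """Insert a support sample at position p (0-based); O(l^2).

    The new column of H is absorbed by forward substitution (u1), a scalar
    pivot (u_pp), and a rank-one downdate of the trailing block.
    """
    l_new = model.size + 1
    if not 0 <= p <= model.size:
        raise ValueError(f"insert position {p} out of range 0..{model.size}")
    x_p = np.asarray(x_p, dtype=float).ravel()
    if y_p not in (-1.0, 1.0, -1, 1):
        raise ValueError("label must be +/-1")

    X_old, y_old = model.support_samples, model.support_labels
    X_new = np.empty((l_new, x_p.size))
    X_new[:p] = X_old[:p]
    X_new[p] = x_p
    X_new[p + 1:] = X_old[p:]
    y_new = np.empty(l_new)
    y_new[:p] = y_old[:p]
    y_new[p] = float(y_p)
    y_new[p + 1:] = y_old[p:]

    if model.size == 0:
        return batch_solve(X_new, y_new, model.C, model.kernel)

    W = model.factor
    k_col = kernel_vector(x_p, model.support_samples, model.kernel)
    FLOPS.add(float(model.size * x_p.size))
    h1 = k_col[:p]
    h2 = k_col[p:]
    hpp = 1.0 + 1.0 / model.C

    W1 = W[:p, :p]
    W2 = W[:p, p:]
    W3 = W[p:, p:]

    if p > 0:
        u1 = dtrsv(W1, h1, lower=0, trans=1)
        FLOPS.add(float(p * p))
    else:
        u1 = np.zeros(0)
    d = hpp - u1.dot(u1)
    if d <= BREAKDOWN_TOL:
        raise FactorBreakdownError("insert pivot lost positive definiteness")
    upp = np.sqrt(d)
    u2 = (h2 - W2.T.dot(u1)) / upp
    FLOPS.add(2.0 * W2.size)
    U3 = cholesky_downdate(W3, u2) if W3.shape[0] else W3

    R = np.zeros((l_new, l_new))
    R[:p, :p] = W1
    R[:p, p] = u1
    R[:p, p + 1:] = W2
    R[p, p] = upp
    R[p, p + 1:] = u2
    R[p + 1:, p + 1:] = U3

    alpha, b = _coefficients(R, y_new)
    return LSSVMModel(X_new, y_new, alpha, b, R, model.C, model.kernel)


def delete(model: LSSVMModel, p: int) -> LSSVMModel:
    """Remove the support sample at position p (0-based).

    The trailing block is repaired by a rank-one Cholesky update with the
    deleted row segment of the factor; O((l-p)^2 + l^2) with the re-solve.
    """
    if model.size < 2:
        raise ValueError("cannot delete from a model of size < 2")
    if not 0 <= p < model.size:
        raise ValueError(f"delete position {p} out of range 0..{model.size - 1}")

    U = model.factor
    u2 = U[p, p + 1:]
    U3 = U[p + 1:, p + 1:]
    W3 = cholesky_update(U3, u2) if U3.shape[0] else U3

    l_new = model.size - 1
    R = np.zeros((l_new, l_new))
    R[:p, :p] = U[:p, :p]
    R[:p, p:] = U[:p, p + 1:]
    R[p:, p:] = W3

    X_old, y_old = model.support_samples, model.support_labels
    X_new = np.empty((l_new, X_old.shape[1]))
    X_new[:p] = X_old[:p]
    X_new[p:] = X_old[p + 1:]
    y_new = np.empty(l_new)
    y_new[:p] = y_old[:p]
    y_new[p:] = y_old[p + 1:]
    alpha, b = _coefficients(R, y_new)
    return LSSVMModel(X_new, y_new, alpha, b, R, model.C, model.kernel)


def replace(model: LSSVMModel, x_new: np.ndarray, y_new: float, p: int) -> LSSVMModel:
    """Substitute the support sample at position p: delete then insert."""
    return insert(delete(model, p), x_new, y_new, p)


# ---------------------------------------------------------------------------
# prediction


def decision_value(
    model: LSSVMModel, x: np.ndarray, return_kernel: bool = False
):
    """f(x) = sum_i a_i k(x_i, x) + b; sign is the binary prediction.

    With ``return_kernel=True`` also returns the vector of k(x_i, x)
    products so the attractive-zone distance can reuse them.
    """
    k = kernel_vector(x, model.support_samples, model.kernel)
    val = float(model.alpha.dot(k) + model.b)
    if return_kernel:
        return val, k
    return val


def predict_sign(value: float) -> int:
    """Sign convention of the indicator: sgn(0) -> +1."""
    return 1 if value >= 0 else -1
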
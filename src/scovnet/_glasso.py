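"""Graphical-lasso solver: L1-penalized sparse inverse covariance.

Solves

    maximize_Theta  log det(Theta) - tr(S @ Theta) - rho * ||Theta||_{1,off}

over symmetric positive-definite precision matrices Theta, where S is a
sample covariance (here: correlation) matrix and the L1 penalty applies to
off-diagonal entries only.  The solver is the classic block coordinate
descent over columns of the working covariance W, with an inner lasso
solved by coordinate descent on the Gram system, and the duality gap

    gap = tr(S @ Theta) - p + rho * ||Theta||_{1,off}

as the stopping criterion.  Warm starts (previous W and Theta) are
supported and are what makes permutation loops affordable: successive
permuted fits differ little, so the solver typically converges in a
handful of sweeps.

The convention (off-diagonal penalty, W_ii = S_ii at optimum, absolute
duality-gap tolerance) matches scikit-learn's GraphicalLasso, which the
test suite uses as an independent numerical cross-check.
"""

from __future__ import annotations

import numpy as np
from numba import njit


class GlassoNonConvergence(RuntimeError):
    """Raised when block coordinate descent fails to reach the gap tolerance.

    Carries the penalty and iteration count used.
    """

    def __init__(self, rho: float, n_iter: int, gap: float):
        self.rho = float(rho)
        self.n_iter = int(n_iter)
        self.gap = float(gap)
        super().__init__(
            f"graphical lasso did not converge at rho={rho:g} "
            f"after {n_iter} iterations (duality gap {gap:.3e})"
        )


@njit(cache=True)
def _dual_gap(S, Theta, rho):
    p = S.shape[0]
    gap = 0.0
    l1_off = 0.0
    for i in range(p):
        for j in range(p):
            gap += S[i, j] * Theta[i, j]
            if i != j:
                l1_off += abs(Theta[i, j])
    return gap - p + rho * l1_off


@njit(cache=True)
def _glasso_cd(S, rho, W, Theta, max_iter, tol, inner_tol, inner_max):
    """Block coordinate descent; W and Theta updated in place.

    Returns (n_iter, gap); n_iter == max_iter means the gap tolerance
    was not reached.
    """
    p = S.shape[0]
    w = np.empty(p)  # lasso coefficients for the active column (w[idx] unused)
    t = np.empty(p)  # running W @ w with w[idx] treated as 0
    gap = np.inf
    for it in range(max_iter):
        for idx in range(p):
            # warm-start the inner lasso from the current precision column
            denom = Theta[idx, idx]
            for j in range(p):
                w[j] = -Theta[j, idx] / denom
            w[idx] = 0.0
            # t = W @ w
            for j in range(p):
                acc = 0.0
                for k in range(p):
                    acc += W[j, k] * w[k]
                t[j] = acc
            # inner coordinate descent on: 0.5 w' W11 w - s12' w + rho |w|_1
            # with an active-set strategy: full sweeps establish the support,
            # then only nonzero coordinates are iterated until stable, with a
            # final full sweep verifying the KKT conditions
            full_pass = True
            for _sweep in range(inner_max):
                max_step = 0.0
                max_coef = 0.0
                for j in range(p):
                    if j == idx:
                        continue
                    if not full_pass and w[j] == 0.0:
                        continue
                    grad = S[j, idx] - (t[j] - W[j, j] * w[j])
                    if grad > rho:
                        new = (grad - rho) / W[j, j]
                    elif grad < -rho:
                        new = (grad + rho) / W[j, j]
                    else:
                        new = 0.0
                    d = new - w[j]
                    if d != 0.0:
                        w[j] = new
                        for k in range(p):
                            t[k] += W[k, j] * d
                    if abs(d) > max_step:
                        max_step = abs(d)
                    if abs(new) > max_coef:
                        max_coef = abs(new)
                converged_pass = max_step <= inner_tol * (max_coef + 1e-16)
                if converged_pass and full_pass:
                    break
                # after a stable active-set pass, verify with a full sweep
                full_pass = converged_pass
            # update covariance column: w12 = W11 @ w
            for j in range(p):
                if j != idx:
                    W[j, idx] = t[j]
                    W[idx, j] = t[j]
            # update precision column; a non-positive Schur complement means
            # the working covariance lost positive definiteness (possible for
            # the off-diagonal-penalty convention at tiny rho with singular S)
            quad = 0.0
            for j in range(p):
                if j != idx:
                    quad += W[j, idx] * w[j]
            den = W[idx, idx] - quad
            if not np.isfinite(den) or den <= 1e-12:
                return max_iter, np.nan
            tii = 1.0 / den
            Theta[idx, idx] = tii
            for j in range(p):
                if j != idx:
                    Theta[j, idx] = -tii * w[j]
                    Theta[idx, j] = -tii * w[j]
        gap = _dual_gap(S, Theta, rho)
        if not np.isfinite(gap):
            return max_iter, np.nan
        if abs(gap) < tol:
            return it + 1, gap
    return max_iter, gap


def glasso(
    S: np.ndarray,
    rho: float,
    *,
    W_init: np.ndarray | None = None,
    Theta_init: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    inner_tol: float = 1e-6,
    inner_max: int = 200,
    raise_on_nonconvergence: bool = True,
    check_input: bool = True,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Fit the graphical lasso on covariance/correlation matrix ``S``.

    Parameters
    ----------
    S
        Symmetric sample covariance matrix (p x p).  For networks on the
        correlation scale pass a correlation matrix.
    rho
        Off-diagonal L1 penalty, >= 0.  ``rho = 0`` inverts ``S`` directly
        and requires ``S`` nonsingular.
    W_init, Theta_init
        Optional warm start: covariance and precision estimates from a
        previous, similar fit.
    tol
        Absolute tolerance on the duality gap.

    Returns
    -------
    (W, Theta, n_iter)
        Estimated covariance, precision, and outer sweeps used.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    p = S.shape[0]
    if check_input and (S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-10)):
        raise ValueError("S must be a square symmetric matrix")
    if rho < 0:
        raise ValueError(f"rho must be >= 0, got {rho}")
    if rho == 0:
        try:
            Theta = np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "rho=0 requires a nonsingular covariance "
                "(need more subjects than regions); use rho > 0"
            ) from exc
        return S.copy(), Theta, 0
    if W_init is not None and Theta_init is not None:
        W = np.ascontiguousarray(W_init, dtype=np.float64).copy()
        # shrink off-diagonals slightly for a conservative, well-conditioned start
        W *= 0.95
        np.fill_diagonal(W, np.diag(S))
        Theta = np.linalg.inv(W)
    else:
        W = 0.95 * S
        np.fill_diagonal(W, np.diag(S))
        Theta = np.linalg.inv(W)
    Theta = np.ascontiguousarray(Theta)
    n_iter, gap = _glasso_cd(S, float(rho), W, Theta, max_iter, tol, inner_tol, inner_max)
    if not np.isfinite(gap):
        raise GlassoNonConvergence(rho, n_iter, gap)
    if abs(gap) >= tol and raise_on_nonconvergence:
        raise GlassoNonConvergence(rho, n_iter, gap)
    # enforce exact symmetry against accumulated round-off
    Theta = 0.5 * (Theta + Theta.T)
    W = 0.5 * (W + W.T)
    return W, Theta, n_iter
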
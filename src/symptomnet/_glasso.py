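"""Block coordinate-descent solver for the graphical lasso.

Maximizes the L1-penalized Gaussian log-likelihood

    log det K - tr(S K) - lambda * sum_{i != j} |k_ij|

over positive-definite precision matrices K (diagonal unpenalized), using
the classic column-wise algorithm: each column update solves a lasso
subproblem on the current covariance estimate W by scalar coordinate
descent.  Written loop-wise so numba can JIT it; falls back to the same
pure-Python code if numba is unavailable.  Problem sizes here are tiny
(p ~ 8), so the solver favors exact zeros and determinism over large-p
scalability.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


class GlassoConvergenceError(RuntimeError):
    """Raised when coordinate descent fails to reach tolerance."""


@njit(cache=True)
def _glasso_sweeps(S, lam, W, Beta, tol, max_sweeps, inner_tol, inner_max):
    """Run coordinate-descent sweeps in place; return (n_sweeps, last_delta).

    W is the working covariance estimate (diagonal fixed at diag(S));
    Beta[:, j] holds the lasso coefficients of column j's subproblem.
    """
    p = S.shape[0]
    n_sweeps = 0
    max_delta = tol + 1.0
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            # lasso for column j: min 0.5 b'W11 b - s12'b + lam |b|_1
            for _ in range(inner_max):
                inner_delta = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    acc = 0.0
                    for l in range(p):
                        if l == j or l == k:
                            continue
                        acc += W[k, l] * Beta[l, j]
                    r = S[k, j] - acc
                    if r > lam:
                        b = (r - lam) / W[k, k]
                    elif r < -lam:
                        b = (r + lam) / W[k, k]
                    else:
                        b = 0.0
                    d = abs(b - Beta[k, j])
                    if d > inner_delta:
                        inner_delta = d
                    Beta[k, j] = b
                if inner_delta < inner_tol:
                    break
            # w12 <- W11 beta
            for i in range(p):
                if i == j:
                    continue
                acc = 0.0
                for l in range(p):
                    if l == j:
                        continue
                    acc += W[i, l] * Beta[l, j]
                d = abs(acc - W[i, j])
                if d > max_delta:
                    max_delta = d
                W[i, j] = acc
                W[j, i] = acc
        n_sweeps = sweep + 1
        if max_delta < tol:
            break
    return n_sweeps, max_delta


def glasso(
    S: np.ndarray,
    lam: float,
    *,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
    warm_start: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Solve the graphical lasso at one penalty.

    Parameters
    ----------
    S : (p, p) symmetric sample correlation/covariance matrix.
    lam : penalty on off-diagonal precision entries, >= 0.
    warm_start : optional (W, Beta) state from a previous (nearby) penalty.

    Returns
    -------
    K : (p, p) precision estimate with exact zeros from the penalty.
    W : (p, p) covariance estimate (inverse of K up to tolerance).
    state : (W, Beta) arrays reusable as ``warm_start``.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    if warm_start is not None:
        W = warm_start[0].copy()
        Beta = warm_start[1].copy()
        np.fill_diagonal(W, np.diag(S))
    else:
        W = S.copy()
        Beta = np.zeros((p, p))

    n_sweeps, delta = _glasso_sweeps(
        S, float(lam), W, Beta, tol, max_sweeps, tol * 0.1, 1000
    )
    if delta >= tol:
        raise GlassoConvergenceError(
            f"graphical lasso did not converge in {max_sweeps} sweeps "
            f"(last max parameter change {delta:.3e}, tol {tol:.0e})"
        )

    # Recover K from (W, Beta): k_jj = 1/(w_jj - w12'beta), k_ij = -beta_ij k_jj.
    # Averaging the two column solutions keeps symmetry; an entry is zero iff
    # both lasso solutions zeroed it, so sparsity comes from the penalty alone.
    K = np.zeros((p, p))
    kdiag = np.empty(p)
    for j in range(p):
        dot = 0.0
        for l in range(p):
            if l != j:
                dot += W[l, j] * Beta[l, j]
        kdiag[j] = 1.0 / (W[j, j] - dot)
    for i in range(p):
        K[i, i] = kdiag[i]
        for j in range(i + 1, p):
            val = -(Beta[i, j] * kdiag[j] + Beta[j, i] * kdiag[i]) / 2.0
            K[i, j] = K[j, i] = val
    return K, W, (W, Beta)


def partial_correlations(K: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix: -k_ij/sqrt(k_ii k_jj)."""
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return P
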
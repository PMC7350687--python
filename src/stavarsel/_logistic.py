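"""Small unpenalized logistic-regression fitter (Newton with step halving).

A fixed tiny ridge on the standardized coefficients keeps the Hessian
invertible and the iteration convergent under the quasi-separation that is
routine with ~20 selected features on ~78 samples; if Newton still fails
the ridge is escalated and the fit retried.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LogisticFit", "fit_logistic"]


class LogisticFit:
    """Coefficients on the original feature scale."""

    __slots__ = ("coef", "intercept", "converged", "ridge")

    def __init__(self, coef, intercept, converged, ridge):
        self.coef = coef
        self.intercept = intercept
        self.converged = converged
        self.ridge = ridge

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = np.clip(X @ self.coef + self.intercept, -35, 35)
        return 1.0 / (1.0 + np.exp(-eta))


def _newton(Xs, y, ridge, max_iter=100, tol=1e-10):
    n, p = Xs.shape
    beta = np.zeros(p + 1)  # [intercept, coefs]
    A = np.column_stack([np.ones(n), Xs])
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(A @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        g = A.T @ (y - mu) - pen * beta
        w = np.maximum(mu * (1 - mu), 1e-10)
        H = (A * w[:, None]).T @ A + np.diag(pen)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, False
        # step halving on the penalized log-likelihood
        ll_new = -np.inf
        for _half in range(30):
            cand = beta + step
            eta_c = np.clip(A @ cand, -35, 35)
            ll_new = float(
                y @ eta_c - np.logaddexp(0.0, eta_c).sum() - 0.5 * pen @ cand**2
            )
            if np.isfinite(ll_new) and ll_new >= ll_old - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        if np.abs(step).max() < tol or abs(ll_new - ll_old) < 1e-12:
            return beta, True
        ll_old = ll_new
    return beta, False


def fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic fit with a tiny ridge safeguard.

    ``ridge`` applies to standardized coefficients; it is escalated
    (x100, up to 1e-2) if the Newton iteration fails to converge.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    Xs = (X - means) / scales
    r = ridge
    while True:
        beta, converged = _newton(Xs, y, r)
        if converged or r >= 1e-2:
            break
        r *= 100.0
    coef = beta[1:] / scales
    intercept = float(beta[0] - coef @ means)
    return LogisticFit(coef, intercept, converged, r)
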
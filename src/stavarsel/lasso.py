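"""L1-penalized logistic regression paths and cross-validated lambda selection.

The solver minimises, at each grid point lambda,

    (1/n) * sum_i [-y_i eta_i + log(1 + exp(eta_i))]  +  lambda * sum_j |beta_j|

with an unpenalized intercept, on internally standardized features
(unit population variance); coefficients are returned on the original
scale. The algorithm is iteratively reweighted least squares with
cyclic coordinate descent on an active set, warm-started along a
geometric lambda grid from lambda_max (the smallest penalty at which
every coefficient is zero) -- the convention popularised by glmnet.

Lambda is chosen by repeated stratified k-fold cross-validation of the
held-out binomial deviance: ``lambda.min`` minimises the CV curve and
``lambda.1se`` is the largest lambda within one standard error of that
minimum (more stringent regularisation, i.e. a sparser model). Repeating
the CV many times with fresh fold splits yields a distribution of lambda
estimates whose mean is used downstream, plus a stability diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LassoPath",
    "LambdaEstimate",
    "LambdaStability",
    "fit_l1_logistic_path",
    "fit_l1_logistic_at",
    "cv_lambda",
    "repeated_cv_lambda",
    "kkt_violation",
]

_WEIGHT_FLOOR = 1e-6


@njit(cache=True)
def _path_kernel(XT, y, lambdas, tol, max_irls, max_cd, devmax):  # pragma: no cover - jit
    """Coordinate-descent path on standardized features.

    XT is (p, n) C-contiguous; returns (coefs (L, p), intercepts (L,)).
    The path stops early once the fraction of null deviance explained
    exceeds ``devmax`` (the model is essentially saturated); remaining
    grid points inherit the last solution.
    """
    p, n = XT.shape
    L = lambdas.shape[0]
    coefs = np.zeros((L, p))
    icepts = np.zeros(L)
    beta = np.zeros(p)
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    active = np.zeros(p, np.bool_)
    mu = np.empty(n)
    w = np.empty(n)
    r = np.empty(n)
    null_dev = -2.0 * n * (ybar * np.log(ybar) + (1.0 - ybar) * np.log(1.0 - ybar))

    saturated = False
    n_solved = 0
    for li in range(L):
        if saturated:
            for j in range(p):
                coefs[li, j] = beta[j]
            icepts[li] = b0
            continue
        n_solved += 1
        lam = lambdas[li]
        for _kkt_round in range(100):
            for _irls in range(max_irls):
                for i in range(n):
                    m = 1.0 / (1.0 + np.exp(-eta[i]))
                    mu[i] = m
                    wi = m * (1.0 - m)
                    if wi < _WEIGHT_FLOOR:
                        wi = _WEIGHT_FLOOR
                    w[i] = wi
                    r[i] = (y[i] - m) / wi
                first_pass_dmax = -1.0
                for _cd in range(max_cd):
                    dmax = 0.0
                    # intercept (unpenalized)
                    sw = 0.0
                    swr = 0.0
                    for i in range(n):
                        sw += w[i]
                        swr += w[i] * r[i]
                    db = swr / sw
                    if db != 0.0:
                        b0 += db
                        for i in range(n):
                            r[i] -= db
                            eta[i] += db
                        d = db * db * (sw / n)
                        if d > dmax:
                            dmax = d
                    for j in range(p):
                        if not active[j]:
                            continue
                        rho = 0.0
                        xwx = 0.0
                        for i in range(n):
                            xji = XT[j, i]
                            rho += w[i] * xji * r[i]
                            xwx += w[i] * xji * xji
                        xwxn = xwx / n
                        rho = rho / n + xwxn * beta[j]
                        if rho > lam:
                            bnew = (rho - lam) / xwxn
                        elif rho < -lam:
                            bnew = (rho + lam) / xwxn
                        else:
                            bnew = 0.0
                        dbj = bnew - beta[j]
                        if dbj != 0.0:
                            beta[j] = bnew
                            for i in range(n):
                                r[i] -= dbj * XT[j, i]
                                eta[i] += dbj * XT[j, i]
                            d = dbj * dbj * xwxn
                            if d > dmax:
                                dmax = d
                    if first_pass_dmax < 0.0:
                        first_pass_dmax = dmax
                    if dmax < tol:
                        break
                if first_pass_dmax < tol:
                    break
            # full KKT screen: activate any violating feature
            for i in range(n):
                mu[i] = 1.0 / (1.0 + np.exp(-eta[i]))
                r[i] = mu[i] - y[i]
            g = np.dot(XT, r) / n
            n_new = 0
            for j in range(p):
                if not active[j] and abs(g[j]) > lam + 1e-9:
                    active[j] = True
                    n_new += 1
            if n_new == 0:
                break
        for j in range(p):
            coefs[li, j] = beta[j]
            if beta[j] != 0.0:
                active[j] = True
        icepts[li] = b0
        dev = 0.0
        for i in range(n):
            e = eta[i]
            if e > 35.0:
                e = 35.0
            elif e < -35.0:
                e = -35.0
            dev += -2.0 * (y[i] * e - np.log(1.0 + np.exp(e)))
        if 1.0 - dev / null_dev > devmax:
            saturated = True
    return coefs, icepts, n_solved


@dataclass
class LassoPath:
    """Fitted regularization path (original-scale coefficients)."""

    lambdas: np.ndarray  # decreasing
    coef: np.ndarray  # (n_features, n_lambdas), original scale
    intercept: np.ndarray  # (n_lambdas,)
    coef_std: np.ndarray  # standardized-scale coefficients (same shape)
    feature_means: np.ndarray
    feature_scales: np.ndarray
    kept: np.ndarray  # indices of non-constant features actually fit

    @property
    def n_nonzero(self) -> np.ndarray:
        return (self.coef != 0).sum(axis=0)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_lambdas) linear predictor for new data."""
        return X @ self.coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = np.clip(self.linear_predictor(X), -35, 35)
        return 1.0 / (1.0 + np.exp(-eta))

    def nonzero_features(self, lambda_index: int) -> np.ndarray:
        return np.flatnonzero(self.coef[:, lambda_index] != 0)


def _standardize(X: np.ndarray):
    means = X.mean(axis=0)
    scales = X.std(axis=0)  # population sd, glmnet convention
    ok = scales > 0
    return means, scales, ok


def lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
) -> np.ndarray:
    """Geometric grid from lambda_max (all-zero model) downwards."""
    n, p = X.shape
    means, scales, ok = _standardize(X)
    Xs = (X[:, ok] - means[ok]) / scales[ok]
    ybar = y.mean()
    lam_max = np.abs(Xs.T @ (y - ybar)).max() / n
    if lambda_min_ratio is None:
        lambda_min_ratio = 0.01 if n < p else 1e-4
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def fit_l1_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    lambdas: np.ndarray | None = None,
    tol: float = 1e-11,
    devmax: float = 0.999,
    truncate_saturated: bool = True,
) -> LassoPath:
    """Fit the full L1-logistic path.

    Constant features are dropped with a warning (their coefficients are
    reported as exactly zero). ``y`` must contain both classes. Once the
    fraction of null deviance explained exceeds ``devmax`` the path stops:
    by default the returned grid is truncated there (every reported point
    satisfies the KKT conditions); with ``truncate_saturated=False`` the
    remaining grid points carry the last solved solution, which keeps grid
    alignment for cross-validation curves.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.min() == y.max():
        raise ValueError("y contains a single class; logistic fit undefined")
    means, scales, ok = _standardize(X)
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} constant feature(s) from lasso fit",
            stacklevel=2,
        )
    kept = np.flatnonzero(ok)
    Xs = (X[:, kept] - means[kept]) / scales[kept]
    if lambdas is None:
        ybar = y.mean()
        lam_max = np.abs(Xs.T @ (y - ybar)).max() / n if kept.size else 1.0
        if lambda_min_ratio is None:
            lambda_min_ratio = 0.01 if n < p else 1e-4
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    else:
        lambdas = np.asarray(lambdas, dtype=float)
        if np.any(np.diff(lambdas) > 0):
            raise ValueError("lambda grid must be decreasing")

    XT = np.ascontiguousarray(Xs.T)
    coef_std_k, icept, n_solved = _path_kernel(XT, y, lambdas, tol, 50, 2000, devmax)
    if truncate_saturated and n_solved < len(lambdas):
        lambdas = lambdas[:n_solved]
        coef_std_k = coef_std_k[:n_solved]
        icept = icept[:n_solved]
    coef_std = np.zeros((p, len(lambdas)))
    coef_std[kept, :] = coef_std_k.T
    coef = np.zeros_like(coef_std)
    coef[kept, :] = coef_std_k.T / scales[kept][:, None]
    intercept = icept - coef[kept, :].T @ means[kept]
    return LassoPath(
        lambdas=lambdas,
        coef=coef,
        intercept=intercept,
        coef_std=coef_std,
        feature_means=means,
        feature_scales=scales,
        kept=kept,
    )


def fit_l1_logistic_at(
    X: np.ndarray, y: np.ndarray, lam: float, n_warm: int = 50
) -> tuple[np.ndarray, float]:
    """Coefficients and intercept at one lambda (warm-started from above)."""
    grid = lambda_grid(X, y, n_lambda=n_warm)
    lam_max = grid[0]
    if lam >= lam_max:
        lambdas = np.array([lam_max, lam]) if lam < lam_max else np.array([lam])
    else:
        upper = grid[grid > lam]
        lambdas = np.concatenate([upper, [lam]])
    path = fit_l1_logistic_path(X, y, lambdas=lambdas, truncate_saturated=False)
    return path.coef[:, -1], float(path.intercept[-1])


def kkt_violation(X: np.ndarray, y: np.ndarray, path: LassoPath) -> np.ndarray:
    """Max KKT subgradient violation per lambda (should be ~0 when converged).

    For nonzero beta_j: |g_j + lam*sign(beta_j)|; for zero: max(|g_j|-lam, 0),
    with g the gradient of the mean binomial deviance/2 on standardized X.
    """
    n = X.shape[0]
    kept = path.kept
    Xs = (X[:, kept] - path.feature_means[kept]) / path.feature_scales[kept]
    out = np.empty(len(path.lambdas))
    for li, lam in enumerate(path.lambdas):
        beta = path.coef_std[kept, li]
        b0 = path.intercept[li] + path.coef[kept, li] @ path.feature_means[kept]
        eta = np.clip(Xs @ beta + b0, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        g = Xs.T @ (mu - y) / n
        nz = beta != 0
        v_nz = np.abs(g[nz] + lam * np.sign(beta[nz])).max() if nz.any() else 0.0
        v_z = max(np.abs(g[~nz]).max() - lam, 0.0) if (~nz).any() else 0.0
        v_int = abs((mu - y).mean())
        out[li] = max(v_nz, v_z, v_int)
    return out


def binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    """Mean held-out binomial deviance, -2*loglik/n."""
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


@dataclass
class LambdaEstimate:
    """One repeat's cross-validated lambda estimates."""

    lambda_min: float
    lambda_1se: float
    index_min: int
    index_1se: int
    lambdas: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    repeat_id: int = 0

    def __post_init__(self) -> None:
        assert self.lambda_1se >= self.lambda_min


@dataclass
class LambdaStability:
    """Stability of repeated lambda estimates: mean and normal-theory 95% CI.

    ``stable`` iff the CI half-width is below 15% of the mean.
    """

    estimates: np.ndarray
    mean: float
    ci_halfwidth: float
    stable: bool
    threshold: float = 0.15

    @classmethod
    def from_estimates(cls, values, threshold: float = 0.15) -> "LambdaStability":
        values = np.asarray(values, dtype=float)
        mean = float(values.mean())
        if len(values) > 1:
            half = float(1.96 * values.std(ddof=1) / np.sqrt(len(values)))
        else:
            half = 0.0
        return cls(values, mean, half, half < threshold * mean, threshold)


def _stratified_folds(y: np.ndarray, k: int, seed: int):
    """Stratified fold assignment; re-seeds (max 10 tries) if any training or
    validation split ends up single-class."""
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed + attempt) % (2**31 - 1))
        folds = list(skf.split(np.zeros(len(y)), y))
        ok = all(
            len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) >= 1
            for tr, te in folds
        )
        if ok:
            return folds
    raise RuntimeError("could not build stratified folds with two classes per training split")


def cv_lambda(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    repeat_id: int = 0,
    fold_tol: float = 1e-8,
) -> LambdaEstimate:
    """Single round of stratified k-fold CV of held-out binomial deviance.

    Fold fits use a slightly looser convergence tolerance than the final
    path fit (the CV deviance curve is insensitive at that scale).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambdas is None:
        lambdas = lambda_grid(X, y, n_lambda=n_lambda)
    folds = _stratified_folds(y.astype(int), k, seed)
    fold_dev = np.empty((k, len(lambdas)))
    for fi, (tr, te) in enumerate(folds):
        path = fit_l1_logistic_path(
            X[tr], y[tr], lambdas=lambdas, tol=fold_tol, truncate_saturated=False
        )
        prob = path.predict_proba(X[te])
        eps = 1e-12
        pc = np.clip(prob, eps, 1 - eps)
        dev = -2.0 * (y[te, None] * np.log(pc) + (1 - y[te, None]) * np.log(1 - pc))
        fold_dev[fi] = dev.mean(axis=0)
    cv_mean = fold_dev.mean(axis=0)
    cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(k)
    i_min = int(np.argmin(cv_mean))  # first (largest-lambda) minimiser
    thresh = cv_mean[i_min] + cv_se[i_min]
    i_1se = int(np.flatnonzero(cv_mean <= thresh)[0])
    return LambdaEstimate(
        lambda_min=float(lambdas[i_min]),
        lambda_1se=float(lambdas[i_1se]),
        index_min=i_min,
        index_1se=i_1se,
        lambdas=lambdas,
        cv_mean=cv_mean,
        cv_se=cv_se,
        repeat_id=repeat_id,
    )


def repeated_cv_lambda(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    repeats: int = 50,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    stability_threshold: float = 0.15,
) -> tuple[list[LambdaEstimate], LambdaStability]:
    """Repeat k-fold CV with independent fold splits; aggregate lambda.min.

    The returned stability diagnostic is on the lambda.min estimates; the
    mean of those estimates is the lambda used downstream.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambdas is None:
        lambdas = lambda_grid(X, y, n_lambda=n_lambda)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(repeats) % (2**31 - 1)
    estimates = [
        cv_lambda(X, y, k=k, seed=int(child_seeds[r]), lambdas=lambdas, repeat_id=r)
        for r in range(repeats)
    ]
    stab = LambdaStability.from_estimates(
        [e.lambda_min for e in estimates], stability_threshold
    )
    if not stab.stable and repeats > 1:
        warnings.warn(
            "repeated CV lambda estimates are unstable "
            f"(95% CI half-width {stab.ci_halfwidth:.3g} >= "
            f"{stability_threshold:.0%} of mean {stab.mean:.3g})",
            stacklevel=2,
        )
    return estimates, stab
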
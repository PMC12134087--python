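"""Gaussian random-intercept mixed model, fitted by profiled ML or REML.

The model is ``y = X b + u[group] + e`` with ``u ~ N(0, s2_a)`` per group
and ``e ~ N(0, s2_e)``.  For a fixed variance ratio ``lam = s2_a / s2_e``
the GLS solution, the profiled residual variance and the log-likelihood are
all closed-form (the per-group covariance ``I + lam * 11'`` inverts by the
Sherman-Morrison identity into a weighted group-mean correction), so the
whole fit reduces to a one-dimensional optimisation over ``log lam``.
Each likelihood evaluation costs O(J p^2) for J groups and p fixed-effect
columns, which makes the thousands of fits of a backward model search
cheap.  Agreement with a general-purpose mixed-model implementation is
covered by the test suite.

ML (not REML) is the default so that AIC values are comparable across
fixed-effect structures during selection; the selected model can be refit
with ``reml=True`` for reporting variance components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["RandomInterceptFit", "fit_random_intercept"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class RandomInterceptFit:
    """Fitted random-intercept model.

    ``sigma_f2`` is the population variance of the fixed-effect linear
    predictor over the fitted data — the fixed-effect variance component of
    the marginal/conditional R² decomposition.
    """

    coefficients: dict
    sigma_a2: float     # between-group (random-intercept) variance
    sigma_e2: float     # residual variance
    sigma_f2: float     # variance of X @ b over the data
    loglik: float
    aic: float
    n: int
    n_groups: int
    method: str         # "ML" or "REML"
    converged: bool = True
    column_names: list = field(default_factory=list)

    @property
    def k_params(self) -> int:
        return len(self.coefficients) + 2

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coefficients[c] for c in self.column_names])


def _profile(lam: float, XtX, Xty, yty, Sx, Sy, nj, n, p, reml: bool):
    """Profiled quantities at a fixed variance ratio lam."""
    c = lam / (1.0 + lam * nj)                     # per-group Sherman-Morrison weight
    A = XtX - (Sx.T * (c * 1.0)) @ Sx              # X' W X
    b = Xty - Sx.T @ (c * Sy)                      # X' W y
    yWy = yty - float(np.sum(c * Sy * Sy))
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return None
    beta = np.linalg.solve(A, b)
    q = yWy - float(beta @ b)                      # r' W r at the GLS solution
    q = max(q, 1e-300)
    logdet_blocks = float(np.sum(np.log1p(lam * nj)))
    if reml:
        s2 = q / (n - p)
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(L))))
        ll = -0.5 * ((n - p) * (_LOG2PI + np.log(s2) + 1.0) + logdet_blocks + logdet_A)
    else:
        s2 = q / n
        ll = -0.5 * (n * (_LOG2PI + np.log(s2) + 1.0) + logdet_blocks)
    return ll, beta, s2


def fit_random_intercept(X: np.ndarray, y: np.ndarray, groups, reml: bool = False,
                         column_names=None) -> RandomInterceptFit:
    """Fit ``y = X b + u[group] + e`` by profiled ML (or REML).

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column
    y : (n,) response
    groups : (n,) group labels (the random-intercept factor)
    reml : restricted likelihood if True; plain ML otherwise
    column_names : names for the coefficient dict (defaults x0..xp-1)
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, p) with matching y")
    n, p = X.shape
    codes, _ = _group_codes(groups)
    J = codes.max() + 1
    if J < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    if n < p + 2:
        raise ValueError("too few rows for the requested fixed effects")
    if column_names is None:
        column_names = [f"x{i}" for i in range(p)]

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    Sx = np.zeros((J, p))
    np.add.at(Sx, codes, X)
    Sy = np.bincount(codes, weights=y, minlength=J)
    nj = np.bincount(codes, minlength=J).astype(float)

    def neg_ll(theta):
        out = _profile(np.exp(theta), XtX, Xty, yty, Sx, Sy, nj, n, p, reml)
        return np.inf if out is None else -out[0]

    res = minimize_scalar(neg_ll, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    lam_hat = float(np.exp(res.x))
    best = _profile(lam_hat, XtX, Xty, yty, Sx, Sy, nj, n, p, reml)
    # boundary check: a pure fixed-effects model (lam -> 0) may beat the interior
    at_zero = _profile(1e-12, XtX, Xty, yty, Sx, Sy, nj, n, p, reml)
    converged = best is not None
    if at_zero is not None and (best is None or at_zero[0] >= best[0]):
        lam_hat, best = 0.0, at_zero
    if best is None:
        raise np.linalg.LinAlgError("singular design matrix")
    ll, beta, s2e = best
    s2a = lam_hat * s2e
    eta = X @ beta
    k = p + 2
    return RandomInterceptFit(
        coefficients=dict(zip(column_names, beta.tolist())),
        sigma_a2=float(s2a), sigma_e2=float(s2e),
        sigma_f2=float(np.var(eta)),
        loglik=float(ll), aic=float(2 * k - 2 * ll),
        n=n, n_groups=int(J), method="REML" if reml else "ML",
        converged=bool(converged),
        column_names=list(column_names),
    )


def _group_codes(groups):
    arr = np.asarray(groups)
    uniq, codes = np.unique(arr, return_inverse=True)
    return codes, uniq
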
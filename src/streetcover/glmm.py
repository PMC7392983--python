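"""Mixed-effects logistic regression via the Laplace approximation.

The model is

    y_ij ~ Bernoulli(expit(x_ij' beta + z_ij' b_i)),   b_i ~ N(0, D),

with one random-effect vector b_i per group (city) and a diagonal
covariance D = diag(sigma_1^2, ..., sigma_q^2).  The marginal likelihood
is approximated by a Laplace expansion around the per-group posterior
modes; modes are found by a damped Newton iteration batched across groups,
and the outer optimization over (beta, log sigma) uses L-BFGS-B.

Standard errors come from the numerically differentiated Hessian of the
Laplace log-likelihood at the optimum (variance parameters pinned at a
bound are profiled out).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm

from .errors import RankDeficiencyError, SeparationError

_THETA_BOUNDS = (-6.0, 3.0)  # log sd bounds; lower bound ~ zero variance
_INNER_TOL = 1e-10
_INNER_MAXIT = 50


@dataclass
class GLMMResult:
    """Fit summary for the Laplace logistic mixed model."""

    beta: np.ndarray
    se: np.ndarray
    fe_names: list[str]
    re_sd: np.ndarray
    re_names: list[str]
    loglik: float
    converged: bool
    n: int
    n_groups: int
    message: str = ""
    p_values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(self.beta) / self.se
        self.p_values = 2.0 * norm.sf(z)

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        zcrit = norm.ppf(0.5 + level / 2.0)
        return np.column_stack(
            [self.beta - zcrit * self.se, self.beta + zcrit * self.se]
        )


class _LaplaceObjective:
    """Negative Laplace log-likelihood with batched inner Newton solves.

    Rows are pre-sorted by group so per-group reductions use
    ``np.add.reduceat`` over contiguous blocks.  Posterior modes are
    warm-started from the previous evaluation, which keeps the outer
    quasi-Newton iterations cheap.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, Z: np.ndarray, group_idx: np.ndarray):
        order = np.argsort(group_idx, kind="stable")
        self.X = np.ascontiguousarray(X[order])
        self.y = np.ascontiguousarray(y[order].astype(float))
        self.Z = np.ascontiguousarray(Z[order])
        g = group_idx[order]
        self.starts = np.concatenate([[0], 1 + np.nonzero(np.diff(g))[0]])
        self.G = len(self.starts)
        self.n, self.p = self.X.shape
        self.q = self.Z.shape[1]
        self.row_group = np.repeat(np.arange(self.G), np.diff(np.append(self.starts, self.n)))
        # per-row outer products z z' flattened to (n, q*q) for reduceat sums
        self.ZZ = (self.Z[:, :, None] * self.Z[:, None, :]).reshape(self.n, -1)
        self.b_hat = np.zeros((self.G, self.q))

    def _segsum(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self.starts, axis=0)

    def _modes(self, offset: np.ndarray, d_inv: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Newton to the per-group posterior modes; returns (b, eta, H)."""
        b = self.b_hat.copy()
        eye_scale = np.diag(d_inv)
        for _ in range(_INNER_MAXIT):
            eta = offset + np.einsum("ij,ij->i", self.Z, b[self.row_group])
            mu = expit(eta)
            w = mu * (1.0 - mu)
            grad = self._segsum(self.Z * (self.y - mu)[:, None]) - b * d_inv
            H = self._segsum(self.ZZ * w[:, None]).reshape(self.G, self.q, self.q)
            H += eye_scale
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
            # damp unusually large steps; the joint posterior is concave so
            # plain Newton is otherwise safe
            norms = np.abs(step).max(axis=1, keepdims=True)
            step = step * np.where(norms > 4.0, 4.0 / np.maximum(norms, 1e-300), 1.0)
            b += step
            if np.abs(step).max() < _INNER_TOL:
                break
        eta = offset + np.einsum("ij,ij->i", self.Z, b[self.row_group])
        mu = expit(eta)
        w = mu * (1.0 - mu)
        H = self._segsum(self.ZZ * w[:, None]).reshape(self.G, self.q, self.q) + eye_scale
        self.b_hat = b
        return b, eta, H

    def neg_loglik(self, params: np.ndarray) -> float:
        beta = params[: self.p]
        theta = params[self.p :]
        sigma2 = np.exp(2.0 * theta)
        d_inv = 1.0 / sigma2
        offset = self.X @ beta
        b, eta, H = self._modes(offset, d_inv)
        # Bernoulli log-likelihood at the mode
        ll_data = float(self.y @ eta - np.logaddexp(0.0, eta).sum())
        quad = 0.5 * float(((b * b) * d_inv).sum())
        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            return np.inf
        # the -log|D|/2 normalizer contributes -sum(theta) once per group
        ll = ll_data - quad - 0.5 * float(logdet.sum()) - float(theta.sum()) * self.G
        return -ll

    def neg_loglik_fixed(self, beta: np.ndarray) -> float:
        """Plain logistic log-likelihood (all random-effect variances at 0)."""
        eta = self.X @ beta
        return -float(self.y @ eta - np.logaddexp(0.0, eta).sum())


def _numerical_hessian(fun, x: np.ndarray, h: float = 3e-4) -> np.ndarray:
    m = len(x)
    H = np.empty((m, m))
    hs = h * np.maximum(1.0, np.abs(x))
    f0 = fun(x)
    for i in range(m):
        ei = np.zeros(m)
        ei[i] = hs[i]
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / hs[i] ** 2
        for j in range(i + 1, m):
            ej = np.zeros(m)
            ej[j] = hs[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * hs[i] * hs[j])
    return H


def fit_logistic_glmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    Z: np.ndarray | None = None,
    fe_names: list[str] | None = None,
    re_names: list[str] | None = None,
    fix_zero_variance: bool = False,
    start_fe: np.ndarray | None = None,
    start_log_sd: float = np.log(0.3),
) -> GLMMResult:
    """Fit the mixed logistic model; see the module docstring for the model.

    Parameters
    ----------
    X, y, groups
        Fixed-effect design, 0/1 outcome, and group labels (one group per
        random-effect vector; here, cities).
    Z
        Random-effect design (default: intercept-only column of ones).
    fix_zero_variance
        Pin every random-effect variance at 0, collapsing the model to a
        plain logistic regression estimated with the same machinery (the
        degenerate-limit contract checked against an independent oracle).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, p) aligned with y")
    if len(X) <= X.shape[1]:
        raise RankDeficiencyError("fewer rows than fixed-effect parameters")
    if y.min() == y.max():
        raise SeparationError("outcome takes a single value; model not identified")
    if Z is None:
        Z = np.ones((len(y), 1))
    Z = np.asarray(Z, dtype=float)
    codes, _ = _group_codes(groups)
    obj = _LaplaceObjective(X, y, Z, codes)
    p, q = obj.p, obj.q
    fe_names = fe_names or [f"x{i}" for i in range(p)]
    re_names = re_names or [f"z{i}" for i in range(q)]

    if start_fe is None:
        start_fe = _logistic_start(X, y)

    if fix_zero_variance:
        res = optimize.minimize(
            obj.neg_loglik_fixed, start_fe, method="BFGS",
            options={"gtol": 1e-8, "maxiter": 500},
        )
        H = _numerical_hessian(obj.neg_loglik_fixed, res.x, h=1e-4)
        se = np.sqrt(np.diag(np.linalg.inv(H)))
        return GLMMResult(
            beta=res.x, se=se, fe_names=fe_names,
            re_sd=np.zeros(q), re_names=re_names,
            loglik=-float(res.fun), converged=bool(res.success),
            n=obj.n, n_groups=obj.G, message=str(res.message),
        )

    x0 = np.concatenate([start_fe, np.full(q, start_log_sd)])
    bounds = [(None, None)] * p + [_THETA_BOUNDS] * q
    res = optimize.minimize(
        obj.neg_loglik, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-8},
    )
    beta = res.x[:p]
    theta = res.x[p:]
    re_sd = np.exp(theta)

    # Profile out variance parameters stuck at a bound before inverting.
    at_bound = (theta <= _THETA_BOUNDS[0] + 1e-6) | (theta >= _THETA_BOUNDS[1] - 1e-6)
    free = np.concatenate([np.ones(p, bool), ~at_bound])
    H_full = _numerical_hessian(obj.neg_loglik, res.x)
    H_free = H_full[np.ix_(free, free)]
    se = np.full(p + q, np.nan)
    try:
        cov = np.linalg.inv(H_free)
        diag = np.diag(cov).copy()
        ok = diag > 0
        se_free = np.full(len(diag), np.nan)
        se_free[ok] = np.sqrt(diag[ok])
        se[free] = se_free
        converged = bool(res.success)
    except np.linalg.LinAlgError:
        converged = False
    re_sd = np.where(theta <= _THETA_BOUNDS[0] + 1e-6, 0.0, re_sd)
    return GLMMResult(
        beta=beta, se=se[:p], fe_names=fe_names,
        re_sd=re_sd, re_names=re_names,
        loglik=-float(res.fun), converged=converged,
        n=obj.n, n_groups=obj.G, message=str(res.message),
    )


def _group_codes(groups) -> tuple[np.ndarray, np.ndarray]:
    uniques, codes = np.unique(np.asarray(groups), return_inverse=True)
    return codes, uniques


def _logistic_start(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cheap ridge-IRLS starting values for the fixed effects."""
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(25):
        eta = X @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-6)
        XtW = X.T * w
        H = XtW @ X + 1e-6 * np.eye(p)
        g = X.T @ (y - mu) - 1e-6 * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    return beta
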
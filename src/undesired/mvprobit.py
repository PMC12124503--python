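"""Multivariate probit estimated by GHK simulated maximum likelihood.

The model: latent ``y*_ij = x_i . beta_j + eps_ij`` with
``eps_i ~ MVN(0, Sigma)`` (unit diagonal) and observed ``y_ij = 1`` iff
``y*_ij > 0``.  Outcome-pattern probabilities are rectangle probabilities
of the multivariate normal, evaluated with the Geweke-Hajivassiliou-Keane
recursive importance sampler.  Common random numbers (one fixed uniform
block per observation) keep the simulated likelihood smooth in the
parameters; pairwise correlations are optimized on the unconstrained
hyperbolic-tangent scale with a positive-definiteness penalty for J > 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

LOG_FLOOR = -700.0  # log-probability floor guarding against underflow
_NORM_EPS = 1e-12   # keeps Phi^{-1} away from the poles in the GHK recursion


class SeparationError(ValueError):
    """Raised when an outcome is degenerate (all 0 or all 1)."""


def _ghk_draws(n: int, R: int, J: int, seed: int, antithetic: bool) -> np.ndarray:
    """Fixed uniform block of shape (n, R, J-1), shared across observations.

    Sharing one block (common random numbers in the strictest sense) keeps
    the simulated likelihood smooth in the parameters and makes identical
    observations contribute identical log-probabilities.
    """
    rng = np.random.default_rng(seed)
    if antithetic:
        half = (R + 1) // 2
        u = rng.random((half, max(J - 1, 1)))
        u = np.concatenate([u, 1.0 - u], axis=0)[:R, :]
    else:
        u = rng.random((R, max(J - 1, 1)))
    return np.broadcast_to(u, (n,) + u.shape)


def _ghk_rectangle(mu_s: np.ndarray, L: np.ndarray, u: np.ndarray) -> np.ndarray:
    """GHK estimate of P(z <= mu_s) for z ~ MVN(0, L L').

    ``mu_s``: (n, J) sign-adjusted upper limits; ``u``: (n, R, J-1) fixed
    uniforms.  Returns (n,) probabilities.
    """
    n, J = mu_s.shape
    R = u.shape[1]
    prob = np.ones((n, R))
    eta = np.zeros((n, R, J))
    for j in range(J):
        partial = np.einsum("l,nrl->nr", L[j, :j], eta[:, :, :j]) if j else 0.0
        upper = (mu_s[:, j][:, None] - partial) / L[j, j]
        p_j = stats.norm.cdf(upper)
        prob *= p_j
        if j < J - 1:
            q = np.clip(u[:, :, j] * p_j, _NORM_EPS, 1.0 - _NORM_EPS)
            eta[:, :, j] = stats.norm.ppf(q)
    return prob.mean(axis=1)


def ghk_probability(
    y: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    R: int = 100,
    seed: int = 0,
    antithetic: bool = True,
    u: np.ndarray | None = None,
) -> float:
    """GHK estimate of P(Y = y) for one observation.

    ``y`` is a binary J-vector, ``mu`` the J linear indices, ``sigma`` the
    residual correlation.  J = 1 is evaluated analytically.  Deterministic
    given ``seed`` (or an explicit uniform block ``u``).
    """
    y = np.asarray(y, dtype=int).ravel()
    mu = np.asarray(mu, dtype=float).ravel()
    sigma = np.asarray(sigma, dtype=float)
    J = len(y)
    s = 2.0 * y - 1.0
    if J == 1:
        return float(stats.norm.cdf(s[0] * mu[0]))
    D = sigma * np.outer(s, s)
    try:
        L = np.linalg.cholesky(D)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("sigma is not positive definite") from None
    if u is None:
        u = _ghk_draws(1, R, J, seed, antithetic)
    return float(_ghk_rectangle((s * mu)[None, :], L, u)[0])


def _grouped_loglik(
    Y: np.ndarray,
    Mu: np.ndarray,
    sigma: np.ndarray,
    u: np.ndarray,
    log_floor: float = LOG_FLOOR,
) -> float:
    """Sum of log GHK probabilities, grouping rows by outcome pattern."""
    n, J = Y.shape
    if J == 1:
        s = 2.0 * Y[:, 0] - 1.0
        p = stats.norm.cdf(s * Mu[:, 0])
        return float(np.maximum(np.log(np.clip(p, 0, 1)), log_floor).sum())
    codes = Y @ (1 << np.arange(J))
    total = 0.0
    for code in np.unique(codes):
        idx = np.flatnonzero(codes == code)
        s = 2.0 * Y[idx[0]] - 1.0
        D = sigma * np.outer(s, s)
        L = np.linalg.cholesky(D)
        p = _ghk_rectangle(Mu[idx] * s, L, u[idx])
        total += float(np.maximum(np.log(np.clip(p, 1e-320, 1.0)), log_floor).sum())
    return total


def log_simulated_likelihood(
    Y: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    sigma: np.ndarray,
    R: int = 100,
    seed: int = 0,
    antithetic: bool = True,
    u: np.ndarray | None = None,
    log_floor: float = LOG_FLOOR,
) -> float:
    """Simulated log-likelihood sum_i log P(y_i | x_i beta, Sigma)."""
    Y = np.asarray(Y, dtype=int)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if u is None:
        u = _ghk_draws(len(Y), R, Y.shape[1], seed, antithetic)
    return _grouped_loglik(Y, X @ beta, np.asarray(sigma, float), u, log_floor)


# ---------------------------------------------------------------------------
# parameterization helpers


def _sigma_from_theta(theta: np.ndarray, J: int) -> np.ndarray:
    rho = np.tanh(theta)
    sigma = np.eye(J)
    iu = np.triu_indices(J, 1)
    sigma[iu] = rho
    sigma[(iu[1], iu[0])] = rho
    return sigma


def _univariate_probit(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Plain probit MLE used for starting values."""

    def nll(b):
        z = X @ b
        ll = y * stats.norm.logcdf(z) + (1 - y) * stats.norm.logcdf(-z)
        return -ll.sum()

    def grad(b):
        z = X @ b
        pdf = stats.norm.pdf(z)
        cdf = np.clip(stats.norm.cdf(z), 1e-12, 1 - 1e-12)
        w = y * pdf / cdf - (1 - y) * pdf / (1 - cdf)
        return -(X * w[:, None]).sum(axis=0)

    res = optimize.minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS")
    return res.x


@dataclass
class MvProbitFit:
    outcomes: list[str]
    regressors: list[str]               # includes the leading intercept
    beta: pd.DataFrame                  # regressors x outcomes
    sigma: pd.DataFrame                 # outcomes x outcomes
    params: pd.DataFrame                # Table-layout rows b_j_k / R_j_k
    loglik: float
    converged: bool
    n_obs: int
    draws: int
    seed: int
    diagnostics: dict = field(default_factory=dict)


def fit(
    data: pd.DataFrame,
    outcomes: list[str],
    regressors: list[str],
    R: int = 100,
    seed: int = 0,
    antithetic: bool = True,
    maxiter: int = 500,
) -> MvProbitFit:
    """Fit the multivariate probit by GHK simulated maximum likelihood.

    Rows with any missing outcome or regressor are dropped listwise.
    Starting values: independent univariate probits and zero correlations.
    Standard errors come from the inverse numerical Hessian of the
    simulated log-likelihood; correlation SEs use the delta method on the
    tanh parameterization.
    """
    cols = list(outcomes) + list(regressors)
    work = data[cols].apply(pd.to_numeric, errors="coerce").dropna()
    n = len(work)
    J = len(outcomes)
    Y = work[outcomes].to_numpy(dtype=int)
    for j, out in enumerate(outcomes):
        uniq = set(np.unique(Y[:, j]).tolist())
        if not uniq <= {0, 1}:
            raise ValueError(f"outcome {out!r} is not binary")
        if len(uniq) < 2:
            raise SeparationError(f"outcome {out!r} is degenerate (all {uniq.pop()})")
    X = np.column_stack(
        [np.ones(n)] + [work[r].to_numpy(dtype=float) for r in regressors]
    )
    k = X.shape[1]
    if n <= J * k + J * (J - 1) // 2:
        raise ValueError("more parameters than observations")

    u = _ghk_draws(n, R, J, seed, antithetic)
    n_pairs = J * (J - 1) // 2

    beta0 = np.column_stack([_univariate_probit(Y[:, j], X) for j in range(J)])
    x0 = np.concatenate([beta0.ravel(order="F"), np.zeros(n_pairs)])

    def unpack(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta = params[: J * k].reshape((k, J), order="F")
        sigma = _sigma_from_theta(params[J * k :], J)
        return beta, sigma

    def negloglik(params: np.ndarray) -> float:
        beta, sigma = unpack(params)
        eig_min = np.linalg.eigvalsh(sigma).min()
        if eig_min < 1e-6:
            return 1e10 + 1e10 * (1e-6 - eig_min)  # PD penalty
        return -_grouped_loglik(Y, X @ beta, sigma, u)

    res = optimize.minimize(
        negloglik,
        x0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7},
    )
    params_hat = res.x
    beta_hat, sigma_hat = unpack(params_hat)
    loglik = -float(res.fun)

    hess = _numerical_hessian(negloglik, params_hat)
    try:
        cov = np.linalg.inv(hess)
        cov_ok = True
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
        cov_ok = False
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    reg_names = ["intercept"] + list(regressors)
    rows = []
    for j, out in enumerate(outcomes):
        for kk in range(k):
            est = float(beta_hat[kk, j])
            s_e = float(se[j * k + kk])
            rows.append(_param_row(f"b_{j + 1}_{kk}", f"{out} ~ {reg_names[kk]}", est, s_e))
    iu = np.triu_indices(J, 1)
    theta_hat = params_hat[J * k :]
    for m, (a, b) in enumerate(zip(*iu)):
        rho = float(np.tanh(theta_hat[m]))
        s_e = float(se[J * k + m] * (1.0 - rho**2))  # delta method
        rows.append(
            _param_row(f"R_{a + 1}_{b + 1}", f"corr({outcomes[a]}, {outcomes[b]})", rho, s_e)
        )
    params_df = pd.DataFrame(rows).set_index("coefficient")

    return MvProbitFit(
        outcomes=list(outcomes),
        regressors=reg_names,
        beta=pd.DataFrame(beta_hat, index=reg_names, columns=outcomes),
        sigma=pd.DataFrame(sigma_hat, index=outcomes, columns=outcomes),
        params=params_df,
        loglik=loglik,
        converged=bool(res.success),
        n_obs=n,
        draws=R,
        seed=seed,
        diagnostics={
            "message": str(res.message),
            "n_iter": int(res.nit),
            "grad_norm": float(np.max(np.abs(res.jac))) if res.jac is not None else None,
            "hessian_invertible": cov_ok,
            "dropped_rows": int(len(data) - n),
        },
    )


def _param_row(name: str, meaning: str, est: float, se: float) -> dict:
    t = est / se if se > 0 else np.nan
    p = 2.0 * stats.norm.sf(abs(t)) if np.isfinite(t) else np.nan
    return {
        "coefficient": name,
        "meaning": meaning,
        "estimate": est,
        "std_error": se,
        "t_value": t,
        "p_value": p,
    }


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian (symmetrized)."""
    p = len(x)
    hess = np.zeros((p, p))
    f0 = f(x)
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = steps[i]
        for j in range(i, p):
            ej = np.zeros(p)
            ej[j] = steps[j]
            if i == j:
                hess[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
            else:
                fpp = f(x + ei + ej)
                fpm = f(x + ei - ej)
                fmp = f(x - ei + ej)
                fmm = f(x - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                    4 * steps[i] * steps[j]
                )
    return hess


def format_fit(fit_result: MvProbitFit) -> pd.DataFrame:
    """Report table: rows b_j_k then R_j_k with Estimate/Std.Error/t/p."""
    df = fit_result.params.copy()
    df = df.rename(
        columns={
            "meaning": "Meaning",
            "estimate": "Estimate",
            "std_error": "Std.Error",
            "t_value": "t values",
            "p_value": "Pr(>t)",
        }
    )
    df.index.name = "Coefficients"
    return df[["Meaning", "Estimate", "Std.Error", "t values", "Pr(>t)"]]
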
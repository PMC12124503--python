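"""Binary-association stage: tetrachoric correlation, KMO, Bartlett, PCA.

The tetrachoric coefficient is the maximum-likelihood estimate under the
latent bivariate-normal threshold model: thresholds are fixed at the
normal quantiles of the margins and the correlation maximizes the
multinomial likelihood of the four cells, searched on (-0.999, 0.999).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

RHO_BOUND = 0.999


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(
        stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True).cdf(
            [h, k]
        )
    )


def _cell_probabilities(h: float, k: float, rho: float) -> np.ndarray:
    """2x2 cell probabilities; cell [i, j] = P(x=i, y=j), x=1 iff latent > h."""
    p_hk = bvn_cdf(h, k, rho)
    p_x0 = stats.norm.cdf(h)
    p_y0 = stats.norm.cdf(k)
    p00 = p_hk
    p01 = p_x0 - p_hk
    p10 = p_y0 - p_hk
    p11 = 1.0 - p_x0 - p_y0 + p_hk
    return np.clip(np.array([[p00, p01], [p10, p11]]), 1e-12, 1.0)


def tetrachoric_pair(table: np.ndarray) -> float:
    """ML tetrachoric correlation from a 2x2 count table.

    ``table[i][j]`` counts observations with x=i, y=j.  Returns NaN (with a
    warning) when either margin is empty; empty cells push the estimate to
    the search boundary, which is flagged with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    n = t.sum()
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        warnings.warn("tetrachoric: zero margin, coefficient undefined")
        return float("nan")
    h = stats.norm.ppf(row[0] / n)  # P(x=0)
    k = stats.norm.ppf(col[0] / n)

    def nll(rho: float) -> float:
        return -float((t * np.log(_cell_probabilities(h, k, rho))).sum())

    res = optimize.minimize_scalar(
        nll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(res.x)
    if (t == 0).any() and abs(rho) > RHO_BOUND - 1e-3:
        warnings.warn("tetrachoric: empty cell, estimate at search boundary")
    return rho


@dataclass
class CorrelationMatrix:
    values: pd.DataFrame
    method: str = "tetrachoric"
    psd_repaired: bool = False

    @property
    def array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def _nearest_psd(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipping PSD repair, diagonal renormalized to 1."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, eps, None)
    repaired = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def tetrachoric_matrix(data: pd.DataFrame, method: str = "tetrachoric") -> CorrelationMatrix:
    """Pairwise correlation matrix of binary columns.

    Non-PSD results (possible with pairwise ML estimates) are repaired by
    eigenvalue clipping and flagged.
    """
    cols = list(data.columns)
    p = len(cols)
    mat = np.eye(p)
    if method == "pearson":
        mat = data.astype(float).corr().to_numpy()
    elif method == "tetrachoric":
        arrays = {c: np.asarray(data[c], dtype=int) for c in cols}
        for c in cols:
            bad = ~np.isin(arrays[c], [0, 1])
            if bad.any():
                raise ValueError(f"column {c!r} is not binary")
        for i in range(p):
            for j in range(i + 1, p):
                x, y = arrays[cols[i]], arrays[cols[j]]
                table = np.array(
                    [
                        [np.sum((x == 0) & (y == 0)), np.sum((x == 0) & (y == 1))],
                        [np.sum((x == 1) & (y == 0)), np.sum((x == 1) & (y == 1))],
                    ]
                )
                mat[i, j] = mat[j, i] = tetrachoric_pair(table)
    else:
        raise ValueError(f"unknown method {method!r}")

    repaired = False
    if not np.isnan(mat).any():
        eigvals = np.linalg.eigvalsh(mat)
        if eigvals.min() < 0:
            mat = _nearest_psd(mat)
            repaired = True
    return CorrelationMatrix(
        values=pd.DataFrame(mat, index=cols, columns=cols),
        method=method,
        psd_repaired=repaired,
    )


def kmo(corr: CorrelationMatrix | pd.DataFrame | np.ndarray) -> tuple[float, pd.Series]:
    """Kaiser-Meyer-Olkin sampling adequacy: overall and per-variable.

    KMO = sum(r^2) / (sum(r^2) + sum(q^2)) over off-diagonal entries, with
    ``q`` the anti-image partial correlations from the inverse matrix.
    """
    r, names = _as_matrix(corr)
    try:
        inv = np.linalg.inv(r)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; apply PSD repair before KMO"
        ) from None
    d = 1.0 / np.sqrt(np.diag(inv))
    partial = -inv * np.outer(d, d)
    off = ~np.eye(len(r), dtype=bool)
    r2 = r[off] ** 2
    q2 = partial[off] ** 2
    overall = float(r2.sum() / (r2.sum() + q2.sum()))
    per_var = {}
    for i, name in enumerate(names):
        mask = np.ones(len(r), dtype=bool)
        mask[i] = False
        ri2 = r[i, mask] ** 2
        qi2 = partial[i, mask] ** 2
        per_var[name] = float(ri2.sum() / (ri2.sum() + qi2.sum()))
    return overall, pd.Series(per_var)


def bartlett_sphericity(
    corr: CorrelationMatrix | pd.DataFrame | np.ndarray, n: int
) -> tuple[float, int, float]:
    """Bartlett test of sphericity: statistic, dof, p-value."""
    r, _ = _as_matrix(corr)
    p = len(r)
    if n <= p:
        raise ValueError("Bartlett test requires n > p")
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise np.linalg.LinAlgError("correlation matrix is not positive definite")
    stat = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    dof = p * (p - 1) // 2
    pval = float(stats.chi2.sf(stat, dof)) if dof > 0 else 1.0
    return float(stat), int(dof), pval


def _as_matrix(corr) -> tuple[np.ndarray, list[str]]:
    if isinstance(corr, CorrelationMatrix):
        return corr.array, list(corr.values.columns)
    if isinstance(corr, pd.DataFrame):
        return corr.to_numpy(dtype=float), list(corr.columns)
    arr = np.asarray(corr, dtype=float)
    return arr, [f"v{i}" for i in range(arr.shape[0])]


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame          # variables x components, scaled by sqrt(eigenvalue)
    eigenvectors: pd.DataFrame      # unit-norm columns
    pct_variance: np.ndarray
    contributions: pd.DataFrame     # percent, columns sum to 100
    retained: list[int] = field(default_factory=list)  # 0-based component indices


def pca(corr: CorrelationMatrix | pd.DataFrame | np.ndarray, n_keep: int | None = None) -> PcaResult:
    """Eigendecomposition of the correlation matrix.

    Components are ordered by decreasing eigenvalue; each eigenvector's
    sign is fixed so its largest-magnitude loading is positive.  Retention
    defaults to the components before the largest successive eigenvalue
    drop (elbow), overridable with ``n_keep``.
    """
    r, names = _as_matrix(corr)
    vals, vecs = np.linalg.eigh(r)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    p = len(vals)
    comp_names = [f"PC{j + 1}" for j in range(p)]
    loadings = vecs * np.sqrt(np.clip(vals, 0.0, None))
    contributions = 100.0 * vecs**2
    if n_keep is not None:
        if not 1 <= n_keep <= p:
            raise ValueError(f"n_keep must lie in 1..{p}")
        retained = list(range(n_keep))
    elif p == 1:
        retained = [0]
    else:
        drops = vals[:-1] - vals[1:]
        retained = list(range(int(np.argmax(drops)) + 1))
    return PcaResult(
        eigenvalues=vals,
        loadings=pd.DataFrame(loadings, index=names, columns=comp_names),
        eigenvectors=pd.DataFrame(vecs, index=names, columns=comp_names),
        pct_variance=100.0 * vals / vals.sum(),
        contributions=pd.DataFrame(contributions, index=names, columns=comp_names),
        retained=retained,
    )


def select_features(result: PcaResult, rule: str = "contribution") -> list[str]:
    """Variables whose contribution to the retained components exceeds 100/p.

    The per-variable contribution is averaged over the retained components
    with eigenvalue weights; variables strictly above the uniform
    expectation are returned in descending order of contribution.
    """
    if rule != "contribution":
        raise ValueError(f"unknown selection rule {rule!r}")
    p = len(result.contributions)
    weights = result.eigenvalues[result.retained]
    weights = weights / weights.sum()
    contrib = result.contributions.iloc[:, result.retained].to_numpy() @ weights
    series = pd.Series(contrib, index=result.contributions.index)
    threshold = 100.0 / p
    selected = series[series > threshold + 1e-9].sort_values(ascending=False)
    return list(selected.index)
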
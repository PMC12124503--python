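"""Independent oracle implementations used only by the test suite.

These deliberately use different algorithms/representations from the
package code they check.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats


def slot_simulator(pref: tuple[int, int, int], events) -> list[tuple[int, int]]:
    """Greedy slot-consumption simulator for the sequential classifier.

    Explicitly re-assigns quota slots to the living children in birth
    order at every birth: each child fills its own sex quota first, then a
    shared either-gender slot; the newborn is gender-excess iff it lands
    in the overflow, parity-excess iff the living count (including it)
    exceeds the ideal family size.  Returns (gender_flag, parity_flag) per
    birth.
    """
    b_quota, g_quota, n_either = pref
    total_quota = b_quota + g_quota + n_either
    living: list[tuple[int, str]] = []  # (birth_order, sex), insertion-ordered
    out = []
    order = 0
    for event in events:
        if event[0] == "birth":
            order += 1
            sex = event[1]
            roster = living + [(order, sex)]
            boys_used = girls_used = either_used = 0
            newborn_overflow = False
            for o, s in sorted(roster):
                if s == "M":
                    if boys_used < b_quota:
                        boys_used += 1
                        slotted = True
                    elif either_used < n_either:
                        either_used += 1
                        slotted = True
                    else:
                        slotted = False
                else:
                    if girls_used < g_quota:
                        girls_used += 1
                        slotted = True
                    elif either_used < n_either:
                        either_used += 1
                        slotted = True
                    else:
                        slotted = False
                if o == order:
                    newborn_overflow = not slotted
            parity = len(roster) > total_quota
            out.append((int(newborn_overflow), int(parity)))
            living.append((order, sex))
        elif event[0] == "death":
            living = [(o, s) for o, s in living if o != event[1]]
        else:
            raise ValueError(event)
    return out


def static_brute_force(pref: tuple[int, int, int], boys: int, girls: int) -> dict:
    """Direct evaluation of the three static inequalities."""
    b_m, g_m, n_m = pref
    return {
        "excess_parity": int(boys + girls > b_m + g_m + n_m),
        "excess_boys": int(boys > b_m + n_m),
        "excess_girls": int(girls > g_m + n_m),
    }


def bvn_cdf_owens(h, k, rho):
    """Vectorized standard bivariate normal CDF via Owen's T function.

    Independent of scipy's multivariate_normal quadrature path.  Accepts
    array-valued rho.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    out = np.empty(h.shape)
    eps = 1e-15

    flat = zip(h.ravel(), k.ravel(), rho.ravel())
    res = []
    for hh, kk, rr in flat:
        rr = np.clip(rr, -1 + 1e-12, 1 - 1e-12)
        denom = np.sqrt(1.0 - rr**2)
        if abs(hh) < eps and abs(kk) < eps:
            res.append(0.25 + np.arcsin(rr) / (2 * np.pi))
            continue
        if abs(hh) < eps:
            hh = eps
        if abs(kk) < eps:
            kk = eps
        ah = (kk / hh - rr) / denom
        ak = (hh / kk - rr) / denom
        val = (
            0.5 * (stats.norm.cdf(hh) + stats.norm.cdf(kk))
            - float(special.owens_t(hh, ah))
            - float(special.owens_t(kk, ak))
        )
        if hh * kk < 0 or (hh * kk == 0 and (hh + kk) < 0):
            val -= 0.5
        res.append(val)
    out.ravel()[:] = res
    return out if out.shape else float(out)


def grid_tetrachoric(table: np.ndarray, step: float = 0.001) -> float:
    """Grid-search tetrachoric MLE over rho using the Owen's-T BVN CDF."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    h = stats.norm.ppf(t.sum(axis=1)[0] / n)
    k = stats.norm.ppf(t.sum(axis=0)[0] / n)
    rhos = np.arange(-0.999, 0.999 + step / 2, step)
    p00 = np.array([bvn_cdf_owens(h, k, r) for r in rhos])
    phh = stats.norm.cdf(h)
    pkk = stats.norm.cdf(k)
    p01 = phh - p00
    p10 = pkk - p00
    p11 = 1.0 - phh - pkk + p00
    cells = np.stack([p00, p01, p10, p11], axis=1)
    cells = np.clip(cells, 1e-12, 1.0)
    counts = np.array([t[0, 0], t[0, 1], t[1, 0], t[1, 1]])
    loglik = (np.log(cells) * counts).sum(axis=1)
    return float(rhos[np.argmax(loglik)])


def quadrant_table(rho: float, n: float = 1_000_000) -> np.ndarray:
    """Exact quadrant probabilities (thresholds 0) scaled to counts."""
    p_pp = 0.25 + np.arcsin(rho) / (2 * np.pi)
    p_pm = 0.5 - p_pp
    return n * np.array([[p_pp, p_pm], [p_pm, p_pp]])


def bvn_rectangle_quadrature(y, mu, rho) -> float:
    """P(Y = y) for a bivariate probit cell by adaptive quadrature."""
    from scipy import integrate

    s = 2 * np.asarray(y) - 1
    r = rho * s[0] * s[1]
    lim = [[-np.inf, s[0] * mu[0]], [-np.inf, s[1] * mu[1]]]

    def pdf(x2, x1):
        det = 1 - r**2
        q = (x1**2 - 2 * r * x1 * x2 + x2**2) / det
        return np.exp(-q / 2) / (2 * np.pi * np.sqrt(det))

    val, _ = integrate.dblquad(pdf, lim[0][0], lim[0][1], lim[1][0], lim[1][1])
    return val
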
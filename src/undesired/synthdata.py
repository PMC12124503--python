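"""DHS-like synthetic population generator with known ground truth.

Mothers receive an ideal composition drawn from a user-specified
distribution over (boys, girls, either) triples (truncated so the ideal
family size never exceeds nine), a number of live births, per-child sexes
and independent under-five deaths, and covariate blocks.  Binary outcomes
are produced from a latent multivariate normal — ``y_j = 1`` iff
``x·beta_j + eps_j > 0`` with ``eps ~ MVN(0, Sigma)`` — so the residual
correlation structure of the downstream multivariate probit is the true
generating process.

Draw order (single seeded generator): preferences, birth counts, child
sexes, deaths, mother covariates, child covariates, outcome residuals.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import schema
from .classify import FertilityPreference, classify_children_sequential

MAX_IDEAL = 9
MAX_BIRTHS = 12


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    """Full parameterization of the synthetic population."""

    n_mothers: int
    ideal_dist: list[tuple[tuple[int, int, int], float]]
    births_dist: list[tuple[int, float]]
    sex_ratio_male: float = 0.512
    u5_death_prob: float = 0.05
    covariate_spec: dict[str, tuple[list, list[float]]] = field(default_factory=dict)
    outcomes: list[str] = field(default_factory=list)
    outcome_beta: dict[str, dict[str, float]] = field(default_factory=dict)
    outcome_sigma: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_mothers < 0:
            raise ConfigError("n_mothers must be non-negative")
        if not 0.0 < self.sex_ratio_male < 1.0:
            raise ConfigError("sex_ratio_male must lie in (0, 1)")
        if not 0.0 <= self.u5_death_prob <= 1.0:
            raise ConfigError("u5_death_prob must lie in [0, 1]")
        _check_dist(self.ideal_dist, "ideal_dist")
        _check_dist(self.births_dist, "births_dist")
        for (b, g, n), _ in self.ideal_dist:
            if min(b, g, n) < 0 or b + g + n > MAX_IDEAL:
                raise ConfigError(
                    f"ideal_dist triple {(b, g, n)} violates the <= {MAX_IDEAL} truncation"
                )
        for k, _ in self.births_dist:
            if not 0 <= k <= MAX_BIRTHS:
                raise ConfigError(f"births_dist support must lie in 0..{MAX_BIRTHS}")
        for name, (levels, probs) in self.covariate_spec.items():
            if len(levels) != len(probs):
                raise ConfigError(f"covariate {name!r}: levels/probs length mismatch")
            _check_probs(probs, f"covariate {name!r}")
        if self.outcomes:
            sigma = np.asarray(self.outcome_sigma, dtype=float)
            j = len(self.outcomes)
            if sigma.shape != (j, j):
                raise ConfigError("outcome_sigma shape does not match outcomes")
            if not np.allclose(sigma, sigma.T):
                raise ConfigError("outcome_sigma is not symmetric")
            if not np.allclose(np.diag(sigma), 1.0):
                raise ConfigError("outcome_sigma must have unit diagonal")
            try:
                np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                raise ConfigError("outcome_sigma is not positive definite") from None
            self.outcome_sigma = sigma
            missing = set(self.outcomes) - set(self.outcome_beta)
            if missing:
                raise ConfigError(f"outcome_beta missing outcomes {sorted(missing)}")


def _check_probs(probs: Sequence[float], what: str) -> None:
    arr = np.asarray(probs, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ConfigError(f"{what}: probabilities must lie in [0, 1]")
    if not np.isclose(arr.sum(), 1.0):
        raise ConfigError(f"{what}: probabilities must sum to 1 (got {arr.sum():.6f})")


def _check_dist(dist: Sequence[tuple], what: str) -> None:
    if not dist:
        raise ConfigError(f"{what} must be non-empty")
    _check_probs([p for _, p in dist], what)


@dataclass
class SimPopulation:
    mothers: pd.DataFrame
    children: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# component draws (scalar API used by tests; the vectorized path mirrors them)


def generate_preferences(config: SimConfig, rng: np.random.Generator) -> FertilityPreference:
    """Draw one ideal-composition triple from ``ideal_dist``."""
    triples = [t for t, _ in config.ideal_dist]
    probs = [p for _, p in config.ideal_dist]
    idx = rng.choice(len(triples), p=probs)
    b, g, n = triples[idx]
    return FertilityPreference(b, g, n)


def generate_birth_history(
    pref: FertilityPreference, config: SimConfig, rng: np.random.Generator
) -> list[dict]:
    """Draw an ordered birth history: count, sexes, then death indicators."""
    ks = [k for k, _ in config.births_dist]
    probs = [p for _, p in config.births_dist]
    k = ks[rng.choice(len(ks), p=probs)]
    sexes = np.where(rng.random(k) < config.sex_ratio_male, "M", "F")
    dead = rng.random(k) < config.u5_death_prob
    return [
        {
            "birth_order": i + 1,
            "sex": str(sexes[i]),
            "alive": int(not dead[i]),
            "death_after": (i + 1) if dead[i] else None,
        }
        for i in range(k)
    ]


def generate_outcomes(
    X: np.ndarray,
    beta: np.ndarray,
    sigma: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent-Gaussian binary outcomes: ``1{X beta_j + eps_j > 0}``.

    ``X`` is (n, p) or (p,); ``beta`` is (p, J); ``sigma`` the (J, J)
    residual correlation.  Returns an int array of matching leading shape.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.asarray(beta, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if X.shape[1] != beta.shape[0]:
        raise ValueError(
            f"design has {X.shape[1]} columns but beta has {beta.shape[0]} rows"
        )
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise ConfigError("outcome_sigma is not positive definite") from None
    eps = rng.standard_normal((X.shape[0], sigma.shape[0])) @ chol.T
    latent = X @ beta + eps
    return (latent > 0).astype(int)


# ---------------------------------------------------------------------------
# full population


def simulate_population(config: SimConfig, compute_analytic: bool = False) -> SimPopulation:
    """Generate a full population; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_mothers

    triples = np.array([t for t, _ in config.ideal_dist], dtype=int)
    tprobs = np.array([p for _, p in config.ideal_dist], dtype=float)
    pref_idx = rng.choice(len(triples), size=n, p=tprobs) if n else np.array([], int)
    prefs = triples[pref_idx] if n else np.empty((0, 3), int)

    ks = np.array([k for k, _ in config.births_dist], dtype=int)
    kprobs = np.array([p for _, p in config.births_dist], dtype=float)
    births = ks[rng.choice(len(ks), size=n, p=kprobs)] if n else np.array([], int)
    total = int(births.sum())

    child_mother = np.repeat(np.arange(1, n + 1), births)
    birth_order = np.concatenate([np.arange(1, k + 1) for k in births]) if total else np.array([], int)
    sexes = np.where(rng.random(total) < config.sex_ratio_male, "M", "F")
    dead = rng.random(total) < config.u5_death_prob

    mothers = pd.DataFrame(
        {
            "mother_id": np.arange(1, n + 1),
            "B_m": prefs[:, 0] if n else np.array([], int),
            "G_m": prefs[:, 1] if n else np.array([], int),
            "N_m": prefs[:, 2] if n else np.array([], int),
        }
    )
    mothers["C_m"] = mothers[["B_m", "G_m", "N_m"]].sum(axis=1)

    children = pd.DataFrame(
        {
            "mother_id": child_mother,
            "birth_order": birth_order,
            "sex": sexes,
            "alive": (~dead).astype(int),
            "death_after": np.where(dead, birth_order, np.nan),
        }
    )

    mother_covs, child_covs = _split_covariate_spec(config.covariate_spec)
    for name, (levels, probs) in mother_covs.items():
        idx = rng.choice(len(levels), size=n, p=probs) if n else np.array([], int)
        mothers[name] = np.asarray(levels, dtype=object)[idx] if n else []
    for name, (levels, probs) in child_covs.items():
        idx = rng.choice(len(levels), size=total, p=probs) if total else np.array([], int)
        children[name] = np.asarray(levels, dtype=object)[idx] if total else []
    if "age_ch" not in children.columns:
        children["age_ch"] = np.zeros(total, dtype=int)

    if config.outcomes:
        design, names = _design_matrix(config, mothers, children)
        beta = np.column_stack(
            [
                [config.outcome_beta[out].get(term, 0.0) for term in names]
                for out in config.outcomes
            ]
        )
        y = generate_outcomes(design, beta, config.outcome_sigma, rng)
        for j, out in enumerate(config.outcomes):
            children[out] = y[:, j] if total else np.array([], int)

    truth = {
        "seed": config.seed,
        "outcomes": list(config.outcomes),
        "beta": {
            out: dict(config.outcome_beta[out]) for out in config.outcomes
        },
        "sigma": np.asarray(config.outcome_sigma).tolist() if config.outcomes else None,
    }
    if compute_analytic:
        truth["analytic_excess_prevalence"] = analytic_excess_prevalence(config)
    return SimPopulation(mothers=mothers, children=children, truth=truth)


def _split_covariate_spec(spec: Mapping) -> tuple[dict, dict]:
    child_names = {"age_ch"}
    mother = {k: v for k, v in spec.items() if k not in child_names}
    child = {k: v for k, v in spec.items() if k in child_names}
    return mother, child


#: design terms resolvable against the merged child+mother table
def _design_matrix(
    config: SimConfig, mothers: pd.DataFrame, children: pd.DataFrame
) -> tuple[np.ndarray, list[str]]:
    terms: set[str] = set()
    for out in config.outcomes:
        terms |= set(config.outcome_beta[out])
    terms.discard("intercept")
    names = ["intercept"] + sorted(terms)
    merged = children.merge(mothers, on="mother_id", how="left", sort=False)
    merged["bord"] = merged["birth_order"]
    merged["sex_ch"] = merged["sex"]
    cols = [np.ones(len(merged))]
    for term in names[1:]:
        if term not in merged.columns:
            raise ConfigError(f"outcome_beta references unknown design term {term!r}")
        cols.append(schema.encode_column(merged[term], term).to_numpy(dtype=float))
    return np.column_stack(cols) if len(merged) else np.empty((0, len(names))), names


# ---------------------------------------------------------------------------
# exact prevalence oracle


def analytic_excess_prevalence(
    config: SimConfig, dual_rule: str = "sex_and_parity", max_births: int = MAX_BIRTHS
) -> dict:
    """Exact expected excess prevalences by full enumeration.

    Enumerates (preference triple, birth count, sex sequence, death
    pattern) with their probabilities, applying the sequential classifier;
    deaths follow the generator's convention (realized immediately after
    the child's own birth).  Child-level prevalence is the ratio of the
    expected flagged count to the expected number of children; mother
    level is the probability of at least one flagged child.
    """
    for k, _ in config.births_dist:
        if k > max_births:
            raise ConfigError(
                f"births_dist support exceeds {max_births}; truncate the distribution"
            )
    p_male = config.sex_ratio_male
    q = config.u5_death_prob
    cats = schema.EXCESS_CATEGORIES
    exp_flagged = dict.fromkeys(cats, 0.0)
    p_any = dict.fromkeys(cats, 0.0)
    exp_children = 0.0

    death_opts = (False, True) if q > 0 else (False,)
    for (b, g, nn), p_pref in config.ideal_dist:
        if p_pref == 0:
            continue
        pref = FertilityPreference(b, g, nn)
        for k, p_k in config.births_dist:
            if p_k == 0:
                continue
            exp_children += p_pref * p_k * k
            if k == 0:
                continue
            for sexes in itertools.product("MF", repeat=k):
                p_sex = 1.0
                for s in sexes:
                    p_sex *= p_male if s == "M" else 1.0 - p_male
                for deaths in itertools.product(death_opts, repeat=k):
                    p_death = 1.0
                    for d in deaths:
                        p_death *= q if d else 1.0 - q
                    prob = p_pref * p_k * p_sex * p_death
                    if prob == 0.0:
                        continue
                    events: list = []
                    for i, (s, d) in enumerate(zip(sexes, deaths), start=1):
                        events.append(("birth", s))
                        if d:
                            events.append(("death", i))
                    flags = classify_children_sequential(pref, events, dual_rule)
                    counts = {
                        "excess_boys": sum(f.excess_boys for f in flags),
                        "excess_girls": sum(f.excess_girls for f in flags),
                        "excess_dual": sum(f.dual_excess for f in flags),
                        "excess_parity": sum(f.parity_excess for f in flags),
                    }
                    for cat in cats:
                        exp_flagged[cat] += prob * counts[cat]
                        if counts[cat] > 0:
                            p_any[cat] += prob

    child_level = {
        cat: (exp_flagged[cat] / exp_children if exp_children > 0 else 0.0)
        for cat in cats
    }
    return {
        "expected_children_per_mother": exp_children,
        "child_level": child_level,
        "mother_level": dict(p_any),
    }


# ---------------------------------------------------------------------------
# IO


def write_population(pop: SimPopulation, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mothers": outdir / "mothers.csv",
        "children": outdir / "children.csv",
        "truth": outdir / "truth.json",
    }
    pop.mothers.to_csv(paths["mothers"], index=False)
    pop.children.to_csv(paths["children"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(pop.truth, fh, indent=2, sort_keys=True)
    return paths


def default_config(n_mothers: int = 2000, seed: int = 0, outcomes: bool = True) -> SimConfig:
    """A ready-to-run configuration resembling a South-Asian household survey."""
    ideal_dist = [
        ((2, 1, 1), 0.30),
        ((1, 1, 2), 0.25),
        ((2, 2, 0), 0.20),
        ((0, 0, 4), 0.15),
        ((1, 1, 0), 0.05),
        ((0, 0, 2), 0.05),
    ]
    births_dist = [
        (0, 0.08),
        (1, 0.15),
        (2, 0.20),
        (3, 0.20),
        (4, 0.15),
        (5, 0.10),
        (6, 0.07),
        (7, 0.03),
        (8, 0.02),
    ]
    covariate_spec = {
        "edu": (["none", "primary", "secondary", "higher"], [0.523, 0.156, 0.201, 0.120]),
        "wealth": (["poor", "middle", "rich"], [0.452, 0.199, 0.349]),
        "resid": (["urban", "rural"], [0.472, 0.528]),
        "prov": (
            ["punjab", "sindh", "kpk", "balochistan", "ict", "fata"],
            [0.2836, 0.1935, 0.1927, 0.1205, 0.0798, 0.1299],
        ),
        "mage": (["<20", "20-29", "30-39", "40-49"], [0.092, 0.603, 0.288, 0.017]),
        "wsw": ([0, 1], [0.844, 0.156]),
        "exc_m": ([0, 1], [0.808, 0.192]),
        "empment": ([0, 1], [0.812, 0.188]),
        "visit_hw": ([0, 1], [0.451, 0.549]),
        "age_ch": ([0, 1, 2, 3, 4], [0.2, 0.2, 0.2, 0.2, 0.2]),
    }
    if not outcomes:
        return SimConfig(
            n_mothers=n_mothers,
            ideal_dist=ideal_dist,
            births_dist=births_dist,
            covariate_spec=covariate_spec,
            seed=seed,
        )
    outs = list(schema.ALL_OUTCOMES)
    base_prev = {
        "diarrhea": 0.22,
        "fever": 0.22,
        "cough": 0.21,
        "srb": 0.20,
        "ari": 0.18,
        "pnc": 0.28,
        "vita": 0.26,
        "tod": 0.46,
        "tofc": 0.40,
    }
    from scipy.stats import norm

    beta = {}
    for out in outs:
        beta[out] = {
            "intercept": float(norm.ppf(base_prev[out])),
            "bord": 0.05,
            "age_ch": -0.04,
            "wealth": -0.05 if out in schema.MORBIDITY_OUTCOMES else 0.08,
            "edu": -0.03 if out in schema.MORBIDITY_OUTCOMES else 0.06,
        }
    j = len(outs)
    sigma = np.full((j, j), 0.05)
    np.fill_diagonal(sigma, 1.0)
    return SimConfig(
        n_mothers=n_mothers,
        ideal_dist=ideal_dist,
        births_dist=births_dist,
        covariate_spec=covariate_spec,
        outcomes=outs,
        outcome_beta=beta,
        outcome_sigma=sigma,
        seed=seed,
    )
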
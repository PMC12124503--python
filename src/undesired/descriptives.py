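"""Moment summaries and prevalence cross-tabulations.

Conventions: sample variance (n-1 denominator); skewness and kurtosis are
the standardized third and fourth central moments with population (biased)
normalization, and kurtosis is *not* excess-corrected (a normal variable
has kurtosis 3).  Constant variables report variance 0 with undefined
(None) skewness/kurtosis.  Percentages are kept at full precision
internally and rounded only when tables are written.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import schema


def summarize_variables(
    table: pd.DataFrame, variables: list[str] | None = None
) -> pd.DataFrame:
    """Mean/variance/sd/skewness/kurtosis per variable (Table-1 layout)."""
    if variables is None:
        variables = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for name in variables:
        x = pd.to_numeric(table[name], errors="raise").dropna().to_numpy(dtype=float)
        if len(x) == 0:
            raise ValueError(f"variable {name!r} has no observations")
        mean = float(x.mean())
        var = float(x.var(ddof=1)) if len(x) > 1 else 0.0
        sd = float(np.sqrt(var))
        m2 = float(((x - mean) ** 2).mean())
        if m2 > 0:
            skew = float(((x - mean) ** 3).mean() / m2**1.5)
            kurt = float(((x - mean) ** 4).mean() / m2**2)
        else:
            skew = None
            kurt = None
        rows.append(
            {
                "variable": name,
                "mean": mean,
                "variance": var,
                "sd": sd,
                "skewness": skew,
                "kurtosis": kurt,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def prevalence_by_excess(
    data: pd.DataFrame,
    outcome: str,
    flag_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Outcome-positive rate among flagged vs unflagged children.

    One row per excess category with the percentage of outcome-positive
    children in the flag=1 and flag=0 strata and both denominators.  Empty
    strata report a None percentage with an explicit zero denominator.
    """
    flag_columns = flag_columns or schema.EXCESS_CATEGORIES
    y = schema.as_binary(data[outcome], outcome)
    rows = []
    for cat in flag_columns:
        f = schema.as_binary(data[cat], cat)
        mask1, mask0 = (f == 1), (f == 0)
        n1, n0 = int(mask1.sum()), int(mask0.sum())
        rows.append(
            {
                "category": cat,
                "rate_flagged": 100.0 * float(y[mask1].mean()) if n1 else None,
                "rate_unflagged": 100.0 * float(y[mask0].mean()) if n0 else None,
                "n_flagged": n1,
                "n_unflagged": n0,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def outcome_composition_table(
    data: pd.DataFrame,
    outcomes: list[str],
    flag_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Composition of outcome-positive children by excess flag (Table-3 layout).

    For each outcome row and each excess category, the No/Yes columns give
    the percentage of outcome-positive children who are unflagged/flagged;
    they sum to 100 by construction.  ``total`` is the outcome-positive
    count.
    """
    flag_columns = flag_columns or schema.EXCESS_CATEGORIES
    rows = []
    for out in outcomes:
        y = schema.as_binary(data[out], out)
        pos = data.loc[y == 1]
        row: dict = {"outcome": out, "total": len(pos)}
        for cat in flag_columns:
            if len(pos):
                yes = 100.0 * float(schema.as_binary(pos[cat], cat).mean())
                row[f"{cat}_no"] = 100.0 - yes
                row[f"{cat}_yes"] = yes
            else:
                row[f"{cat}_no"] = None
                row[f"{cat}_yes"] = None
        rows.append(row)
    return pd.DataFrame(rows).set_index("outcome")


def crosstab_background(
    data: pd.DataFrame,
    background_var: str,
    flag_columns: list[str] | None = None,
    levels: list | None = None,
) -> pd.DataFrame:
    """Percent flagged in each excess category per background level (Table 2).

    Unknown levels (not in the documented level set) are pooled into an
    ``other`` row with a warning.
    """
    import warnings

    flag_columns = flag_columns or schema.EXCESS_CATEGORIES
    if levels is None:
        levels = schema.CATEGORICAL_LEVELS.get(background_var)
    col = data[background_var]
    if levels is not None:
        known = col.isin(levels)
        if (~known).any():
            warnings.warn(
                f"{background_var}: {int((~known).sum())} records with unknown "
                "levels pooled into 'other'"
            )
        groups = [(lev, data.loc[col == lev]) for lev in levels]
        if (~known).any():
            groups.append(("other", data.loc[~known]))
    else:
        groups = [(lev, grp) for lev, grp in data.groupby(background_var, sort=True)]
    rows = []
    for lev, grp in groups:
        row: dict = {"level": lev, "total": len(grp)}
        for cat in flag_columns:
            row[cat] = (
                100.0 * float(schema.as_binary(grp[cat], cat).mean()) if len(grp) else None
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("level")
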
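"""Column schemas, level orders and recode maps shared by every stage.

All categorical covariates are stored as labelled strings in the CSV
artifacts; models receive ordinal codes produced by :func:`encode_column`.
Binary flags are stored as {0, 1} integers and child sex as {"M", "F"}.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

SEX_LEVELS = ["M", "F"]

#: ordered level sets for the labelled categorical covariates
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "edu": ["none", "primary", "secondary", "higher"],
    "wealth": ["poor", "middle", "rich"],
    "resid": ["urban", "rural"],
    "prov": ["punjab", "sindh", "kpk", "balochistan", "ict", "fata"],
    "mage": ["<20", "20-29", "30-39", "40-49"],
    "sex_ch": ["M", "F"],
}

#: covariates stored directly as {0,1}
BINARY_COVARIATES = ["wsw", "exc_m", "empment", "visit_hw"]

#: integer-valued covariates
INTEGER_COVARIATES = ["age_ch", "bord"]

MORBIDITY_OUTCOMES = ["diarrhea", "fever", "cough", "srb", "ari"]
TREATMENT_OUTCOMES = ["pnc", "vita", "tod", "tofc"]
ALL_OUTCOMES = MORBIDITY_OUTCOMES + TREATMENT_OUTCOMES

EXCESS_CATEGORIES = ["excess_boys", "excess_girls", "excess_dual", "excess_parity"]

#: short regressor aliases used on model surfaces
EXCESS_ALIASES = {
    "eb": "excess_boys",
    "eg": "excess_girls",
    "ed": "excess_dual",
    "ep": "excess_parity",
}

MOTHER_COLUMNS = [
    "mother_id",
    "B_m",
    "G_m",
    "N_m",
    "C_m",
    "edu",
    "wealth",
    "resid",
    "prov",
    "mage",
    "wsw",
    "exc_m",
    "empment",
    "visit_hw",
]

CHILD_COLUMNS = [
    "mother_id",
    "birth_order",
    "sex",
    "alive",
    "death_after",
    "age_ch",
] + ALL_OUTCOMES

#: DHS-style numeric recodes accepted on input and remapped with a warning
NUMERIC_SEX_RECODE = {"1": "M", "2": "F", 1: "M", 2: "F"}


def encode_column(series: pd.Series, name: str) -> pd.Series:
    """Return the ordinal numeric encoding of a covariate column.

    Labelled categoricals map to 0-based codes in their documented level
    order; binary and integer covariates pass through as numbers.
    """
    if name in CATEGORICAL_LEVELS:
        levels = CATEGORICAL_LEVELS[name]
        mapping = {lev: i for i, lev in enumerate(levels)}
        unknown = set(series.dropna().unique()) - set(levels)
        if unknown:
            raise ValueError(f"column {name!r} has unknown levels {sorted(unknown)}")
        return series.map(mapping).astype(float)
    return pd.to_numeric(series)


def encode_frame(df: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    """Ordinal-encode the named columns of ``df`` into a numeric frame."""
    out = {}
    for name in columns:
        if name not in df.columns:
            raise KeyError(f"missing column {name!r}")
        out[name] = encode_column(df[name], name)
    return pd.DataFrame(out, index=df.index)


def check_columns(df: pd.DataFrame, required: Iterable[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{table}: missing required column(s) {missing}")


def remap_sex(series: pd.Series) -> tuple[pd.Series, bool]:
    """Remap DHS-style 1/2 sex codes to M/F. Returns (series, remapped?)."""
    values = set(series.dropna().unique())
    if values <= set(SEX_LEVELS):
        return series, False
    if values <= set(NUMERIC_SEX_RECODE):
        return series.map(NUMERIC_SEX_RECODE), True
    raise ValueError(f"sex column has unrecognised codes {sorted(map(str, values))}")


def as_binary(series: pd.Series, name: str) -> pd.Series:
    arr = pd.to_numeric(series)
    bad = ~arr.isin([0, 1]) & arr.notna()
    if bad.any():
        raise ValueError(f"column {name!r} is not binary 0/1")
    return arr.astype("Int64")
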
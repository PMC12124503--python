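"""Undesiredness classification from fertility preferences and birth histories.

Two classifiers are provided:

* a *static* mother-level rule comparing the living composition at survey
  time with the stated ideal composition, and
* a *sequential* child-level rule that walks the ordered birth/death events
  and flags each newborn at the moment of its birth.  Flags, once assigned,
  are immutable; a death frees the deceased child's quota slot for later
  births but never revises an earlier flag.

The "either gender" quota (``N_m``) is consumed greedily in birth order
once a sex-specific quota is full, so with an ideal of two boys, one girl
and one either-gender child, a third consecutive boy occupies the
either-gender slot and only a fourth boy is flagged.

Two dual-excess readings exist and are both implemented behind
``dual_rule``:

* ``sex_and_parity`` (default): a unit is dual-excess when it is excess in
  its own gender composition *and* in parity;
* ``both_sexes``: dual-excess requires the boy quota and the girl quota to
  be simultaneously exceeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import schema

DualRule = Literal["sex_and_parity", "both_sexes"]
DUAL_RULES = ("sex_and_parity", "both_sexes")


@dataclass(frozen=True)
class FertilityPreference:
    """A mother's ideal composition: boys, girls and either-gender slots."""

    boys: int
    girls: int
    either: int

    def __post_init__(self) -> None:
        if min(self.boys, self.girls, self.either) < 0:
            raise ValueError("preference counts must be non-negative")

    @property
    def total(self) -> int:
        """Ideal family size (sum of the three quota components)."""
        return self.boys + self.girls + self.either

    def quota(self, sex: str) -> int:
        return self.boys if sex == "M" else self.girls


@dataclass(frozen=True)
class ChildRecord:
    birth_order: int
    sex: str
    alive: bool = True


@dataclass
class BirthHistory:
    """Ordered per-child records with derived living composition counts."""

    records: list[ChildRecord] = field(default_factory=list)

    @property
    def living_boys(self) -> int:
        return sum(1 for r in self.records if r.alive and r.sex == "M")

    @property
    def living_girls(self) -> int:
        return sum(1 for r in self.records if r.alive and r.sex == "F")

    @property
    def living_children(self) -> int:
        return self.living_boys + self.living_girls


@dataclass(frozen=True)
class ExcessFlags:
    excess_parity: int
    excess_boys: int
    excess_girls: int
    excess_dual: int
    level: str = "mother"

    def as_dict(self) -> dict[str, int]:
        return {
            "excess_boys": self.excess_boys,
            "excess_girls": self.excess_girls,
            "excess_dual": self.excess_dual,
            "excess_parity": self.excess_parity,
        }


def classify_mother_static(
    pref: FertilityPreference,
    hist: BirthHistory,
    dual_rule: DualRule = "sex_and_parity",
) -> ExcessFlags:
    """Static mother-level classification from living counts at survey time.

    Parity excess holds when living children exceed the ideal family size;
    a sex is in excess when its living count exceeds its own quota plus all
    either-gender slots.
    """
    _check_dual_rule(dual_rule)
    b, g = hist.living_boys, hist.living_girls
    ep = int(b + g - pref.total > 0)
    eb = int(b - (pref.boys + pref.either) > 0)
    eg = int(g - (pref.girls + pref.either) > 0)
    if dual_rule == "both_sexes":
        ed = int(eb and eg)
    else:
        ed = int((eb or eg) and ep)
    return ExcessFlags(ep, eb, eg, ed, level="mother")


# ---------------------------------------------------------------------------
# sequential child-level classifier


@dataclass(frozen=True)
class ChildFlags:
    birth_order: int
    sex: str
    gender_excess: int
    parity_excess: int
    dual_excess: int

    @property
    def excess_boys(self) -> int:
        return self.gender_excess if self.sex == "M" else 0

    @property
    def excess_girls(self) -> int:
        return self.gender_excess if self.sex == "F" else 0


Event = tuple[str, object]  # ("birth", "M"|"F") or ("death", birth_order)


class SequenceError(ValueError):
    """Raised for malformed event sequences (e.g. death of unknown child)."""


def _check_dual_rule(dual_rule: str) -> None:
    if dual_rule not in DUAL_RULES:
        raise ValueError(f"dual_rule must be one of {DUAL_RULES}, got {dual_rule!r}")


def _gender_excess_at_birth(
    pref: FertilityPreference, n_same: int, n_other: int, sex: str
) -> bool:
    """Is the newborn gender-excess given living same/other-sex counts?

    ``n_same`` includes the newborn.  Either-gender slots already consumed
    by living other-sex children are unavailable to the newborn's sex.
    """
    other = "F" if sex == "M" else "M"
    either_used_by_other = min(pref.either, max(0, n_other - pref.quota(other)))
    return n_same > pref.quota(sex) + (pref.either - either_used_by_other)


def classify_children_sequential(
    pref: FertilityPreference,
    events: Sequence[Event],
    dual_rule: DualRule = "sex_and_parity",
) -> list[ChildFlags]:
    """Flag each newborn at the moment of its birth, walking the events.

    For every ``("birth", sex)`` event the newborn is

    * gender-excess iff the living same-sex count including it exceeds the
      sex quota plus the either-gender slots not consumed by the other sex;
    * parity-excess iff the living children including it exceed the ideal
      family size;
    * dual-excess per ``dual_rule``.

    ``("death", birth_order)`` events remove the named child from the
    living set; subsequent births then see the freed composition.
    """
    _check_dual_rule(dual_rule)
    living: dict[int, str] = {}
    live = {"M": 0, "F": 0, "U": 0}  # "U" = missing sex: parity only
    flags: list[ChildFlags] = []
    next_order = 1
    for event in events:
        kind = event[0]
        if kind == "birth":
            sex = event[1]
            if sex not in ("M", "F", "U"):
                raise SequenceError(f"birth event with invalid sex {sex!r}")
            order = next_order
            next_order += 1
            n_boys = live["M"] + (sex == "M")
            n_girls = live["F"] + (sex == "F")
            parity = (n_boys + n_girls + live["U"] + (sex == "U")) > pref.total
            if sex == "U":
                gender = False
            else:
                n_same = n_boys if sex == "M" else n_girls
                n_other = n_girls if sex == "M" else n_boys
                gender = _gender_excess_at_birth(pref, n_same, n_other, sex)
            if dual_rule == "both_sexes":
                boys_exceed = _gender_excess_at_birth(pref, n_boys, n_girls, "M")
                girls_exceed = _gender_excess_at_birth(pref, n_girls, n_boys, "F")
                dual = boys_exceed and girls_exceed
            else:
                dual = gender and parity
            flags.append(ChildFlags(order, sex, int(gender), int(parity), int(dual)))
            living[order] = sex
            live[sex] += 1
        elif kind == "death":
            order = event[1]
            if order not in living:
                raise SequenceError(f"death event for unknown or dead child {order!r}")
            live[living.pop(order)] -= 1
        else:
            raise SequenceError(f"unknown event kind {kind!r}")
    return flags


def events_from_records(children: pd.DataFrame) -> list[Event]:
    """Build an event sequence from child rows of one mother.

    Births are emitted in birth order.  A dead child contributes a death
    event placed immediately after the birth indicated by ``death_after``
    (default: its own birth), mirroring the generator's convention.
    """
    rows = children.sort_values("birth_order")
    deaths: dict[int, list[int]] = {}
    for _, row in rows.iterrows():
        if not bool(row["alive"]):
            after = row.get("death_after")
            pos = int(row["birth_order"]) if pd.isna(after) else int(after)
            deaths.setdefault(pos, []).append(int(row["birth_order"]))
    events: list[Event] = []
    for _, row in rows.iterrows():
        order = int(row["birth_order"])
        events.append(("birth", str(row["sex"])))
        for dead in deaths.pop(order, []):
            events.append(("death", dead))
    if deaths:
        raise SequenceError(f"death_after positions beyond last birth: {sorted(deaths)}")
    return events


# ---------------------------------------------------------------------------
# table-level drivers


def apply_eligibility_filters(
    mothers: pd.DataFrame,
    children: pd.DataFrame,
    max_ideal: int = 9,
    max_child_age: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply the eligibility rules and return filtered tables plus a report.

    Mothers with an ideal family size above ``max_ideal`` or a missing
    ideal response are dropped (with their children).  Child-level outcome
    analysis is restricted to children aged ``max_child_age`` or less at
    the survey (born in the five years before it).
    """
    schema.check_columns(mothers, ["mother_id", "B_m", "G_m", "N_m", "C_m"], "mothers")
    schema.check_columns(
        children, ["mother_id", "birth_order", "sex", "alive"], "children"
    )
    report: dict = {"input_mothers": len(mothers), "input_children": len(children)}

    ideal = mothers[["B_m", "G_m", "N_m", "C_m"]].apply(pd.to_numeric, errors="coerce")
    missing = ideal.isna().any(axis=1)
    too_many = ideal["C_m"] > max_ideal
    keep = ~(missing | too_many)
    report["dropped_ideal_missing"] = int(missing.sum())
    report["dropped_ideal_gt9"] = int((too_many & ~missing).sum())

    mothers_out = mothers.loc[keep].copy()
    kept_ids = set(mothers_out["mother_id"])
    child_of_kept = children["mother_id"].isin(kept_ids)
    report["dropped_children_of_excluded_mothers"] = int((~child_of_kept).sum())
    children_out = children.loc[child_of_kept].copy()

    if "age_ch" in children_out.columns:
        young = pd.to_numeric(children_out["age_ch"]) <= max_child_age
        report["dropped_child_age_gt_window"] = int((~young).sum())
        children_out = children_out.loc[young].copy()
    else:
        report["dropped_child_age_gt_window"] = 0

    report["output_mothers"] = len(mothers_out)
    report["output_children"] = len(children_out)
    return mothers_out, children_out, report


def classify_population(
    mothers: pd.DataFrame,
    children: pd.DataFrame,
    dual_rule: DualRule = "sex_and_parity",
) -> pd.DataFrame:
    """Per-child sequential flags plus per-mother static flags.

    Returns one row per child (``level="child"``) and one row per mother
    (``level="mother"``, ``birth_order`` 0) with the four excess columns.
    """
    _check_dual_rule(dual_rule)
    schema.check_columns(mothers, ["mother_id", "B_m", "G_m", "N_m"], "mothers")
    cs = children.sort_values(["mother_id", "birth_order"])
    n_unknown_sex = int((~cs["sex"].isin(["M", "F"])).sum())
    if n_unknown_sex:
        import warnings

        warnings.warn(
            f"{n_unknown_sex} children with missing sex: "
            "counted for parity, excluded from gender excess"
        )
    has_death_after = "death_after" in cs.columns
    grouped: dict = {}
    for mid, grp in cs.groupby("mother_id", sort=False):
        orders = grp["birth_order"].to_numpy(dtype=int)
        sexes = grp["sex"].to_numpy(dtype=object)
        alive = grp["alive"].to_numpy(dtype=int)
        death_after = (
            grp["death_after"].to_numpy(dtype=float)
            if has_death_after
            else np.full(len(grp), np.nan)
        )
        grouped[mid] = (orders, sexes, alive, death_after)

    rows: list[tuple] = []
    mcols = mothers[["mother_id", "B_m", "G_m", "N_m"]].to_numpy(dtype=object)
    for mid, bm, gm, nm in mcols:
        pref = FertilityPreference(int(bm), int(gm), int(nm))
        group = grouped.get(mid)
        if group is not None:
            orders, sexes, alive, death_after = group
            deaths: dict[int, list[int]] = {}
            for o, a, d in zip(orders, alive, death_after):
                if not a:
                    pos = int(o) if np.isnan(d) else int(d)
                    deaths.setdefault(pos, []).append(int(o))
            events: list[Event] = []
            for o, s in zip(orders, sexes):
                s = str(s) if s in ("M", "F") else "U"  # missing sex: parity only
                events.append(("birth", s))
                for dead in deaths.pop(int(o), []):
                    events.append(("death", dead))
            if deaths:
                raise SequenceError(
                    f"mother {mid}: death_after positions beyond last birth"
                )
            for cf in classify_children_sequential(pref, events, dual_rule):
                rows.append(
                    (mid, cf.birth_order, "child", cf.excess_boys,
                     cf.excess_girls, cf.dual_excess, cf.parity_excess)
                )
            hist = BirthHistory(
                [
                    ChildRecord(int(o), str(s), bool(a))
                    for o, s, a in zip(orders, sexes, alive)
                ]
            )
        else:
            hist = BirthHistory([])
        mf = classify_mother_static(pref, hist, dual_rule)
        rows.append(
            (mid, 0, "mother", mf.excess_boys, mf.excess_girls,
             mf.excess_dual, mf.excess_parity)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mother_id",
            "birth_order",
            "level",
            "excess_boys",
            "excess_girls",
            "excess_dual",
            "excess_parity",
        ],
    )


def aggregate_excess(flags: pd.DataFrame) -> dict:
    """Population prevalence of each excess category.

    Child level: fraction of children flagged.  Mother level: fraction of
    mothers with at least one flagged child (mothers without children count
    in the denominator, unflagged).
    """
    child = flags[flags["level"] == "child"]
    mother_ids = flags.loc[flags["level"] == "mother", "mother_id"]
    n_children = len(child)
    n_mothers = len(mother_ids)
    out = {
        "n_children": n_children,
        "n_mothers": n_mothers,
        "child_level": {},
        "mother_level": {},
    }
    any_by_mother = (
        child.groupby("mother_id")[schema.EXCESS_CATEGORIES].max()
        if n_children
        else pd.DataFrame(columns=schema.EXCESS_CATEGORIES)
    )
    for cat in schema.EXCESS_CATEGORIES:
        c_count = int(child[cat].sum()) if n_children else 0
        m_count = int(any_by_mother[cat].sum()) if len(any_by_mother) else 0
        out["child_level"][cat] = {
            "count": c_count,
            "percent": 100.0 * c_count / n_children if n_children else 0.0,
        }
        out["mother_level"][cat] = {
            "count": m_count,
            "percent": 100.0 * m_count / n_mothers if n_mothers else 0.0,
        }
    return out
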
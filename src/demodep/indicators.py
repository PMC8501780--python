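"""Dependency indicators: ADR, LFDR and the productivity-weighted LFDR.

* ``ADR`` — age dependency ratio: (population under 15 + population 65+) /
  population 15-64.  Purely age-based; the conventional measure.
* ``LFDR`` — labour-force dependency ratio: inactive persons of *all* ages
  (children count as inactive here, "out of the labour force irrespective of
  age") per active person.
* ``PWLFDR`` — the LFDR with each active person multiplied by the
  productivity factor of their education level:
  ``I / sum_e W_e * A_e``.  With unit weights it reduces to the LFDR
  exactly.  A value of 1 means one inactive per productivity equivalent of a
  reference-education (upper secondary) worker.

Ratios are computed on weighted person counts and are invariant to a uniform
rescaling of all case weights.
"""

from __future__ import annotations

import pandas as pd

from .types import (
    AGE_LABELS,
    CHILD_MAX,
    EducationLadder,
    OLD_MIN,
    PopulationFrame,
    ProductivityWeights,
    WORKING_MAX,
    WORKING_MIN,
)


def adr(frame: PopulationFrame) -> float:
    """(under-15 + 65-and-over) / 15-64, in weighted persons."""
    age = frame.age_codes()
    w = frame.weights()
    workers = w[(age >= WORKING_MIN) & (age <= WORKING_MAX)].sum()
    if workers <= 0:
        raise ZeroDivisionError("no weighted population aged 15-64")
    dependents = w[(age <= CHILD_MAX) | (age >= OLD_MIN)].sum()
    return float(dependents / workers)


def lfdr(frame: PopulationFrame) -> float:
    """Inactive (all ages, children included) per active person."""
    active = frame.data["activity"].astype(str).to_numpy() == "active"
    w = frame.weights()
    a = w[active].sum()
    if a <= 0:
        raise ZeroDivisionError("no weighted active population")
    return float((w.sum() - a) / a)


def pwlfdr(frame: PopulationFrame, weights: ProductivityWeights) -> float:
    """I / sum_e W_e * A_e — inactives per productivity-equivalent worker.

    The numerator is the unweighted inactive count (productivity factors
    apply to workers only); every occupied active education level must have
    a factor.
    """
    df = frame.data
    active = df["activity"].astype(str).to_numpy() == "active"
    w = frame.weights()
    inactive_total = float(w.sum() - w[active].sum())
    denom = 0.0
    sub = df[active]
    for lvl, grp in sub.groupby("education", observed=True):
        denom += weights[str(lvl)] * float(grp["weight"].sum())
    if denom <= 0:
        raise ZeroDivisionError("zero productivity-weighted active population")
    return inactive_total / denom


def indicator_series(
    trajectory, weights: ProductivityWeights
) -> pd.DataFrame:
    """ADR/LFDR/PWLFDR per period for a projection trajectory.

    Accepts a list of frames or of ``(frame, tally)`` pairs; returns a frame
    indexed by period with columns ``adr, lfdr, pwlfdr``.
    """
    rows = {}
    for item in trajectory:
        frame = item[0] if isinstance(item, tuple) else item
        rows[frame.period] = {
            "adr": adr(frame),
            "lfdr": lfdr(frame),
            "pwlfdr": pwlfdr(frame, weights),
        }
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "period"
    return out


def normalize_series(series: pd.DataFrame, base_period: int) -> pd.DataFrame:
    """Divide each indicator by its own base-period value (base maps to 1)."""
    if base_period not in series.index:
        raise KeyError(f"base period {base_period} not in series")
    base = series.loc[base_period]
    if (base <= 0).any():
        raise ZeroDivisionError("base-period indicator value is zero")
    return series / base


def tier_map(ladder: EducationLadder) -> dict[str, str]:
    """Collapse the ladder to low/medium/high around the reference level.

    Low = below the reference ("lower than secondary"), medium = the
    reference (upper secondary), high = above (postsecondary).  Children's
    placeholder education maps to low.
    """
    ref = ladder.index(ladder.reference)
    mapping = {"none": "low"}
    for lvl in ladder.levels:
        i = ladder.index(lvl)
        mapping[lvl] = "low" if i < ref else ("medium" if i == ref else "high")
    return mapping


def pyramid_summary(frame: PopulationFrame) -> pd.DataFrame:
    """Weighted counts by age band x sex x education tier x activity.

    The tabular analogue of an age pyramid coloured by education tier and
    labour-force status; rows partition the population, so the ``weight``
    column sums to the weighted total.
    """
    df = frame.data
    if len(df) == 0:
        return pd.DataFrame(columns=["age_group", "sex", "tier", "activity", "weight"])
    tiers = df["education"].astype(str).map(tier_map(frame.ladder))
    out = (
        df.assign(tier=tiers, age_group=[AGE_LABELS[a] for a in df["age"]])
        .groupby(["age_group", "sex", "tier", "activity"], observed=True)["weight"]
        .sum()
        .reset_index()
    )
    return out[out["weight"] > 0].reset_index(drop=True)


def active_counts_by_education(trajectory) -> pd.DataFrame:
    """Weighted active population per education tier per period."""
    if not len(trajectory):
        raise ValueError("empty trajectory")
    rows = []
    for item in trajectory:
        frame = item[0] if isinstance(item, tuple) else item
        df = frame.data
        active = df[df["activity"].astype(str) == "active"]
        tiers = active["education"].astype(str).map(tier_map(frame.ladder))
        grouped = active.groupby(tiers, observed=True)["weight"].sum()
        for tier in ("low", "medium", "high"):
            rows.append(
                {"period": frame.period, "tier": tier,
                 "active_weight": float(grouped.get(tier, 0.0))}
            )
    return pd.DataFrame(rows)
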
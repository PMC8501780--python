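"""Discrete-time stochastic projection engine.

Each 5-year step applies, in the fixed order the model prescribes:

1. mortality (survival ratios by age, sex, education),
2. education shifts (entry distribution at 15-19, upward transitions until
   attainment freezes at 30-34),
3. emigration of survivors (rates by age and sex),
4. immigration (case injection from an a-priori profile),
5. fertility (births to exposed women; the newborn inherits the mother's
   weight),
6. labour-force assignment from the participation logit.

Ages are incremented immediately after mortality: survivorship ratios apply
to the band occupied at *t*, while the education/emigration/fertility events
are phrased in terms of the band attained at *t+5* ("at the age of 15 to 19
the cohort is broken down ...").  Incrementing early is arithmetically the
same model as incrementing at the end of the step with event lookups shifted
by one band, but it keeps every frame valid under the data-model invariants:
a cohort reaching 15-19 gets its education and labour-force status within the
same step it enters working age.

Every Monte Carlo outcome comes from :mod:`demodep.streams` keyed by
(seed, individual, event, period), so runs are reproducible and scenarios
sharing a seed share randomness individual by individual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import streams
from .base_population import make_immigrant_cases
from .types import (
    AGE_LABELS,
    CHILD_MAX,
    EDU_NONE,
    EducationLadder,
    FERTILE_MAX,
    FERTILE_MIN,
    LfpLogitParams,
    N_AGE,
    PopulationFrame,
    RateSchedules,
    ScenarioConfig,
    SEXES,
    age_code,
)
from .rate_models import predict_participation_rate


@dataclass
class EventTally:
    """Weighted event counts for one projection step (all values >= 0).

    ``births`` is the weight of newborns alive at the end of the step; it is
    the quantity entering the accounting identity
    ``N(t+5) = N(t) - deaths - emigrants + immigrants + births``.
    """

    period: int
    deaths: float = 0.0
    emigrants: float = 0.0
    immigrants: float = 0.0
    births: float = 0.0
    births_total: float = 0.0
    newborn_deaths: float = 0.0

    def as_dict(self) -> dict:
        return {
            "period": self.period,
            "deaths": self.deaths,
            "emigrants": self.emigrants,
            "immigrants": self.immigrants,
            "births": self.births,
            "births_total": self.births_total,
            "newborn_deaths": self.newborn_deaths,
        }


# --------------------------------------------------------------------------
# Schedule lookups
# --------------------------------------------------------------------------


def _sex_index(values) -> np.ndarray:
    return pd.Categorical(values, categories=SEXES).codes.astype(np.int64)


def _survival_lookup(schedules: RateSchedules, period: int, ladder: EducationLadder) -> np.ndarray:
    sub = schedules.survival[schedules.survival["period"] == period]
    arr = np.full((N_AGE, 2, len(ladder.all_codes)), np.nan)
    ages = np.array([age_code(a) for a in sub["age_group"]])
    sexes = _sex_index(sub["sex"])
    edus = np.array([ladder.code(e) for e in sub["education"]])
    arr[ages, sexes, edus] = sub["ratio"].to_numpy(dtype=float)
    return arr


def _emigration_lookup(schedules: RateSchedules, period: int) -> np.ndarray:
    sub = schedules.emigration[schedules.emigration["period"] == period]
    arr = np.full((N_AGE, 2), np.nan)
    ages = np.array([age_code(a) for a in sub["age_group"]])
    arr[ages, _sex_index(sub["sex"])] = sub["rate"].to_numpy(dtype=float)
    return arr


def _fertility_lookup(schedules: RateSchedules, period: int) -> np.ndarray:
    sub = schedules.fertility[schedules.fertility["period"] == period]
    arr = np.zeros(N_AGE)
    ages = np.array([age_code(a) for a in sub["age_group"]])
    arr[ages] = sub["shape"].to_numpy(dtype=float)
    return arr


def _newborn_survival_lookup(schedules: RateSchedules, period: int) -> np.ndarray:
    sub = schedules.newborn_survival[schedules.newborn_survival["period"] == period]
    arr = np.ones(2)
    arr[_sex_index(sub["sex"])] = sub["ratio"].to_numpy(dtype=float)
    return arr


def _raise_missing(frame: PopulationFrame, missing: np.ndarray, what: str) -> None:
    if missing.any():
        i = int(np.argmax(missing))
        row = frame.data.iloc[i]
        raise ValueError(
            f"no {what} for occupied stratum period={frame.period} "
            f"age={AGE_LABELS[int(row['age'])]} sex={row['sex']} education={row['education']}"
        )


# --------------------------------------------------------------------------
# Events
# --------------------------------------------------------------------------


def step_mortality(
    frame: PopulationFrame, schedules: RateSchedules, seed: int
) -> tuple[PopulationFrame, float]:
    """Remove non-survivors; returns the surviving frame and weighted deaths."""
    lookup = _survival_lookup(schedules, frame.period, frame.ladder)
    s = lookup[frame.age_codes(), frame.sex_codes(), frame.edu_codes()]
    _raise_missing(frame, np.isnan(s), "survival ratio")
    u = streams.uniforms(seed, frame.ids(), streams.EV_MORTALITY, frame.period + 5)
    alive = u < s
    deaths = float(frame.weights()[~alive].sum())
    return frame.replace(data=frame.data[alive].reset_index(drop=True)), deaths


def age_increment(frame: PopulationFrame) -> PopulationFrame:
    """Move every case up one band; the top-open 100+ band absorbs."""
    df = frame.data.copy()
    df["age"] = np.minimum(df["age"].to_numpy() + 1, N_AGE - 1).astype(np.int16)
    return frame.replace(data=df)


def step_education(
    frame: PopulationFrame, schedules: RateSchedules, seed: int
) -> PopulationFrame:
    """Assign entry attainment at 15-19 and apply upward transitions.

    Ages in the frame are the bands attained at the end of the step; the
    transition table is keyed accordingly.  Transitions never move down the
    ladder, and a state's outgoing probabilities may sum to at most 1 (the
    remainder is "stay").
    """
    ladder = frame.ladder
    sub = schedules.education_transitions[
        schedules.education_transitions["period"] == frame.period
    ]
    if len(sub) == 0:
        return frame
    df = frame.data.copy()
    edu = df["education"].cat.codes.to_numpy().copy()
    age = df["age"].to_numpy()
    sexc = df["sex"].cat.codes.to_numpy()
    ids = df["id"].to_numpy()
    key = frame.period + 5

    for (age_lab, sex, from_lvl), grp in sub.groupby(
        ["age_group", "sex", "from_level"], observed=True
    ):
        acode = age_code(age_lab)
        scode = SEXES.index(sex)
        fcode = ladder.code(from_lvl)
        mask = (age == acode) & (sexc == scode) & (edu == fcode)
        if not mask.any():
            continue
        grp = grp.sort_values("to_level", key=lambda s: s.map(ladder.code))
        dest = np.array([ladder.code(lvl) for lvl in grp["to_level"]])
        probs = grp["prob"].to_numpy(dtype=float)
        if from_lvl == EDU_NONE:
            total = probs.sum()
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"education entry distribution at {age_lab}/{sex} sums to {total}"
                )
            event = streams.EV_EDU_ENTRY
        else:
            if probs.sum() > 1 + 1e-9:
                raise ValueError(
                    f"education transition probabilities out of {from_lvl} at "
                    f"{age_lab}/{sex} sum to {probs.sum()}"
                )
            if (dest <= fcode).any():
                raise ValueError("education transitions must move up the ladder")
            event = streams.EV_EDU_ADVANCE
        cum = np.cumsum(probs)
        if from_lvl == EDU_NONE:
            cum[-1] = 1.0  # guard the last bin against float undershoot
        u = streams.uniforms(seed, ids[mask], event, key)
        pick = np.searchsorted(cum, u, side="right")
        stay = pick >= len(dest)
        new = np.where(stay, edu[mask], dest[np.minimum(pick, len(dest) - 1)])
        edu[mask] = new

    df["education"] = pd.Categorical.from_codes(edu, categories=ladder.all_codes)
    return frame.replace(data=df)


def step_emigration(
    frame: PopulationFrame, schedules: RateSchedules, seed: int
) -> tuple[PopulationFrame, float]:
    """Bernoulli removal at age x sex emigration rates (survivors only)."""
    lookup = _emigration_lookup(schedules, frame.period)
    r = lookup[frame.age_codes(), frame.sex_codes()]
    _raise_missing(frame, np.isnan(r), "emigration rate")
    u = streams.uniforms(seed, frame.ids(), streams.EV_EMIGRATION, frame.period + 5)
    leave = u < r
    emigrants = float(frame.weights()[leave].sum())
    return frame.replace(data=frame.data[~leave].reset_index(drop=True)), emigrants


def step_immigration(
    frame: PopulationFrame, schedules: RateSchedules, cfg: ScenarioConfig, seed: int
) -> tuple[PopulationFrame, float]:
    """Add the period's immigrant cases (may be none)."""
    profile = schedules.immigration[schedules.immigration["period"] == frame.period]
    cases = make_immigrant_cases(
        profile.drop(columns=["period"]), cfg, frame.ladder, period=frame.period
    )
    if len(cases) == 0:
        return frame, 0.0
    merged = pd.concat([frame.data, PopulationFrame(cases, frame.period, frame.ladder).data],
                       ignore_index=True)
    return frame.replace(data=merged), float(cases["weight"].sum())


def step_fertility(
    frame: PopulationFrame, schedules: RateSchedules, cfg: ScenarioConfig, seed: int
) -> tuple[PopulationFrame, dict]:
    """Draw births for exposed women and append surviving newborns.

    Births per woman over the step are Poisson with mean
    ``5 * TFR * shape(age)`` (a Bernoulli would cap at one birth per 5-year
    step and bias high-fertility scenarios down), inverted from a single
    keyed uniform so counts stay comparable across scenarios.  Each newborn
    inherits its mother's weight, draws a sex at the configured sex ratio at
    birth, and survives the remainder of the step with the newborn
    survivorship ratio.
    """
    if cfg.tfr < 0:
        raise ValueError("tfr must be >= 0")
    shape = _fertility_lookup(schedules, frame.period)
    span = 5.0 * shape.sum()
    if abs(span - 1.0) > 1e-6:
        raise ValueError(f"fertility shape for period {frame.period} is unnormalised")
    nb_surv = _newborn_survival_lookup(schedules, frame.period)
    key = frame.period + 5

    df = frame.data
    age = df["age"].to_numpy()
    women = (df["sex"].cat.codes.to_numpy() == 1) & (age >= FERTILE_MIN) & (age <= FERTILE_MAX)
    tally = {"births": 0.0, "births_total": 0.0, "newborn_deaths": 0.0}
    if not women.any() or cfg.tfr == 0:
        return frame, tally

    mother_ids = df["id"].to_numpy()[women]
    mother_w = df["weight"].to_numpy()[women]
    mu = 5.0 * cfg.tfr * shape[age[women]]
    u = streams.uniforms(seed, mother_ids, streams.EV_FERTILITY, key)
    nbirths = streams.poisson_from_uniform(u, mu)

    p_male = cfg.sex_ratio_at_birth / (1.0 + cfg.sex_ratio_at_birth)
    newborn_frames = []
    for parity in range(1, int(nbirths.max()) + 1 if len(nbirths) else 1):
        sel = nbirths >= parity
        if not sel.any():
            break
        cids = streams.child_ids(mother_ids[sel], key, parity)
        w = mother_w[sel]
        tally["births_total"] += float(w.sum())
        male = streams.uniforms(seed, cids, streams.EV_BIRTH_SEX, key) < p_male
        sexc = np.where(male, 0, 1)
        alive = streams.uniforms(seed, cids, streams.EV_NEWBORN_SURVIVAL, key) < nb_surv[sexc]
        tally["newborn_deaths"] += float(w[~alive].sum())
        if alive.any():
            newborn_frames.append(
                pd.DataFrame(
                    {
                        "id": cids[alive],
                        "age": np.zeros(int(alive.sum()), dtype=np.int16),
                        "sex": np.where(male[alive], "male", "female"),
                        "education": EDU_NONE,
                        "activity": "not_applicable",
                        "weight": w[alive],
                        "origin": "birth",
                    }
                )
            )
    tally["births"] = tally["births_total"] - tally["newborn_deaths"]
    if not newborn_frames:
        return frame, tally
    newborns = PopulationFrame(pd.concat(newborn_frames, ignore_index=True),
                               frame.period, frame.ladder)
    merged = pd.concat([frame.data, newborns.data], ignore_index=True)
    return frame.replace(data=merged), tally


def participation_table(params: LfpLogitParams, ladder: EducationLadder) -> np.ndarray:
    """Dense (sex, age band, education-code) probability table.

    Zero outside the prediction window: children are never drawn, and bands
    above the survey window (75+) receive rate 0 rather than an unsafe
    quadratic extrapolation.
    """
    arr = np.zeros((2, N_AGE, len(ladder.all_codes)))
    lo, hi = params.window
    for si, sex in enumerate(SEXES):
        for code in range(lo, hi + 1):
            for lvl in ladder.levels:
                arr[si, code, ladder.code(lvl)] = predict_participation_rate(
                    params, sex, code, lvl
                )
    return arr


def step_labor_force(
    frame: PopulationFrame,
    lfp_params: LfpLogitParams,
    seed: int,
    key_period: int | None = None,
) -> PopulationFrame:
    """Redraw every adult's labour-force status from the participation model.

    Status is cross-sectional — redrawn each period with constant parameters,
    so aggregate participation moves only through composition.  Children stay
    ``not_applicable``; adults above the prediction window are inactive.
    """
    key = frame.period + 5 if key_period is None else key_period
    ladder = frame.ladder
    table = participation_table(lfp_params, ladder)
    df = frame.data.copy()
    age = df["age"].to_numpy()
    adult = age > CHILD_MAX
    if (adult & (df["education"].cat.codes.to_numpy() == 0)).any():
        raise ValueError("adult case(s) without an education level: no prediction stratum")
    p = table[df["sex"].cat.codes.to_numpy(), age, df["education"].cat.codes.to_numpy()]
    u = streams.uniforms(seed, df["id"].to_numpy(), streams.EV_LFP, key)
    active = u < p
    activity = np.where(adult, np.where(active, "active", "inactive"), "not_applicable")
    df["activity"] = pd.Categorical(activity, categories=("active", "inactive", "not_applicable"))
    return frame.replace(data=df)


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------


def run_projection(
    base: PopulationFrame,
    schedules: RateSchedules,
    lfp: LfpLogitParams,
    cfg: ScenarioConfig,
) -> list[tuple[PopulationFrame, EventTally]]:
    """Project ``base`` from ``cfg.start`` to ``cfg.horizon`` in 5-year steps.

    Returns the full trajectory ``[(frame, tally), ...]`` starting with the
    base frame (labour force assigned, empty tally).  Schedule coverage gaps
    are reported before any simulation; the run is fully reproducible from
    ``cfg.seed``.
    """
    if base.period != cfg.start:
        raise ValueError(f"base frame period {base.period} != cfg.start {cfg.start}")
    gaps = schedules.coverage_gaps(cfg.start, cfg.horizon)
    if gaps:
        raise ValueError("schedule coverage gaps: " + "; ".join(gaps))

    current = step_labor_force(base, lfp, cfg.seed, key_period=cfg.start)
    trajectory = [(current, EventTally(period=cfg.start))]
    for t in range(cfg.start, cfg.horizon, 5):
        f = current.replace(period=t)
        f, deaths = step_mortality(f, schedules, cfg.seed)
        f = age_increment(f)
        f = step_education(f, schedules, cfg.seed)
        f, emigrants = step_emigration(f, schedules, cfg.seed)
        f, immigrants = step_immigration(f, schedules, cfg, cfg.seed)
        f, births = step_fertility(f, schedules, cfg, cfg.seed)
        f = step_labor_force(f, lfp, cfg.seed)  # keyed to the attained period t+5
        f = f.replace(period=t + 5)
        tally = EventTally(
            period=t + 5,
            deaths=deaths,
            emigrants=emigrants,
            immigrants=immigrants,
            births=births["births"],
            births_total=births["births_total"],
            newborn_deaths=births["newborn_deaths"],
        )
        trajectory.append((f, tally))
        current = f
    return trajectory


def tallies_frame(trajectory: list[tuple[PopulationFrame, EventTally]]) -> pd.DataFrame:
    """Event tallies of a trajectory as one tidy table."""
    return pd.DataFrame([t.as_dict() for _, t in trajectory])
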
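"""Synthetic inputs with known ground truth for the whole pipeline.

Real applications of this model feed it external population estimates
(age x sex x education), demographic assumption schedules and labour-force
survey microdata.  This module manufactures all three from a single
:class:`SyntheticWorldSpec` so the system is testable end to end with the
generating parameters in hand:

* an aggregate pyramid of a **stylised ageing population** — a mid-age bulge,
  a child deficit and an old-age taper — whose education composition steepens
  toward younger cohorts (cohort replacement: the young are better educated
  than the old they replace);
* complete rate schedules: Gompertz-style survivorship improving over time
  and graded by education, an education entry distribution that keeps
  shifting upward period by period, upward transition probabilities that
  freeze attainment by 30-34, a bell-shaped fertility schedule normalised so
  the scenario TFR scales it exactly, low-volume immigration against larger
  emigration (negative net migration under defaults);
* survey microdata whose activity status is drawn from the true
  participation logit and whose wages are drawn from the true log-link wage
  model, so the calibration fits have a known target to recover.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    AGE_LABELS,
    AGE_MID,
    CHILD_MAX,
    DEFAULT_LADDER,
    EDU_NONE,
    EducationLadder,
    FERTILE_MAX,
    FERTILE_MIN,
    LfpLogitParams,
    N_AGE,
    RateSchedules,
    SEXES,
    WageModelParams,
)

_RANK = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])  # centred ladder ranks (5 levels)


def default_true_lfp(ladder: EducationLadder = DEFAULT_LADDER) -> LfpLogitParams:
    """Plausible ground-truth participation coefficients.

    Reverse-U age profile; higher participation for the better educated in
    mid-life, later retirement for the low educated; women roughly 10-15
    points below men except for highly educated women in their 30s.
    """
    lv = ladder.levels
    male = {
        "intercept": 2.0, "age": 0.08, "age2": -0.13,
        f"edu:{lv[0]}": -0.5, f"edu:{lv[1]}": -0.3, f"edu:{lv[2]}": -0.1,
        f"edu:{lv[4]}": 0.5,
        f"edu_age:{lv[0]}": 0.10, f"edu_age:{lv[1]}": 0.06,
        f"edu_age:{lv[2]}": 0.02, f"edu_age:{lv[4]}": -0.05,
        f"edu_age2:{lv[0]}": 0.020, f"edu_age2:{lv[1]}": 0.012,
        f"edu_age2:{lv[2]}": 0.005, f"edu_age2:{lv[4]}": -0.030,
    }
    female = {
        "intercept": 1.2, "age": 0.05, "age2": -0.14,
        f"edu:{lv[0]}": -0.8, f"edu:{lv[1]}": -0.5, f"edu:{lv[2]}": -0.2,
        f"edu:{lv[4]}": 0.7,
        f"edu_age:{lv[0]}": 0.12, f"edu_age:{lv[1]}": 0.07,
        f"edu_age:{lv[2]}": 0.02, f"edu_age:{lv[4]}": -0.04,
        f"edu_age2:{lv[0]}": 0.022, f"edu_age2:{lv[1]}": 0.012,
        f"edu_age2:{lv[2]}": 0.004, f"edu_age2:{lv[4]}": -0.025,
    }
    return LfpLogitParams(coef={"male": male, "female": female}, ladder=ladder,
                          reference=ladder.reference)


def default_true_wage(ladder: EducationLadder = DEFAULT_LADDER) -> WageModelParams:
    """Ground-truth log-wage model: education premia spanning roughly 0.4x-2x
    the reference wage, a mid-career age hump, a female gap, mild year drift."""
    lv = ladder.levels
    age_eff = {}
    for code in range(3, 15):
        mid = AGE_MID[code]
        age_eff[AGE_LABELS[code]] = round(float(0.35 * np.exp(-0.5 * ((mid - 47.5) / 16.0) ** 2)), 4)
    age_eff[AGE_LABELS[3]] = 0.0  # reference band
    return WageModelParams(
        intercept=float(np.log(1500.0)),
        edu={lv[0]: -1.0, lv[1]: -0.55, lv[2]: -0.25, lv[4]: 0.70},
        age=age_eff,
        sex={"female": -0.25},
        year={2012: 0.08, 2015: 0.20, 2017: 0.30},
        ladder=ladder,
        reference=ladder.reference,
        age_reference=AGE_LABELS[3],
        sex_reference="male",
        year_reference=2010,
    )


@dataclass
class SyntheticWorldSpec:
    """Everything the generators need, with study-condition defaults.

    ``total_population`` defaults to a test-friendly one million persons; the
    shapes (not the scale) are what the generated world shares with a large
    ageing population.  ``edu_gradient`` > 0 makes younger cohorts more
    educated; 0 freezes composition across cohorts.
    """

    total_population: int = 1_000_000
    ladder: EducationLadder = field(default_factory=EducationLadder)
    # pyramid: mid-age bulge, child deficit, old-age taper
    pyramid_mode: float = 45.0
    pyramid_spread: float = 22.0
    child_deficit: float = 0.75
    old_taper_years: float = 12.0
    male_share_young: float = 0.51
    male_share_old: float = 0.47
    # education composition
    edu_base_scores: tuple[float, ...] = (0.6, 0.9, 1.0, 0.6, -0.4)
    edu_gradient: float = 0.8
    female_edu_shift: float = 0.25
    period_edu_gradient: float = 0.15
    # mortality (5-year hazard A*exp(B*age), improving per period)
    mortality_a: float = 5e-5
    mortality_b: float = 0.085
    mortality_improvement: float = 0.985
    edu_mortality_mult: tuple[float, ...] = (1.30, 1.15, 1.00, 0.90, 0.80)
    female_mortality_mult: float = 0.85
    newborn_survival_female: float = 0.995
    newborn_survival_male: float = 0.994
    # fertility shape over bands 15-19 .. 45-49 (normalised internally)
    fertility_raw: tuple[float, ...] = (0.05, 0.35, 0.30, 0.17, 0.09, 0.03, 0.01)
    # migration: low-volume immigration against young-adult emigration
    emigration_peak: float = 0.004
    emigration_age_mode: float = 27.0
    emigration_age_spread: float = 12.0
    male_emigration_mult: float = 1.1
    immigration_per_period: int = 500
    # calibration truth
    true_lfp: LfpLogitParams = field(default_factory=default_true_lfp)
    true_wage: WageModelParams = field(default_factory=default_true_wage)
    survey_years: tuple[int, ...] = (2010, 2012, 2015, 2017)
    wage_overdispersion: float = 0.0

    def pyramid_shares(self) -> np.ndarray:
        mid = AGE_MID
        w = np.exp(-0.5 * ((mid - self.pyramid_mode) / self.pyramid_spread) ** 2)
        w[: CHILD_MAX + 1] *= self.child_deficit
        old = mid > 77.0
        w[old] *= np.exp(-(mid[old] - 77.0) / self.old_taper_years)
        return w / w.sum()

    def male_share(self, code: int) -> float:
        return self.male_share_young if code < 13 else self.male_share_old


def education_probs(
    spec: SyntheticWorldSpec, code: int, sex: str, period_index: int = 0
) -> np.ndarray:
    """Cohort education composition at one adult age band.

    Softmax over ladder-level scores; the gradient term rewards higher levels
    for younger cohorts (and, via ``period_index``, for later entry cohorts).
    At 15-19 any postsecondary mass is folded into upper secondary — nobody
    has completed postsecondary by 19.
    """
    if code <= CHILD_MAX:
        raise ValueError("education composition is defined for ages 15+")
    youth = float(np.clip((12 - min(code, 12)) / 9.0, 0.0, 1.0))
    scores = np.asarray(spec.edu_base_scores, dtype=float).copy()
    scores = scores + spec.edu_gradient * (youth + spec.period_edu_gradient * period_index) * _RANK
    if sex == "female":
        scores = scores - spec.female_edu_shift * _RANK
    p = np.exp(scores - scores.max())
    p = p / p.sum()
    if code == 3:
        ref = spec.ladder.index(spec.ladder.reference)
        top = ref + 1
        p[ref] += p[top:].sum()
        p[top:] = 0.0
    return p


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Round nonnegative targets to integers summing exactly to ``total``."""
    base = np.floor(targets).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(targets - base), kind="stable")
        base[order[:short]] += 1
    return base


def make_aggregate_estimates(spec: SyntheticWorldSpec, seed: int = 0) -> pd.DataFrame:
    """Aggregate base-period person counts by age x sex x education.

    Deterministic (the seed is accepted for interface uniformity): expected
    cell counts are computed from the spec's shares and rounded by largest
    remainder so the table sums exactly to ``total_population``.
    """
    shares = spec.pyramid_shares()
    rows = []
    targets = []
    for code in range(N_AGE):
        for sex in SEXES:
            p_sex = spec.male_share(code) if sex == "male" else 1 - spec.male_share(code)
            if code <= CHILD_MAX:
                rows.append((AGE_LABELS[code], sex, EDU_NONE))
                targets.append(spec.total_population * shares[code] * p_sex)
            else:
                probs = education_probs(spec, code, sex)
                for lvl, p_e in zip(spec.ladder.levels, probs):
                    rows.append((AGE_LABELS[code], sex, lvl))
                    targets.append(spec.total_population * shares[code] * p_sex * p_e)
    counts = _largest_remainder(np.asarray(targets), spec.total_population)
    out = pd.DataFrame(rows, columns=["age_group", "sex", "education"])
    out["count"] = counts
    return out[out["count"] > 0].reset_index(drop=True)


def make_rate_schedules(
    spec: SyntheticWorldSpec, start: int = 2015, horizon: int = 2070
) -> RateSchedules:
    """Complete, validity-checked assumption schedules for [start, horizon)."""
    if horizon < start:
        raise ValueError("horizon must not precede start")
    periods = list(range(start, max(horizon, start + 5), 5))
    ladder = spec.ladder

    surv_rows = []
    emig_rows = []
    fert_rows = []
    nb_rows = []
    tr_rows = []
    imm_rows = []

    fert_shape = np.asarray(spec.fertility_raw, dtype=float)
    fert_shape = fert_shape / (5.0 * fert_shape.sum())

    # immigration composition: young adults, mostly well educated
    imm_age_shares = {4: 0.35, 5: 0.35, 6: 0.20, 7: 0.10}
    imm_edu_shares = dict(zip(ladder.levels, (0.0, 0.0, 0.10, 0.40, 0.50)))

    for k, period in enumerate(periods):
        improve = spec.mortality_improvement**k
        for code in range(N_AGE):
            mid = AGE_MID[code]
            hazard = spec.mortality_a * np.exp(spec.mortality_b * mid) * improve
            for sex in SEXES:
                sex_mult = spec.female_mortality_mult if sex == "female" else 1.0
                if code <= CHILD_MAX:
                    ratio = float(np.exp(-5.0 * hazard * sex_mult))
                    surv_rows.append((period, AGE_LABELS[code], sex, EDU_NONE, ratio))
                else:
                    for lvl, mult in zip(ladder.levels, spec.edu_mortality_mult):
                        ratio = float(np.exp(-5.0 * hazard * sex_mult * mult))
                        surv_rows.append((period, AGE_LABELS[code], sex, lvl, ratio))
                rate = spec.emigration_peak * np.exp(
                    -0.5 * ((mid - spec.emigration_age_mode) / spec.emigration_age_spread) ** 2
                )
                if sex == "male":
                    rate *= spec.male_emigration_mult
                emig_rows.append((period, AGE_LABELS[code], sex, float(min(rate, 1.0))))

        for code, shp in zip(range(FERTILE_MIN, FERTILE_MAX + 1), fert_shape):
            fert_rows.append((period, AGE_LABELS[code], float(shp)))

        nb_improve = spec.mortality_improvement**k
        nb_rows.append((period, "male", float(1 - (1 - spec.newborn_survival_male) * nb_improve)))
        nb_rows.append((period, "female", float(1 - (1 - spec.newborn_survival_female) * nb_improve)))

        # education: entry distribution at 15-19 (shifting upward over periods)
        for sex in SEXES:
            probs = education_probs(spec, 3, sex, period_index=k)
            probs = probs / probs.sum()
            for lvl, p in zip(ladder.levels, probs):
                if p > 0:
                    tr_rows.append((period, AGE_LABELS[3], sex, EDU_NONE, lvl, float(p)))
        # upward transitions; attainment frozen from 30-34 on
        advance = {
            AGE_LABELS[4]: {3: 0.35, 2: 0.10, 1: 0.05, 0: 0.03},
            AGE_LABELS[5]: {3: 0.12, 2: 0.04, 1: 0.02},
            AGE_LABELS[6]: {3: 0.03},
        }
        for age_lab, moves in advance.items():
            for from_idx, p in moves.items():
                for sex in SEXES:
                    tr_rows.append(
                        (period, age_lab, sex,
                         ladder.levels[from_idx], ladder.levels[from_idx + 1], p)
                    )

        # immigration profile
        cell_targets, cell_keys = [], []
        for code, pa in imm_age_shares.items():
            for sex in SEXES:
                for lvl, pe in imm_edu_shares.items():
                    if pe > 0:
                        cell_keys.append((period, AGE_LABELS[code], sex, lvl))
                        cell_targets.append(spec.immigration_per_period * pa * 0.5 * pe)
        counts = _largest_remainder(np.asarray(cell_targets), spec.immigration_per_period)
        for (p_, a_, s_, l_), c in zip(cell_keys, counts):
            if c > 0:
                imm_rows.append((p_, a_, s_, l_, int(c)))

    schedules = RateSchedules(
        survival=pd.DataFrame(surv_rows, columns=["period", "age_group", "sex", "education", "ratio"]),
        education_transitions=pd.DataFrame(
            tr_rows, columns=["period", "age_group", "sex", "from_level", "to_level", "prob"]
        ),
        fertility=pd.DataFrame(fert_rows, columns=["period", "age_group", "shape"]),
        emigration=pd.DataFrame(emig_rows, columns=["period", "age_group", "sex", "rate"]),
        immigration=pd.DataFrame(imm_rows, columns=["period", "age_group", "sex", "education", "count"]),
        newborn_survival=pd.DataFrame(nb_rows, columns=["period", "sex", "ratio"]),
    )
    problems = schedules.validate(ladder)
    if problems:  # pragma: no cover - generator bug guard
        raise AssertionError("generated schedules invalid: " + "; ".join(problems))
    return schedules


def make_survey_microdata(
    spec: SyntheticWorldSpec, n: int = 57_411, seed: int = 0
) -> tuple[pd.DataFrame, tuple[LfpLogitParams, WageModelParams]]:
    """Survey-like microdata (ages 15-74) drawn from the spec's true models.

    Activity is Bernoulli at the true logit probability; wages of active
    respondents are Poisson at the true log-linear mean (optionally
    gamma-overdispersed to probe estimator robustness).  Returns the records
    together with the generating (logit, wage) parameters.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    shares = spec.pyramid_shares()[3:15]
    codes = rng.choice(np.arange(3, 15), size=n, p=shares / shares.sum())
    male = rng.random(n) < np.array([spec.male_share(c) for c in codes])
    sexes = np.where(male, "male", "female")
    edu = np.empty(n, dtype=object)
    for code in range(3, 15):
        for sex in SEXES:
            m = (codes == code) & (sexes == sex)
            if m.any():
                probs = education_probs(spec, code, sex)
                edu[m] = rng.choice(spec.ladder.levels, size=int(m.sum()), p=probs)
    years = rng.choice(spec.survey_years, size=n)

    p = np.empty(n)
    for sex in SEXES:
        m = sexes == sex
        eta = spec.true_lfp.linear_predictor(sex, codes[m], edu[m])
        p[m] = 1.0 / (1.0 + np.exp(-eta))
    active = rng.random(n) < p

    wage = np.full(n, np.nan)
    if active.any():
        mu = np.exp(
            spec.true_wage.linear_predictor(edu[active], codes[active], sexes[active], years[active])
        )
        if spec.wage_overdispersion > 0:
            k = 1.0 / spec.wage_overdispersion
            mu = mu * rng.gamma(k, 1.0 / k, size=mu.shape)
        wage[active] = rng.poisson(mu).astype(float)

    records = pd.DataFrame(
        {
            "age_group": [AGE_LABELS[c] for c in codes],
            "sex": sexes,
            "education": edu,
            "in_labor_force": active,
            "wage": wage,
            "survey_year": years,
        }
    )
    return records, (spec.true_lfp, spec.true_wage)
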
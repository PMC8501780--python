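"""Calibration models: participation logit and log-wage Poisson regression.

Two regressions feed the projection:

* A **sex-specific logit of labour-force participation** on a quadratic in
  age with education main effects and full education x age, education x age^2
  interactions.  Age enters as the centred, scaled band midpoint
  ``x = (mid - 45) / 5`` so the quadratic is well conditioned; the coding is
  recorded on the returned parameter object so coefficients stay
  interpretable.  The fitted parameters are held constant over the
  projection: aggregate participation then moves only through population
  composition.

* A **Poisson regression with log link on the wage** of active respondents,
  with additive education, age-group, sex and survey-year controls.  The
  education coefficients, exponentiated, are the productivity factors
  ``W_e = exp(beta_1[e])``; the reference category (upper secondary by
  default) has ``beta = 0`` by coding and hence weight exactly 1.  The wage
  is a continuous response pushed through count-model machinery — the
  estimate is the standard quasi-likelihood GLM solution for a log-linear
  mean, which is all the weights need.

Fits are unweighted; a survey-weight hook (``weight_col``) is exposed for
data that require it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit as _logit
from scipy.stats import rankdata

from .types import (
    AGE_MID,
    AGE_LABELS,
    DEFAULT_LADDER,
    EducationLadder,
    LfpLogitParams,
    ProductivityWeights,
    SEXES,
    WageModelParams,
    WORKING_MIN,
    age_code,
)

SURVEY_COLUMNS = ("age_group", "sex", "education", "in_labor_force", "wage", "survey_year")
#: Survey window: band codes 15-19 .. 70-74.
SURVEY_WINDOW = (WORKING_MIN, 14)


def _check_survey(records: pd.DataFrame, ladder: EducationLadder) -> pd.DataFrame:
    df = records.copy()
    for col in ("age_group", "sex", "education", "in_labor_force"):
        if col not in df.columns:
            raise ValueError(f"survey records lack column {col!r}")
    df["age"] = [age_code(v) for v in df["age_group"]]
    lo, hi = SURVEY_WINDOW
    if ((df["age"] < lo) | (df["age"] > hi)).any():
        raise ValueError("survey records outside the 15-74 age window")
    bad = set(df["education"]) - set(ladder.levels)
    if bad:
        raise ValueError(f"unknown education level(s) in survey: {sorted(bad)}")
    bad = set(df["sex"]) - set(SEXES)
    if bad:
        raise ValueError(f"unknown sex value(s) in survey: {sorted(bad)}")
    return df


def _lfp_design(
    df: pd.DataFrame, ladder: EducationLadder, reference: str,
    age_center: float, age_scale: float,
) -> pd.DataFrame:
    x = (AGE_MID[df["age"].to_numpy()] - age_center) / age_scale
    cols = {"intercept": np.ones(len(df)), "age": x, "age2": x**2}
    for lvl in ladder.levels:
        if lvl == reference:
            continue
        d = (df["education"] == lvl).to_numpy(dtype=float)
        cols[f"edu:{lvl}"] = d
        cols[f"edu_age:{lvl}"] = d * x
        cols[f"edu_age2:{lvl}"] = d * x**2
    return pd.DataFrame(cols, index=df.index)


def _c_statistic(y: np.ndarray, p: np.ndarray) -> float:
    """Concordance (ROC area) via the rank-sum identity."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def fit_lfp_logit(
    records: pd.DataFrame,
    ladder: EducationLadder = DEFAULT_LADDER,
    reference: str | None = None,
    age_center: float = 45.0,
    age_scale: float = 5.0,
    weight_col: str | None = None,
) -> LfpLogitParams:
    """Fit the participation logit separately by sex.

    Raises ``ValueError`` if a sex is missing, if any sex x education stratum
    has a constant outcome (complete separation), or if the optimiser fails,
    naming the offending stratum.
    """
    reference = reference or ladder.reference
    df = _check_survey(records, ladder)
    missing = set(SEXES) - set(df["sex"])
    if missing:
        raise ValueError(f"survey records lack sex stratum: {sorted(missing)}")

    coef: dict[str, dict[str, float]] = {}
    se: dict[str, dict[str, float]] = {}
    diagnostics: dict[str, dict[str, float]] = {}
    for sex in SEXES:
        sub = df[df["sex"] == sex]
        y = sub["in_labor_force"].astype(float).to_numpy()
        if y.min() == y.max():
            raise ValueError(
                f"complete separation: every record for sex={sex} has "
                f"in_labor_force={bool(y[0])}"
            )
        for lvl, grp in sub.groupby("education", observed=True):
            v = grp["in_labor_force"].astype(float)
            if v.min() == v.max():
                raise ValueError(
                    f"complete separation in stratum sex={sex}, education={lvl}: "
                    f"all records have in_labor_force={bool(v.iloc[0])}"
                )
        X = _lfp_design(sub, ladder, reference, age_center, age_scale)
        freq = sub[weight_col].to_numpy() if weight_col else None
        try:
            model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=freq)
            res = model.fit(maxiter=200)
        except Exception as exc:  # statsmodels raises PerfectSeparation et al.
            raise ValueError(f"participation logit failed for sex={sex}: {exc}") from exc
        if not res.converged:
            raise ValueError(f"participation logit did not converge for sex={sex}")
        coef[sex] = dict(zip(X.columns, np.asarray(res.params, dtype=float)))
        se[sex] = dict(zip(X.columns, np.asarray(res.bse, dtype=float)))
        p = np.asarray(res.fittedvalues)
        lln = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(),
                     freq_weights=freq).fit().llf
        n = len(y)
        cox_snell = 1.0 - np.exp(2.0 * (lln - res.llf) / n)
        diagnostics[sex] = {
            "n": n,
            "max_rescaled_r2": float(cox_snell / (1.0 - np.exp(2.0 * lln / n))),
            "c_statistic": _c_statistic(y, p),
        }
    return LfpLogitParams(
        coef=coef, ladder=ladder, reference=reference,
        age_center=age_center, age_scale=age_scale,
        window=SURVEY_WINDOW, se=se, diagnostics=diagnostics,
    )


def predict_participation_rate(
    params: LfpLogitParams, sex: str, age_group, education
) -> float | np.ndarray:
    """Inverse-logit participation probability for the given covariates.

    ``age_group`` (label or band code) must fall inside the model's
    prediction window; values are strictly inside (0, 1).
    """
    scalar = np.isscalar(age_group) and np.isscalar(education)
    codes = np.atleast_1d(np.asarray(
        [age_code(a) for a in np.atleast_1d(np.asarray(age_group, dtype=object))]
    ))
    lo, hi = params.window
    if ((codes < lo) | (codes > hi)).any():
        raise ValueError(
            f"age band outside the prediction window {AGE_LABELS[lo]}..{AGE_LABELS[hi]}"
        )
    eta = params.linear_predictor(sex, codes, education)
    p = expit(eta)
    return float(p[0]) if scalar else p


def linear_predictor_roundtrip(params: LfpLogitParams, sex, age_group, education):
    """logit(predict(...)) — equals the linear predictor up to float error."""
    return _logit(predict_participation_rate(params, sex, age_group, education))


def fit_wage_poisson(
    records: pd.DataFrame,
    ladder: EducationLadder = DEFAULT_LADDER,
    reference: str | None = None,
    weight_col: str | None = None,
) -> WageModelParams:
    """Fit the log-link Poisson wage model on active, wage-bearing records.

    Inactive records and records without a wage are dropped internally.
    Education is coded with the reference level at zero, so
    ``exp(edu coefficient)`` is directly the productivity factor.
    """
    reference = reference or ladder.reference
    df = _check_survey(records, ladder)
    if "wage" not in df.columns or "survey_year" not in df.columns:
        raise ValueError("survey records lack 'wage'/'survey_year' columns")
    df = df[df["in_labor_force"].astype(bool) & df["wage"].notna()]
    if len(df) == 0:
        raise ValueError("no wage-bearing active records to fit on")
    if (df["wage"] < 0).any():
        raise ValueError("negative wages")

    age_ref = AGE_LABELS[int(df["age"].min())]
    year_ref = int(df["survey_year"].min())
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    for lvl in ladder.levels:
        if lvl != reference:
            cols[f"edu:{lvl}"] = (df["education"] == lvl).to_numpy(dtype=float)
    for code in sorted(df["age"].unique()):
        lab = AGE_LABELS[int(code)]
        if lab != age_ref:
            cols[f"age:{lab}"] = (df["age"] == code).to_numpy(dtype=float)
    cols["sex:female"] = (df["sex"] == "female").to_numpy(dtype=float)
    for yr in sorted(df["survey_year"].unique()):
        if int(yr) != year_ref:
            cols[f"year:{int(yr)}"] = (df["survey_year"] == yr).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=df.index)
    freq = df[weight_col].to_numpy() if weight_col else None
    res = sm.GLM(
        df["wage"].to_numpy(), X, family=sm.families.Poisson(), freq_weights=freq
    ).fit(maxiter=200)
    if not res.converged:
        raise ValueError("wage Poisson regression did not converge")
    params = dict(zip(X.columns, np.asarray(res.params, dtype=float)))
    ses = dict(zip(X.columns, np.asarray(res.bse, dtype=float)))

    def collect(prefix: str, cast=lambda v: v):
        return {
            cast(k.split(":", 1)[1]): params[k] for k in params if k.startswith(prefix)
        }

    return WageModelParams(
        intercept=params["intercept"],
        edu=collect("edu:"),
        age=collect("age:"),
        sex=collect("sex:"),
        year=collect("year:", int),
        ladder=ladder,
        reference=reference,
        age_reference=age_ref,
        sex_reference="male",
        year_reference=year_ref,
        se={"all": ses},
    )


def derive_productivity_weights(
    params: WageModelParams, reference: str | None = None
) -> ProductivityWeights:
    """Productivity factors ``W_e = exp(beta_1[e])`` with W(reference) = 1.

    If ``reference`` differs from the level the model was coded against, the
    coefficients are recentred first; the reference weight is exactly 1.0
    either way.
    """
    ladder = params.ladder
    reference = reference or params.reference
    if reference not in ladder:
        raise KeyError(f"reference level {reference!r} not on the ladder")
    beta = {lvl: params.edu.get(lvl, 0.0) for lvl in ladder.levels}
    beta.setdefault(params.reference, 0.0)
    shift = beta[reference]
    weights = {lvl: float(np.exp(b - shift)) for lvl, b in beta.items()}
    weights[reference] = 1.0
    return ProductivityWeights(weights=weights, reference=reference)


def predicted_rate_schedule(
    params: LfpLogitParams, ladder: EducationLadder | None = None
) -> pd.DataFrame:
    """Participation rates over the full prediction grid (age x sex x education)."""
    ladder = ladder or params.ladder
    lo, hi = params.window
    rows = []
    for sex in SEXES:
        for code in range(lo, hi + 1):
            for lvl in ladder.levels:
                rows.append(
                    {
                        "sex": sex,
                        "age_group": AGE_LABELS[code],
                        "education": lvl,
                        "rate": predict_participation_rate(params, sex, code, lvl),
                    }
                )
    return pd.DataFrame(rows)
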
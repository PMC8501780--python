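"""Core data model shared by every stage of the microsimulation.

The population is kept as a *weighted case file*: each case (row) stands for
``weight`` real persons who share one combination of 5-year age band, sex,
educational attainment and labour-force status.  Projection events are Monte
Carlo experiments applied case by case, so the case file is both the state of
the simulation and its unit of randomness.

Conventions
-----------
* Age is a 5-year band, coded ``0`` (0-4) through ``20`` (100+, top-open).
* Children (bands below 15-19) carry education ``"none"`` — attainment is not
  a meaningful variable before 15 — and labor-force status
  ``"not_applicable"``.
* Education is an ordered ladder.  The default ladder has the five categories
  no education (incl. primary incomplete), primary, lower secondary, upper
  secondary and postsecondary; the number of categories is configurable
  (some human-capital datasets split postsecondary, giving six levels).
* The reference category for productivity weights is upper secondary
  (weight 1 by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Age bands
# --------------------------------------------------------------------------

N_AGE = 21
AGE_LABELS: tuple[str, ...] = tuple(f"{5 * i}-{5 * i + 4}" for i in range(20)) + ("100+",)
_AGE_CODE: dict[str, int] = {lab: i for i, lab in enumerate(AGE_LABELS)}
#: Band midpoints in years (used as the numeric age covariate).
AGE_MID = np.array([5.0 * i + 2.5 for i in range(N_AGE)])

CHILD_MAX = 2        #: last band below working age (10-14)
WORKING_MIN = 3      #: 15-19
WORKING_MAX = 12     #: 60-64
OLD_MIN = 13         #: 65-69
FERTILE_MIN = 3      #: 15-19
FERTILE_MAX = 9      #: 45-49

SEXES = ("male", "female")
ACTIVITIES = ("active", "inactive", "not_applicable")
ORIGINS = ("baseline", "birth", "immigrant")
#: Education code used for ages 0-14 ("not yet assigned").
EDU_NONE = "none"


def age_code(value: str | int) -> int:
    """Return the integer band code for a band label (or pass codes through)."""
    if isinstance(value, (int, np.integer)):
        code = int(value)
        if not 0 <= code < N_AGE:
            raise ValueError(f"age band code out of range: {code}")
        return code
    try:
        return _AGE_CODE[str(value)]
    except KeyError:
        raise ValueError(f"unknown age band label: {value!r}") from None


def age_label(code: int) -> str:
    return AGE_LABELS[age_code(code)]


# --------------------------------------------------------------------------
# Education ladder
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EducationLadder:
    """Strictly ordered education categories with a designated reference level.

    ``levels`` excludes the ``"none"`` placeholder used for children; helper
    :meth:`all_codes` prepends it so frames can store both in one categorical.
    """

    levels: tuple[str, ...] = (
        "no_education",
        "primary",
        "lower_secondary",
        "upper_secondary",
        "postsecondary",
    )
    reference: str = "upper_secondary"

    def __post_init__(self) -> None:
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("education levels must be unique")
        if EDU_NONE in self.levels:
            raise ValueError(f"{EDU_NONE!r} is reserved for children")
        if self.reference not in self.levels:
            raise ValueError(f"reference level {self.reference!r} not in ladder")

    @property
    def all_codes(self) -> tuple[str, ...]:
        return (EDU_NONE,) + tuple(self.levels)

    def index(self, level: str) -> int:
        """Rank of ``level`` on the ladder (0 = lowest).  Unknown level raises."""
        try:
            return self.levels.index(level)
        except ValueError:
            raise KeyError(f"unknown education level: {level!r}") from None

    def code(self, value: str) -> int:
        """Position of ``value`` in :meth:`all_codes` (``none`` -> 0)."""
        if value == EDU_NONE:
            return 0
        return self.index(value) + 1

    def __contains__(self, level: object) -> bool:
        return level in self.levels


DEFAULT_LADDER = EducationLadder()


# --------------------------------------------------------------------------
# Individuals and population frames
# --------------------------------------------------------------------------


@dataclass
class Individual:
    """One weighted case.  ``age_group`` may be a band label or code."""

    age_group: str | int
    sex: str
    education: str
    activity: str
    weight: float
    origin: str = "baseline"
    id: int | None = None


class PopulationFrame:
    """Weighted case file for one calendar period.

    Wraps a :class:`pandas.DataFrame` with columns ``id`` (uint64), ``age``
    (band code, int16), ``sex``, ``education``, ``activity``, ``origin``
    (categoricals with fixed category order) and ``weight`` (float64).
    Category order is fixed so ``.cat.codes`` are stable across runs, which
    the engine relies on for reproducibility.
    """

    COLUMNS = ("id", "age", "sex", "education", "activity", "weight", "origin")

    def __init__(
        self,
        data: pd.DataFrame,
        period: int,
        ladder: EducationLadder = DEFAULT_LADDER,
        copy: bool = True,
    ) -> None:
        self.period = int(period)
        self.ladder = ladder
        self.data = _normalize_data(data, ladder, copy=copy)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_individuals(
        cls,
        individuals: Iterable[Individual],
        period: int,
        ladder: EducationLadder = DEFAULT_LADDER,
    ) -> "PopulationFrame":
        rows = list(individuals)
        df = pd.DataFrame(
            {
                "id": [
                    r.id if r.id is not None else i for i, r in enumerate(rows)
                ],
                "age": [age_code(r.age_group) for r in rows],
                "sex": [r.sex for r in rows],
                "education": [r.education for r in rows],
                "activity": [r.activity for r in rows],
                "weight": [r.weight for r in rows],
                "origin": [r.origin for r in rows],
            }
        )
        return cls(df, period, ladder)

    @classmethod
    def from_csv(
        cls, path: str | Path, ladder: EducationLadder = DEFAULT_LADDER
    ) -> "PopulationFrame":
        df = pd.read_csv(path)
        periods = df["period"].unique()
        if len(periods) != 1:
            raise ValueError(f"frame CSV must hold one period, found {sorted(periods)}")
        return cls(df.drop(columns=["period"]), int(periods[0]), ladder)

    def to_csv(self, path: str | Path) -> None:
        out = pd.DataFrame(
            {
                "period": self.period,
                "age_group": [AGE_LABELS[a] for a in self.data["age"]],
                "sex": self.data["sex"].astype(str),
                "education": self.data["education"].astype(str),
                "activity": self.data["activity"].astype(str),
                "weight": self.data["weight"].to_numpy(),
                "id": self.data["id"].to_numpy(),
                "origin": self.data["origin"].astype(str),
            }
        )
        out.to_csv(path, index=False)

    # -- views -------------------------------------------------------------

    @property
    def n_cases(self) -> int:
        return len(self.data)

    @property
    def weighted_total(self) -> float:
        return float(self.data["weight"].sum())

    def age_codes(self) -> np.ndarray:
        return self.data["age"].to_numpy()

    def sex_codes(self) -> np.ndarray:
        return self.data["sex"].cat.codes.to_numpy()

    def edu_codes(self) -> np.ndarray:
        """Education as index into ``ladder.all_codes`` (0 = none)."""
        return self.data["education"].cat.codes.to_numpy()

    def ids(self) -> np.ndarray:
        return self.data["id"].to_numpy()

    def weights(self) -> np.ndarray:
        return self.data["weight"].to_numpy()

    def replace(self, data: pd.DataFrame | None = None, period: int | None = None,
                copy: bool = False) -> "PopulationFrame":
        return PopulationFrame(
            self.data if data is None else data,
            self.period if period is None else period,
            self.ladder,
            copy=copy,
        )

    def copy(self) -> "PopulationFrame":
        return self.replace(data=self.data.copy(), copy=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<PopulationFrame period={self.period} cases={self.n_cases} "
            f"persons={self.weighted_total:.0f}>"
        )


def _normalize_data(
    data: pd.DataFrame, ladder: EducationLadder, copy: bool = True
) -> pd.DataFrame:
    df = data.copy() if copy else data
    if "age" not in df.columns:
        if "age_group" not in df.columns:
            raise ValueError("frame data needs an 'age' or 'age_group' column")
        df["age"] = [age_code(v) for v in df["age_group"]]
        df = df.drop(columns=["age_group"])
    df["age"] = df["age"].astype(np.int16)
    if (df["age"] < 0).any() or (df["age"] >= N_AGE).any():
        raise ValueError("age band codes out of range")
    if "id" not in df.columns:
        df["id"] = np.arange(len(df), dtype=np.uint64)
    df["id"] = df["id"].astype(np.uint64)
    if "origin" not in df.columns:
        df["origin"] = "baseline"
    if "activity" not in df.columns:
        df["activity"] = np.where(
            df["age"] <= CHILD_MAX, "not_applicable", "inactive"
        )
    for col, cats in (
        ("sex", SEXES),
        ("education", ladder.all_codes),
        ("activity", ACTIVITIES),
        ("origin", ORIGINS),
    ):
        if col not in df.columns:
            raise ValueError(f"frame data lacks column {col!r}")
        cat = pd.Categorical(df[col], categories=cats)
        if cat.isna().any() and not pd.isna(df[col]).any():
            bad = sorted(set(df[col]) - set(cats))
            raise ValueError(f"unknown {col} value(s): {bad}")
        df[col] = cat
    df["weight"] = df["weight"].astype(np.float64)
    return df[list(PopulationFrame.COLUMNS)].reset_index(drop=True)


def validate_frame(frame: PopulationFrame) -> list[str]:
    """Check every frame-level invariant; return a list of violation messages.

    An empty list means the frame is valid.  This is a reporting operation:
    it never raises.
    """
    df = frame.data
    problems: list[str] = []
    w = df["weight"].to_numpy()
    if not np.isfinite(w).all():
        problems.append(f"{int((~np.isfinite(w)).sum())} case(s) with non-finite weight")
    if (w <= 0).any():
        problems.append(f"{int((w <= 0).sum())} case(s) with weight <= 0")
    child = df["age"].to_numpy() <= CHILD_MAX
    act = df["activity"].astype(str).to_numpy()
    edu = df["education"].astype(str).to_numpy()
    bad = child & (act != "not_applicable")
    if bad.any():
        problems.append(f"{int(bad.sum())} child case(s) with a labor-force status")
    bad = (~child) & (act == "not_applicable")
    if bad.any():
        problems.append(f"{int(bad.sum())} adult case(s) marked not_applicable")
    bad = child & (edu != EDU_NONE)
    if bad.any():
        problems.append(f"{int(bad.sum())} child case(s) with an education level")
    bad = (~child) & (edu == EDU_NONE)
    if bad.any():
        problems.append(f"{int(bad.sum())} adult case(s) without an education level")
    for col in ("sex", "education", "activity", "origin"):
        n_na = int(df[col].isna().sum())
        if n_na:
            problems.append(f"{n_na} case(s) with missing {col}")
    return problems


# --------------------------------------------------------------------------
# Model parameter containers
# --------------------------------------------------------------------------


@dataclass
class LfpLogitParams:
    """Sex-specific logit coefficients for labour-force participation.

    The linear predictor for one sex is::

        eta = b["intercept"] + b["age"] * x + b["age2"] * x**2
              + b[f"edu:{e}"] + b[f"edu_age:{e}"] * x + b[f"edu_age2:{e}"] * x**2

    where ``x = (band midpoint - age_center) / age_scale`` and the reference
    education level contributes nothing (its coefficients are 0 by coding;
    missing keys are read as 0).  ``window`` is the inclusive band-code range
    the model may be evaluated on (survey window 15-74 by default).
    """

    coef: dict[str, dict[str, float]]
    ladder: EducationLadder = DEFAULT_LADDER
    reference: str = "upper_secondary"
    age_center: float = 45.0
    age_scale: float = 5.0
    window: tuple[int, int] = (WORKING_MIN, 14)
    se: dict[str, dict[str, float]] | None = None
    diagnostics: dict = field(default_factory=dict)

    def age_x(self, codes) -> np.ndarray:
        return (AGE_MID[np.asarray(codes)] - self.age_center) / self.age_scale

    def linear_predictor(self, sex: str, age_codes, education) -> np.ndarray:
        """Vectorised eta for one sex; ``education`` is level name(s)."""
        if sex not in self.coef:
            raise KeyError(f"no coefficients for sex {sex!r}")
        b = self.coef[sex]
        codes = np.atleast_1d(np.asarray(age_codes))
        edu = np.atleast_1d(np.asarray(education, dtype=object))
        for e in np.unique(edu):
            if e not in self.ladder:
                raise KeyError(f"unknown education level: {e!r}")
        x = self.age_x(codes)
        eta = b.get("intercept", 0.0) + b.get("age", 0.0) * x + b.get("age2", 0.0) * x**2
        b3 = np.array([b.get(f"edu:{e}", 0.0) for e in edu])
        b4 = np.array([b.get(f"edu_age:{e}", 0.0) for e in edu])
        b5 = np.array([b.get(f"edu_age2:{e}", 0.0) for e in edu])
        return eta + b3 + b4 * x + b5 * x**2


@dataclass
class WageModelParams:
    """Log-link (Poisson) wage model coefficients, Eq.-style additive controls.

    ``edu`` holds the education effects on the log-wage scale with the
    reference level at exactly 0 by coding; ``age``, ``sex`` and ``year``
    are nuisance controls and never enter the productivity weights.
    """

    intercept: float
    edu: dict[str, float]
    age: dict[str, float]
    sex: dict[str, float]
    year: dict[int, float]
    ladder: EducationLadder = DEFAULT_LADDER
    reference: str = "upper_secondary"
    age_reference: str = "15-19"
    sex_reference: str = "male"
    year_reference: int | None = None
    se: dict[str, dict] | None = None

    def linear_predictor(self, education, age_codes, sex, year) -> np.ndarray:
        edu = np.atleast_1d(np.asarray(education, dtype=object))
        codes = np.atleast_1d(np.asarray(age_codes))
        sx = np.atleast_1d(np.asarray(sex, dtype=object))
        yr = np.atleast_1d(np.asarray(year))
        eta = self.intercept + np.array([self.edu.get(e, 0.0) for e in edu])
        eta = eta + np.array([self.age.get(AGE_LABELS[c], 0.0) for c in codes])
        eta = eta + np.array([self.sex.get(s, 0.0) for s in sx])
        eta = eta + np.array([self.year.get(int(y), 0.0) for y in yr])
        return eta


@dataclass
class ProductivityWeights:
    """Per-education productivity factors W_e with W(reference) = 1 exactly."""

    weights: dict[str, float]
    reference: str = "upper_secondary"

    def __post_init__(self) -> None:
        for lvl, w in self.weights.items():
            if not w > 0:
                raise ValueError(f"productivity weight for {lvl!r} must be > 0")
        if self.reference in self.weights and self.weights[self.reference] != 1.0:
            raise ValueError("reference level must carry weight 1")

    def __getitem__(self, level: str) -> float:
        try:
            return self.weights[level]
        except KeyError:
            raise KeyError(f"no productivity weight for level {level!r}") from None


# --------------------------------------------------------------------------
# Assumption schedules and scenario configuration
# --------------------------------------------------------------------------

#: Expected columns per schedule table (the on-disk CSV schema).
SCHEDULE_SCHEMAS: Mapping[str, tuple[str, ...]] = {
    "survival": ("period", "age_group", "sex", "education", "ratio"),
    "education_transitions": ("period", "age_group", "sex", "from_level", "to_level", "prob"),
    "fertility": ("period", "age_group", "shape"),
    "emigration": ("period", "age_group", "sex", "rate"),
    "immigration": ("period", "age_group", "sex", "education", "count"),
    "newborn_survival": ("period", "sex", "ratio"),
}


@dataclass
class RateSchedules:
    """All period-indexed demographic assumption tables.

    Period convention: a row with ``period == t`` applies to the projection
    interval (t, t+5].  Age convention: ``age_group`` in the education,
    emigration, immigration and fertility tables refers to the band *attained
    at t+5* (so the education entry distribution sits at 15-19, matching the
    reading "at the age of 15 to 19 the cohort is broken down"); the survival
    table refers to the band occupied at t, as survivorship ratios do.
    ``fertility.shape`` is the normalised fertility schedule: multiplying by
    a scenario TFR gives age-specific fertility rates, and
    ``sum(shape) * 5 == 1`` so the TFR is recovered exactly.
    """

    survival: pd.DataFrame
    education_transitions: pd.DataFrame
    fertility: pd.DataFrame
    emigration: pd.DataFrame
    immigration: pd.DataFrame
    newborn_survival: pd.DataFrame

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def validate(self, ladder: EducationLadder = DEFAULT_LADDER) -> list[str]:
        """Schema and range checks; returns a list of problems (empty if OK)."""
        problems: list[str] = []
        for name, cols in SCHEDULE_SCHEMAS.items():
            df = self.table(name)
            missing = set(cols) - set(df.columns)
            if missing:
                problems.append(f"{name}: missing column(s) {sorted(missing)}")
        for name, col, lo, hi in (
            ("survival", "ratio", 0.0, 1.0),
            ("emigration", "rate", 0.0, 1.0),
            ("newborn_survival", "ratio", 0.0, 1.0),
        ):
            vals = self.table(name)[col]
            if ((vals < lo) | (vals > hi)).any():
                problems.append(f"{name}.{col}: values outside [{lo}, {hi}]")
        if (self.survival["ratio"] <= 0).any():
            problems.append("survival.ratio: zero survivorship band (must be in (0, 1])")
        if (self.immigration["count"] < 0).any():
            problems.append("immigration.count: negative counts")
        tr = self.education_transitions
        if len(tr):
            if ((tr["prob"] < 0) | (tr["prob"] > 1)).any():
                problems.append("education_transitions.prob: outside [0, 1]")
            sums = tr.groupby(["period", "age_group", "sex", "from_level"])["prob"].sum()
            if (sums > 1 + 1e-9).any():
                problems.append("education_transitions: probabilities out of a state exceed 1")
            adv = tr[tr["from_level"] != EDU_NONE]
            if len(adv):
                fr = adv["from_level"].map(ladder.index)
                to = adv["to_level"].map(ladder.index)
                if (to <= fr).any():
                    problems.append(
                        "education_transitions: downward or flat transition(s) on the ladder"
                    )
        for period, grp in self.fertility.groupby("period"):
            total = 5.0 * grp["shape"].sum()
            if abs(total - 1.0) > 1e-6:
                problems.append(
                    f"fertility: shape for period {period} sums to {total:.6f} x TFR (expected 1)"
                )
        return problems

    def periods(self, name: str) -> set[int]:
        return set(int(p) for p in self.table(name)["period"].unique())

    def coverage_gaps(self, start: int, horizon: int) -> list[str]:
        """Schedules that fail to cover every interval start in [start, horizon)."""
        needed = set(range(start, horizon, 5))
        gaps = []
        for name in ("survival", "education_transitions", "fertility",
                     "emigration", "newborn_survival"):
            missing = needed - self.periods(name)
            if missing:
                gaps.append(f"{name}: no rows for period(s) {sorted(missing)}")
        return gaps


@dataclass
class ScenarioConfig:
    """One projection scenario: fertility level plus run constants.

    ``sampling_fraction`` is the case-generation fraction (paper-style default
    0.05%); ``oversample_threshold`` is the subgroup size below which extra
    cases are generated with proportionally reduced weights.
    """

    tfr: float
    start: int = 2015
    horizon: int = 2070
    seed: int = 0
    sampling_fraction: float = 0.0005
    oversample_threshold: int = 10_000
    floor_cases: int = 20
    sex_ratio_at_birth: float = 1.05

    def __post_init__(self) -> None:
        if self.tfr < 0:
            raise ValueError("tfr must be >= 0")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must be in (0, 1]")
        if self.horizon < self.start:
            raise ValueError("horizon must not precede start")
        if (self.horizon - self.start) % 5 != 0:
            raise ValueError("horizon - start must be a multiple of the 5-year step")
        if self.sex_ratio_at_birth <= 0:
            raise ValueError("sex_ratio_at_birth must be positive")

    def with_tfr(self, tfr: float) -> "ScenarioConfig":
        return replace(self, tfr=tfr)
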
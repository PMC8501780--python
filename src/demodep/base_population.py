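"""Synthesise the weighted starting case file from aggregate estimates.

The base population is built by sampling down each age x sex x education cell
of an aggregate table to ``sampling_fraction`` of its person count (0.05% at
paper scale), with *oversampling* for small cells: any nonempty cell below
``oversample_threshold`` persons receives at least ``floor_cases`` cases with
proportionally reduced weights, which curbs Monte Carlo error where the
population is thin.  Weights are ``count / n_cases`` exactly, so the weighted
frame reproduces the aggregates cell by cell.

Case counts are rounded deterministically (round-half-up, minimum one case
per nonempty cell); the builder involves no randomness at all, which makes
base files reproducible byte for byte.  Immigrant cases injected during the
projection follow the same statistical rules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    CHILD_MAX,
    DEFAULT_LADDER,
    EDU_NONE,
    EducationLadder,
    PopulationFrame,
    ScenarioConfig,
    age_code,
)

#: Immigrant ids live in a dedicated block so they never collide with the
#: baseline ids (a dense range from 0) or newborn ids (top bit set).
IMMIGRANT_ID_BASE = np.uint64(1) << np.uint64(40)
_IMMIGRANT_PERIOD_BLOCK = np.uint64(1) << np.uint64(24)

ESTIMATE_COLUMNS = ("age_group", "sex", "education", "count")


def case_count(count: float, cfg: ScenarioConfig) -> int:
    """Number of cases generated for one cell of ``count`` persons.

    Round-half-up of ``count * sampling_fraction`` with a floor of one case;
    cells below the oversampling threshold are topped up to ``floor_cases``
    cases, capped at one case per person so a full census
    (``sampling_fraction == 1``) degenerates to one case per person.
    """
    if count <= 0:
        return 0
    n = int(np.floor(count * cfg.sampling_fraction + 0.5))
    n = max(n, 1)
    if count < cfg.oversample_threshold:
        n = max(n, min(cfg.floor_cases, int(np.ceil(count))))
    return n


def _validate_cells(est: pd.DataFrame, ladder: EducationLadder) -> pd.DataFrame:
    missing = set(ESTIMATE_COLUMNS) - set(est.columns)
    if missing:
        raise ValueError(f"aggregate estimates lack column(s) {sorted(missing)}")
    if len(est) == 0:
        raise ValueError("aggregate estimates are empty")
    df = est.copy()
    df["age"] = [age_code(v) for v in df["age_group"]]
    if (df["count"] < 0).any():
        raise ValueError("aggregate estimates contain negative counts")
    known = set(ladder.all_codes)
    bad = set(df["education"]) - known
    if bad:
        raise ValueError(f"unknown education level(s) in estimates: {sorted(bad)}")
    child = df["age"] <= CHILD_MAX
    if (child & (df["education"] != EDU_NONE) & (df["count"] > 0)).any():
        raise ValueError("child cells must carry the not-applied education code")
    if (~child & (df["education"] == EDU_NONE) & (df["count"] > 0)).any():
        raise ValueError("adult cells must carry a ladder education level")
    return df


def _cells_to_cases(
    cells: pd.DataFrame,
    cfg: ScenarioConfig,
    ladder: EducationLadder,
    ids: np.ndarray | None = None,
    origin: str = "baseline",
) -> pd.DataFrame:
    """Expand validated cells into case rows in deterministic cell order."""
    cells = cells.copy()
    cells["sexc"] = cells["sex"].map({s: i for i, s in enumerate(("male", "female"))})
    if cells["sexc"].isna().any():
        bad = sorted(set(cells["sex"]) - {"male", "female"})
        raise ValueError(f"unknown sex value(s): {bad}")
    cells["educ"] = cells["education"].map(ladder.code)
    cells = cells.sort_values(["age", "sexc", "educ"], kind="mergesort")

    ages, sexes, edus, weights = [], [], [], []
    for age, sex, edu, count in zip(
        cells["age"], cells["sex"], cells["education"], cells["count"]
    ):
        n = case_count(count, cfg)
        if n == 0:
            continue
        ages.append(np.full(n, age, dtype=np.int16))
        sexes.append(np.full(n, sex, dtype=object))
        edus.append(np.full(n, edu, dtype=object))
        weights.append(np.full(n, count / n, dtype=np.float64))
    if not ages:
        return pd.DataFrame(
            {"id": np.array([], dtype=np.uint64), "age": np.array([], dtype=np.int16),
             "sex": [], "education": [], "weight": np.array([], dtype=float),
             "origin": []}
        )
    age_arr = np.concatenate(ages)
    df = pd.DataFrame(
        {
            "age": age_arr,
            "sex": np.concatenate(sexes),
            "education": np.concatenate(edus),
            "weight": np.concatenate(weights),
            "origin": origin,
        }
    )
    df.insert(0, "id", np.arange(len(df), dtype=np.uint64) if ids is None else ids[: len(df)])
    return df


def build_base_population(
    est: pd.DataFrame,
    cfg: ScenarioConfig,
    ladder: EducationLadder = DEFAULT_LADDER,
    rng=None,
) -> PopulationFrame:
    """Build the weighted base :class:`PopulationFrame` for ``cfg.start``.

    Parameters
    ----------
    est
        Aggregate person counts with columns ``age_group, sex, education,
        count``.  Child cells (under 15) must use education ``"none"``.
    cfg
        Scenario constants; only the sampling parameters are used here.
    rng
        Unused; accepted for interface symmetry.  Case synthesis is
        deterministic (see module docstring).

    The weighted total of the returned frame matches ``est`` cell by cell
    exactly, because each case in a cell carries ``count / n_cases``.
    """
    cells = _validate_cells(est, ladder)
    if cells["count"].sum() <= 0:
        raise ValueError("aggregate estimates contain no persons")
    cases = _cells_to_cases(cells, cfg, ladder)
    return PopulationFrame(cases, cfg.start, ladder)


def make_immigrant_cases(
    profile: pd.DataFrame,
    cfg: ScenarioConfig,
    ladder: EducationLadder = DEFAULT_LADDER,
    period: int = 0,
    rng=None,
) -> pd.DataFrame:
    """Generate immigrant case rows for one period's immigration profile.

    ``profile`` has columns ``age_group, sex, education, count`` (persons).
    The same sampling and oversampling rules as the base population apply.
    Ids are drawn from a per-period block that is a pure function of the
    period, so immigrant identities coincide across scenarios (common random
    numbers then make their later life events identical too).
    """
    if len(profile) == 0 or (len(profile) and profile["count"].sum() == 0):
        return pd.DataFrame(
            {"id": np.array([], dtype=np.uint64), "age": np.array([], dtype=np.int16),
             "sex": pd.Series([], dtype=object), "education": pd.Series([], dtype=object),
             "weight": np.array([], dtype=float), "origin": pd.Series([], dtype=object)}
        )
    cells = _validate_cells(profile, ladder)
    block = IMMIGRANT_ID_BASE + np.uint64(max(period, 0) // 5) * _IMMIGRANT_PERIOD_BLOCK
    n_total = int(sum(case_count(c, cfg) for c in cells["count"]))
    ids = block + np.arange(n_total, dtype=np.uint64)
    return _cells_to_cases(cells, cfg, ladder, ids=ids, origin="immigrant")
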
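"""Plain-text round trips for every input and output the pipeline uses.

Schedules live in a directory of CSVs (one per schedule, headers as in
:data:`demodep.types.SCHEDULE_SCHEMAS`); aggregate estimates and survey
microdata are single CSVs; scenario and experiment configuration is YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .types import RateSchedules, SCHEDULE_SCHEMAS, ScenarioConfig


def write_schedules(schedules: RateSchedules, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in SCHEDULE_SCHEMAS:
        schedules.table(name).to_csv(directory / f"{name}.csv", index=False)


def read_schedules(directory: str | Path) -> RateSchedules:
    directory = Path(directory)
    tables = {}
    for name, cols in SCHEDULE_SCHEMAS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing schedule file: {path}")
        df = pd.read_csv(path)
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        tables[name] = df
    return RateSchedules(**tables)


def write_estimates(est: pd.DataFrame, path: str | Path) -> None:
    est.to_csv(path, index=False)


def read_estimates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_survey(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_survey(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_scenario_config(cfg: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


def read_scenario_config(path: str | Path, **overrides) -> ScenarioConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    return ScenarioConfig(**raw)


def write_weights(weights, path: str | Path) -> None:
    rows = [{"education": lvl, "weight": w} for lvl, w in weights.weights.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_weights(path: str | Path, reference: str = "upper_secondary"):
    from .types import ProductivityWeights

    df = pd.read_csv(path)
    return ProductivityWeights(
        weights=dict(zip(df["education"], df["weight"])), reference=reference
    )


def write_lfp_params(params, path: str | Path) -> None:
    """Coefficient table (sex, term, estimate, se) plus coding metadata."""
    rows = []
    for sex, terms in params.coef.items():
        for term, val in terms.items():
            rows.append(
                {
                    "sex": sex,
                    "term": term,
                    "estimate": val,
                    "se": (params.se or {}).get(sex, {}).get(term, float("nan")),
                }
            )
    meta = (
        f"# age coding: x = (band midpoint - {params.age_center}) / {params.age_scale}; "
        f"reference education: {params.reference}\n"
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(meta)
        pd.DataFrame(rows).to_csv(fh, index=False)
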
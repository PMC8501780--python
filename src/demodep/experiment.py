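"""Two-scenario fertility experiments with reproducible outputs.

An experiment runs the same projection under alternative constant TFRs (the
defaults are the low/high pair 0.8 and 1.7 children per woman) from one base
population, one set of assumption schedules and one calibrated participation
model, with a shared seed.  Scenarios differ in fertility *only*; every other
assumption — and, through common random numbers, every Monte Carlo draw — is
shared, so differences between scenario outputs are differences in
assumptions, and adult cohorts born before the start are identical across
scenarios until fertility-born cohorts reach them.

Outputs per scenario: one frame CSV per period, an event tally CSV and the
raw + normalised indicator series; plus a cross-scenario comparison table
and a manifest (config echo, seed, output digests) from which the run can be
reproduced.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .base_population import build_base_population
from .engine import run_projection, tallies_frame
from .indicators import indicator_series, normalize_series
from .rate_models import (
    derive_productivity_weights,
    fit_lfp_logit,
    fit_wage_poisson,
    predicted_rate_schedule,
)
from .synthetic import SyntheticWorldSpec, make_aggregate_estimates, make_rate_schedules, make_survey_microdata
from .types import EducationLadder, ScenarioConfig


class StageError(RuntimeError):
    """An experiment stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"experiment stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ExperimentConfig:
    """Scenario list plus shared inputs.

    Either point the three path fields at real input files, or leave them
    ``None`` and supply (or default) a synthetic world spec.  All scenarios
    share every non-fertility assumption by construction: they are generated
    from one base :class:`ScenarioConfig` by replacing ``tfr`` alone.
    """

    scenarios: dict[str, float] = field(
        default_factory=lambda: {"tfr_low": 0.8, "tfr_high": 1.7}
    )
    seed: int = 0
    start: int = 2015
    horizon: int = 2070
    sampling_fraction: float = 0.0005
    estimates_csv: str | None = None
    schedules_dir: str | None = None
    survey_csv: str | None = None
    synth: SyntheticWorldSpec | None = None
    survey_n: int = 57_411
    outdir: str | None = None
    write_frames: bool = True
    ladder: EducationLadder = field(default_factory=EducationLadder)

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("at least one scenario is required")
        for name, tfr in self.scenarios.items():
            if tfr < 0:
                raise ValueError(f"scenario {name!r} has negative TFR")

    def base_scenario_config(self, tfr: float) -> ScenarioConfig:
        return ScenarioConfig(
            tfr=tfr, start=self.start, horizon=self.horizon, seed=self.seed,
            sampling_fraction=self.sampling_fraction,
        )


@dataclass
class ExperimentResult:
    trajectories: dict
    indicators: dict
    normalized: dict
    comparison: pd.DataFrame
    weights: object
    lfp: object
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapper

    return deco


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run every scenario and assemble (optionally write) the outputs."""
    ladder = cfg.ladder

    try:
        if cfg.estimates_csv and cfg.schedules_dir and cfg.survey_csv:
            est = io.read_estimates(cfg.estimates_csv)
            schedules = io.read_schedules(cfg.schedules_dir)
            survey = io.read_survey(cfg.survey_csv)
        else:
            spec = cfg.synth or SyntheticWorldSpec(ladder=ladder)
            est = make_aggregate_estimates(spec, seed=cfg.seed)
            schedules = make_rate_schedules(spec, cfg.start, cfg.horizon)
            survey, _ = make_survey_microdata(spec, n=cfg.survey_n, seed=cfg.seed)
    except Exception as exc:
        raise StageError("inputs", exc) from exc

    try:
        lfp = fit_lfp_logit(survey, ladder)
        wage = fit_wage_poisson(survey, ladder)
        weights = derive_productivity_weights(wage)
    except Exception as exc:
        raise StageError("calibration", exc) from exc

    try:
        base_cfg = cfg.base_scenario_config(next(iter(cfg.scenarios.values())))
        base = build_base_population(est, base_cfg, ladder)
    except Exception as exc:
        raise StageError("base_population", exc) from exc

    trajectories, series, normed = {}, {}, {}
    for name, tfr in cfg.scenarios.items():
        try:
            scen_cfg = replace(base_cfg, tfr=tfr)
            trajectories[name] = run_projection(base, schedules, lfp, scen_cfg)
        except Exception as exc:
            raise StageError(f"projection:{name}", exc) from exc
        try:
            series[name] = indicator_series(trajectories[name], weights)
            normed[name] = normalize_series(series[name], cfg.start)
        except Exception as exc:
            raise StageError(f"indicators:{name}", exc) from exc

    comparison = _comparison_table(series, normed)
    manifest = {
        "seed": cfg.seed,
        "start": cfg.start,
        "horizon": cfg.horizon,
        "sampling_fraction": cfg.sampling_fraction,
        "scenarios": dict(cfg.scenarios),
        "ladder": list(ladder.levels),
        "reference": ladder.reference,
        "survey_n": int(len(survey)),
        "base_cases": int(base.n_cases),
        "productivity_weights": {k: float(v) for k, v in weights.weights.items()},
        "lfp_diagnostics": lfp.diagnostics,
    }
    result = ExperimentResult(
        trajectories=trajectories, indicators=series, normalized=normed,
        comparison=comparison, weights=weights, lfp=lfp, manifest=manifest,
    )
    if cfg.outdir:
        _write_outputs(cfg, result, schedules)
    return result


def _comparison_table(series: dict, normed: dict) -> pd.DataFrame:
    rows = []
    for name in series:
        raw = series[name]
        nrm = normed[name]
        for period in raw.index:
            row = {"scenario": name, "period": period}
            for col in ("adr", "lfdr", "pwlfdr"):
                row[col] = raw.loc[period, col]
                row[f"{col}_norm"] = nrm.loc[period, col]
            rows.append(row)
    return pd.DataFrame(rows)


def _write_outputs(cfg: ExperimentConfig, result: ExperimentResult, schedules) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    digests = {}

    def record(path: Path) -> None:
        digests[str(path.relative_to(out))] = hashlib.sha256(path.read_bytes()).hexdigest()

    calib = out / "calibration"
    calib.mkdir(exist_ok=True)
    io.write_weights(result.weights, calib / "productivity_weights.csv")
    record(calib / "productivity_weights.csv")
    io.write_lfp_params(result.lfp, calib / "lfp_coefficients.csv")
    record(calib / "lfp_coefficients.csv")
    predicted_rate_schedule(result.lfp).to_csv(calib / "predicted_rates.csv", index=False)
    record(calib / "predicted_rates.csv")

    for name, traj in result.trajectories.items():
        sdir = out / name
        sdir.mkdir(exist_ok=True)
        if cfg.write_frames:
            fdir = sdir / "frames"
            fdir.mkdir(exist_ok=True)
            for frame, _ in traj:
                p = fdir / f"period_{frame.period}.csv"
                frame.to_csv(p)
                record(p)
        tallies_frame(traj).to_csv(sdir / "events.csv", index=False)
        record(sdir / "events.csv")
        merged = result.indicators[name].join(
            result.normalized[name], rsuffix="_norm"
        ).reset_index()
        merged.to_csv(sdir / "indicators.csv", index=False)
        record(sdir / "indicators.csv")

    result.comparison.to_csv(out / "comparison.csv", index=False)
    record(out / "comparison.csv")
    manifest = dict(result.manifest)
    manifest["outputs_sha256"] = digests
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
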
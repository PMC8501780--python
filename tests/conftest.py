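import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import demodep as d

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ladder():
    return d.DEFAULT_LADDER


@pytest.fixture(scope="session")
def world_spec():
    return d.SyntheticWorldSpec(total_population=400_000)


@pytest.fixture(scope="session")
def estimates(world_spec):
    return d.make_aggregate_estimates(world_spec, seed=0)


@pytest.fixture(scope="session")
def schedules(world_spec):
    return d.make_rate_schedules(world_spec, 2015, 2070)


@pytest.fixture(scope="session")
def survey_50k(world_spec):
    records, truth = d.make_survey_microdata(world_spec, n=50_000, seed=0)
    return records, truth


@pytest.fixture(scope="session")
def fitted_lfp(survey_50k):
    records, _ = survey_50k
    return d.fit_lfp_logit(records)


@pytest.fixture(scope="session")
def fitted_wage(survey_50k):
    records, _ = survey_50k
    return d.fit_wage_poisson(records)


@pytest.fixture(scope="session")
def productivity_weights(fitted_wage):
    return d.derive_productivity_weights(fitted_wage)


def frame_of(rows, period=2015):
    """Build a small PopulationFrame from row dicts (age_group/sex/... keys)."""
    return d.PopulationFrame(pd.DataFrame(rows), period)


@pytest.fixture
def make_frame():
    return frame_of
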
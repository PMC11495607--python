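import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mrpsup as m
from mrpsup.models import SamplerConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> m.PopulationSpec:
    """Reduced synthetic geography: fast fits, full factor structure."""
    levels = {
        "sex": ("Female", "Male"),
        "age_band": ("18-34", "35-64", "65+"),
        "education": ("No degree", "Degree"),
        "income": ("Below median", "Above median"),
        "race": ("White", "Other"),
        "state": ("S1", "S2", "S3", "S4"),
    }
    party = m.PartyModel(
        intercepts={"Democrat": 0.2, "Republican": 0.1},
        coefficients={
            "Democrat": {"education": {"Degree": 0.5}},
            "Republican": {"age_band": {"65+": 0.5}},
        },
    )
    return m.PopulationSpec(
        levels=levels,
        state_region={"S1": "East", "S2": "East", "S3": "West", "S4": "West"},
        state_covariate={"S1": 0.08, "S2": 0.13, "S3": 0.19, "S4": 0.24},
        total_population=200_000,
        party_model=party,
    )


@pytest.fixture(scope="session")
def small_table(small_spec) -> m.PoststratTable:
    return m.build_poststrat_table(small_spec, seed=7)


@pytest.fixture()
def fast_sampler() -> SamplerConfig:
    return SamplerConfig(chains=2, draws=400, warmup=300, seed=123,
                         check_convergence=False)
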
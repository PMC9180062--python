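import pytest
from hypothesis import HealthCheck, settings

from tearisk import reference as ref
from tearisk.datatypes import DEFAULT_BREWING
from tearisk.synthetic import default_profiles, default_sim_specs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toxref():
    return ref.toxref_map()


@pytest.fixture(scope="session")
def mean_concentrations():
    """Published per-element made-tea means, mg/kg."""
    return {e: ref.MADE_TEA_SUMMARY_MG_KG[e][2] for e in ref.STUDY_ELEMENTS}


@pytest.fixture(scope="session")
def transfer_rates():
    return dict(ref.MEAN_TRANSFER_RATE)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def sim_specs():
    return default_sim_specs()


@pytest.fixture(scope="session")
def brewing():
    return DEFAULT_BREWING
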
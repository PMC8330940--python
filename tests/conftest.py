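import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from whalerepro.life_history import classify_records
from whalerepro.mixture import fit_mixture
from whalerepro.pipeline import load_table4, table4_records

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table4_df():
    return load_table4()


@pytest.fixture(scope="session")
def table4_recs(table4_df):
    return table4_records(table4_df)


@pytest.fixture(scope="session")
def table4_classified(table4_recs):
    return classify_records(table4_recs)


@pytest.fixture(scope="session")
def table4_concentrations(table4_classified):
    return table4_classified["progesterone_ng_g"].to_numpy(float)


@pytest.fixture(scope="session")
def table4_fit(table4_concentrations):
    return fit_mixture(np.log(table4_concentrations))
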
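import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from minisplice.acmg_engine import load_evidence_table
from minisplice.cohort_filter import load_proband_series
from minisplice.gene_model import compute_region_windows, load_myo7a_transcript


@pytest.fixture(scope="session")
def myo7a():
    return load_myo7a_transcript()


@pytest.fixture(scope="session")
def windows(myo7a):
    return compute_region_windows(myo7a)


@pytest.fixture(scope="session")
def probands(myo7a):
    return load_proband_series(transcript=myo7a)


@pytest.fixture(scope="session")
def evidence_rows():
    return load_evidence_table()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
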
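import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import qscomm as q

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def printed_encoder() -> q.AllometricParams:
    """The fitted encoder operating point used throughout the analyses."""
    return q.AllometricParams(a=9.6, b=2.09, a_se=0.6, b_se=0.10)


@pytest.fixture
def printed_decoder() -> q.HillParams:
    return q.HillParams(wmax=1.0, km=4.0, n=2.3, km_se=0.5, n_se=0.2)


@pytest.fixture
def fermenter_growth() -> q.LogisticParams:
    return q.LogisticParams(n0=0.02, nmax=1.0, r=0.7)


@pytest.fixture
def printed_dynamics() -> q.DynamicsParams:
    return q.DynamicsParams(k=760.0, rm0=5.5)


def make_dose_table(concs, responses_per_conc) -> pd.DataFrame:
    """Long-format dose-response table from explicit replicate values."""
    rows = [
        (c, i, r)
        for c, reps in zip(concs, responses_per_conc)
        for i, r in enumerate(np.atleast_1d(reps))
    ]
    return pd.DataFrame(rows, columns=["sm_nM", "replicate_id", "response"])
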
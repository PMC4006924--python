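import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sepsiskit as sk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design() -> sk.SyntheticDesign:
    """Compact two-model design with clear effects: fast enough for the
    full pipeline, large enough that selections are non-trivial."""
    return sk.SyntheticDesign(
        n_probes=600,
        n_control=6,
        n_per_group=4,
        de_fraction=0.2,
        effect_sd=1.5,
        noise_sd=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return sk.generate_dataset(small_design)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_matrix() -> pd.DataFrame:
    """3 probes x 4 samples with hand-enterable values."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [5.0, 5.0, 5.0, 5.0],
         [2.0, 1.0, 4.0, 3.0]],
        index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
        columns=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
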
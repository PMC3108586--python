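import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

STUDY2_ZTS = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)


def make_samples(mesor, amplitude, acrophase_h, zts=STUDY2_ZTS, n_per_zt=5,
                 noise_sd=0.0, rng=None, **labels):
    """Cross-sectional cosinor samples with known truth."""
    t = np.repeat(zts, n_per_zt)
    y = mesor + amplitude * np.cos(2 * np.pi * (t - acrophase_h) / 24.0)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, t.size)
    cols = {"subject_id": [f"s{i}" for i in range(t.size)],
            "strain": labels.get("strain", "B6D2F1"),
            "sex": labels.get("sex", "male"),
            "tissue": labels.get("tissue", "mucosa"),
            "zt_h": t, "value": y}
    return pd.DataFrame(cols)


@pytest.fixture
def rng():
    return np.random.default_rng(2011)


@pytest.fixture
def noiseless_samples():
    return make_samples(10.0, 5.0, 12.0)
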
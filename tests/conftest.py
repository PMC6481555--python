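import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def instrument():
    """The packaged 31-SNP urate instrument table."""
    from mrkit import load_urate_instrument
    return load_urate_instrument()


@pytest.fixture
def rng():
    return np.random.default_rng(20180831)


def make_assoc(rsid="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01):
    return {"rsid": rsid, "effect_allele": ea, "other_allele": oa,
            "eaf": eaf, "beta": beta, "se": se}


@pytest.fixture
def assoc_table():
    """Build small association DataFrames from keyword rows."""
    def build(*rows):
        return pd.DataFrame([make_assoc(**r) for r in rows])
    return build


@pytest.fixture
def random_harmonized(rng):
    """A synthetic harmonized-record frame with positive exposure betas."""
    def build(n=31, true_effect=0.0, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        gx = r.uniform(0.02, 0.25, n)
        sx = r.uniform(0.002, 0.006, n)
        sy = r.uniform(0.01, 0.03, n)
        gy = r.normal(true_effect * gx, sy)
        return pd.DataFrame({
            "rsid": [f"rs{i}" for i in range(n)],
            "beta_exposure": gx, "se_exposure": sx,
            "beta_outcome": gy, "se_outcome": sy,
        })
    return build
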
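import numpy as np
import pandas as pd
import pytest

from sexewas.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_cpgs=1200, n_cohorts=2, n_female=(60, 45), n_male=(45, 35),
                     n_snps=120, n_genes=60, n_mqtl=15, n_eqtm=15, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def noiseless_study():
    cfg = SimConfig(n_cpgs=500, n_cohorts=1, n_female=(50,), n_male=(40,),
                    noise_sd=1e-12, batch_effect_sd=0.0, region_loading=0.0,
                    frac_failing_probes=0.0, seed=3)
    return cfg, generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_sheet(n, rng, sexes=("F", "M")):
    """Small random sample sheet for direct model tests."""
    sex = rng.choice(sexes, n)
    return pd.DataFrame({
        "sex": sex,
        "age_at_death": rng.uniform(60, 90, n),
        "braak": rng.integers(0, 7, n),
        "slide": rng.choice(["a", "b"], n),
        "plate": "p0",
        "bisulfite_conversion": 97.0,
        "neuron_prop": rng.beta(5, 7, n),
    }, index=[f"s{i}" for i in range(n)])
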
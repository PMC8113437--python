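import pytest

import csburden as cb
from csburden.simulate import DEFAULT_ENV, DEFAULT_TRUTH


@pytest.fixture(scope="session")
def env():
    return DEFAULT_ENV


@pytest.fixture(scope="session")
def truth():
    return DEFAULT_TRUTH


def make_clean_config(seed=0, n=600, truth=None, noise=1.0, **overrides):
    """Homoscedastic config with no grouping structure and no outliers."""
    kw = dict(
        seed=seed,
        n_samples=n,
        district_sd={"Q": 0.0, "mu": 0.0, "A": 0.0, "P": 0.0},
        municipality_sd={"Q": 0.0},
        noise_sd_by_district=(noise,) * 7,
        outlier_fraction=0.0,
    )
    if truth is not None:
        kw["truth"] = truth
    kw.update(overrides)
    return cb.SimulationConfig(**kw)


@pytest.fixture(scope="session")
def clean_config():
    return make_clean_config


@pytest.fixture(scope="session")
def clean_records():
    """One shared clean data set (n=600, ln-noise SD 1)."""
    cfg = make_clean_config(seed=42, n=600)
    records, truth = cb.generate_fukushima(cfg)
    return records, truth, cfg
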
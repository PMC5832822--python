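import numpy as np
import pandas as pd
import pytest

from idhscape import synth


@pytest.fixture(scope="session")
def pool():
    """Reference-size regional species pool shared across tests."""
    return synth.gen_species_pool(1581, alpha_regional=180.0, seed=42)


@pytest.fixture(scope="session")
def site():
    cfg = synth.GeneratorConfig(n_sites=4, seed=42)
    sites = synth.gen_site_table(cfg)
    return sites.iloc[0]


@pytest.fixture(scope="session")
def sites_table():
    return synth.gen_site_table(synth.GeneratorConfig(n_sites=8, seed=42))


@pytest.fixture(scope="session")
def inventory(pool, site):
    mapping = synth.gen_vernacular_mapping(pool, 0.6, seed=42)
    stems, _ = synth.gen_inventory(site, pool, 2000, 0.6, seed=42,
                                   mapping=mapping)
    return stems, mapping


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_power_data(n, theta, sigma, seed, u_max=6.5):
    """Sites drawn from the diversity-disturbance model, for recovery tests."""
    r = np.random.default_rng(seed)
    t0, t1, t2, t3, t4, t5 = theta
    u = r.uniform(0.0, u_max, n)
    rain = r.uniform(2000.0, 4000.0, n)
    alt = r.uniform(0.0, 830.0, n)
    mu = t0 + t1 * u + t2 * u**t3 + t4 * rain + t5 * alt
    return pd.DataFrame({
        "urti_pct": u, "rainfall_mm": rain, "elevation_m": alt,
        "alpha_mean": mu + r.normal(0.0, sigma, n),
    })
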
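import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from multitroph import CommunityTable, EnvTable, SimConfig, generate_metacommunity, toy_fixture

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """Fixed 6-site, 8-species toy dataset."""
    return toy_fixture()


@pytest.fixture(scope="session")
def small_metacommunity():
    """A small generated metacommunity (60 sites, 10 species) for cheap tests."""
    cfg = SimConfig(n_sites=60, n_fish=6, n_zoo=4, seed=5)
    return generate_metacommunity(cfg)


def make_community(matrix, guilds=None, sites=None, species=None) -> CommunityTable:
    matrix = np.asarray(matrix)
    n, s = matrix.shape
    sites = sites or [f"s{i}" for i in range(n)]
    species = species or [f"sp{j}" for j in range(s)]
    guilds = guilds or ["fish"] * s
    occ = pd.DataFrame(matrix, index=sites, columns=species)
    return CommunityTable(occ, pd.Series(guilds, index=species))


def make_env(covariates: dict, sites=None, classes=None) -> EnvTable:
    cov = pd.DataFrame(covariates)
    if sites is not None:
        cov.index = pd.Index(sites)
    classes = classes or {c: "climate" for c in cov.columns}
    coords = pd.DataFrame(
        {"longitude": np.zeros(len(cov)), "latitude": np.linspace(45, 60, len(cov))},
        index=cov.index,
    )
    return EnvTable(cov, pd.Series(classes), coords, "baseline")
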
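"""Synthetic metacommunities with known ground truth.

The generator emulates the structure of a lake metacommunity sampled along
a broad latitudinal climate gradient: two guilds (fish and zooplankton) of
presence-absence species, climate covariates that are monotone functions
of latitude plus noise, morphometry covariates independent of climate,
lognormal continuous traits and multinomial categorical traits, and
occurrences drawn from the same trait-structured latent-factor probit
model the pipeline fits:

    beta_.j ~ N(Gamma' t_j, V),   z = X beta + eta1 Lam1 + eta2 Lam2 + eps,
    y = 1[z > 0],

with a planted cross-guild factor (strong loadings of opposite or equal
sign on chosen fish-zooplankton pairs) inducing residual associations the
fitted model should recover.  All truths are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CommunityTable, EnvTable, TraitTable, ValidationError
from .jsdm import build_trait_design

CLIMATE_COVARIATES = ("max_temp", "min_temp", "precipitation")
MORPHOMETRY_COVARIATES = ("lake_area",)


@dataclass
class SimConfig:
    """Study-condition knobs for :func:`generate_metacommunity`.

    Defaults are the desk-scale conditions used throughout the test suite:
    150 sites spanning 17 degrees of latitude, 30 species in two guilds,
    a handful of strong trait-environment effects, one planted cross-guild
    site factor and one weak spatial factor.
    """

    n_sites: int = 150
    n_fish: int = 18
    n_zoo: int = 12
    lat_range: tuple = (45.0, 62.0)           # degrees, ~17 degree gradient
    lon_range: tuple = (-79.0, -63.0)
    gradient_strength: float = 1.0            # climate-latitude coupling
    gamma_entries: dict = field(default_factory=lambda: {
        ("intercept", "max_temp"): 0.5,
        ("length", "max_temp"): -0.8,
        ("ctmax", "min_temp"): 0.6,
        ("length", "precipitation"): -0.5,
    })
    v_scale: float = 0.05                     # residual niche covariance V = v * I
    n_planted_pairs: int = 3                  # cross-guild pairs on the planted factor
    planted_loading: float = 1.2
    shared_site_loading: float = 0.0          # >0 adds a site factor loading +value
                                              # on every species (site-quality axis)
    n_spatial_factors: int = 1
    spatial_loading_sd: float = 0.25
    spatial_loading_mode: str = "gaussian"    # "fixed": magnitude sd, random sign;
                                              # "shared": all species load +sd
                                              # (a common site-quality axis)
    alpha_true: float = 5.0                   # degrees
    scenario_deltas: dict = field(default_factory=lambda: {
        "SSP1-2.6": {"max_temp": 1.5, "min_temp": 1.5},
        "SSP3-7.0": {"max_temp": 3.5, "min_temp": 3.5},
        "SSP5-8.5": {"max_temp": 5.0, "min_temp": 5.0},
    })
    max_attempts: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sites, self.n_fish, self.n_zoo) < 1:
            raise ValidationError("dimensions must be positive")
        if self.seed is None:
            raise ValidationError("a seed is mandatory")

    @classmethod
    def network_scenario(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Planted structure for climate-compression network experiments.

        Two niche modules (thermal littoral species vs precipitation-driven
        pelagic species) plus a common site-quality factor every species
        loads on weakly.  At baseline the strong climate gradient keeps the
        modules apart; a gradient-compressing warming lets the shared axis
        dominate site orderings, so cross-module associations surface —
        connectance rises and modularity falls, the homogenization
        signature.
        """
        kw = dict(
            gamma_entries={("intercept", "max_temp"): 0.9,
                           ("habitat_pelagic", "max_temp"): -0.9,
                           ("habitat_pelagic", "precipitation"): 0.9},
            v_scale=0.02, shared_site_loading=0.35, n_spatial_factors=0,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class TrueParams:
    gamma_true: pd.DataFrame          # trait design x covariates (incl. intercepts)
    beta_true: pd.DataFrame           # covariates x species
    V_true: np.ndarray
    loadings_site_true: np.ndarray    # H1 x S
    loadings_spatial_true: np.ndarray # H2 x S
    eta_site_true: np.ndarray         # J x H1 generated factor scores
    eta_spatial_true: np.ndarray      # J x H2
    planted_pairs: list               # [(fish_id, zoo_id, sign), ...]
    alpha_true: float
    X_standardized: pd.DataFrame      # design actually used for liabilities
    trait_design: pd.DataFrame
    seed: int


def _covariate_recipe(lat: np.ndarray, lon: np.ndarray, strength: float,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Climate as monotone functions of latitude plus noise; morphometry
    independent lognormal."""
    n = lat.size
    lat01 = (lat - lat.min()) / max(np.ptp(lat), 1e-9)
    lon01 = (lon - lon.min()) / max(np.ptp(lon), 1e-9)
    return pd.DataFrame({
        "max_temp": 26.0 - 12.0 * strength * lat01 + rng.normal(0, 1.0, n),
        "min_temp": -8.0 - 14.0 * strength * lat01 + rng.normal(0, 3.0, n),
        # a second, longitudinal axis: keeps precipitation near-independent
        # of the thermal gradient, as inland-maritime contrasts are
        "precipitation": 1150.0 - 150.0 * lon01 + rng.normal(0, 60.0, n),
        "lake_area": np.exp(rng.normal(2.0, 1.0, n)),
    })


def _draw_traits(species: list, guild: pd.Series, rng: np.random.Generator) -> TraitTable:
    n = len(species)
    is_fish = (guild.loc[species] == "fish").to_numpy()
    # body length: fish in the few-hundred-mm range, zooplankton around 1 mm
    length = np.where(is_fish,
                      np.exp(rng.normal(5.0, 1.1, n)),
                      np.exp(rng.normal(0.0, 0.5, n)))
    ctmax = rng.normal(30.0, 2.5, n).clip(20.0, 40.0)
    trophic = rng.choice(["herbivore", "omnivore", "carnivore"], size=n,
                         p=[0.4, 0.35, 0.25])
    habitat = rng.choice(["littoral", "pelagic"], size=n, p=[0.55, 0.45])
    cont = pd.DataFrame({"length": length, "ctmax": ctmax}, index=species)
    cat = pd.DataFrame({"trophic_group": trophic, "habitat": habitat}, index=species)
    return TraitTable(cont, cat)


def generate_metacommunity(config: SimConfig):
    """Simulate one metacommunity; returns
    ``(CommunityTable, EnvTable, TraitTable, TrueParams)``.

    The environmental table holds *raw* covariates (the pipeline's
    preprocessor standardises them); liabilities are built from the
    standardised design so the recorded ``beta_true`` lives on the same
    scale as coefficients fitted after preprocessing.  Species whose
    simulated prevalence is 0 or 1 trigger a full resample with a spawned
    seed, up to ``config.max_attempts``.
    """
    root = np.random.SeedSequence(config.seed)
    for attempt, ss in enumerate(root.spawn(config.max_attempts)):
        rng = np.random.default_rng(ss)
        result = _generate_once(config, rng)
        if result is not None:
            return result
    raise ValidationError(
        f"no all-variable community in {config.max_attempts} attempts; "
        "weaken the environmental signal or enlarge n_sites"
    )


def _generate_once(config: SimConfig, rng: np.random.Generator):
    J = config.n_sites
    site_ids = [f"L{i + 1:03d}" for i in range(J)]
    lat = np.sort(rng.uniform(*config.lat_range, J))
    lon = rng.uniform(*config.lon_range, J)
    coords = pd.DataFrame({"longitude": lon, "latitude": lat}, index=site_ids)

    cov = _covariate_recipe(lat, lon, config.gradient_strength, rng)
    cov.index = pd.Index(site_ids)
    classes = pd.Series(
        {c: "climate" for c in CLIMATE_COVARIATES} |
        {c: "morphometry" for c in MORPHOMETRY_COVARIATES}
    )
    env = EnvTable(cov, classes, coords, "baseline")

    species = [f"F{i + 1:02d}" for i in range(config.n_fish)] + \
              [f"Z{i + 1:02d}" for i in range(config.n_zoo)]
    guild = pd.Series(["fish"] * config.n_fish + ["zooplankton"] * config.n_zoo,
                      index=species)
    traits = _draw_traits(species, guild, rng)
    tdesign = build_trait_design(traits)
    S, Q = tdesign.shape

    cov_names = ["intercept"] + list(cov.columns)
    K = len(cov_names)
    Xs = (cov - cov.mean()) / cov.std(ddof=1)
    X = np.column_stack([np.ones(J), Xs.to_numpy()])

    gamma = pd.DataFrame(0.0, index=tdesign.columns, columns=cov_names)
    for (trait, covname), value in config.gamma_entries.items():
        if trait not in gamma.index or covname not in gamma.columns:
            raise ValidationError(f"unknown gamma entry ({trait!r}, {covname!r})")
        gamma.loc[trait, covname] = value

    V = config.v_scale * np.eye(K)
    mean_B = (tdesign.to_numpy() @ gamma.to_numpy()).T          # K x S
    B = mean_B + np.sqrt(config.v_scale) * rng.standard_normal((K, S))

    # planted cross-guild site factor (+ optional shared site-quality factor)
    L1 = np.zeros((1, S))
    planted = []
    fish_ids = species[:config.n_fish]
    zoo_ids = species[config.n_fish:]
    n_pairs = min(config.n_planted_pairs, len(fish_ids), len(zoo_ids))
    for i in range(n_pairs):
        f, z = fish_ids[i], zoo_ids[i]
        sign = 1 if i % 2 == 0 else -1
        L1[0, species.index(f)] = config.planted_loading
        L1[0, species.index(z)] = sign * config.planted_loading
        planted.append((f, z, sign))
    if config.shared_site_loading > 0:
        L1 = np.vstack([L1, config.shared_site_loading * np.ones((1, S))])
    eta1 = rng.standard_normal((J, L1.shape[0]))

    # weak spatial factors with exponential distance decay
    H2 = config.n_spatial_factors
    if not H2:
        L2 = np.zeros((0, S))
    elif config.spatial_loading_mode == "fixed":
        L2 = config.spatial_loading_sd * rng.choice([-1.0, 1.0], size=(H2, S))
    elif config.spatial_loading_mode == "shared":
        L2 = config.spatial_loading_sd * np.ones((H2, S))
    else:
        L2 = config.spatial_loading_sd * rng.standard_normal((H2, S))
    eta2 = np.zeros((J, H2))
    if H2:
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(coords.to_numpy()))
        C = np.exp(-d / config.alpha_true) + 1e-8 * np.eye(J)
        cf = np.linalg.cholesky(C)
        eta2 = cf @ rng.standard_normal((J, H2))

    z = X @ B + eta1 @ L1 + eta2 @ L2 + rng.standard_normal((J, S))
    Y = (z > 0).astype(int)
    prevalence = Y.mean(axis=0)
    if ((prevalence == 0) | (prevalence == 1)).any():
        return None

    community = CommunityTable(pd.DataFrame(Y, index=site_ids, columns=species), guild)
    truth = TrueParams(
        gamma_true=gamma,
        beta_true=pd.DataFrame(B, index=cov_names, columns=species),
        V_true=V, loadings_site_true=L1, loadings_spatial_true=L2,
        eta_site_true=eta1, eta_spatial_true=eta2,
        planted_pairs=planted, alpha_true=config.alpha_true,
        X_standardized=pd.DataFrame(X, index=site_ids, columns=cov_names),
        trait_design=tdesign, seed=config.seed,
    )
    return community, env, traits, truth


def generate_scenario_shift(env: EnvTable, deltas: dict) -> EnvTable:
    """Shifted copy of a raw environmental table (a custom climate scenario).

    ``deltas`` maps climate-class covariate names to a scalar or a per-site
    array added to the raw values; non-climate covariates are refused.
    """
    climate = set(env.climate_covariates())
    cov = env.covariates.copy()
    for name, delta in deltas.items():
        if name not in climate:
            raise ValidationError(
                f"scenario delta on non-climate covariate {name!r}"
            )
        cov[name] = cov[name] + np.asarray(delta)
    return EnvTable(cov, env.covariate_class, env.coords, "custom")


def compress_gradient_deltas(env: EnvTable, covariate: str, warming: float) -> dict:
    """Per-site deltas that warm cold (high-latitude) sites the most,
    shrinking the between-site spread of ``covariate`` — the signature of a
    northern-amplified climate scenario."""
    values = env.covariates[covariate]
    span = np.ptp(values.to_numpy())
    if span == 0:
        raise ValidationError(f"constant covariate {covariate!r}")
    cold = (values.max() - values) / span            # 1 at the coldest site
    return {covariate: (warming * cold).to_numpy()}


def true_occurrence_probabilities(truth: TrueParams, env_baseline: EnvTable,
                                  env_scenario: EnvTable | None = None) -> pd.DataFrame:
    """Conditional occurrence probabilities under the *true* parameters.

    Standardises the (scenario) covariates with the baseline mean/sd, keeps
    the generated factor scores fixed, and returns ``Phi(X beta + eta Lam)``
    as a sites x species DataFrame — the noiseless analogue of a fitted
    model's conditional posterior-predictive matrix.
    """
    from scipy.special import ndtr

    base = env_baseline.covariates
    use = env_scenario.covariates if env_scenario is not None else base
    Xs = (use[base.columns] - base.mean()) / base.std(ddof=1)
    X = np.column_stack([np.ones(len(Xs)), Xs.to_numpy()])
    lin = X @ truth.beta_true.to_numpy()
    lin += truth.eta_site_true @ truth.loadings_site_true
    lin += truth.eta_spatial_true @ truth.loadings_spatial_true
    return pd.DataFrame(ndtr(lin), index=env_baseline.site_ids,
                        columns=truth.beta_true.columns)


# ---------------------------------------------------------------------------
# fixed toy fixture
# ---------------------------------------------------------------------------

def toy_fixture():
    """Deterministic 6-site, 8-species, 3-covariate dataset.

    Occurrence matrix (sites x species; F* fish, Z* zooplankton)::

               F1 F2 F3 F4 F5 Z1 Z2 Z3
        S1      1  1  1  0  0  1  0  0
        S2      1  1  0  1  0  1  1  0
        S3      0  1  1  0  1  0  1  1
        S4      0  0  1  1  1  0  1  1
        S5      1  0  0  1  1  1  0  1
        S6      0  1  0  0  1  0  1  0

    Hand-checkable facts: per-site richness (4, 5, 5, 5, 5, 3); per-species
    prevalence >= 2 everywhere, so the rare-species filter is a no-op;
    Jaccard LCBD (all 8 species) = (0.225320, 0.141409, 0.107004, 0.150631,
    0.186557, 0.189079) to 6 decimals, from the Gower-centred decomposition.
    """
    sites = [f"S{i}" for i in range(1, 7)]
    species = ["F1", "F2", "F3", "F4", "F5", "Z1", "Z2", "Z3"]
    occ = pd.DataFrame(
        [
            [1, 1, 1, 0, 0, 1, 0, 0],
            [1, 1, 0, 1, 0, 1, 1, 0],
            [0, 1, 1, 0, 1, 0, 1, 1],
            [0, 0, 1, 1, 1, 0, 1, 1],
            [1, 0, 0, 1, 1, 1, 0, 1],
            [0, 1, 0, 0, 1, 0, 1, 0],
        ],
        index=sites, columns=species,
    )
    guild = pd.Series(["fish"] * 5 + ["zooplankton"] * 3, index=species)
    community = CommunityTable(occ, guild)

    cov = pd.DataFrame(
        {
            "max_temp": [24.0, 22.0, 20.0, 18.0, 16.0, 14.0],
            "precipitation": [900.0, 950.0, 1000.0, 980.0, 940.0, 910.0],
            "lake_area": [2.0, 8.0, 4.0, 16.0, 6.0, 3.0],
        },
        index=sites,
    )
    classes = pd.Series({"max_temp": "climate", "precipitation": "climate",
                         "lake_area": "morphometry"})
    coords = pd.DataFrame(
        {"longitude": [-70.0, -71.0, -72.0, -73.0, -74.0, -75.0],
         "latitude": [46.0, 48.0, 50.0, 52.0, 54.0, 56.0]},
        index=sites,
    )
    env = EnvTable(cov, classes, coords, "baseline")

    cont = pd.DataFrame(
        {"length": [320.0, 150.0, 80.0, 450.0, 210.0, 1.2, 0.4, 0.9],
         "ctmax": [28.0, 31.0, 33.0, 26.0, 30.0, 32.0, 34.0, 31.0]},
        index=species,
    )
    cat = pd.DataFrame(
        {"trophic_group": ["carnivore", "omnivore", "herbivore", "carnivore",
                           "omnivore", "herbivore", "herbivore", "omnivore"]},
        index=species,
    )
    traits = TraitTable(cont, cat)
    return community, env, traits
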
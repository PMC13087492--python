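"""Tables, validation, preprocessing and configuration.

The pipeline works with three aligned tables:

* a site x species binary occurrence matrix split into two guilds
  (fish and zooplankton) — the response matrix ``Y``;
* a site x covariate environmental table carrying coordinates and a
  scenario label — the design matrix ``X``;
* a species x trait table mixing continuous traits (body length in mm,
  critical thermal maximum in degrees C) and categorical traits
  (trophic level, habitat, feeding type) — the trait matrix ``T``.

All tables are CSV with the identifier in the first column.  Covariate
preprocessing (variance-stabilising transforms, a Pearson collinearity
screen, median imputation and z-standardisation) is handled by
:class:`EnvPreprocessor`, an sklearn-style transformer fitted on the
baseline table so that the identical affine standardisation is re-applied
to every climate-scenario table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger("multitroph")

GUILDS = ("fish", "zooplankton")
SCENARIOS = ("baseline", "SSP1-2.6", "SSP3-7.0", "SSP5-8.5", "custom")
COVARIATE_CLASSES = ("climate", "morphometry", "anthropogenic")


class ValidationError(ValueError):
    """A table violates one of the pipeline's structural contracts."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CommunityTable:
    """Site x species binary occurrences with a guild label per species."""

    occurrence: pd.DataFrame          # sites x species, values in {0, 1}
    guild: pd.Series                  # species -> {"fish", "zooplankton"}

    def __post_init__(self) -> None:
        occ = self.occurrence
        if occ.index.has_duplicates:
            dupes = occ.index[occ.index.duplicated()].tolist()
            raise ValidationError(f"duplicated site ids: {dupes}")
        if occ.columns.has_duplicates:
            dupes = occ.columns[occ.columns.duplicated()].tolist()
            raise ValidationError(f"duplicated species ids: {dupes}")
        values = occ.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary occurrence value {values[i, j]!r} at "
                f"site {occ.index[i]!r}, species {occ.columns[j]!r}"
            )
        self.occurrence = occ.astype(np.int8)
        missing = occ.columns.difference(self.guild.index)
        if len(missing):
            raise ValidationError(f"species without a guild label: {missing.tolist()}")
        self.guild = self.guild.reindex(occ.columns)
        unknown = set(self.guild.unique()) - set(GUILDS)
        if unknown:
            raise ValidationError(f"unknown guild labels: {sorted(unknown)}")

    @property
    def site_ids(self) -> pd.Index:
        return self.occurrence.index

    @property
    def species_ids(self) -> pd.Index:
        return self.occurrence.columns

    def species_of_guild(self, guild: str) -> pd.Index:
        if guild not in GUILDS:
            raise ValidationError(f"unknown guild {guild!r}; expected one of {GUILDS}")
        return self.species_ids[self.guild.to_numpy() == guild]

    def subset_species(self, species: Sequence) -> "CommunityTable":
        return CommunityTable(self.occurrence[list(species)], self.guild.loc[list(species)])

    def to_csv(self, path) -> None:
        """Write sites x species CSV with a leading ``guild`` row."""
        out = self.occurrence.astype(object).copy()
        out.loc["guild"] = self.guild
        out = out.reindex(["guild"] + list(self.occurrence.index))
        out.index.name = "site_id"
        out.to_csv(path)


@dataclass
class EnvTable:
    """Site x covariate table with coordinates and a scenario label."""

    covariates: pd.DataFrame          # sites x covariates, numeric
    covariate_class: pd.Series        # covariate -> class label
    coords: pd.DataFrame              # sites x (longitude, latitude), degrees
    scenario: str = "baseline"

    def __post_init__(self) -> None:
        if self.covariates.index.has_duplicates:
            raise ValidationError("duplicated site ids in environmental table")
        if self.scenario not in SCENARIOS:
            raise ValidationError(
                f"scenario {self.scenario!r} not in {SCENARIOS}"
            )
        missing = self.covariates.columns.difference(self.covariate_class.index)
        if len(missing):
            raise ValidationError(f"covariates without class label: {missing.tolist()}")
        self.covariate_class = self.covariate_class.reindex(self.covariates.columns)
        unknown = set(self.covariate_class.unique()) - set(COVARIATE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown covariate classes: {sorted(unknown)}")
        self.coords = self.coords.reindex(self.covariates.index)
        if not np.isfinite(self.coords.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite site coordinates")

    @property
    def site_ids(self) -> pd.Index:
        return self.covariates.index

    @property
    def covariate_names(self) -> pd.Index:
        return self.covariates.columns

    def climate_covariates(self) -> pd.Index:
        return self.covariate_names[self.covariate_class.to_numpy() == "climate"]

    def with_scenario(self, scenario: str) -> "EnvTable":
        return replace(self, scenario=scenario)

    def to_csv(self, path) -> None:
        """Write sites x covariate CSV with coordinate columns and a leading
        ``covariate_class`` row."""
        out = self.covariates.astype(object).copy()
        out.insert(0, "longitude", self.coords["longitude"].astype(object))
        out.insert(1, "latitude", self.coords["latitude"].astype(object))
        classes = self.covariate_class.reindex(out.columns).fillna("coordinate")
        out.loc["covariate_class"] = classes
        out = out.reindex(["covariate_class"] + list(self.covariates.index))
        out.index.name = "site_id"
        out.to_csv(path)


@dataclass
class TraitTable:
    """Species x trait table (continuous + categorical blocks)."""

    continuous: pd.DataFrame          # species x continuous traits
    categorical: pd.DataFrame         # species x categorical traits (strings)

    def __post_init__(self) -> None:
        if not self.continuous.index.equals(self.categorical.index):
            self.categorical = self.categorical.reindex(self.continuous.index)
        if self.continuous.index.has_duplicates:
            raise ValidationError("duplicated species ids in trait table")

    @property
    def species_ids(self) -> pd.Index:
        return self.continuous.index

    def subset(self, species: Sequence) -> "TraitTable":
        sp = list(species)
        return TraitTable(self.continuous.loc[sp], self.categorical.loc[sp])

    def impute_group_means(self, groups: pd.Series | None = None) -> "TraitTable":
        """Fill missing continuous traits with group means (overall mean fallback)."""
        cont = self.continuous.copy()
        for col in cont.columns:
            if groups is not None:
                means = cont[col].groupby(groups.reindex(cont.index)).transform("mean")
                cont[col] = cont[col].fillna(means)
            cont[col] = cont[col].fillna(cont[col].mean())
        return TraitTable(cont, self.categorical)

    def validate_complete(self) -> None:
        if self.continuous.isna().any().any():
            bad = self.continuous.index[self.continuous.isna().any(axis=1)].tolist()
            raise ValidationError(f"species with missing continuous traits: {bad}")
        if not np.isfinite(self.continuous.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite continuous trait values")

    def to_csv(self, path) -> None:
        out = pd.concat([self.continuous, self.categorical], axis=1)
        out.index.name = "species_id"
        out.to_csv(path)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (mirrors the YAML config file)."""

    transform_map: dict = field(default_factory=dict)   # covariate -> "log"|"sqrt"|"none"
    correlation_threshold: float = 0.9
    imputation: str = "median"                          # "median" | "mean"
    rare_min_sites: int = 2
    rf_n_trees: int = 100
    rf_top_k: int = 10
    rf_exclude: list = field(default_factory=lambda: ["longitude", "latitude"])
    mcmc_thin: int = 5
    mcmc_samples: int = 1000
    mcmc_chains: int = 2
    mcmc_transient: int = 2500
    beta_support: float = 0.90
    gamma_support: float = 0.90
    omega_support: float = 0.95
    network_alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("beta_support", "gamma_support", "omega_support", "network_alpha",
                     "correlation_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name}={v} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_manifest(path, config: PipelineConfig, extra: Mapping | None = None) -> None:
    """Run manifest: seed, config hash, library versions."""
    import networkx
    import scipy
    import sklearn

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
            "networkx": networkx.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _read_indexed_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df

def load_community(path, guild_map: Mapping[str, str] | None = None,
                   guild_row: str = "guild", binarize: bool = False) -> CommunityTable:
    """Load a site x species CSV.

    The guild of each species comes either from ``guild_map`` or from a row
    of the CSV whose site id equals ``guild_row``.  With ``binarize=True``
    positive abundances are converted to presences (the model is strictly
    presence-absence).
    """
    df = _read_indexed_csv(path)
    embedded = None
    if guild_row in df.index:
        embedded = df.loc[guild_row].astype(str)
        df = df.drop(index=guild_row)
    if guild_map is not None:
        guild = pd.Series({str(k): v for k, v in guild_map.items()})
    elif embedded is not None:
        guild = embedded
    else:
        raise ValidationError(
            f"no guild information: pass guild_map or include a {guild_row!r} row"
        )
    df = df.apply(pd.to_numeric)
    if binarize:
        df = (df > 0).astype(int)
    return CommunityTable(df, guild)

def load_env(path, covariate_class: Mapping[str, str] | None = None,
             scenario: str = "baseline") -> EnvTable:
    df = _read_indexed_csv(path)
    embedded = None
    if "covariate_class" in df.index:
        embedded = df.loc["covariate_class"].astype(str)
        df = df.drop(index="covariate_class")
    if not {"longitude", "latitude"} <= set(df.columns):
        raise ValidationError("environmental table must carry longitude and latitude columns")
    coords = df[["longitude", "latitude"]].astype(float)
    cov = df.drop(columns=["longitude", "latitude"]).apply(pd.to_numeric)
    if covariate_class:
        classes = pd.Series({str(k): v for k, v in covariate_class.items()})
    elif embedded is not None:
        classes = embedded
    else:
        classes = pd.Series("climate", index=cov.columns)   # permissive default
    return EnvTable(cov, classes.reindex(cov.columns), coords, scenario)

def load_traits(path, continuous: Sequence[str]) -> TraitTable:
    df = _read_indexed_csv(path)
    cont_cols = [c for c in df.columns if c in set(continuous)]
    cat_cols = [c for c in df.columns if c not in set(continuous)]
    cont = df[cont_cols].apply(pd.to_numeric)
    cat = df[cat_cols].astype("string")
    return TraitTable(cont, cat)


def load_dataset(community_path, env_path, trait_path, config: PipelineConfig | None = None,
                 *, guild_map=None, covariate_class=None, continuous_traits=(),
                 binarize: bool = False):
    """Load and align the three tables; raise on any identifier mismatch.

    Returns ``(community, env, traits)`` with identical site order in the
    first two and the community's species order in the third.
    """
    community = load_community(community_path, guild_map=guild_map, binarize=binarize)
    env = load_env(env_path, covariate_class or {})
    traits = load_traits(trait_path, continuous_traits)

    missing_env = community.site_ids.difference(env.site_ids)
    if len(missing_env):
        raise ValidationError(
            f"sites present in community but absent from env table: {missing_env.tolist()}"
        )
    extra_env = env.site_ids.difference(community.site_ids)
    if len(extra_env):
        logger.info("dropping %d env-only sites: %s", len(extra_env), extra_env.tolist())
    env = EnvTable(env.covariates.loc[community.site_ids],
                   env.covariate_class,
                   env.coords.loc[community.site_ids],
                   env.scenario)

    missing_traits = community.species_ids.difference(traits.species_ids)
    if len(missing_traits):
        raise ValidationError(
            f"species without trait rows: {missing_traits.tolist()}"
        )
    traits = traits.subset(community.species_ids)
    logger.info("aligned %d sites, %d species", len(community.site_ids),
                len(community.species_ids))
    return community, env, traits


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_rare_species(community: CommunityTable, min_sites: int = 2) -> CommunityTable:
    """Drop species occurring at fewer than ``min_sites`` sites.

    The default removes singletons — species recorded in only one lake —
    which carry no information for a co-occurrence model.  Idempotent.
    """
    counts = community.occurrence.sum(axis=0)
    keep = counts[counts >= min_sites].index
    if len(keep) == 0:
        raise ValidationError("rare-species filter removed every species")
    dropped = community.species_ids.difference(keep)
    if len(dropped):
        logger.info("rare-species filter dropped %d species: %s",
                    len(dropped), dropped.tolist())
    return community.subset_species(keep)


# ---------------------------------------------------------------------------
# environmental preprocessing
# ---------------------------------------------------------------------------

class EnvPreprocessor(BaseEstimator, TransformerMixin):
    """Transform, screen and standardise environmental covariates.

    Fitted on the baseline table; the stored transform parameters (kept
    covariates, per-covariate means and standard deviations) are then
    applied unchanged to scenario tables, so baseline and scenario designs
    live on the same scale.

    Steps, in order:

    1. per-covariate variance-stabilising transform (``log``/``sqrt``/none);
    2. column-median (or mean) imputation of missing values;
    3. collinearity screen: of any pair with ``|Pearson r|`` above
       ``correlation_threshold`` the later-listed covariate is dropped;
    4. z-standardisation (mean 0, sd 1) of the retained covariates.

    Parameters
    ----------
    transform_map : mapping of covariate name to {"log", "sqrt", "none"}
    correlation_threshold : absolute Pearson r above which a pair is
        considered collinear (default 0.9)
    imputation : "median" (default) or "mean"
    """

    def __init__(self, transform_map: dict | None = None,
                 correlation_threshold: float = 0.9,
                 imputation: str = "median"):
        self.transform_map = transform_map
        self.correlation_threshold = correlation_threshold
        self.imputation = imputation

    # -- helpers -----------------------------------------------------------
    def _apply_transforms(self, cov: pd.DataFrame) -> pd.DataFrame:
        cov = cov.astype(float).copy()
        for name, how in (self.transform_map or {}).items():
            if name not in cov.columns or how in (None, "none"):
                continue
            col = cov[name]
            if how == "log":
                if (col <= 0).any():
                    bad = col.index[(col <= 0).fillna(False)][0]
                    raise ValidationError(
                        f"log transform of non-positive value in {name!r} at site {bad!r}"
                    )
                cov[name] = np.log(col)
            elif how == "sqrt":
                if (col < 0).any():
                    bad = col.index[(col < 0).fillna(False)][0]
                    raise ValidationError(
                        f"sqrt transform of negative value in {name!r} at site {bad!r}"
                    )
                cov[name] = np.sqrt(col)
            else:
                raise ValidationError(f"unknown transform {how!r} for {name!r}")
        return cov

    def _impute(self, cov: pd.DataFrame) -> pd.DataFrame:
        fill = cov.median() if self.imputation == "median" else cov.mean()
        return cov.fillna(fill)

    # -- sklearn interface -------------------------------------------------
    def fit(self, env: EnvTable, y=None):
        if not 0.0 < self.correlation_threshold <= 1.0:
            raise ValidationError("correlation_threshold must lie in (0, 1]")
        if self.imputation not in ("median", "mean"):
            raise ValidationError("imputation must be 'median' or 'mean'")
        cov = self._impute(self._apply_transforms(env.covariates))

        sd = cov.std(ddof=1)
        zero_var = sd.index[(sd == 0) | sd.isna()]
        if len(zero_var):
            logger.warning("dropping zero-variance covariates: %s", zero_var.tolist())
            cov = cov.drop(columns=zero_var)

        corr = cov.corr().abs().to_numpy()
        keep_mask = np.ones(cov.shape[1], dtype=bool)
        dropped = []
        for j in range(cov.shape[1]):           # later-listed member is dropped
            for i in range(j):
                if keep_mask[i] and keep_mask[j] and corr[i, j] > self.correlation_threshold:
                    keep_mask[j] = False
                    dropped.append((cov.columns[j], cov.columns[i], corr[i, j]))
                    break
        if dropped:
            logger.info("collinearity screen dropped: %s",
                        [(d, f"r={r:.3f} with {k}") for d, k, r in dropped])
        kept = cov.columns[keep_mask]

        self.kept_covariates_ = list(kept)
        self.dropped_covariates_ = [d for d, _, _ in dropped]
        self.center_ = cov[kept].mean()
        self.scale_ = cov[kept].std(ddof=1)
        return self

    def transform(self, env: EnvTable) -> EnvTable:
        check_is_fitted(self, "kept_covariates_")
        cov = self._impute(self._apply_transforms(env.covariates))
        missing = [c for c in self.kept_covariates_ if c not in cov.columns]
        if missing:
            raise ValidationError(f"scenario table lacks fitted covariates: {missing}")
        z = (cov[self.kept_covariates_] - self.center_) / self.scale_
        return EnvTable(z, env.covariate_class.loc[self.kept_covariates_],
                        env.coords, env.scenario)


def preprocess_env(env: EnvTable, config: PipelineConfig) -> tuple[EnvTable, EnvPreprocessor]:
    """Fit an :class:`EnvPreprocessor` on ``env`` and return the transformed
    table together with the fitted transformer (for scenario reuse)."""
    prep = EnvPreprocessor(
        transform_map=config.transform_map,
        correlation_threshold=config.correlation_threshold,
        imputation=config.imputation,
    ).fit(env)
    return prep.transform(env), prep
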
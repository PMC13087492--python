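"""Probability-weighted community trait summaries (CWMs) and their trends.

The community-weighted mean of a continuous trait at site ``i`` is

    CWM_i = sum_j p_ij t_j / sum_j p_ij,

with ``p_ij`` the posterior-predictive occurrence probability; categorical
traits yield per-level proportions with the same weights.  Regressing a
CWM on a raw climate covariate (per scenario) gives the trait-climate
trend whose slope sign is the comparable quantity across scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_io import EnvTable, TraitTable, ValidationError
from .projection import ProbabilityMatrix


@dataclass
class CWMTable:
    continuous: pd.DataFrame        # sites x continuous-trait CWMs
    proportions: dict               # trait -> sites x level proportions
    guild: str | None
    scenario: str


def cwm(prob: ProbabilityMatrix, traits: TraitTable, guild: str | None = None,
        guild_labels: pd.Series | None = None) -> CWMTable:
    """Community-weighted trait means, optionally restricted to one guild."""
    species = list(prob.species_ids)
    if guild is not None:
        if guild_labels is None:
            raise ValidationError("guild restriction needs guild_labels")
        species = [s for s in species if guild_labels.get(s) == guild]
        if not species:
            raise ValidationError(f"no species of guild {guild!r} in the matrix")
    missing = [s for s in species if s not in traits.species_ids]
    if missing:
        raise ValidationError(f"species without trait values: {missing}")

    P = prob.prob[species].to_numpy(dtype=float)
    weight_sum = P.sum(axis=1)
    empty = weight_sum == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} sites with zero total probability; CWM is NaN")
    safe = np.where(empty, np.nan, weight_sum)

    tsub = traits.subset(species)
    cont = pd.DataFrame(index=prob.site_ids)
    for col in tsub.continuous.columns:
        t = tsub.continuous[col].to_numpy(dtype=float)
        cont[col] = (P @ t) / safe

    proportions = {}
    for col in tsub.categorical.columns:
        levels = tsub.categorical[col]
        out = pd.DataFrame(index=prob.site_ids)
        for level in pd.unique(levels.dropna()):
            sel = (levels == level).to_numpy()
            out[str(level)] = P[:, sel].sum(axis=1) / safe
        proportions[col] = out
    return CWMTable(cont, proportions, guild, prob.scenario)


@dataclass
class TrendFit:
    covariate: str
    slope: float
    intercept: float
    r2: float
    fit_form: str
    scenario: str | None = None


def trait_climate_trend(values: pd.Series, env: EnvTable, covariate: str,
                        scenario: str | None = None) -> TrendFit:
    """OLS of a per-site CWM (or proportion) on one raw covariate."""
    if covariate not in env.covariate_names:
        raise ValidationError(f"unknown covariate {covariate!r}")
    x = env.covariates[covariate].reindex(values.index).to_numpy(dtype=float)
    y = values.to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValidationError("too few sites with finite CWM and covariate")
    if np.ptp(x) == 0:
        raise ValidationError(f"constant covariate {covariate!r}")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return TrendFit(
        covariate=covariate, slope=float(fit.params[1]),
        intercept=float(fit.params[0]), r2=float(fit.rsquared),
        fit_form="linear", scenario=scenario,
    )


def richness_length_summary(prob: ProbabilityMatrix, traits: TraitTable,
                            env: EnvTable, covariate: str,
                            length_trait: str = "length",
                            threshold: float = 0.5) -> pd.DataFrame:
    """Per-site expected richness, probability-weighted mean length, and
    expected richness split into small/large size classes at ``threshold``
    (0.5 mm is the conventional zooplankton cutoff)."""
    species = [s for s in prob.species_ids if s in traits.species_ids]
    P = prob.prob[species].to_numpy(dtype=float)
    lengths = traits.subset(species).continuous[length_trait].to_numpy(dtype=float)
    weight_sum = P.sum(axis=1)
    safe = np.where(weight_sum == 0, np.nan, weight_sum)
    small = lengths < threshold
    out = pd.DataFrame(index=prob.site_ids)
    out["expected_richness"] = P.sum(axis=1)
    out["mean_length"] = (P @ lengths) / safe
    out["richness_small"] = P[:, small].sum(axis=1)
    out["richness_large"] = P[:, ~small].sum(axis=1)
    if covariate in env.covariate_names:
        out[covariate] = env.covariates[covariate].reindex(prob.site_ids)
    return out
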
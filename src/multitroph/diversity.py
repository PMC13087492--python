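"""Richness and local contribution to beta diversity (LCBD).

LCBD partitions total community-composition variance among sites: from a
pairwise dissimilarity matrix ``D`` (Jaccard on presence-absence by
default) the Gower-centred matrix of ``-D^2/2`` is formed, and site ``i``'s
contribution is its diagonal element divided by the total sum of squares.
LCBD values are non-negative and sum to one over sites; a large value marks
a compositionally unusual ("unique") site.  Significance is assessed by
permuting each species column independently and recomputing LCBD, with a
Holm step-down correction across sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .data_io import CommunityTable, ValidationError


def richness(community: CommunityTable, guild: str | None = None) -> pd.Series:
    """Per-site species counts, optionally restricted to one guild."""
    occ = community.occurrence
    if guild is not None:
        occ = occ[community.species_of_guild(guild)]
    return occ.sum(axis=1).rename("richness")


def _lcbd_from_occurrence(occ: np.ndarray, metric: str) -> tuple[np.ndarray, float]:
    """LCBD values and total SS from a binary site x species matrix."""
    d = pdist(occ.astype(bool), metric=metric)
    a = -0.5 * squareform(d) ** 2
    n = a.shape[0]
    row_mean = a.mean(axis=1, keepdims=True)
    g = a - row_mean - row_mean.T + a.mean()
    ss_i = np.diag(g).copy()
    ss_total = ss_i.sum()
    return ss_i, ss_total


@dataclass
class LCBDResult:
    lcbd: pd.Series
    p_value: pd.Series
    significant: pd.Series
    index_name: str
    n_permutations: int


def lcbd(community: CommunityTable, index: str = "jaccard", n_perm: int = 999,
         alpha: float = 0.05, seed: int | None = None) -> LCBDResult:
    """LCBD with per-species-column permutation p-values and Holm correction.

    ``p_i = (#{LCBD*_i >= LCBD_i} + 1) / (n_perm + 1)`` where each permuted
    replicate shuffles every species column independently, breaking
    site-species association while preserving species prevalences.
    """
    occ = community.occurrence.to_numpy()
    n_sites, n_species = occ.shape
    if n_sites < 2 or n_species < 1:
        raise ValidationError("LCBD needs at least 2 sites and 1 species")
    ss_i, ss_total = _lcbd_from_occurrence(occ, index)
    if ss_total <= 1e-12:
        raise ValidationError("no beta diversity: all site compositions identical")
    values = ss_i / ss_total

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_sites, dtype=int)
    for _ in range(n_perm):
        perm = np.empty_like(occ)
        for j in range(n_species):
            perm[:, j] = occ[rng.permutation(n_sites), j]
        ss_p, tot_p = _lcbd_from_occurrence(perm, index)
        if tot_p <= 1e-12:
            continue
        exceed += (ss_p / tot_p) >= values
    pvals = (exceed + 1) / (n_perm + 1)
    sig = multipletests(pvals, alpha=alpha, method="holm")[0]

    sites = community.site_ids
    return LCBDResult(
        lcbd=pd.Series(values, index=sites, name="lcbd"),
        p_value=pd.Series(pvals, index=sites, name="p_value"),
        significant=pd.Series(sig, index=sites, name="significant"),
        index_name=index,
        n_permutations=n_perm,
    )


@dataclass
class RegressionFit:
    model_form: str                 # "linear" or "quadratic"
    coefficients: dict
    r2: float
    adjusted_r2: float
    n: int
    linear: dict
    quadratic: dict


def fit_richness_lcbd(x, y, criterion: str = "adjusted_r2") -> RegressionFit:
    """OLS of ``y ~ x`` and ``y ~ x + x^2``; keep the better-supported form.

    The quadratic nests the linear model, so raw R^2 would always prefer it;
    by default the choice uses adjusted R^2 with ties going to the linear
    form.  ``criterion="r2"`` switches to raw R^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValidationError("need equal-length inputs with at least 4 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in regression inputs")
    if np.ptp(x) == 0:
        raise ValidationError("constant predictor")

    lin = sm.OLS(y, sm.add_constant(x)).fit()
    quad = sm.OLS(y, sm.add_constant(np.column_stack([x, x ** 2]))).fit()

    def _summary(fit, names):
        return {
            "coefficients": dict(zip(names, fit.params)),
            "r2": float(max(fit.rsquared, 0.0)),
            "adjusted_r2": float(fit.rsquared_adj),
        }

    lin_s = _summary(lin, ["intercept", "x"])
    quad_s = _summary(quad, ["intercept", "x", "x2"])

    key = "r2" if criterion == "r2" else "adjusted_r2"
    tol = 1e-12
    form = "quadratic" if quad_s[key] > lin_s[key] + tol else "linear"
    chosen = quad_s if form == "quadratic" else lin_s
    return RegressionFit(
        model_form=form,
        coefficients=chosen["coefficients"],
        r2=chosen["r2"],
        adjusted_r2=chosen["adjusted_r2"],
        n=int(x.size),
        linear=lin_s,
        quadratic=quad_s,
    )


def diversity_table(community: CommunityTable, n_perm: int = 999, alpha: float = 0.05,
                    seed: int | None = None) -> pd.DataFrame:
    """Per-site richness and LCBD for both guilds (LCBD families tested
    separately per guild, as fish and zooplankton uniqueness are distinct
    questions)."""
    out = pd.DataFrame(index=community.site_ids)
    rng = np.random.default_rng(seed)
    for guild, tag in (("fish", "fish"), ("zooplankton", "zoo")):
        species = community.species_of_guild(guild)
        if len(species) == 0:
            continue
        sub = community.subset_species(species)
        out[f"richness_{tag}"] = richness(sub)
        res = lcbd(sub, n_perm=n_perm, alpha=alpha,
                   seed=int(rng.integers(2 ** 31 - 1)))
        out[f"lcbd_{tag}"] = res.lcbd
        out[f"p_{tag}"] = res.p_value
        out[f"sig_{tag}"] = res.significant
    return out
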
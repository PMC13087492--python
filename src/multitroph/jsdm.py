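"""Trait-structured latent-factor joint species distribution model.

The model is a multivariate probit regression for a site x species binary
occurrence matrix ``Y`` (J sites, S species), sharing information across
species through a trait hierarchy and through latent factors:

    y_ij = 1[z_ij > 0]
    z_ij = x_i' beta_j + sum_h eta1_ih lam1_hj + sum_h eta2_ih lam2_hj + eps_ij
    eps_ij ~ N(0, 1)
    beta_j ~ N(Gamma' t_j, V)                      (trait hierarchy)
    eta1_i ~ N(0, I_H1)                            (site-level factors)
    eta2_.h ~ N(0, C(alpha_h)),  C_rs = exp(-d_rs / alpha_h)   (spatial factors)

``beta`` (K x S) are species-environment coefficients, ``Gamma`` (Q x K)
the trait-environment effects (how traits shift species' niches), ``V``
the residual niche covariance, ``lam1``/``lam2`` factor loadings with
multiplicative-gamma shrinkage priors, and ``alpha_h`` a spatial decay
range in degrees sampled over a discrete grid.  The product of loadings
induces the residual species-species association matrix
``Omega = Lambda' Lambda`` interpreted on the correlation scale.

Inference is by Gibbs sampling with truncated-normal data augmentation of
the probit liabilities; all conditional updates are conjugate except the
spatial range, which is drawn from its discrete conditional posterior.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.spatial.distance import pdist, squareform
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart
from sklearn.base import BaseEstimator

from .data_io import CommunityTable, EnvTable, TraitTable, ValidationError

logger = logging.getLogger("multitroph")

_TINY = 1e-12


@dataclass
class MCMCConfig:
    """Chain settings: retained ``samples`` per chain after ``transient``
    burn-in iterations, keeping every ``thin``-th draw."""

    thin: int = 5
    samples: int = 1000
    n_chains: int = 2
    transient: int = 2500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("thin", "samples", "n_chains", "transient"):
            if int(getattr(self, name)) < 1 and name != "transient":
                raise ValidationError(f"{name} must be a positive integer")
        if self.transient < 0:
            raise ValidationError("transient must be non-negative")


@dataclass
class JSDMPosterior:
    """Retained MCMC draws plus the design information needed downstream."""

    beta: np.ndarray            # (n_draws, K, S)
    gamma: np.ndarray           # (n_draws, Q, K)
    V: np.ndarray               # (n_draws, K, K)
    lambda_site: np.ndarray     # (n_draws, H1, S)
    lambda_spatial: np.ndarray  # (n_draws, H2, S)
    eta_site: np.ndarray        # (n_draws, J, H1)
    eta_spatial: np.ndarray     # (n_draws, J, H2)
    alpha: np.ndarray           # (n_draws, H2), degrees
    chain: np.ndarray           # (n_draws,) chain index of each draw
    X: np.ndarray               # (J, K) training design
    Y: np.ndarray               # (J, S) training occurrences
    covariate_names: list = field(default_factory=list)
    species_ids: list = field(default_factory=list)
    trait_names: list = field(default_factory=list)
    site_ids: list = field(default_factory=list)
    guild: pd.Series | None = None
    alpha_grid: np.ndarray | None = None
    seed: int = 0

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain.max()) + 1 if self.n_draws else 0

    def save(self, directory) -> None:
        """Archive the posterior: flat ``.npy`` arrays plus a JSON manifest
        (dimensions, identifiers, seed)."""
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        arrays = ("beta", "gamma", "V", "lambda_site", "lambda_spatial",
                  "eta_site", "eta_spatial", "alpha", "chain", "X", "Y")
        for name in arrays:
            np.save(d / f"{name}.npy", getattr(self, name))
        manifest = {
            "covariate_names": list(self.covariate_names),
            "species_ids": list(self.species_ids),
            "trait_names": list(self.trait_names),
            "site_ids": list(self.site_ids),
            "guild": self.guild.to_dict() if self.guild is not None else None,
            "alpha_grid": self.alpha_grid.tolist() if self.alpha_grid is not None else None,
            "seed": int(self.seed),
            "n_draws": int(self.n_draws),
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "JSDMPosterior":
        import json
        from pathlib import Path

        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        arrays = {name: np.load(d / f"{name}.npy")
                  for name in ("beta", "gamma", "V", "lambda_site", "lambda_spatial",
                               "eta_site", "eta_spatial", "alpha", "chain", "X", "Y")}
        guild = manifest["guild"]
        return cls(
            **arrays,
            covariate_names=manifest["covariate_names"],
            species_ids=manifest["species_ids"],
            trait_names=manifest["trait_names"],
            site_ids=manifest["site_ids"],
            guild=pd.Series(guild) if guild else None,
            alpha_grid=np.asarray(manifest["alpha_grid"]) if manifest["alpha_grid"] else None,
            seed=manifest["seed"],
        )

    def fitted_probabilities(self) -> np.ndarray:
        """Posterior-mean occurrence probabilities at the training sites,
        conditional on the estimated factors (probabilities, not liabilities,
        are averaged over draws)."""
        p = np.zeros(self.Y.shape)
        for s in range(self.n_draws):
            m = self.X @ self.beta[s]
            if self.eta_site.shape[2]:
                m += self.eta_site[s] @ self.lambda_site[s]
            if self.eta_spatial.shape[2]:
                m += self.eta_spatial[s] @ self.lambda_spatial[s]
            p += ndtr(m)
        return p / self.n_draws


def build_trait_design(traits: TraitTable, log_continuous: bool = True) -> pd.DataFrame:
    """Species x Q trait design: intercept, z-scored (log) continuous traits,
    and dummy-coded categorical traits (first level as reference)."""
    parts = [pd.Series(1.0, index=traits.species_ids, name="intercept")]
    for col in traits.continuous.columns:
        v = traits.continuous[col].astype(float)
        if log_continuous:
            if (v <= 0).any():
                raise ValidationError(f"non-positive values in continuous trait {col!r}")
            v = np.log(v)
        sd = v.std(ddof=1)
        parts.append(((v - v.mean()) / (sd if sd > 0 else 1.0)).rename(col))
    for col in traits.categorical.columns:
        dummies = pd.get_dummies(traits.categorical[col], prefix=col, drop_first=True)
        parts.append(dummies.astype(float))
    return pd.concat(parts, axis=1)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _spatial_grid(coords: np.ndarray, grid_size: int):
    """Inverse correlation matrices and log-determinants for a discrete grid
    of spatial ranges, 0 to the maximum pairwise distance (degrees)."""
    d = squareform(pdist(coords))
    dmax = d.max()
    grid = np.linspace(0.0, dmax if dmax > 0 else 1.0, grid_size)
    J = coords.shape[0]
    inv = np.empty((grid_size, J, J))
    logdet = np.empty(grid_size)
    inv[0] = np.eye(J)
    logdet[0] = 0.0
    for g in range(1, grid_size):
        C = np.exp(-d / grid[g]) + 1e-8 * np.eye(J)
        L = cholesky(C, lower=True)
        logdet[g] = 2.0 * np.log(np.diag(L)).sum()
        inv[g] = cho_solve((L, True), np.eye(J))
    return grid, inv, logdet


def _mgps_delta_update(L: np.ndarray, delta: np.ndarray, a1: float, a2: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Multiplicative-gamma shrinkage update for one loading block (H x S)."""
    H, S = L.shape
    lam2 = (L ** 2).sum(axis=1)
    for l in range(H):
        tau = np.cumprod(delta)
        tau_minus = tau[l:] / delta[l]
        shape = (a1 if l == 0 else a2) + 0.5 * S * (H - l)
        rate = 1.0 + 0.5 * (tau_minus * lam2[l:]).sum()
        delta[l] = rng.gamma(shape, 1.0 / rate)
    return delta


def _run_chain(Y, X, Tmat, spatial, settings, mcmc_iters, record_from, thin, rng,
               likelihood=True, fixed_gamma=None, fixed_v=None):
    """One Gibbs chain; yields a dict of recorded draws."""
    J, S = Y.shape
    K = X.shape[1]
    Q = Tmat.shape[1]
    H1 = settings["n_factors_site"]
    H2 = settings["n_factors_spatial"]
    gamma_var = settings["gamma_prior_var"]
    a1, a2 = settings["shrink_a1"], settings["shrink_a2"]
    nu0 = K + 2                       # prior mean of V is the identity

    grid, Cinv, Clogdet = spatial if H2 else (None, None, None)

    XtX = X.T @ X
    B = np.zeros((K, S))
    G = np.zeros((K, Q)) if fixed_gamma is None else np.asarray(fixed_gamma, float).T.copy()
    V = np.eye(K) if fixed_v is None else np.asarray(fixed_v, float).copy()
    Vinv = np.linalg.inv(V)
    L1 = 0.1 * rng.standard_normal((H1, S)) if H1 else np.zeros((0, S))
    L2 = 0.1 * rng.standard_normal((H2, S)) if H2 else np.zeros((0, S))
    E1 = np.zeros((J, H1))
    E2 = np.zeros((J, H2))
    delta1 = np.ones(H1)
    delta2 = np.ones(H2)
    alpha_idx = np.zeros(H2, dtype=int)
    z = np.where(Y == 1, 0.7, -0.7).astype(float)

    records = []
    for it in range(mcmc_iters):
        # -- liabilities -------------------------------------------------
        M = X @ B
        if H1:
            M += E1 @ L1
        if H2:
            M += E2 @ L2
        if likelihood:
            u = rng.uniform(size=(J, S))
            p0 = ndtr(-M)
            q = np.where(Y == 1, p0 + u * (1.0 - p0), u * p0)
            z = M + ndtri(np.clip(q, _TINY, 1.0 - _TINY))
        else:
            z = M + rng.standard_normal((J, S))
        if not np.isfinite(z).all():
            raise FloatingPointError(
                f"non-finite liability at iteration {it}; "
                f"|B|max={np.abs(B).max():.3g}, |M|max={np.abs(M).max():.3g}"
            )

        # -- species coefficients beta ----------------------------------
        Rz = z - (E1 @ L1 if H1 else 0.0) - (E2 @ L2 if H2 else 0.0)
        A = Vinv + XtX
        cA = cholesky(A, lower=True)
        mean_B = cho_solve((cA, True), X.T @ Rz + Vinv @ (G @ Tmat.T))
        B = mean_B + solve_triangular(cA.T, rng.standard_normal((K, S)), lower=False)

        # -- trait effects Gamma and niche covariance V ------------------
        if fixed_gamma is None:
            P = np.kron(Tmat.T @ Tmat, Vinv) + np.eye(K * Q) / gamma_var
            rhs = (Vinv @ B @ Tmat).flatten(order="F")
            cP = cholesky(P, lower=True)
            mean_g = cho_solve((cP, True), rhs)
            gvec = mean_g + solve_triangular(cP.T, rng.standard_normal(K * Q), lower=False)
            G = gvec.reshape(K, Q, order="F")
        if fixed_v is None:
            E = B - G @ Tmat.T
            scale = np.eye(K) + E @ E.T
            V = invwishart.rvs(df=nu0 + S, scale=scale, random_state=rng)
            V = np.atleast_2d(V)
            Vinv = np.linalg.inv(V)

        # -- factor loadings with shrinkage ------------------------------
        H = H1 + H2
        if H:
            F = np.hstack([E1, E2])
            tau = np.concatenate([np.cumprod(delta1), np.cumprod(delta2)])
            P = np.diag(tau) + F.T @ F
            cP = cholesky(P, lower=True)
            resid = z - X @ B
            mean_L = cho_solve((cP, True), F.T @ resid)
            L = mean_L + solve_triangular(cP.T, rng.standard_normal((H, S)), lower=False)
            L1, L2 = L[:H1], L[H1:]
            if H1:
                delta1 = _mgps_delta_update(L1, delta1, a1, a2, rng)
            if H2:
                delta2 = _mgps_delta_update(L2, delta2, a1, a2, rng)

        # -- site-level factors ------------------------------------------
        if H1:
            R1 = z - X @ B - (E2 @ L2 if H2 else 0.0)
            P1 = np.eye(H1) + L1 @ L1.T
            c1 = cholesky(P1, lower=True)
            mean_E1 = cho_solve((c1, True), L1 @ R1.T)
            E1 = (mean_E1 + solve_triangular(
                c1.T, rng.standard_normal((H1, J)), lower=False)).T

        # -- spatial factors and their ranges ----------------------------
        if H2:
            R2 = z - X @ B - (E1 @ L1 if H1 else 0.0)
            total = E2 @ L2
            for h in range(H2):
                resid_h = R2 - total + np.outer(E2[:, h], L2[h])
                lin = resid_h @ L2[h]
                c = (L2[h] ** 2).sum()
                P = Cinv[alpha_idx[h]] + c * np.eye(J)
                cF = cholesky(P, lower=True)
                mean_h = cho_solve((cF, True), lin)
                eta = mean_h + solve_triangular(cF.T, rng.standard_normal(J), lower=False)
                total += np.outer(eta - E2[:, h], L2[h])
                E2[:, h] = eta
                # discrete conditional posterior over the range grid
                quad = (Cinv.reshape(-1, J) @ eta).reshape(len(grid), J) @ eta
                logp = -0.5 * quad - 0.5 * Clogdet
                logp -= logp.max()
                p = np.exp(logp)
                alpha_idx[h] = rng.choice(len(grid), p=p / p.sum())

        if it >= record_from and (it - record_from) % thin == 0:
            records.append({
                "beta": B.copy(), "gamma": G.T.copy(), "V": V.copy(),
                "lambda_site": L1.copy(), "lambda_spatial": L2.copy(),
                "eta_site": E1.copy(), "eta_spatial": E2.copy(),
                "alpha": grid[alpha_idx].copy() if H2 else np.zeros(0),
            })
    return records


class JointSpeciesModel(BaseEstimator):
    """Sklearn-style estimator wrapping the Gibbs sampler.

    Parameters
    ----------
    n_factors_site : number of non-spatial latent factors H1 (default 2).
    n_factors_spatial : number of spatial latent factors H2 (default 4);
        each carries its own range parameter ``alpha`` in degrees.
    thin, samples, n_chains, transient : MCMC schedule (defaults mirror a
        full-length run: thin 5, 1000 retained per chain, 2 chains,
        2500 transient; reduce for desk-scale work).
    gamma_prior_var : prior variance of each Gamma element (default 10).
    shrink_a1, shrink_a2 : multiplicative-gamma shrinkage hyperparameters
        for the factor loadings (default 5, 5).
    alpha_grid_size : number of candidate spatial ranges, equally spaced
        from 0 to the maximum pairwise site distance (default 101).
    log_continuous_traits : log-transform continuous traits before
        z-scoring in the trait design (default True).
    likelihood : set False to sample the prior (diagnostic mode: the data
        augmentation draws liabilities from the model instead of
        conditioning on Y).
    fixed_gamma, fixed_v : hold Gamma (Q x K) / V (K x K) fixed instead of
        sampling them (diagnostic mode).
    random_state : master seed; chain seeds are spawned from it.
    """

    def __init__(self, n_factors_site: int = 2, n_factors_spatial: int = 4,
                 thin: int = 5, samples: int = 1000, n_chains: int = 2,
                 transient: int = 2500, gamma_prior_var: float = 10.0,
                 shrink_a1: float = 5.0, shrink_a2: float = 5.0,
                 alpha_grid_size: int = 101, log_continuous_traits: bool = True,
                 likelihood: bool = True, fixed_gamma=None, fixed_v=None,
                 random_state: int | None = None):
        self.n_factors_site = n_factors_site
        self.n_factors_spatial = n_factors_spatial
        self.thin = thin
        self.samples = samples
        self.n_chains = n_chains
        self.transient = transient
        self.gamma_prior_var = gamma_prior_var
        self.shrink_a1 = shrink_a1
        self.shrink_a2 = shrink_a2
        self.alpha_grid_size = alpha_grid_size
        self.log_continuous_traits = log_continuous_traits
        self.likelihood = likelihood
        self.fixed_gamma = fixed_gamma
        self.fixed_v = fixed_v
        self.random_state = random_state

    def fit(self, env: EnvTable, community: CommunityTable,
            traits: TraitTable | None = None):
        Y = community.occurrence.to_numpy(dtype=float)
        col_sums = Y.sum(axis=0)
        degenerate = (col_sums == 0) | (col_sums == Y.shape[0])
        if degenerate.any():
            bad = community.species_ids[degenerate].tolist()
            raise ValidationError(
                f"species with constant occurrence (filter first): {bad}"
            )
        X = np.column_stack([np.ones(Y.shape[0]),
                             env.covariates.to_numpy(dtype=float)])
        cov_names = ["intercept"] + list(env.covariate_names)
        if traits is not None:
            tdesign = build_trait_design(traits.subset(community.species_ids),
                                         self.log_continuous_traits)
        else:
            tdesign = pd.DataFrame(
                {"intercept": np.ones(Y.shape[1])}, index=community.species_ids)
        Tmat = tdesign.to_numpy(dtype=float)

        spatial = None
        if self.n_factors_spatial:
            spatial = _spatial_grid(env.coords.to_numpy(dtype=float),
                                    self.alpha_grid_size)
        settings = {
            "n_factors_site": self.n_factors_site,
            "n_factors_spatial": self.n_factors_spatial,
            "gamma_prior_var": self.gamma_prior_var,
            "shrink_a1": self.shrink_a1,
            "shrink_a2": self.shrink_a2,
        }
        n_iter = self.transient + self.samples * self.thin
        seed = self.random_state if self.random_state is not None else 0
        chain_seeds = np.random.SeedSequence(seed).spawn(self.n_chains)

        all_records, chain_index = [], []
        for c in range(self.n_chains):
            rng = np.random.default_rng(chain_seeds[c])
            recs = _run_chain(Y, X, Tmat, spatial, settings, n_iter,
                              record_from=self.transient, thin=self.thin,
                              rng=rng, likelihood=self.likelihood,
                              fixed_gamma=self.fixed_gamma, fixed_v=self.fixed_v)
            all_records.extend(recs)
            chain_index.extend([c] * len(recs))

        stack = {k: np.stack([r[k] for r in all_records])
                 for k in all_records[0]}
        self.posterior_ = JSDMPosterior(
            beta=stack["beta"], gamma=stack["gamma"], V=stack["V"],
            lambda_site=stack["lambda_site"], lambda_spatial=stack["lambda_spatial"],
            eta_site=stack["eta_site"], eta_spatial=stack["eta_spatial"],
            alpha=stack["alpha"], chain=np.asarray(chain_index),
            X=X, Y=Y.astype(np.int8),
            covariate_names=cov_names,
            species_ids=list(community.species_ids),
            trait_names=list(tdesign.columns),
            site_ids=list(community.site_ids),
            guild=community.guild.copy(),
            alpha_grid=spatial[0] if spatial else None,
            seed=seed,
        )
        return self

    def predict_proba(self, env: EnvTable, mode: str = "conditional"):
        from .projection import predict_occurrence
        return predict_occurrence(self.posterior_, env, mode=mode)


def fit_jsdm(community: CommunityTable, env: EnvTable, traits: TraitTable | None,
             mcmc: MCMCConfig | None = None, **model_kw) -> JSDMPosterior:
    """Functional wrapper over :class:`JointSpeciesModel`."""
    mcmc = mcmc or MCMCConfig()
    model = JointSpeciesModel(
        thin=mcmc.thin, samples=mcmc.samples, n_chains=mcmc.n_chains,
        transient=mcmc.transient, random_state=mcmc.seed, **model_kw,
    ).fit(env, community, traits)
    return model.posterior_


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def split_psrf(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor.

    ``draws`` has shape (n_chains, n_per_chain, ...); each chain is split in
    half, and PSRF = sqrt(((n-1)/n W + B/n) / W) over the resulting
    half-chains, elementwise over trailing dimensions.
    """
    n_chains, n = draws.shape[0], draws.shape[1]
    half = n // 2
    halves = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    m, hn = halves.shape[0], halves.shape[1]
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean(axis=0)
    Bn = means.var(axis=0, ddof=1)            # B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (hn - 1) / hn * W + Bn
        psrf = np.sqrt(var_hat / W)
    return np.where(W > 0, psrf, 1.0)


def check_convergence(posterior: JSDMPosterior) -> dict:
    """Split-chain PSRF and effective sample size for beta and gamma."""
    if posterior.n_chains < 2:
        warnings.warn("single chain: PSRF unavailable")
        return {"psrf": None, "ess": None}
    out = {}
    for name in ("beta", "gamma"):
        arr = getattr(posterior, name)
        per_chain = [arr[posterior.chain == c] for c in range(posterior.n_chains)]
        n = min(a.shape[0] for a in per_chain)
        stacked = np.stack([a[:n] for a in per_chain])     # (chains, n, ...)
        psrf = split_psrf(stacked)
        try:
            import arviz as az
            ess = np.asarray(az.ess(az.convert_to_dataset(stacked)).to_array())[0]
        except Exception:       # pragma: no cover - arviz optional at runtime
            ess = np.full(psrf.shape, np.nan)
        out[name] = {
            "psrf": psrf,
            "psrf_max": float(np.nanmax(psrf)),
            "psrf_median": float(np.nanmedian(psrf)),
            "ess_min": float(np.nanmin(ess)),
        }
    out["psrf_max"] = max(out["beta"]["psrf_max"], out["gamma"]["psrf_max"])
    return out


def tjur_r2(y, p) -> float:
    """Tjur's coefficient of discrimination:
    mean predicted probability at presences minus at absences."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValidationError("y and p must have equal length")
    if y.min() == y.max():
        raise ValidationError("Tjur R2 undefined for constant response")
    return float(p[y == 1].mean() - p[y == 0].mean())


@dataclass
class SignSupportMatrix:
    posterior_mean: pd.DataFrame
    support: pd.DataFrame           # max(P(>0), P(<0)) per element
    mask: pd.DataFrame              # support > threshold
    threshold: float

    @property
    def masked_mean(self) -> pd.DataFrame:
        return self.posterior_mean.where(self.mask)


def _sign_support(samples: np.ndarray):
    p_pos = (samples > 0).mean(axis=0)
    p_neg = (samples < 0).mean(axis=0)
    return samples.mean(axis=0), np.maximum(p_pos, p_neg)


def support_filter(posterior: JSDMPosterior, parameter: str = "beta",
                   threshold: float = 0.90) -> SignSupportMatrix:
    """Posterior-mean matrix masked at a sign-support threshold.

    Support is the posterior probability that the element shares the sign
    of its mean, ``max(P(>0), P(<0))`` over retained draws; heatmap exports
    keep elements whose support exceeds the threshold (0.90 for beta and
    gamma, 0.95 for residual associations by convention).
    """
    if not 0.5 < threshold < 1.0:
        raise ValidationError("support threshold must lie in (0.5, 1)")
    if parameter == "beta":
        samples = posterior.beta                      # (n, K, S)
        index, columns = posterior.covariate_names, posterior.species_ids
    elif parameter == "gamma":
        samples = posterior.gamma                     # (n, Q, K)
        index, columns = posterior.trait_names, posterior.covariate_names
    else:
        raise ValidationError("parameter must be 'beta' or 'gamma'")
    if samples.shape[0] == 0:
        raise ValidationError("empty posterior")
    mean, support = _sign_support(samples)
    mean = pd.DataFrame(mean, index=index, columns=columns)
    support = pd.DataFrame(support, index=index, columns=columns)
    return SignSupportMatrix(mean, support, support > threshold, threshold)


def residual_associations(posterior: JSDMPosterior, threshold: float = 0.95):
    """Residual species-species correlations from the latent factors.

    Per draw the residual covariance is ``Omega = Lambda' Lambda + I`` (the
    identity is the probit noise), converted to a correlation matrix; the
    per-pair sign support is then filtered at ``threshold``.  Returns the
    mean correlation matrix, a :class:`SignSupportMatrix`, and a per-guild-
    pairing summary of positive/negative retained percentages.
    """
    n, S = posterior.beta.shape[0], posterior.beta.shape[2]
    H = posterior.lambda_site.shape[1] + posterior.lambda_spatial.shape[1]
    if H == 0:
        warnings.warn("model has no latent factors; associations are identity")
        corr_samples = np.broadcast_to(np.eye(S), (n, S, S)).copy()
    else:
        corr_samples = np.empty((n, S, S))
        for s in range(n):
            lam = np.vstack([posterior.lambda_site[s], posterior.lambda_spatial[s]])
            omega = lam.T @ lam + np.eye(S)
            d = np.sqrt(np.diag(omega))
            corr_samples[s] = omega / np.outer(d, d)
    mean, support = _sign_support(corr_samples)
    np.fill_diagonal(support, 1.0)
    sp = posterior.species_ids
    mean_df = pd.DataFrame(mean, index=sp, columns=sp)
    support_df = pd.DataFrame(support, index=sp, columns=sp)
    mask = (support_df > threshold) & ~np.eye(S, dtype=bool)
    ssm = SignSupportMatrix(mean_df, support_df, mask, threshold)

    summary = {}
    if posterior.guild is not None:
        g = posterior.guild.reindex(sp).to_numpy()
        iu = np.triu_indices(S, k=1)
        pair_guilds = np.stack([g[iu[0]], g[iu[1]]])
        kinds = {"fish-fish": ("fish", "fish"),
                 "fish-zooplankton": ("fish", "zooplankton"),
                 "zooplankton-zooplankton": ("zooplankton", "zooplankton")}
        retained = mask.to_numpy()[iu]
        signs = np.sign(mean[iu])
        for label, (ga, gb) in kinds.items():
            sel = (((pair_guilds[0] == ga) & (pair_guilds[1] == gb)) |
                   ((pair_guilds[0] == gb) & (pair_guilds[1] == ga)))
            total = int(sel.sum())
            pos = int((retained & sel & (signs > 0)).sum())
            neg = int((retained & sel & (signs < 0)).sum())
            summary[label] = {
                "n_pairs": total,
                "pct_positive": 100.0 * pos / total if total else 0.0,
                "pct_negative": 100.0 * neg / total if total else 0.0,
            }
    return mean_df, ssm, summary


@dataclass
class VariancePartition:
    fractions: pd.DataFrame       # species x group, raw, sums to 1
    adjusted: pd.DataFrame        # fractions x Tjur R2, sums to Tjur R2
    tjur: pd.Series
    groups: list


def variance_partitioning(posterior: JSDMPosterior,
                          groups: dict | None = None) -> VariancePartition:
    """Partition each species' explained variance over covariate groups and
    random-effect levels, then rescale by the species' Tjur R2.

    Per draw and species, the contribution of fixed-effect group ``g`` is
    ``sum_{k in g} sum_{k'} cov(X)_{kk'} beta_k beta_k'`` (covariance terms
    split evenly between the two groups involved; the rare negative split
    is clipped at zero); random-effect contributions are ``sum_h
    lambda_hj^2`` per factor block.  Fractions are normalised per draw,
    averaged, and finally multiplied by the species' Tjur R2 so they sum to
    the absolute explanatory power.  The intercept's (zero) variance is kept
    in its own pooled group and excluded from named covariate fractions.
    """
    names = posterior.covariate_names
    if groups is None:
        groups = {c: c for c in names if c != "intercept"}
    for c in groups:
        if c not in names:
            raise ValidationError(f"unknown covariate in grouping: {c!r}")
    group_names = list(dict.fromkeys(groups.values()))
    if not group_names:
        raise ValidationError("empty covariate grouping")
    re_names = []
    if posterior.lambda_site.shape[1]:
        re_names.append("random: site")
    if posterior.lambda_spatial.shape[1]:
        re_names.append("random: spatial")
    all_names = group_names + re_names

    X = posterior.X
    cM = np.cov(X, rowvar=False, ddof=1)
    cM = np.atleast_2d(cM)
    k_index = {c: i for i, c in enumerate(names)}
    group_rows = {g: [k_index[c] for c, gg in groups.items() if gg == g]
                  for g in group_names}

    n, K, S = posterior.beta.shape
    frac_sum = np.zeros((S, len(all_names)))
    for s in range(n):
        B = posterior.beta[s]
        contrib = np.empty((len(all_names), S))
        full = cM @ B                       # (K, S)
        for gi, g in enumerate(group_names):
            rows = group_rows[g]
            contrib[gi] = (B[rows] * full[rows]).sum(axis=0)
        ri = len(group_names)
        if posterior.lambda_site.shape[1]:
            contrib[ri] = (posterior.lambda_site[s] ** 2).sum(axis=0)
            ri += 1
        if posterior.lambda_spatial.shape[1]:
            contrib[ri] = (posterior.lambda_spatial[s] ** 2).sum(axis=0)
        contrib = np.clip(contrib, 0.0, None)
        totals = contrib.sum(axis=0)
        totals[totals == 0] = 1.0
        frac_sum += (contrib / totals).T
    fractions = pd.DataFrame(frac_sum / n, index=posterior.species_ids,
                             columns=all_names)

    fitted = posterior.fitted_probabilities()
    tjur = pd.Series(
        [tjur_r2(posterior.Y[:, j], fitted[:, j]) for j in range(S)],
        index=posterior.species_ids, name="tjur_r2",
    )
    adjusted = fractions.mul(tjur, axis=0)
    return VariancePartition(fractions, adjusted, tjur, all_names)
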
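"""Posterior-predictive occurrence probabilities under climate scenarios.

A scenario table replaces the climate-class covariates of the baseline
environment (2081-2100 projections under an SSP forcing, say) while
morphometry stays fixed; the replacement columns are standardised with the
*baseline* transform parameters so both designs share one scale.  Occurrence
probabilities are then averaged over posterior draws — probabilities, not
liabilities, so the posterior-predictive mean is exact for the probit link.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .data_io import EnvPreprocessor, EnvTable, ValidationError
from .jsdm import JSDMPosterior


@dataclass
class ProbabilityMatrix:
    """Sites x species mean posterior-predictive occurrence probabilities."""

    prob: pd.DataFrame
    scenario: str

    def __post_init__(self) -> None:
        v = self.prob.to_numpy()
        if (v < -1e-9).any() or (v > 1 + 1e-9).any():
            raise ValidationError("occurrence probabilities outside [0, 1]")

    @property
    def site_ids(self) -> pd.Index:
        return self.prob.index

    @property
    def species_ids(self) -> pd.Index:
        return self.prob.columns

    def to_csv(self, path) -> None:
        out = self.prob.copy()
        out.index.name = "site_id"
        out.to_csv(path)


def build_scenario_env(baseline: EnvTable, scenario_climate: pd.DataFrame,
                       scenario_name: str, preprocessor: EnvPreprocessor | None = None,
                       raw_baseline: EnvTable | None = None) -> EnvTable:
    """Replace climate covariates of the baseline with scenario values.

    ``scenario_climate`` holds raw (unstandardised) per-site replacement
    values for a subset of the climate-class covariates.  When a fitted
    ``preprocessor`` is given, ``raw_baseline`` must be the untransformed
    baseline table; the scenario copy of it is pushed through the *fitted*
    transformer, so baseline standardisation parameters are reused, never
    refitted.  Without a preprocessor the replacement happens directly on
    ``baseline`` (already-standardised inputs).
    """
    climate = set(baseline.climate_covariates())
    non_climate = set(scenario_climate.columns) - climate
    if non_climate:
        raise ValidationError(
            f"scenario may only replace climate covariates; got {sorted(non_climate)}"
        )
    target = raw_baseline if preprocessor is not None else baseline
    cov = target.covariates.copy()
    for col in scenario_climate.columns:
        cov[col] = scenario_climate[col].reindex(cov.index)
    shifted = EnvTable(cov, target.covariate_class, target.coords, "custom")
    if preprocessor is not None:
        shifted = preprocessor.transform(shifted)
    return shifted.with_scenario(scenario_name)


def predict_occurrence(posterior: JSDMPosterior, env: EnvTable,
                       mode: str = "conditional") -> ProbabilityMatrix:
    """Mean posterior-predictive occurrence probabilities.

    ``conditional`` (default) reuses the training-site latent factor
    estimates — the natural prediction at the fitted lakes;
    ``marginal`` integrates the factors over their prior, giving
    ``Phi(x'beta / sqrt(1 + sum_h lambda_hj^2))`` per draw, valid for new
    sites.
    """
    fitted_cov = [c for c in posterior.covariate_names if c != "intercept"]
    missing = [c for c in fitted_cov if c not in env.covariate_names]
    if missing:
        raise ValidationError(f"scenario table lacks fitted covariates: {missing}")
    X = np.column_stack([np.ones(len(env.site_ids)),
                         env.covariates[fitted_cov].to_numpy(dtype=float)])
    n = posterior.n_draws
    J, S = X.shape[0], posterior.beta.shape[2]
    H1 = posterior.lambda_site.shape[1]
    H2 = posterior.lambda_spatial.shape[1]

    if mode == "conditional":
        site_index = {sid: i for i, sid in enumerate(posterior.site_ids)}
        unseen = [s for s in env.site_ids if s not in site_index]
        if unseen:
            raise ValidationError(
                f"conditional prediction needs training sites; unseen: {unseen}"
            )
        rows = np.array([site_index[s] for s in env.site_ids])
    elif mode != "marginal":
        raise ValidationError("mode must be 'conditional' or 'marginal'")

    p = np.zeros((J, S))
    for s in range(n):
        m = X @ posterior.beta[s]
        if mode == "conditional":
            if H1:
                m += posterior.eta_site[s][rows] @ posterior.lambda_site[s]
            if H2:
                m += posterior.eta_spatial[s][rows] @ posterior.lambda_spatial[s]
            p += ndtr(m)
        else:
            var = np.zeros(S)
            if H1:
                var += (posterior.lambda_site[s] ** 2).sum(axis=0)
            if H2:
                var += (posterior.lambda_spatial[s] ** 2).sum(axis=0)
            p += ndtr(m / np.sqrt(1.0 + var))
    prob = pd.DataFrame(p / n, index=env.site_ids, columns=posterior.species_ids)
    return ProbabilityMatrix(prob, env.scenario)
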
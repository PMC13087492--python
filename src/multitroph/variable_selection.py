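"""Environmental variable screening with multi-species random forests.

One classification forest is fitted per species (binary occurrence as the
response, all covariates as predictors).  For each species the out-of-bag
(OOB) misclassification error and the classic OOB permutation importance
are recorded; the global importance of a covariate is the across-species
average weighted by each species' predictive skill,

    global_v = sum_s w_s I_{s,v} / sum_s w_s,   w_s = max(0, 1 - oob_error_s),

so poorly predictable species contribute little to the ranking.  The top-k
covariates by global importance (minus an exclusion list, e.g. raw
coordinates destined for a spatial random effect) form the fixed-effect
design of the downstream joint species distribution model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier

from .data_io import CommunityTable, EnvTable, ValidationError

logger = logging.getLogger("multitroph")


@dataclass
class ImportanceTable:
    covariate_names: list
    importance: pd.DataFrame        # species x covariate OOB permutation importance
    oob_error: pd.Series            # per-species OOB misclassification rate
    global_importance: pd.Series    # error-weighted mean over species
    ranking: list                   # covariates, most important first


def _oob_permutation_importance(forest: RandomForestClassifier, X: np.ndarray,
                                y: np.ndarray, rng: np.random.Generator):
    """Breiman-style OOB permutation importance and OOB error for one forest.

    For every tree, accuracy on its out-of-bag rows is compared with
    accuracy after permuting one covariate among those rows; the importance
    of the covariate is the mean accuracy drop across trees.
    """
    n, k = X.shape
    importance = np.zeros(k)
    oob_votes = np.zeros((n, 2))
    n_trees_used = 0
    for tree, sampled in zip(forest.estimators_, forest.estimators_samples_):
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[sampled] = False
        idx = np.flatnonzero(oob_mask)
        if idx.size == 0:
            continue
        n_trees_used += 1
        Xo, yo = X[idx], y[idx]
        pred = tree.predict(Xo)
        base_acc = (pred == yo).mean()
        oob_votes[idx, pred.astype(int)] += 1
        for v in range(k):
            Xp = Xo.copy()
            Xp[:, v] = Xo[rng.permutation(idx.size), v]
            acc = (tree.predict(Xp) == yo).mean()
            importance[v] += base_acc - acc
    if n_trees_used == 0:
        raise ValidationError("no out-of-bag rows; increase the number of sites")
    importance /= n_trees_used
    voted = oob_votes.sum(axis=1) > 0
    oob_pred = oob_votes[voted].argmax(axis=1)
    oob_error = float((oob_pred != y[voted]).mean())
    return importance, oob_error


class ForestVariableSelector(BaseEstimator):
    """Rank covariates by error-weighted OOB permutation importance.

    Parameters
    ----------
    n_trees : trees per per-species forest (default 100).
    top_k : number of covariates to retain (default 10).
    exclude : covariates removed from the retained set after ranking
        (they still compete for ranks), e.g. ``["longitude", "latitude"]``
        when coordinates enter the downstream model as a spatial random
        effect instead of fixed terms.
    weighting : "skill" (default, ``w_s = max(0, 1 - oob_error)``) or
        "error" (``w_s = oob_error``).
    random_state : seed for bootstrap and permutation randomness.

    Attributes
    ----------
    importance_table_ : :class:`ImportanceTable`
    selected_ : list of retained covariate names, importance order.
    """

    def __init__(self, n_trees: int = 100, top_k: int = 10, exclude: list | None = None,
                 weighting: str = "skill", random_state: int | None = None):
        self.n_trees = n_trees
        self.top_k = top_k
        self.exclude = exclude
        self.weighting = weighting
        self.random_state = random_state

    def fit(self, env: EnvTable, community: CommunityTable):
        import zlib

        X = env.covariates.to_numpy(dtype=float)
        names = list(env.covariate_names)
        master = self.random_state if self.random_state is not None else 0

        rows, errors, fitted_species = [], [], []
        for sp in community.species_ids:
            y = community.occurrence[sp].to_numpy()
            if y.min() == y.max():
                warnings.warn(f"species {sp!r} has constant occurrence; skipped")
                continue
            # one stream per species, keyed by id: importances do not depend
            # on the order species appear in the table
            rng = np.random.default_rng(
                np.random.SeedSequence([master, zlib.crc32(str(sp).encode())]))
            forest = RandomForestClassifier(
                n_estimators=self.n_trees, bootstrap=True,
                random_state=int(rng.integers(2 ** 31 - 1)),
            ).fit(X, y)
            imp, err = _oob_permutation_importance(forest, X, y, rng)
            rows.append(imp)
            errors.append(err)
            fitted_species.append(sp)
        if not rows:
            raise ValidationError("no species with variable occurrence to fit")

        imp = pd.DataFrame(rows, index=fitted_species, columns=names)
        err = pd.Series(errors, index=fitted_species, name="oob_error")
        if self.weighting == "skill":
            w = np.maximum(0.0, 1.0 - err.to_numpy())
        elif self.weighting == "error":
            w = err.to_numpy().copy()
        else:
            raise ValidationError("weighting must be 'skill' or 'error'")
        if w.sum() <= 0:
            w = np.ones_like(w)
        global_imp = pd.Series(
            (imp.to_numpy() * w[:, None]).sum(axis=0) / w.sum(),
            index=names, name="global_importance",
        )
        ranking = list(global_imp.sort_values(ascending=False, kind="stable").index)
        self.importance_table_ = ImportanceTable(
            covariate_names=names, importance=imp, oob_error=err,
            global_importance=global_imp, ranking=ranking,
        )
        self.selected_ = select_top_k(self.importance_table_, k=self.top_k,
                                      exclude=self.exclude or [])
        return self

    def get_support(self) -> list:
        return list(self.selected_)

    def transform(self, env: EnvTable) -> EnvTable:
        cov = env.covariates[self.selected_]
        return EnvTable(cov, env.covariate_class.loc[self.selected_],
                        env.coords, env.scenario)


def fit_species_forests(community: CommunityTable, env: EnvTable,
                        n_trees: int = 100, seed: int | None = None) -> ImportanceTable:
    """Functional wrapper over :class:`ForestVariableSelector` (fit only)."""
    sel = ForestVariableSelector(n_trees=n_trees, random_state=seed).fit(env, community)
    return sel.importance_table_


def select_top_k(importance: ImportanceTable, k: int = 10,
                 exclude: list | None = None) -> list:
    """Top-k covariates by global importance, then drop the exclusion list.

    Ranking order is preserved; excluded members (e.g. coordinates) are
    removed *after* taking the top k, matching a workflow where they are
    promoted to random effects rather than fixed terms.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    ranking = importance.ranking
    if k > len(ranking):
        warnings.warn(f"k={k} exceeds {len(ranking)} covariates; retaining all")
        k = len(ranking)
    top = ranking[:k]
    excl = set(exclude or [])
    return [c for c in top if c not in excl]
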
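"""Significance-filtered Spearman co-occurrence networks and their metrics.

For each unordered species pair, Spearman's rank correlation is computed
over sites from the posterior-predictive probability matrix; pairs with a
two-sided p-value below ``alpha`` (0.01 by default, uncorrected) become
signed edges.  Topology metrics (connectance, mean path length,
edge-betweenness communities, modularity) treat the graph as unweighted
and sign-agnostic; the correlation sign is kept as an edge attribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community
from scipy import stats

from .data_io import ValidationError
from .projection import ProbabilityMatrix


@dataclass
class Network:
    graph: nx.Graph                 # nodes: species (guild attr); edges: rho, p, sign
    scenario: str
    species_universe: list = field(default_factory=list)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"species_a": a, "species_b": b, "rho": d["rho"], "p": d["p"],
             "sign": d["sign"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["species_a", "species_b", "rho", "p", "sign"])

    def edge_set(self) -> set:
        return {frozenset((a, b)) for a, b in self.graph.edges()}

    def to_csv(self, path) -> None:
        self.edges.to_csv(path, index=False)


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    connectance: float
    mean_path_length: float | None
    n_communities: int | None
    modularity: float | None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def correlation_network(prob: ProbabilityMatrix, alpha: float = 0.01,
                        guild: pd.Series | None = None) -> Network:
    """Build the signed Spearman network from a probability matrix.

    Ties receive average ranks and the two-sided p-value uses the
    t-approximation with ``n - 2`` degrees of freedom.  Constant species
    columns have undefined correlations; their pairs are skipped.
    """
    mat = prob.prob
    n_sites, n_species = mat.shape
    if n_sites < 10 or n_species < 2:
        raise ValidationError("need at least 10 sites and 2 species")
    values = mat.to_numpy(dtype=float)
    constant = values.ptp(axis=0) == 0 if hasattr(values, "ptp") else np.ptp(values, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant probability columns skipped: {mat.columns[constant].tolist()}"
        )

    valid = np.flatnonzero(~constant)       # scipy degenerates on constant cols
    rho = np.full((n_species, n_species), np.nan)
    p = np.full((n_species, n_species), np.nan)
    if valid.size >= 2:
        r_v, p_v = stats.spearmanr(values[:, valid])
        if np.ndim(r_v) == 0:               # scalars for exactly two columns
            r_v = np.array([[1.0, r_v], [r_v, 1.0]])
            p_v = np.array([[0.0, p_v], [p_v, 0.0]])
        rho[np.ix_(valid, valid)] = r_v
        p[np.ix_(valid, valid)] = p_v

    g = nx.Graph()
    species = list(mat.columns)
    for sp in species:
        attrs = {}
        if guild is not None and sp in guild.index:
            attrs["guild"] = guild.loc[sp]
        g.add_node(sp, **attrs)
    iu = np.triu_indices(n_species, k=1)
    for i, j in zip(*iu):
        if constant[i] or constant[j]:
            continue
        if np.isfinite(p[i, j]) and p[i, j] < alpha:
            g.add_edge(species[i], species[j], rho=float(rho[i, j]),
                       p=float(p[i, j]), sign=int(np.sign(rho[i, j])))
    return Network(g, prob.scenario, species_universe=species)


def network_metrics(net: Network) -> NetworkMetrics:
    """Topology metrics on edge-incident species.

    Nodes are species with at least one retained edge (isolated species are
    not counted).  Mean path length averages unweighted shortest paths over
    reachable ordered pairs within components.  Communities come from the
    Girvan-Newman edge-betweenness dendrogram cut at the partition with
    maximum modularity (the trivial one-community partition, Q = 0, is a
    candidate); singleton components count as communities.
    """
    g = net.graph.edge_subgraph(net.graph.edges()).copy()
    n, m = g.number_of_nodes(), g.number_of_edges()
    if m == 0:
        return NetworkMetrics(0, 0, 0.0, None, None, None)
    connectance = m / (n * (n - 1) / 2)

    total, count = 0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            for target, dist in lengths.items():
                if dist > 0:
                    total += dist
                    count += 1
    mean_path = total / count if count else None

    components = [set(c) for c in nx.connected_components(g)]
    best_partition = components
    best_q = nx_community.modularity(g, components)
    if m > 1:
        for partition in nx_community.girvan_newman(g):
            parts = [set(c) for c in partition]
            q = nx_community.modularity(g, parts)
            if q > best_q + 1e-12:
                best_q = q
                best_partition = parts
    return NetworkMetrics(
        n_nodes=n, n_edges=m, connectance=float(connectance),
        mean_path_length=float(mean_path) if mean_path is not None else None,
        n_communities=len(best_partition), modularity=float(best_q),
    )


@dataclass
class EdgeChange:
    gained: list
    lost: list
    retained: list
    sign_flipped: list

    @property
    def counts(self) -> dict:
        return {"gained": len(self.gained), "lost": len(self.lost),
                "retained": len(self.retained), "sign_flipped": len(self.sign_flipped)}


def compare_networks(reference: Network, other: Network) -> EdgeChange:
    """Edge gains/losses/retentions of ``other`` relative to ``reference``."""
    if set(reference.species_universe) != set(other.species_universe):
        raise ValidationError("networks must share the same species universe")
    ref_edges = reference.edge_set()
    oth_edges = other.edge_set()
    gained = sorted(tuple(sorted(e)) for e in oth_edges - ref_edges)
    lost = sorted(tuple(sorted(e)) for e in ref_edges - oth_edges)
    retained = sorted(tuple(sorted(e)) for e in ref_edges & oth_edges)
    flipped = [
        (a, b) for a, b in retained
        if reference.graph.edges[a, b]["sign"] != other.graph.edges[a, b]["sign"]
    ]
    return EdgeChange(gained, lost, retained, flipped)
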
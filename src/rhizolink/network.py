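"""Sparse co-occurrence networks and module detection.

Filtered, CLR-transformed abundances are fed to the graphical lasso over
a log-spaced penalty path; the penalty is selected by subsample
stability (StARS: the smallest penalty whose monotonized edge-selection
instability stays below a threshold).  Nonzero off-diagonal precision
entries define edges; edge weights are the correlations implied by the
estimated covariance.  Modules are Louvain communities of the
positive-edge graph; isolated vertices become singleton modules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

log = logging.getLogger(__name__)


def network_filter(counts: pd.DataFrame, min_samples: int = 4,
                   min_mean_rel_abund: float = 0.005) -> list[str]:
    """Features detected in >= min_samples samples with mean relative
    abundance > min_mean_rel_abund within the group."""
    if counts.empty:
        raise ValueError("empty sample group")
    present = (counts > 0).sum(axis=0)
    rel = counts.div(counts.sum(axis=1), axis=0).mean(axis=0)
    keep = [
        f for f in counts.columns
        if present[f] >= min_samples and rel[f] > min_mean_rel_abund
    ]
    if not keep:
        raise ValueError("no features pass the network filter")
    return keep


def clr(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Plain CLR over all columns (used for network inference)."""
    logs = np.log(counts.to_numpy(dtype=float) + pseudocount)
    return pd.DataFrame(
        logs - logs.mean(axis=1, keepdims=True), index=counts.index, columns=counts.columns
    )


def covariance_to_correlation(cov) -> np.ndarray:
    """cov2cor: corr(i,j) = cov(i,j) / sqrt(cov(i,i) cov(j,j))."""
    cov = np.asarray(cov, dtype=float)
    d = np.diag(cov)
    if (d <= 0).any():
        raise ValueError("covariance diagonal must be positive")
    s = np.sqrt(d)
    return cov / np.outer(s, s)


@dataclass
class StarsConfig:
    subsample_ratio: float = 0.8
    n_subsamples: int = 50
    instability_threshold: float = 0.05


@dataclass
class Network:
    graph: nx.Graph
    sample_group: str
    lambda_selected: float
    lambda_path: np.ndarray
    instability: np.ndarray
    precision: pd.DataFrame
    covariance: pd.DataFrame
    modules: dict | None = None

    @property
    def features(self) -> list:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": min(i, j), "target": max(i, j), "weight": d["weight"]}
            for i, j, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])


def _glasso_support(emp_cov: np.ndarray, alpha: float, max_iter: int = 200):
    """Graphical lasso with a small retry ladder on numerical failure."""
    for bump in (1.0, 1.5, 3.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cov, prec = graphical_lasso(emp_cov, alpha=alpha * bump, max_iter=max_iter)
            if bump > 1:
                log.info("glasso needed increased regularization (x%.1f)", bump)
            return cov, prec
        except (FloatingPointError, np.linalg.LinAlgError):
            continue
    raise np.linalg.LinAlgError("graphical lasso failed to converge")


def infer_network(
    counts_subset: pd.DataFrame,
    lambda_min_ratio: float = 0.01,
    n_lambda: int = 20,
    stability: StarsConfig | None = None,
    seed: int = 0,
    pseudocount: float = 0.5,
    sample_group: str = "",
) -> Network:
    """Sparse inverse-covariance network with StARS penalty selection."""
    n, p = counts_subset.shape
    if n < 10:
        raise ValueError("need at least 10 samples for network inference")
    if p < 3:
        raise ValueError("need at least 3 features")
    stability = stability or StarsConfig()
    X = clr(counts_subset, pseudocount).to_numpy()
    features = list(counts_subset.columns)

    emp = np.cov(X, rowvar=False)
    if np.linalg.matrix_rank(emp) == 0:
        raise ValueError("singular input")
    lam_max = np.abs(emp - np.diag(np.diag(emp))).max()
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    rng = np.random.default_rng(seed)
    b = max(10, int(stability.subsample_ratio * n))
    iu = np.triu_indices(p, 1)
    sub_covs = []
    for _ in range(stability.n_subsamples):
        idx = rng.choice(n, size=b, replace=False)
        sub_covs.append(np.cov(X[idx], rowvar=False))
    # walk the path from sparse to dense; the monotonized instability only
    # grows along the way, so the first crossing of the threshold fixes the
    # selection and the (expensive) dense tail need not be fitted
    instability = np.full(n_lambda, np.nan)
    best = 0
    for li, lam in enumerate(lambdas):
        freq = np.zeros(len(iu[0]))
        for sub_cov in sub_covs:
            try:
                # support estimation tolerates a loose iteration cap
                _, prec = _glasso_support(sub_cov, lam, max_iter=60)
            except np.linalg.LinAlgError:
                continue
            freq += (np.abs(prec[iu]) > 1e-8).astype(float)
        theta = freq / stability.n_subsamples
        instability[li] = (2 * theta * (1 - theta)).mean()
        if np.nanmax(instability[: li + 1]) > stability.instability_threshold:
            break
        best = li
    lam_star = float(lambdas[best])

    cov, prec = _glasso_support(emp, lam_star)
    corr = covariance_to_correlation(cov)

    graph = nx.Graph()
    rel = counts_subset.div(counts_subset.sum(axis=1), axis=0).mean(axis=0)
    for f in features:
        graph.add_node(f, mean_rel_abund=float(rel[f]))
    for a, bidx in zip(*iu):
        if abs(prec[a, bidx]) > 1e-8:
            graph.add_edge(features[a], features[bidx], weight=float(corr[a, bidx]))

    return Network(
        graph=graph,
        sample_group=sample_group,
        lambda_selected=lam_star,
        lambda_path=lambdas,
        instability=instability,
        precision=pd.DataFrame(prec, index=features, columns=features),
        covariance=pd.DataFrame(cov, index=features, columns=features),
    )


def detect_modules(network: Network | nx.Graph, seed: int = 0) -> dict:
    """Louvain modules of the positive-edge graph; singletons for isolates."""
    graph = network.graph if isinstance(network, Network) else network
    pos = nx.Graph()
    pos.add_nodes_from(graph.nodes)
    pos.add_weighted_edges_from(
        (u, v, d["weight"]) for u, v, d in graph.edges(data=True) if d["weight"] > 0
    )
    communities = nx.community.louvain_communities(pos, weight="weight", seed=seed)
    communities = sorted(communities, key=lambda c: (-len(c), sorted(c)[0]))
    labels = {}
    for m, nodes in enumerate(communities):
        for node in nodes:
            labels[node] = f"M{m + 1:03d}"
    if isinstance(network, Network):
        network.modules = labels
        nx.set_node_attributes(graph, labels, "module")
    return labels


@dataclass
class NetworkStats:
    n_vertices: int
    n_edges: int
    mean_degree: float
    mean_strength: float  # mean per-vertex sum of |incident weights|
    mean_strength_signed: float
    mean_weight: float
    n_modules: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def network_stats(network: Network | nx.Graph, modules: dict | None = None) -> NetworkStats:
    graph = network.graph if isinstance(network, Network) else network
    if modules is None:
        modules = network.modules if isinstance(network, Network) and network.modules else detect_modules(graph)
    V, E = graph.number_of_nodes(), graph.number_of_edges()
    if V == 0:
        log.warning("empty network")
        return NetworkStats(0, 0, 0.0, 0.0, 0.0, 0.0, 0)
    weights = [d["weight"] for _, _, d in graph.edges(data=True)]
    strength_abs = [
        sum(abs(d["weight"]) for _, _, d in graph.edges(v, data=True)) for v in graph.nodes
    ]
    strength_signed = [
        sum(d["weight"] for _, _, d in graph.edges(v, data=True)) for v in graph.nodes
    ]
    return NetworkStats(
        n_vertices=V,
        n_edges=E,
        mean_degree=2 * E / V,
        mean_strength=float(np.mean(strength_abs)),
        mean_strength_signed=float(np.mean(strength_signed)),
        mean_weight=float(np.mean(weights)) if weights else 0.0,
        n_modules=len(set(modules.values())),
    )


def subset_strong_edges(network: Network | nx.Graph, growth_associated_ids):
    """Quartile-thresholded subnetwork around growth-associated vertices.

    Quartiles come from the full network's weight distribution; edges are
    strong if weight > Q3 or < Q1.  The subnetwork keeps growth-associated
    vertices with at least one strong edge plus their strong neighbors,
    and every strong edge among the kept vertices.  Growth-associated
    vertices without strong edges are returned separately.
    """
    graph = network.graph if isinstance(network, Network) else network
    growth_ids = [g for g in growth_associated_ids if g in graph]
    weights = np.array([d["weight"] for _, _, d in graph.edges(data=True)])
    sub = nx.Graph()
    if len(growth_ids) == 0:
        log.warning("no growth-associated vertices present in the network")
        return sub, list(growth_associated_ids), (np.nan, np.nan)
    q1, q3 = (np.quantile(weights, [0.25, 0.75]) if weights.size else (np.nan, np.nan))
    strong = [
        (u, v, d["weight"])
        for u, v, d in graph.edges(data=True)
        if d["weight"] > q3 or d["weight"] < q1
    ]
    keep = set()
    for u, v, _ in strong:
        if u in set(growth_ids) or v in set(growth_ids):
            keep.update((u, v))
    sub.add_nodes_from((v, graph.nodes[v]) for v in keep)
    for u, v, w in strong:
        if u in keep and v in keep:
            sub.add_edge(u, v, weight=w)
    dropped = [g for g in growth_ids if g not in keep]
    return sub, dropped, (float(q1), float(q3))


def module_abundances(counts: pd.DataFrame, module_labels: dict) -> pd.DataFrame:
    """Per-sample module abundances: sums of member-feature counts."""
    by_module: dict[str, list] = {}
    seen = {}
    for feature, module in module_labels.items():
        if feature in seen:
            raise ValueError(f"feature {feature} mapped to two modules")
        seen[feature] = module
        if feature in counts.columns:
            by_module.setdefault(module, []).append(feature)
    cols = {m: counts[feats].sum(axis=1) for m, feats in sorted(by_module.items())}
    return pd.DataFrame(cols, index=counts.index)


def write_graphml(network: Network, path) -> None:
    nx.write_graphml(network.graph, path)
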
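"""Bootstrap partial-correlation networks over the 13 ADAS-Cog items.

Each cluster's neurocognitive network has the 13 test items as nodes and the
mean bootstrap partial correlation between item pairs as edge weights.  Per
bootstrap repetition a small subgroup (default 10 subjects) is drawn without
replacement and the partial-correlation matrix of its item scores is
estimated.  With 10 observations of 13 variables the sample covariance is
singular, so the estimator shrinks the correlation matrix toward the
identity (Ledoit-Wolf analytic intensity) before inversion; the precision
matrix Theta then gives partial correlations

    rho_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj).

A Moore-Penrose pseudo-inverse of the unshrunk covariance is available as an
alternative.  Global topology (diameter, density, average degree, average
clustering coefficient) is computed per repetition on the graph binarized at
|weight| >= tau, so every metric has a bootstrap distribution; cluster
networks are compared metric-wise by ANOVA + Tukey HSD over those
distributions.  (The bootstrap replicates are not independent samples; the
comparison inherits that pseudo-replication and its p-values are
descriptive, not strictly calibrated.)
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import LedoitWolf

from .phenotype_profiling import anova_tukey_continuous

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.05  #: |weight| threshold when binarizing for global metrics
METRIC_NAMES = ("diameter", "density", "average_degree", "average_clustering")


def adascog_item_info() -> dict:
    """Shipped ADAS-Cog item metadata: names, cognitive domains, score ranges."""
    text = resources.files("netstrat.data").joinpath("adascog_domains.json").read_text()
    return json.loads(text)["items"]


def adascog_items() -> list[str]:
    return list(adascog_item_info())


@dataclass
class CognitiveNetwork:
    """Mean bootstrap partial-correlation graph plus per-repetition metrics."""

    items: list[str]
    weights: np.ndarray  # items x items, symmetric, zero diagonal
    metric_distributions: dict[str, np.ndarray]  # one value per repetition
    degree_centrality: dict[str, float]  # bootstrap-averaged, normalized
    n_reps: int
    subset_n: int

    def to_dict(self) -> dict:
        return {
            "items": self.items,
            "weights": self.weights.tolist(),
            "metric_means": {
                k: float(np.nanmean(v)) for k, v in self.metric_distributions.items()
            },
            "degree_centrality": self.degree_centrality,
            "n_reps": self.n_reps,
            "subset_n": self.subset_n,
        }


def partial_correlations(
    X: np.ndarray, shrinkage: bool = True
) -> np.ndarray:
    """Partial-correlation matrix of the columns of X.

    ``shrinkage=True`` (default) regularizes via Ledoit-Wolf before
    inversion; otherwise a pseudo-inverse of the sample covariance is used.
    The result is symmetric with unit diagonal.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance column in draw")
    Z = (X - X.mean(axis=0)) / sd
    if shrinkage:
        lw = LedoitWolf(assume_centered=True).fit(Z)
        theta = lw.precision_
    else:
        theta = np.linalg.pinv(np.cov(Z, rowvar=False))
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return (rho + rho.T) / 2.0


def _graph_from_weights(weights: np.ndarray, items: list[str],
                        tau: float) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(items)
    n = len(items)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(weights[i, j]) >= tau:
                G.add_edge(items[i], items[j], weight=float(weights[i, j]))
    return G


def graph_global_metrics(G: nx.Graph) -> dict[str, float]:
    """Diameter, density, average degree, average clustering on one graph.

    The diameter of a disconnected graph is the maximum finite eccentricity
    over its connected components; an edgeless graph codes diameter as NaN
    and the other metrics as 0.
    """
    n = G.number_of_nodes()
    if G.number_of_edges() == 0:
        return {"diameter": np.nan, "density": 0.0,
                "average_degree": 0.0, "average_clustering": 0.0}
    diam = max(
        nx.diameter(G.subgraph(c))
        for c in nx.connected_components(G) if len(c) > 1
    )
    return {
        "diameter": float(diam),
        "density": float(nx.density(G)),
        "average_degree": float(2 * G.number_of_edges() / n),
        "average_clustering": float(nx.average_clustering(G)),
    }


def bootstrap_partial_correlations(
    subscores: pd.DataFrame,
    subset_n: int = 10,
    reps: int = 250,
    seed: int = 0,
    tau: float = DEFAULT_TAU,
    shrinkage: bool = True,
    with_replacement: bool = False,
    max_redraws: int = 20,
) -> CognitiveNetwork:
    """Build one cluster's cognitive network by bootstrap aggregation.

    Per repetition, ``subset_n`` subjects are drawn (without replacement by
    default), the partial-correlation matrix estimated, and the binarized
    graph's global metrics recorded.  Edge weights are the element-wise mean
    over repetitions; degree centrality is averaged over repetitions and
    normalized by (n_items - 1).  Draws hitting a zero-variance item are
    retried up to ``max_redraws`` times.
    """
    items = [c for c in subscores.columns if c != "subject_id"]
    X = subscores[items].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing item scores")
    n = X.shape[0]
    if not with_replacement and n < subset_n:
        raise ValueError(f"cluster has {n} subjects < subset_n={subset_n}")
    rng = np.random.default_rng(seed)
    p = len(items)
    weight_sum = np.zeros((p, p))
    centrality_sum = np.zeros(p)
    metrics: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for _ in range(reps):
        rho = None
        for _attempt in range(max_redraws):
            idx = rng.choice(n, size=subset_n, replace=with_replacement)
            try:
                rho = partial_correlations(X[idx], shrinkage=shrinkage)
                break
            except ValueError:
                continue
        if rho is None:
            # shrinkage handles near-singularity; constant columns cannot be
            # correlated, so fall back to a zero contribution
            logger.warning("bootstrap draw degenerate after retries; skipped")
            continue
        W = rho.copy()
        np.fill_diagonal(W, 0.0)
        weight_sum += W
        G = _graph_from_weights(W, items, tau)
        for k, v in graph_global_metrics(G).items():
            metrics[k].append(v)
        deg = dict(G.degree())
        centrality_sum += np.array([deg[it] for it in items]) / (p - 1)
    n_ok = len(metrics["density"])
    if n_ok == 0:
        raise RuntimeError("every bootstrap repetition was degenerate")
    weights = weight_sum / n_ok
    weights = (weights + weights.T) / 2.0
    return CognitiveNetwork(
        items=items,
        weights=weights,
        metric_distributions={k: np.asarray(v) for k, v in metrics.items()},
        degree_centrality={
            it: float(c / n_ok) for it, c in zip(items, centrality_sum)
        },
        n_reps=n_ok,
        subset_n=subset_n,
    )


def network_global_metrics(
    net: CognitiveNetwork, tau: float = DEFAULT_TAU
) -> dict[str, float]:
    """Global metrics of the mean-weight network binarized at |w| >= tau."""
    G = _graph_from_weights(net.weights, net.items, tau)
    return graph_global_metrics(G)


def degree_centrality_profile(net: CognitiveNetwork) -> list[tuple[str, float]]:
    """Bootstrap-averaged degree centrality per item, descending."""
    return sorted(net.degree_centrality.items(), key=lambda kv: -kv[1])


def compare_network_metrics(
    networks: dict[object, CognitiveNetwork]
) -> pd.DataFrame:
    """ANOVA + Tukey HSD per metric across clusters' bootstrap distributions.

    Rows: one per metric, with F, p, and pairwise Tukey p columns.  Constant
    distributions are flagged (NaN statistics).  Caveat: bootstrap replicates
    are pseudo-replicates, not independent samples.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 cluster networks to compare")
    keys = list(networks)
    rows = []
    for metric in METRIC_NAMES:
        groups = [
            networks[k].metric_distributions[metric][
                ~np.isnan(networks[k].metric_distributions[metric])
            ]
            for k in keys
        ]
        row: dict = {"metric": metric}
        if any(len(np.unique(g)) <= 1 for g in groups):
            logger.warning("metric %s has a constant distribution; flagged",
                           metric)
            row.update({"F": np.nan, "p": np.nan, "degenerate": True})
        else:
            F, p, pairs = anova_tukey_continuous(groups)
            row.update({"F": F, "p": p, "degenerate": False})
            for (i, j), tp in pairs.items():
                row[f"tukey_p_{keys[i]}_vs_{keys[j]}"] = tp
        rows.append(row)
    return pd.DataFrame(rows)


def write_network(net: CognitiveNetwork, path_edges, path_json) -> None:
    """Export as weighted edge-list TSV plus JSON with metrics."""
    rows = []
    p = len(net.items)
    for i in range(p):
        for j in range(i + 1, p):
            rows.append((net.items[i], net.items[j], net.weights[i, j]))
    pd.DataFrame(rows, columns=["item1", "item2", "weight"]).to_csv(
        path_edges, sep="\t", index=False
    )
    with open(path_json, "w") as fh:
        json.dump(net.to_dict(), fh, indent=2)
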
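"""Genetic description of the clusters: which edges differ, which variants drive them.

Two stages.  First an ANOVA + Tukey HSD scan over edge-score columns flags
interactions whose conservation differs between clusters (raw p < 0.05 by
default, Benjamini-Hochberg optionally).  Second, the variants mapped to the
genes flanking those significant edges become features of one-vs-rest
random-forest classifiers — one per cluster — whose impurity importances rank
the variants that drive each cluster's identity.  Because cluster sizes are
typically very unbalanced, each tree of the forest is grown on a balanced
bootstrap sample (equal draws from the positive cluster and the rest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier
from sklearn.model_selection import train_test_split
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class EdgeComparisonResult:
    edge: str
    cluster_means: dict[int, float]
    f_statistic: float
    p_value: float
    tukey_p: dict[tuple[int, int], float]
    significant: bool


@dataclass
class ImportanceRanking:
    positive_cluster: int
    importances: list[tuple[str, float]]  # sorted descending
    confusion_matrix: np.ndarray  # 2x2: rows true (rest, positive)
    seed: int

    def top(self, n: int = 10) -> list[tuple[str, float]]:
        return self.importances[:n]


# ---------------------------------------------------------------------------
# Edge scan
# ---------------------------------------------------------------------------

def anova_tukey_edge_scan(
    scores: pd.DataFrame,
    labels,
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[EdgeComparisonResult]:
    """One-way ANOVA per edge column, Tukey HSD on the significant ones.

    ``fdr=True`` applies Benjamini-Hochberg to the ANOVA p-values before the
    significance call (recommended for large edge sets; the default mirrors
    the raw-threshold convention).  Zero-variance columns are reported
    non-significant with NaN statistics.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    for c in clusters:
        if (labels == c).sum() < 2:
            raise ValueError(f"cluster {c} has fewer than 2 members")
    results = []
    pvals = []
    for edge in scores.columns:
        col = scores[edge].to_numpy(dtype=float)
        groups = [col[labels == c] for c in clusters]
        means = {int(c): float(g.mean()) for c, g in zip(clusters, groups)}
        if np.allclose(col, col[0]):
            logger.warning("edge %s has zero variance; marked non-significant",
                           edge)
            results.append(EdgeComparisonResult(
                edge, means, np.nan, np.nan, {}, False))
            pvals.append(np.nan)
            continue
        F, p = stats.f_oneway(*groups)
        results.append(EdgeComparisonResult(
            edge, means, float(F), float(p), {}, False))
        pvals.append(float(p))
    pvals = np.asarray(pvals)
    ok = ~np.isnan(pvals)
    if fdr and ok.any():
        adj = np.full_like(pvals, np.nan)
        adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        decide = adj
    else:
        decide = pvals
    for res, p in zip(results, decide):
        if np.isnan(p) or p >= alpha:
            continue
        res.significant = True
        # Tukey only on the ANOVA-significant edges (two-step reading)
        col = scores[res.edge].to_numpy(dtype=float)
        tuk = pairwise_tukeyhsd(col, labels, alpha=alpha)
        res.tukey_p = _tukey_pairs(tuk)
    return results


def _tukey_pairs(tuk) -> dict[tuple[int, int], float]:
    groups = tuk.groupsunique
    out = {}
    idx = 0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            out[(int(groups[i]), int(groups[j]))] = float(tuk.pvalues[idx])
            idx += 1
    return out


def edge_scan_report(results: list[EdgeComparisonResult]) -> pd.DataFrame:
    """Flatten the scan into a table (edge, means, F, p, pairwise p, flag)."""
    rows = []
    for r in results:
        row = {"edge": r.edge, "F": r.f_statistic, "p": r.p_value,
               "significant": r.significant}
        for c, m in r.cluster_means.items():
            row[f"mean_cluster_{c}"] = m
        for (a, b), p in r.tukey_p.items():
            row[f"tukey_p_{a}_vs_{b}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def collect_candidate_variants(
    significant: list[EdgeComparisonResult],
    gene_map: dict[str, set[str]],
) -> set[str]:
    """Union of mapped variants over genes flanking significant edges."""
    sig = [r for r in significant if r.significant]
    if not sig:
        logger.warning("no significant edges: candidate variant set is empty")
        return set()
    out: set[str] = set()
    for r in sig:
        for gene in r.edge.split("-"):
            out |= gene_map.get(gene, set())
    return out


# ---------------------------------------------------------------------------
# Balanced random forest
# ---------------------------------------------------------------------------

class BalancedRandomForest:
    """Random forest where every tree sees a balanced bootstrap sample.

    Each of ``n_estimators`` trees is fit on a bootstrap drawing
    ``min(class sizes)`` samples with replacement from every class, which
    keeps minority clusters from being outvoted.  Importances are the mean of
    the trees' impurity importances; prediction is a majority vote.
    """

    def __init__(self, n_estimators: int = 500, max_features: str = "sqrt",
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state
        self.trees_: list[DecisionTreeClassifier] = []
        self.classes_: np.ndarray | None = None
        self.feature_importances_: np.ndarray | None = None

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training fold contains a single class")
        rng = np.random.default_rng(self.random_state)
        n_draw = min(int((y == c).sum()) for c in self.classes_)
        idx_by_class = {c: np.flatnonzero(y == c) for c in self.classes_}
        self.trees_ = []
        importances = np.zeros(X.shape[1])
        for i in range(self.n_estimators):
            boot = np.concatenate([
                rng.choice(idx_by_class[c], size=n_draw, replace=True)
                for c in self.classes_
            ])
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            self.trees_.append(tree)
            importances += tree.feature_importances_
        self.feature_importances_ = importances / self.n_estimators
        return self

    def predict(self, X):
        X = np.asarray(X)
        votes = np.zeros((X.shape[0], len(self.classes_)), dtype=int)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        for tree in self.trees_:
            pred = tree.predict(X)
            for r, p in enumerate(pred):
                votes[r, class_index[p]] += 1
        return self.classes_[votes.argmax(axis=1)]


def rf_one_vs_rest_importance(
    genotypes: pd.DataFrame,
    labels,
    positive_cluster: int,
    seed: int = 0,
    n_estimators: int = 500,
    test_size: float = 0.2,
) -> ImportanceRanking:
    """Rank candidate variants by importance for one cluster vs the rest.

    Stratified 80/20 split, balanced-bootstrap forest, impurity importances.
    The returned ranking is complete; reporting layers print the top 10.
    The confusion matrix rows/columns are ordered (rest, positive).
    """
    labels = np.asarray(labels)
    y = (labels == positive_cluster).astype(int)
    if y.sum() < 5:
        raise ValueError(
            f"positive cluster {positive_cluster} has fewer than 5 members"
        )
    X = genotypes.to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    if len(np.unique(y_tr)) < 2:
        raise ValueError("single-class training fold")
    forest = BalancedRandomForest(
        n_estimators=n_estimators, random_state=seed
    ).fit(X_tr, y_tr)
    pred = forest.predict(X_te)
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_te, pred):
        cm[t, p] += 1
    order = np.argsort(forest.feature_importances_)[::-1]
    ranking = [
        (str(genotypes.columns[i]), float(forest.feature_importances_[i]))
        for i in order
    ]
    return ImportanceRanking(
        positive_cluster=int(positive_cluster),
        importances=ranking,
        confusion_matrix=cm,
        seed=seed,
    )
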
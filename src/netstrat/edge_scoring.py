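"""Per-subject PPI edge conservation scores.

Each subnetwork edge (g1, g2) receives, per subject, a score in [0, 1]:

    burden = (m_s(g1) + m_s(g2)) / (M(g1) + M(g2))
    score  = 1 - burden

where ``m_s(g)`` is the number of selected variants the subject carries in
gene ``g`` and ``M(g)`` is the number of distinct selected variants of ``g``
carried by at least one cohort subject.  A score of 1 means the interaction
is fully conserved for that subject (no variant burden in either interactor);
0 means the subject carries every cohort-observed variant in both genes.
Because the denominator is cohort-relative, the score of an edge depends on
the cohort the matrix was built from, not only on the subject.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .network_assembly import PPINetwork

logger = logging.getLogger(__name__)


def compute_cohort_gene_totals(
    genotypes: pd.DataFrame, gene_map: dict[str, set[str]]
) -> dict[str, int]:
    """Count, per gene, the distinct mapped variants carried by >= 1 subject.

    Genes whose mapped variants are carried by nobody get M = 0 (kept in the
    result but flagged, since edges between two such genes have an undefined
    burden denominator).
    """
    missing = {
        v for vs in gene_map.values() for v in vs
    } - set(genotypes.columns)
    if missing:
        raise ValueError(
            f"gene_map variants absent from genotype columns: {sorted(missing)[:5]}"
        )
    observed = genotypes.any(axis=0)
    totals = {
        gene: int(sum(bool(observed[v]) for v in variants))
        for gene, variants in gene_map.items()
    }
    zeros = [g for g, m in totals.items() if m == 0]
    if zeros:
        logger.warning(
            "%d genes have no cohort-observed variant (M=0): %s",
            len(zeros), zeros[:5],
        )
    return totals


def compute_edge_conservation(
    m1: int, m2: int, M1: int, M2: int
) -> float:
    """Conservation score of one edge for one subject.

    ``m`` are the subject's carried-variant counts in the two interactors,
    ``M`` the cohort-wide totals.  Zero total denominator (no cohort-observed
    variant in either gene) yields a fully conserved score of 1.
    """
    for name, x in (("m1", m1), ("m2", m2), ("M1", M1), ("M2", M2)):
        if x < 0:
            raise ValueError(f"{name} must be nonnegative, got {x}")
    if m1 > M1 or m2 > M2:
        raise ValueError(
            f"subject carries more variants than the cohort total: "
            f"m=({m1},{m2}) M=({M1},{M2})"
        )
    denom = M1 + M2
    if denom == 0:
        logger.debug("zero-denominator edge scored as fully conserved")
        return 1.0
    return 1.0 - (m1 + m2) / denom


def build_edge_score_matrix(
    genotypes: pd.DataFrame,
    subnet: PPINetwork,
    gene_map: dict[str, set[str]],
    drop_constant: bool = False,
) -> pd.DataFrame:
    """Score every (subject, edge) pair of the subnetwork.

    Returns a subjects x edges DataFrame whose columns are the canonical
    ``"G1-G2"`` labels in sorted order and whose rows follow the genotype
    matrix's subject order.  ``drop_constant`` removes edges whose score is
    identical for all subjects (they carry no clustering information).
    """
    if not subnet.edges:
        raise ValueError("subnetwork has no edges")
    totals = compute_cohort_gene_totals(genotypes, gene_map)
    # per-gene subject burden m_s(g): row sums over the gene's mapped variants
    m_sub = {}
    for gene in subnet.nodes:
        variants = sorted(gene_map.get(gene, ()))
        if variants:
            m_sub[gene] = genotypes[variants].to_numpy().sum(axis=1)
        else:
            m_sub[gene] = np.zeros(len(genotypes), dtype=int)
    cols = {}
    for a, b in sorted(subnet.edges):
        Ma, Mb = totals.get(a, 0), totals.get(b, 0)
        denom = Ma + Mb
        if denom == 0:
            logger.warning("edge %s-%s has zero denominator; scores all 1", a, b)
            cols[f"{a}-{b}"] = np.ones(len(genotypes))
        else:
            cols[f"{a}-{b}"] = 1.0 - (m_sub[a] + m_sub[b]) / denom
    scores = pd.DataFrame(cols, index=genotypes.index.copy())
    if (scores.to_numpy() < -1e-12).any() or (scores.to_numpy() > 1 + 1e-12).any():
        raise AssertionError("edge scores escaped [0, 1]")
    if drop_constant:
        constant = scores.columns[scores.nunique(axis=0) <= 1]
        if len(constant):
            logger.warning(
                "dropping %d constant edge-score columns", len(constant)
            )
            scores = scores.drop(columns=constant)
    return scores


def write_edge_scores(scores: pd.DataFrame, path) -> None:
    """Write the score matrix as TSV (subject_id first column, full precision)."""
    scores.to_csv(path, sep="\t", index_label="subject_id", float_format="%.17g")


def read_edge_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    vals = df.to_numpy()
    if np.isnan(vals).any():
        raise ValueError("edge score matrix contains missing values")
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("edge scores outside [0, 1]")
    return df
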
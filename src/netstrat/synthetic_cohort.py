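"""Synthetic cohort generation with planted ground truth.

The real study cohort (WGS genotypes, clinical phenotypes, FDG-PET SUVRs,
ADAS-Cog subscores) is access-controlled, so every pipeline input is
emulated here with known structure: a connected scale-free-ish PPI layer
with designated hub genes, genotype carrier flags enriched in each cluster's
signature genes, phenotype tables with planted group shifts, longitudinal
ROI trajectories with planted baseline offsets and cluster x time slopes,
and ADAS-Cog item scores discretized from a latent Gaussian with a planted
domain-block precision matrix.

Every generator is a pure function of (config, seed): fixed seeds reproduce
outputs exactly.  Defaults mirror the scale of the motivating cohort
(728 subjects split 32/63/5 percent over three clusters, a 66-node /
102-edge brain PPI subnetwork); ``SimulationConfig.small()`` gives a
120-subject / 20-gene / 30-edge fixture for fast tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .network_assembly import PPINetwork, VariantAnnotation
from .cognitive_networks import adascog_item_info
from .phenotype_profiling import aal_labels

logger = logging.getLogger(__name__)

#: CUI codes of the neurodegenerative diseases whose variant associations
#: seed the feature space (AD, general neurodegeneration, CNS degeneration,
#: FTD, PD, corticobasal degeneration, vascular dementia, PPA, DLB).
NEURODEGENERATION_CUIS = (
    "C0002395", "C0524851", "C0262424", "C0270715", "C0338451",
    "C0030567", "C0393570", "C0011269", "C0282513", "C0752347",
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults mirror the study scale."""

    seed: int = 0
    n_subjects: int = 728
    cluster_proportions: tuple[float, ...] = (0.32, 0.63, 0.05)
    n_genes: int = 66
    n_edges: int = 102
    hub_genes_per_cluster: int = 1
    signature_genes_per_cluster: int = 5
    enrichment_rate: float = 0.6
    background_rate: float = 0.05
    variants_per_gene: int = 3
    # phenotype: per-cluster {column: shift in SD units}; defaults mirror the
    # trend of a tau-elevated first cluster and an older third cluster
    phenotype_effects: dict = field(default_factory=lambda: {
        0: {"tTau": 1.0, "pTau": 1.0},
        2: {"age": 1.0},
    })
    # ROI longitudinal model
    n_rois: int = 12
    affected_rois_per_cluster: int = 3
    roi_baseline_offset: float = -0.05
    roi_interaction_slope: float = -0.02
    roi_noise_sd: float = 0.05
    roi_subject_sd: float = 0.05
    visit_schedule: tuple[float, ...] = (0.0, 1.0, 2.0)
    n_controls: int = 40
    # ADAS-Cog latent structure: within-domain partial-correlation strength;
    # must stay below 1/(largest domain size - 1) = 0.25 for a positive-
    # definite precision (the language domain has 5 items)
    adascog_domain_rho: float = 0.2

    def __post_init__(self) -> None:
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        for r in (self.enrichment_rate, self.background_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_edges > self.n_genes * (self.n_genes - 1) // 2:
            raise ValueError("n_edges exceeds the complete graph")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_proportions)

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Fast 120-subject / 20-gene / 30-edge fixture."""
        base = dict(
            seed=seed, n_subjects=120, n_genes=20, n_edges=30,
            signature_genes_per_cluster=3, n_rois=6,
            affected_rois_per_cluster=2, n_controls=30,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """Planted structure the generators used; the yardstick for recovery tests."""

    labels: np.ndarray
    signature_genes: dict[int, list[str]]
    roi_coefficients: dict | None = None
    subscore_precision: np.ndarray | None = None


def _subject_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def _cluster_labels(cfg: SimulationConfig, rng) -> np.ndarray:
    counts = [int(np.floor(p * cfg.n_subjects)) for p in cfg.cluster_proportions]
    while sum(counts) < cfg.n_subjects:
        counts[int(np.argmax(cfg.cluster_proportions))] += 1
    labels = np.concatenate([
        np.full(c, i, dtype=int) for i, c in enumerate(counts)
    ])
    rng.shuffle(labels)
    return labels


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def simulate_ppi_network(cfg: SimulationConfig) -> PPINetwork:
    """Connected random PPI layer with high-degree hub genes.

    One hub per (cluster x hub_genes_per_cluster); non-hub genes attach to a
    hub with probability 1/2 while growing a random spanning tree, and half
    of the surplus edges are anchored at hubs, so hub degree clearly exceeds
    the median.
    """
    n, e = cfg.n_genes, cfg.n_edges
    if e < n - 1:
        raise ValueError("n_edges too small for a connected network")
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:03d}" for i in range(1, n + 1)]
    n_hubs = cfg.n_clusters * cfg.hub_genes_per_cluster
    hubs = genes[:n_hubs]
    edges: set[tuple[str, str]] = set()

    def add(a: str, b: str) -> bool:
        if a == b:
            return False
        pair = (a, b) if a < b else (b, a)
        if pair in edges:
            return False
        edges.add(pair)
        return True

    # spanning tree with preferential attachment to hubs
    for i in range(1, n):
        if i < n_hubs:
            target = genes[rng.integers(i)]
        elif rng.random() < 0.5:
            target = hubs[rng.integers(n_hubs)]
        else:
            target = genes[rng.integers(i)]
        add(genes[i], target)
    # surplus edges: half hub-anchored, half uniform
    guard = 0
    while len(edges) < e:
        guard += 1
        if guard > 100 * e:
            raise RuntimeError("edge count infeasible for this construction")
        if rng.random() < 0.5:
            a = hubs[rng.integers(n_hubs)]
        else:
            a = genes[rng.integers(n)]
        b = genes[rng.integers(n)]
        add(a, b)
    return PPINetwork(frozenset(genes), frozenset(edges), tissue="brain")


# ---------------------------------------------------------------------------
# Genotypes + annotations
# ---------------------------------------------------------------------------

def simulate_genotypes_with_clusters(
    cfg: SimulationConfig, ppi: PPINetwork
) -> tuple[pd.DataFrame, list[VariantAnnotation], GroundTruth]:
    """Carrier flags with cluster-enriched signature genes, plus annotations.

    Each cluster's signature is one of the PPI hubs plus its nearest
    neighbours (signature sets disjoint across clusters).  Cluster members
    carry each variant of their signature genes with probability
    ``enrichment_rate``; every other (subject, variant) pair carries at the
    ``background_rate``.  Annotations give every gene at least one
    exonic-class variant so the genes survive subnetwork induction, and tag
    each cluster's signature variants with a distinct disease CUI.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    labels = _cluster_labels(cfg, rng)
    genes = sorted(ppi.nodes)
    degree = {g: 0 for g in genes}
    neighbours: dict[str, set[str]] = {g: set() for g in genes}
    for a, b in ppi.edges:
        degree[a] += 1
        degree[b] += 1
        neighbours[a].add(b)
        neighbours[b].add(a)
    ranked = sorted(genes, key=lambda g: (-degree[g], g))
    n_hubs = cfg.n_clusters * cfg.hub_genes_per_cluster
    hubs = ranked[:n_hubs]

    taken: set[str] = set()
    signature: dict[int, list[str]] = {}
    for c in range(cfg.n_clusters):
        sig = []
        for h in hubs[c * cfg.hub_genes_per_cluster:(c + 1) * cfg.hub_genes_per_cluster]:
            if h not in taken:
                sig.append(h)
                taken.add(h)
            for nb in sorted(neighbours[h], key=lambda g: (-degree[g], g)):
                if len(sig) >= cfg.signature_genes_per_cluster:
                    break
                if nb not in taken:
                    sig.append(nb)
                    taken.add(nb)
        signature[c] = sig

    variants: list[str] = []
    var_gene: list[str] = []
    annotations: list[VariantAnnotation] = []
    sig_cui = {c: NEURODEGENERATION_CUIS[c % len(NEURODEGENERATION_CUIS)]
               for c in range(cfg.n_clusters)}
    vid = 1000000
    for gene in genes:
        in_sig = [c for c, s in signature.items() if gene in s]
        for j in range(cfg.variants_per_gene):
            rsid = f"rs{vid}"
            vid += 1
            consequence = "missense" if j == 0 else "intronic"
            if in_sig:
                cuis = frozenset(sig_cui[c] for c in in_sig)
            else:
                cuis = frozenset({NEURODEGENERATION_CUIS[
                    rng.integers(len(NEURODEGENERATION_CUIS))]})
            variants.append(rsid)
            var_gene.append(gene)
            annotations.append(
                VariantAnnotation(rsid, gene, cuis, consequence)
            )

    n, m = cfg.n_subjects, len(variants)
    rates = np.full((n, m), cfg.background_rate)
    sig_cols = {
        c: [j for j, g in enumerate(var_gene) if g in signature[c]]
        for c in range(cfg.n_clusters)
    }
    for c in range(cfg.n_clusters):
        rows = np.flatnonzero(labels == c)
        rates[np.ix_(rows, sig_cols[c])] = cfg.enrichment_rate
    carriers = (rng.random((n, m)) < rates).astype(int)
    genotypes = pd.DataFrame(
        carriers, index=pd.Index(_subject_ids(n), name="subject_id"),
        columns=variants,
    )
    return genotypes, annotations, GroundTruth(labels=labels,
                                               signature_genes=signature)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

#: (column, mean, SD) of the baseline phenotype variables; biomarker scales
#: follow typical CSF/PET/MRI ADNI ranges.
_PHENOTYPE_SPECS = [
    ("age", 73.0, 7.0),
    ("education", 16.0, 2.7),
    ("abeta", 1000.0, 440.0),
    ("tTau", 280.0, 120.0),
    ("pTau", 27.0, 13.0),
    ("av45", 1.2, 0.2),
    ("fdg", 1.2, 0.15),
    ("mri_hippocampus", 0.0045, 0.0007),
    ("mmse", 27.0, 2.0),
    ("cdr_sob", 1.5, 1.0),
]

_APOE_GENOTYPES = ("E2/E2", "E2/E3", "E2/E4", "E3/E3", "E3/E4", "E4/E4")
_APOE_PROBS = (0.02, 0.10, 0.05, 0.50, 0.25, 0.08)


def simulate_phenotype_table(
    cfg: SimulationConfig, truth: GroundTruth
) -> pd.DataFrame:
    """Baseline demographics/biomarkers with planted per-cluster shifts.

    ``cfg.phenotype_effects[cluster][column]`` shifts that cluster's mean by
    the given number of column SDs.  Diagnosis, sex and APOE genotype are
    drawn from cohort-typical frequencies independent of cluster.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n = len(truth.labels)
    df = pd.DataFrame({"subject_id": _subject_ids(n)})
    df["diagnosis"] = rng.choice(
        ["CN", "MCI", "Dementia"], size=n, p=[0.30, 0.55, 0.15]
    )
    df["sex"] = rng.choice(["F", "M"], size=n, p=[0.45, 0.55])
    df["apoe"] = rng.choice(_APOE_GENOTYPES, size=n, p=_APOE_PROBS)
    for col, mean, sd in _PHENOTYPE_SPECS:
        vals = rng.normal(mean, sd, size=n)
        for c, effects in cfg.phenotype_effects.items():
            if col in effects:
                vals[truth.labels == c] += effects[col] * sd
        df[col] = vals
    df["mmse"] = df["mmse"].clip(0, 30).round(0)
    df["cdr_sob"] = df["cdr_sob"].clip(lower=0.0).round(1)
    df["abeta"] = df["abeta"].clip(lower=50.0)
    converts = df["diagnosis"] != "CN"
    df["age_to_dementia"] = np.where(
        converts, df["age"] + rng.normal(4.0, 2.0, size=n), np.nan
    )
    return df


# ---------------------------------------------------------------------------
# ROI longitudinal SUVR
# ---------------------------------------------------------------------------

def simulate_roi_longitudinal(
    cfg: SimulationConfig,
    truth: GroundTruth,
    phenotypes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format (subject, ROI, SUVR, time, sex, age, group) records.

    Cohort subjects (grouped ``cluster_1..k``) plus ``n_controls`` extra
    controls follow the visit schedule.  Each cluster's designated ROIs get
    the planted baseline offset and cluster x time interaction slope on top
    of a subject random intercept and i.i.d. noise.  The planted
    coefficients are recorded in ``truth.roi_coefficients``.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    rois = aal_labels()[: cfg.n_rois]
    a = cfg.affected_rois_per_cluster
    coeffs: dict[tuple[str, str], tuple[float, float]] = {}
    for c in range(cfg.n_clusters):
        start = (c * a) % max(1, len(rois) - a + 1)
        for roi in rois[start:start + a]:
            coeffs[(f"cluster_{c + 1}", roi)] = (
                cfg.roi_baseline_offset, cfg.roi_interaction_slope
            )
    truth.roi_coefficients = coeffs

    subjects = _subject_ids(len(truth.labels))
    groups = [f"cluster_{c + 1}" for c in truth.labels]
    subjects += [f"CTRL{i:03d}" for i in range(1, cfg.n_controls + 1)]
    groups += ["control"] * cfg.n_controls

    if phenotypes is not None:
        ages = dict(zip(phenotypes["subject_id"], phenotypes["age"]))
        sexes = dict(zip(phenotypes["subject_id"], phenotypes["sex"]))
    else:
        ages, sexes = {}, {}
    base_by_roi = {roi: 1.2 + rng.normal(0, 0.03) for roi in rois}
    rows = []
    for subj, grp in zip(subjects, groups):
        age = ages.get(subj, float(rng.normal(73, 7)))
        sex = sexes.get(subj, str(rng.choice(["F", "M"])))
        u = rng.normal(0, cfg.roi_subject_sd)
        for roi in rois:
            off, slope = coeffs.get((grp, roi), (0.0, 0.0))
            for t in cfg.visit_schedule:
                suvr = (base_by_roi[roi] + off + slope * t + u
                        + rng.normal(0, cfg.roi_noise_sd))
                rows.append((subj, roi, max(suvr, 1e-3), t, sex, age, grp))
    return pd.DataFrame(
        rows, columns=["subject_id", "roi", "suvr", "time_years",
                       "sex", "age", "group"],
    )


# ---------------------------------------------------------------------------
# ADAS-Cog subscores
# ---------------------------------------------------------------------------

def planted_subscore_precision(rho: float) -> tuple[np.ndarray, list[str]]:
    """Precision matrix with -rho off-diagonals inside each cognitive domain."""
    info = adascog_item_info()
    items = list(info)
    p = len(items)
    theta = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            if info[items[i]]["domain"] == info[items[j]]["domain"]:
                theta[i, j] = theta[j, i] = -rho
    eigmin = np.linalg.eigvalsh(theta).min()
    if eigmin <= 0:
        raise ValueError(f"domain rho {rho} makes the precision indefinite")
    return theta, items


def simulate_adascog_scores(
    cfg: SimulationConfig, truth: GroundTruth
) -> pd.DataFrame:
    """Item subscores from a latent Gaussian with domain-block precision.

    Latent scores are drawn from N(0, Theta^{-1}) with Theta the planted
    domain-block precision, then discretized item-wise to each item's
    declared score range by Gaussian-quantile binning (rank-preserving).
    """
    theta, items = planted_subscore_precision(cfg.adascog_domain_rho)
    truth.subscore_precision = theta
    rng = np.random.default_rng(cfg.seed + 4)
    n = len(truth.labels)
    cov = np.linalg.inv(theta)
    latent = rng.multivariate_normal(np.zeros(len(items)), cov, size=n,
                                     method="cholesky")
    info = adascog_item_info()
    df = pd.DataFrame({"subject_id": _subject_ids(n)})
    scale = np.sqrt(np.diag(cov))
    for j, item in enumerate(items):
        lo, hi = info[item]["range"]
        u = norm.cdf(latent[:, j] / scale[j])
        df[item] = np.clip(np.floor(u * (hi - lo + 1)).astype(int) + lo, lo, hi)
    return df


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

def generate_all(cfg: SimulationConfig) -> dict:
    """Generate every pipeline input plus ground truth in one call."""
    ppi = simulate_ppi_network(cfg)
    genotypes, annotations, truth = simulate_genotypes_with_clusters(cfg, ppi)
    phenotypes = simulate_phenotype_table(cfg, truth)
    roi = simulate_roi_longitudinal(cfg, truth, phenotypes)
    adascog = simulate_adascog_scores(cfg, truth)
    return {
        "ppi": ppi,
        "genotypes": genotypes,
        "annotations": annotations,
        "phenotypes": phenotypes,
        "roi": roi,
        "adascog": adascog,
        "truth": truth,
    }


def write_fixtures(cfg: SimulationConfig, outdir) -> dict:
    """Write all six input files in the formats the pipeline reads."""
    from pathlib import Path

    from .edge_scoring import write_edge_scores  # noqa: F401 (re-export site)
    from .network_assembly import write_ppi_table, write_genotype_matrix

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_all(cfg)
    rows = []
    for ann in bundle["annotations"]:
        for cui in sorted(ann.disease_cuis):
            rows.append((ann.variant_id, ann.gene, cui, ann.consequence))
    pd.DataFrame(rows, columns=["variant_id", "gene", "cui", "consequence"]) \
        .to_csv(out / "vda.tsv", sep="\t", index=False)
    write_ppi_table(bundle["ppi"], out / "ppi.tsv")
    write_genotype_matrix(bundle["genotypes"], out / "genotypes.tsv")
    bundle["phenotypes"].to_csv(out / "phenotypes.csv", index=False)
    bundle["roi"].to_csv(out / "roi_suvr.csv", index=False)
    bundle["adascog"].to_csv(out / "adascog.csv", index=False)
    pd.DataFrame({
        "subject_id": _subject_ids(len(bundle["truth"].labels)),
        "true_cluster": bundle["truth"].labels,
    }).to_csv(out / "true_labels.tsv", sep="\t", index=False)
    return bundle
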
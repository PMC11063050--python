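"""Assemble the variant-bearing PPI subnetwork that defines the edge-score feature space.

The pipeline starts from three exported tables: a variant-disease-association
(VDA) table (rsID, gene symbol, disease CUI, consequence class), a per-subject
genotype carrier matrix, and a tissue-specific protein-protein interaction
edge list (PPT-Ohmnet dialect).  This module filters the VDAs to the diseases
of interest, maps retained variants onto genes present in the genotype data,
and induces the subnetwork of interactions whose endpoints carry at least one
exonic-class variant.  The resulting subnetwork's edges are the feature space
for per-subject conservation scoring.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

#: Consequence classes counted as "exonic" when deciding which genes survive
#: the subnetwork induction.  Configurable because different annotation
#: pipelines draw the exonic boundary differently.
DEFAULT_EXONIC_CLASSES = frozenset({"exonic", "missense", "synonymous"})

CONSEQUENCE_CLASSES = frozenset(
    {"exonic", "intronic", "synonymous", "missense", "other"}
)

_CUI_RE = re.compile(r"^C\d{7}$")


@dataclass(frozen=True)
class VariantAnnotation:
    """One variant-gene annotation with its associated disease concepts."""

    variant_id: str
    gene: str
    disease_cuis: frozenset[str]
    consequence: str = "other"

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValueError("variant_id must be non-empty")
        if not self.gene:
            raise ValueError("gene must be non-empty")
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(
                f"unknown consequence class {self.consequence!r}; "
                f"expected one of {sorted(CONSEQUENCE_CLASSES)}"
            )


@dataclass(frozen=True)
class PPINetwork:
    """Undirected PPI graph with canonically ordered edges.

    Edges are stored as lexicographically sorted gene pairs so that the edge
    label ``"G1-G2"`` (G1 < G2) is stable across runs and round-trips through
    the on-disk edge-list format.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    tissue: str = ""

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r} not allowed")
            if a > b:
                raise ValueError(f"edge ({a}, {b}) not in canonical order")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) has endpoint outside nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_labels(self) -> list[str]:
        """Canonical, sorted ``"G1-G2"`` labels for all edges."""
        return sorted(f"{a}-{b}" for a, b in self.edges)

    @staticmethod
    def from_pairs(pairs, tissue: str = "") -> "PPINetwork":
        """Build a network from arbitrary gene pairs, canonicalizing order."""
        edges = set()
        nodes = set()
        for a, b in pairs:
            if a == b:
                continue
            lo, hi = (a, b) if a < b else (b, a)
            edges.add((lo, hi))
            nodes.update((lo, hi))
        return PPINetwork(frozenset(nodes), frozenset(edges), tissue)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_vda_table(path) -> list[VariantAnnotation]:
    """Read a VDA TSV (columns variant_id, gene, cui, consequence).

    Rows sharing (variant_id, gene) are merged, their CUIs unioned.  The
    consequence of the first row wins on conflict (logged).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_id", "gene", "cui", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"VDA table missing columns: {sorted(missing)}")
    merged: dict[tuple[str, str], dict] = {}
    for row in df.itertuples(index=False):
        key = (row.variant_id, row.gene)
        rec = merged.setdefault(
            key, {"cuis": set(), "consequence": row.consequence}
        )
        rec["cuis"].add(row.cui)
        if row.consequence != rec["consequence"]:
            logger.warning(
                "conflicting consequence for %s/%s: keeping %r, ignoring %r",
                row.variant_id, row.gene, rec["consequence"], row.consequence,
            )
    return [
        VariantAnnotation(v, g, frozenset(rec["cuis"]), rec["consequence"])
        for (v, g), rec in merged.items()
    ]


def read_ppi_table(path, tissue: str | None = None) -> PPINetwork:
    """Read a tissue PPI edge list (gene1 TAB gene2 TAB tissue).

    Accepts the PPT-Ohmnet dialect: tab-separated, header row optional.  When
    ``tissue`` is given, only edges annotated with that tissue are kept.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("PPI edge list needs at least two columns")
    first = [str(x).lower() for x in df.iloc[0]]
    if first[0] in {"gene1", "protein1", "node1"}:  # header row present
        df = df.iloc[1:]
    if df.shape[1] >= 3:
        df.columns = ["gene1", "gene2", "tissue"] + list(df.columns[3:])
        if tissue is not None:
            df = df[df["tissue"] == tissue]
    else:
        df.columns = ["gene1", "gene2"]
    pairs = list(zip(df["gene1"], df["gene2"]))
    return PPINetwork.from_pairs(pairs, tissue=tissue or "")


def write_ppi_table(net: PPINetwork, path) -> None:
    """Write the canonical edge list (round-trips through read_ppi_table)."""
    rows = [(a, b, net.tissue) for a, b in sorted(net.edges)]
    pd.DataFrame(rows, columns=["gene1", "gene2", "tissue"]).to_csv(
        path, sep="\t", index=False
    )


def read_genotype_matrix(path) -> pd.DataFrame:
    """Read a subjects x variants TSV of {0,1} carrier flags."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate subject IDs in genotype matrix")
    if df.columns.duplicated().any():
        raise ValueError("duplicate variant IDs in genotype matrix")
    vals = df.to_numpy()
    if not ((vals == 0) | (vals == 1)).all():
        raise ValueError("genotype carrier matrix must be binary")
    return df.astype(int)


def write_genotype_matrix(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index_label="subject_id")


def genotypes_from_vcf(path, variant_ids: set[str] | None = None) -> pd.DataFrame:
    """Convert VCF genotype calls to a carrier-flag matrix.

    Any non-reference genotype call (het or hom-alt) becomes a carrier flag
    of 1; missing calls count as non-carrier.  Records without an rsID are
    skipped.  ``variant_ids`` optionally restricts the ingest.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    subjects = list(vf.header.samples)
    data: dict[str, list[int]] = {}
    for rec in vf:
        rsid = rec.id
        if rsid is None or rsid == ".":
            continue
        if variant_ids is not None and rsid not in variant_ids:
            continue
        flags = []
        for s in subjects:
            gt = rec.samples[s].get("GT", (None,))
            flags.append(int(any(a not in (None, 0) for a in gt)))
        data[rsid] = flags
    return pd.DataFrame(data, index=pd.Index(subjects, name="subject_id"))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def filter_vda_by_disease(
    vda_table: list[VariantAnnotation], cuis: set[str]
) -> list[VariantAnnotation]:
    """Keep annotations whose disease CUIs intersect the requested set.

    The result is deduplicated on (variant_id, gene); an empty input yields
    an empty result with a warning.  CUIs must look like UMLS concept IDs
    (``C`` followed by seven digits).
    """
    if not cuis:
        raise ValueError("cuis must be non-empty")
    bad = [c for c in cuis if not _CUI_RE.match(c)]
    if bad:
        raise ValueError(
            f"unrecognized CUI format: {sorted(bad)} (expected e.g. C0002395)"
        )
    if not vda_table:
        logger.warning("empty VDA table passed to disease filter")
        return []
    seen: set[tuple[str, str]] = set()
    out = []
    for ann in vda_table:
        if ann.disease_cuis & cuis and (ann.variant_id, ann.gene) not in seen:
            seen.add((ann.variant_id, ann.gene))
            out.append(ann)
    return out


def build_variant_gene_map(
    annotations: list[VariantAnnotation], genotypes: pd.DataFrame
) -> dict[str, set[str]]:
    """Map each gene to its annotated variants that exist as genotype columns.

    Variants absent from the genotype matrix are dropped (count logged).  A
    variant annotated to several genes is kept under every annotated gene.
    Genes left with no retained variant do not appear in the map.
    """
    if not annotations:
        return {}
    available = set(genotypes.columns)
    gene_map: dict[str, set[str]] = {}
    dropped = set()
    for ann in annotations:
        if ann.variant_id not in available:
            dropped.add(ann.variant_id)
            continue
        gene_map.setdefault(ann.gene, set()).add(ann.variant_id)
    if dropped:
        logger.info(
            "%d annotated variants absent from genotype columns were dropped",
            len(dropped),
        )
    multi = {
        v for g, vs in gene_map.items() for v in vs
        if sum(v in vs2 for vs2 in gene_map.values()) > 1
    }
    if multi:
        logger.info(
            "%d variants annotated to multiple genes kept under every gene",
            len(multi),
        )
    return gene_map


def induce_brain_subnetwork(
    ppi: PPINetwork,
    gene_map: dict[str, set[str]],
    annotations: list[VariantAnnotation],
    exonic_classes: frozenset[str] = DEFAULT_EXONIC_CLASSES,
) -> PPINetwork:
    """Induce the subnetwork on genes carrying at least one exonic-class variant.

    Node retention requires an exonic-class variant among the gene's retained
    (genotyped) variants; downstream edge scoring then uses *all* retained
    variants of the surviving genes, including intronic ones.  Isolated nodes
    are dropped.  A zero-edge result is a hard error: there would be no
    feature space to score.
    """
    if not ppi.edges:
        raise ValueError("input PPI network has no edges")
    consequence = {
        (a.variant_id, a.gene): a.consequence for a in annotations
    }
    exonic_genes = set()
    for gene, variants in gene_map.items():
        if any(
            consequence.get((v, gene)) in exonic_classes for v in variants
        ):
            exonic_genes.add(gene)
    keep = exonic_genes & ppi.nodes
    edges = frozenset(
        (a, b) for a, b in ppi.edges if a in keep and b in keep
    )
    if not edges:
        raise ValueError(
            "induced subnetwork has zero edges: no feature space remains"
        )
    connected = {g for e in edges for g in e}
    iso = keep - connected
    if iso:
        logger.info("dropping %d isolated nodes from subnetwork", len(iso))
    return PPINetwork(frozenset(connected), edges, ppi.tissue)
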
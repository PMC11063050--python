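import numpy as np
import pytest

import netstrat as ns
from netstrat.synthetic_cohort import NEURODEGENERATION_CUIS


@pytest.fixture(scope="session")
def small_bundle():
    """One small synthetic cohort shared by read-only tests."""
    cfg = ns.SimulationConfig.small(seed=7)
    return ns.generate_all(cfg)


@pytest.fixture(scope="session")
def small_scores(small_bundle):
    """Edge-score matrix + gene map + subnetwork derived from the bundle."""
    selected = ns.filter_vda_by_disease(
        small_bundle["annotations"], set(NEURODEGENERATION_CUIS)
    )
    gene_map = ns.build_variant_gene_map(selected, small_bundle["genotypes"])
    subnet = ns.induce_brain_subnetwork(small_bundle["ppi"], gene_map, selected)
    scores = ns.build_edge_score_matrix(
        small_bundle["genotypes"], subnet, gene_map
    )
    return {"scores": scores, "gene_map": gene_map, "subnet": subnet,
            "selected": selected}


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def toy_annotations():
    """Small hand-written VDA set used across assembly tests."""
    A = ns.VariantAnnotation
    return [
        A("rs1", "GENEA", frozenset({"C0002395"}), "missense"),
        A("rs2", "GENEA", frozenset({"C0030567"}), "intronic"),
        A("rs3", "GENEB", frozenset({"C0002395", "C0011269"}), "synonymous"),
        A("rs4", "GENEC", frozenset({"C0338451"}), "exonic"),
        A("rs5", "GENED", frozenset({"C0002395"}), "intronic"),
    ]
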
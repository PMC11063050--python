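"""End-to-end orchestration: assemble -> score -> cluster -> profile.

A run is driven by a :class:`RunConfig` (loadable from YAML), executes each
stage in order, and writes every stage output plus a manifest (input hashes,
package version, seed, chosen clustering solution) so a completed run is
reproducible from its manifest.  Any stage failure halts the run with a
stage-tagged error and leaves partial outputs under a ``FAILED`` marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .network_assembly import (
    filter_vda_by_disease, build_variant_gene_map, induce_brain_subnetwork,
    read_vda_table, read_ppi_table, read_genotype_matrix, write_ppi_table,
)
from .edge_scoring import build_edge_score_matrix, write_edge_scores
from .snf_clustering import SNFConfig, model_selection_grid, ClusteringSolution
from .genetic_profiling import (
    anova_tukey_edge_scan, collect_candidate_variants,
    rf_one_vs_rest_importance, edge_scan_report,
)
from .phenotype_profiling import (
    summarize_cluster_phenotypes, fit_roi_model_baseline,
    fit_roi_model_longitudinal, roi_results_table,
)
from .cognitive_networks import (
    bootstrap_partial_correlations, compare_network_metrics, write_network,
)
from .synthetic_cohort import NEURODEGENERATION_CUIS

logger = logging.getLogger(__name__)

#: Top-two silhouettes closer than this require an explicit cluster choice.
SI_AMBIGUITY_BAND = 0.2


@dataclass
class RunConfig:
    """Configuration of one stratification run."""

    vda_path: str
    ppi_path: str
    genotypes_path: str
    out_dir: str
    seed: int
    phenotypes_path: str | None = None
    roi_path: str | None = None
    adascog_path: str | None = None
    cuis: tuple[str, ...] = NEURODEGENERATION_CUIS
    tissue: str | None = None
    #: {column: [allowed values]} row filter on the phenotype table applied
    #: before scoring (e.g. an ancestry restriction)
    cohort_filters: dict = field(default_factory=dict)
    snf: SNFConfig = field(default_factory=SNFConfig)
    chosen_k: int | None = None
    chosen_mu: float | None = None
    strata: tuple[str, ...] = ("MCI", "Dementia")
    run_genetic: bool = True
    run_phenotype: bool = True
    run_roi: bool = True
    run_cognitive: bool = True
    subset_n: int = 10
    bootstrap_reps: int = 250
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        snf = SNFConfig(**raw.pop("snf", {}))
        if "cuis" in raw:
            raw["cuis"] = tuple(raw["cuis"])
        cfg = cls(snf=snf, **raw)
        for key in ("vda_path", "ppi_path", "genotypes_path"):
            if not Path(getattr(cfg, key)).exists():
                raise FileNotFoundError(f"{key}: {getattr(cfg, key)}")
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def choose_solution(
    solutions: list[ClusteringSolution],
    chosen_k: int | None = None,
    chosen_mu: float | None = None,
) -> ClusteringSolution:
    """Pick the working solution from the silhouette ranking.

    With no explicit choice the top-ranked solution is returned, unless the
    top two silhouettes are within ``SI_AMBIGUITY_BAND`` of each other — a
    genuinely ambiguous ranking in which the lower-SI solution may well be
    the scientifically preferable one — in which case an explicit
    ``chosen_k`` is required.
    """
    if chosen_k is not None:
        pool = [s for s in solutions if s.n_clusters == chosen_k]
        if chosen_mu is not None:
            pool = [s for s in pool if abs(s.mu - chosen_mu) < 1e-9]
        if not pool:
            raise ValueError(f"no solution with k={chosen_k}, mu={chosen_mu}")
        return pool[0]
    if len(solutions) > 1 and \
            solutions[0].rank_value - solutions[1].rank_value < SI_AMBIGUITY_BAND:
        raise ValueError(
            "top two silhouettes are within "
            f"{SI_AMBIGUITY_BAND}: k={solutions[0].n_clusters} "
            f"(SI={solutions[0].rank_value:.3f}) vs "
            f"k={solutions[1].n_clusters} (SI={solutions[1].rank_value:.3f}); "
            "set chosen_k explicitly"
        )
    return solutions[0]


def run_stratification(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report (also written to disk)."""
    logging.basicConfig(
        level=cfg.log_level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    report: dict = {"seed": cfg.seed, "version": __version__, "stages": {}}

    def stage(name):
        def deco(fn):
            def wrapped(*a, **kw):
                logger.info("stage %s: start", name)
                try:
                    res = fn(*a, **kw)
                except Exception as exc:
                    failed_marker.write_text(f"stage {name} failed: {exc}\n")
                    raise RuntimeError(f"[{name}] {exc}") from exc
                report["stages"][name] = "ok"
                return res
            return wrapped
        return deco

    @stage("assemble")
    def _assemble():
        vda = read_vda_table(cfg.vda_path)
        ppi = read_ppi_table(cfg.ppi_path, tissue=cfg.tissue)
        genotypes = read_genotype_matrix(cfg.genotypes_path)
        phenotypes = None
        if cfg.phenotypes_path:
            phenotypes = pd.read_csv(cfg.phenotypes_path)
            for col, allowed in cfg.cohort_filters.items():
                keep = phenotypes[col].isin(allowed)
                phenotypes = phenotypes[keep]
            keep_ids = set(phenotypes["subject_id"])
            genotypes = genotypes.loc[genotypes.index.isin(keep_ids)]
            phenotypes = phenotypes.set_index("subject_id") \
                .loc[genotypes.index].reset_index()
        selected = filter_vda_by_disease(vda, set(cfg.cuis))
        gene_map = build_variant_gene_map(selected, genotypes)
        subnet = induce_brain_subnetwork(ppi, gene_map, selected)
        write_ppi_table(subnet, out / "subnetwork.tsv")
        return selected, gene_map, subnet, genotypes, phenotypes

    @stage("score")
    def _score(genotypes, subnet, gene_map):
        scores = build_edge_score_matrix(genotypes, subnet, gene_map)
        write_edge_scores(scores, out / "edge_scores.tsv")
        return scores

    @stage("cluster")
    def _cluster(scores):
        solutions = model_selection_grid(scores, cfg.snf)
        with open(out / "solutions.json", "w") as fh:
            json.dump([s.to_dict() for s in solutions], fh)
        chosen = choose_solution(solutions, cfg.chosen_k, cfg.chosen_mu)
        pd.DataFrame({
            "subject_id": scores.index, "cluster": chosen.labels,
        }).to_csv(out / "labels.tsv", sep="\t", index=False)
        return solutions, chosen

    @stage("profile_genetic")
    def _genetic(scores, labels, gene_map, genotypes):
        scan = anova_tukey_edge_scan(scores, labels)
        edge_scan_report(scan).to_csv(out / "edges_report.tsv", sep="\t",
                                      index=False)
        candidates = sorted(collect_candidate_variants(scan, gene_map))
        confusions = {}
        for c in sorted(np.unique(labels)):
            if (labels == c).sum() < 5:
                logger.warning("cluster %d too small for classification", c)
                continue
            if not candidates:
                break
            ranking = rf_one_vs_rest_importance(
                genotypes[candidates], labels, int(c), seed=cfg.seed
            )
            pd.DataFrame(ranking.importances,
                         columns=["variant_id", "importance"]).to_csv(
                out / f"importance_cluster_{c}.tsv", sep="\t", index=False)
            confusions[str(c)] = ranking.confusion_matrix.tolist()
        with open(out / "confusion_matrices.json", "w") as fh:
            json.dump(confusions, fh)
        return candidates

    @stage("profile_phenotype")
    def _phenotype(phenotypes, labels):
        for stratum in cfg.strata:
            table = summarize_cluster_phenotypes(phenotypes, labels, stratum)
            table.to_csv(out / f"phenotypes_{stratum}.csv", index=False)

    @stage("profile_roi")
    def _roi():
        obs = pd.read_csv(cfg.roi_path)
        base = roi_results_table(fit_roi_model_baseline(obs))
        base.to_csv(out / "roi_baseline.csv", index=False)
        longit = roi_results_table(fit_roi_model_longitudinal(obs))
        longit.to_csv(out / "roi_longitudinal.csv", index=False)

    @stage("profile_cognitive")
    def _cognitive(labels, genotypes):
        adascog = pd.read_csv(cfg.adascog_path)
        id_to_label = dict(zip(genotypes.index, labels))
        networks = {}
        for c in sorted(set(labels)):
            ids = [s for s, l in id_to_label.items() if l == c]
            sub = adascog[adascog["subject_id"].isin(ids)]
            if len(sub) < cfg.subset_n:
                logger.warning("cluster %d too small for cognitive network", c)
                continue
            net = bootstrap_partial_correlations(
                sub, subset_n=cfg.subset_n, reps=cfg.bootstrap_reps,
                seed=cfg.seed + int(c),
            )
            networks[int(c)] = net
            write_network(net, out / f"cognet_cluster_{c}.tsv",
                          out / f"cognet_cluster_{c}.json")
        if len(networks) >= 2:
            compare_network_metrics(networks).to_csv(
                out / "cognet_comparison.csv", index=False)
        return networks

    selected, gene_map, subnet, genotypes, phenotypes = _assemble()
    scores = _score(genotypes, subnet, gene_map)
    solutions, chosen = _cluster(scores)
    labels = chosen.labels
    if cfg.run_genetic:
        _genetic(scores, labels, gene_map, genotypes)
    if cfg.run_phenotype and phenotypes is not None:
        _phenotype(phenotypes, labels)
    if cfg.run_roi and cfg.roi_path:
        _roi()
    if cfg.run_cognitive and cfg.adascog_path:
        _cognitive(labels, genotypes)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "inputs": {
            k: _sha256(p) for k, p in {
                "vda": cfg.vda_path, "ppi": cfg.ppi_path,
                "genotypes": cfg.genotypes_path,
                "phenotypes": cfg.phenotypes_path,
                "roi": cfg.roi_path, "adascog": cfg.adascog_path,
            }.items() if p
        },
        "subnetwork": {"nodes": subnet.n_nodes, "edges": subnet.n_edges},
        "chosen_solution": {
            "n_clusters": chosen.n_clusters, "mu": chosen.mu,
            "K": chosen.K, "silhouette": chosen.silhouette,
        },
        "cluster_sizes": {
            str(c): int((labels == c).sum()) for c in np.unique(labels)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    if failed_marker.exists():
        failed_marker.unlink()
    report["manifest"] = manifest
    return report
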
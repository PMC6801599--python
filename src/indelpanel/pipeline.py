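"""Orchestration of the full marker-panel analysis.

Stages: phenotype descriptives and correlations -> per-locus allele
frequencies -> diversity statistics -> Ochiai distance + trees (with locus
bootstrap) -> PCoA -> AMOVA / pairwise PhiPT on grain-type subpopulations ->
marker-trait association -> favorable-allele pyramiding.  Every stage writes
a CSV (trees: Newick) into the output directory; a JSON manifest records the
seed, configuration and package version so a run is reproducible from the
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allele_stats import allele_frequencies
from .amova import amova, drop_singleton_groups, grain_type_grouping, pairwise_phi
from .association import (
    FavorableRule,
    allele_group_anova,
    classify_alleles,
    pyramid_summary,
)
from .distance import bootstrap_support, ochiai_dissimilarity, write_phylip
from .diversity import informativeness_class, locus_diversity, panel_diversity_summary
from .markers import (
    HET_AB,
    MarkerGenotypeTable,
    PhenotypeTable,
    to_binary_matrix,
    write_tables,
)
from .ordination import pcoa
from .pheno import correlations, describe_traits, phenotype_clusters, phenotype_pca

log = logging.getLogger("indelpanel")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    output_dir: str = "indelpanel_out"
    seed: int = 0
    bootstrap: int = 100
    permutations: int = 999
    tree_method: str = "nj"
    alpha: float = 0.05
    min_group_n: int = 20
    favorable_gl_threshold: float = 8.0
    pheno_clusters: int = 3
    traits: tuple[str, ...] = ("GL", "GW", "GT", "TGW")

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.bootstrap < 1 or self.permutations < 1:
            raise ValueError("bootstrap and permutations must be >= 1")
        if self.tree_method not in ("nj", "upgma"):
            raise ValueError("tree_method must be 'nj' or 'upgma'")


def _check_ids(tab: MarkerGenotypeTable, ph: PhenotypeTable) -> None:
    g, p = set(tab.accession_ids), set(ph.accession_ids)
    if g != p:
        only_g = sorted(g - p)[:5]
        only_p = sorted(p - g)[:5]
        raise ValueError(
            "genotype/phenotype accession id mismatch: "
            f"only in genotypes {only_g}, only in phenotypes {only_p}"
        )


def run_pipeline(
    tab: MarkerGenotypeTable,
    ph: PhenotypeTable,
    cfg: RunConfig | None = None,
) -> dict:
    """Run every stage; returns {stage name: output path or result}."""
    cfg = cfg or RunConfig()
    cfg.validate()
    _check_ids(tab, ph)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    log.info("panel: %d accessions x %d loci", tab.n_accessions, tab.n_markers)

    # --- phenotype stage
    summaries = describe_traits(ph)
    write_tables(summaries, out / "trait_summary.csv")
    corr = correlations(ph)
    write_tables(corr, out / "trait_correlations.csv")
    pca = phenotype_pca(ph)
    pca.to_frame().to_csv(out / "phenotype_pca_scores.csv")
    clus = phenotype_clusters(ph, cfg.pheno_clusters)
    clus.to_frame().to_csv(out / "phenotype_clusters.csv", index=False)
    results["phenotype"] = summaries

    # --- allele frequencies and diversity
    freq_records = []
    div_rows = []
    for m in tab.marker_ids:
        recs = allele_frequencies(tab, m)
        freq_records.extend(recs)
        j = tab.marker_index(m)
        het = int(np.sum(tab.calls[:, j] == HET_AB))
        div_rows.append(locus_diversity(recs, het, tab.n_accessions))
    write_tables(freq_records, out / "allele_frequencies.csv")
    div_frame = pd.DataFrame(
        [{**d.to_dict(), "informativeness": informativeness_class(d)}
         for d in div_rows]
    )
    div_frame.to_csv(out / "diversity.csv", index=False)
    summary = panel_diversity_summary(div_rows)
    results["diversity_summary"] = summary

    # --- distances, trees, ordination
    bm = to_binary_matrix(tab)
    dm = ochiai_dissimilarity(bm)
    write_phylip(dm, out / "ochiai_distances.phy")
    tree = bootstrap_support(
        bm, method=cfg.tree_method, n_replicates=cfg.bootstrap, seed=cfg.seed
    )
    (out / f"tree_{cfg.tree_method}.nwk").write_text(tree.newick() + "\n")
    ord_res = pcoa(dm, axes=2)
    ord_res.to_frame().to_csv(out / "pcoa_scores.csv")
    results["pcoa_percent_first_two"] = float(ord_res.percent_explained[:2].sum())

    # --- AMOVA on grain-type subpopulations (singleton bins cannot enter a
    # variance partition; dropped with a warning)
    groups = drop_singleton_groups(grain_type_grouping(ph))
    amova_res = amova(
        bm, groups, n_permutations=cfg.permutations,
        seed=cfg.seed + 1, grouping_name="grain_type",
    )
    write_tables([amova_res], out / "amova.csv")
    phi = pairwise_phi(bm, groups, n_permutations=cfg.permutations, seed=cfg.seed + 2)
    phi.to_csv(out / "pairwise_phi.csv", index=False)
    results["amova"] = amova_res

    # --- association and pyramiding
    assoc_rows = []
    assoc_by_trait: dict[str, list] = {t: [] for t in cfg.traits}
    for m in tab.marker_ids:
        for t in cfg.traits:
            try:
                res = allele_group_anova(
                    tab, ph, m, t, alpha=cfg.alpha, min_group_n=cfg.min_group_n
                )
            except ValueError as err:
                log.warning("association %s/%s skipped: %s", m, t, err)
                continue
            assoc_by_trait[t].append(res)
            assoc_rows.append(res.to_dict())
    pd.DataFrame(assoc_rows).to_csv(out / "associations.csv", index=False)
    rule = FavorableRule(
        trait="GL", mean_threshold=cfg.favorable_gl_threshold,
        alpha=cfg.alpha, min_group_n=cfg.min_group_n,
    )
    classified = classify_alleles(assoc_by_trait["GL"], rule)
    write_tables(classified, out / "allele_classification_GL.csv")
    pyramid = pyramid_summary(classified, assoc_by_trait["GL"], "GL", alpha=cfg.alpha)
    pyramid.to_frame().to_csv(out / "pyramiding_GL.csv", index=False)
    results["pyramiding_GL"] = pyramid

    manifest = {
        "package": "indelpanel",
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "n_accessions": tab.n_accessions,
        "n_markers": tab.n_markers,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
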
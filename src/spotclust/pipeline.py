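"""End-to-end orchestration: data to trees, support, stability, markers
and tree-concordance reports.

The pipeline mirrors the full comparative-proteomics workflow: ingest (or
simulate) a binary spot table, consolidate technical replicates if
present, cluster samples (UPGMA + AU support; NJ + ordinary bootstrap),
build species-level consensus or frequency proteomes and their trees,
assess clusterwise bootstrap stability, screen for taxon markers, and —
given a reference phylogeny — quantify proteome/phylogeny concordance.
All outputs are plain text (TSV / Newick / JSON) and byte-reproducible
for a fixed configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import spotclust
from spotclust.dissimilarity import distance_to_tsv, jaccard_binary, jaccard_quantitative
from spotclust.indval import TargetCluster, marker_table
from spotclust.spot_data import (
    ReplicateTable,
    SampleAnnotation,
    SpotMatrix,
    consensus_proteomes,
    consolidate_replicates,
    occurrence_frequency,
    read_spot_table,
)
from spotclust.stability import bootstrap_cluster_stability, stability_table
from spotclust.support import (
    DEFAULT_SCALES,
    annotate_tree_support,
    felsenstein_bootstrap_support,
    multiscale_bootstrap_support,
    support_table,
)
from spotclust.treecmp import compare_trees
from spotclust.trees import (
    midpoint_root,
    neighbor_joining,
    read_newick,
    upgma,
    write_newick,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run.

    Either ``spot_table``/``annotation`` paths or a synthetic
    ``generator`` config must be supplied. Bootstrap sizes default to a
    scaled-down 1,000 iterations so a paper-shaped matrix finishes in
    minutes; raise them for production runs.
    """

    spot_table: str | None = None
    annotation: str | None = None
    generator: "object | None" = None  # GeneratorConfig for synthetic input
    reference_tree: str | None = None  # Newick path or literal
    consensus_mode: str = "binary"  # binary | frequency
    group_by: str = "species"
    scales: tuple[float, ...] = DEFAULT_SCALES
    b_au: int = 1_000
    b_felsenstein: int = 1_000
    b_stability: int = 1_000
    k_range: tuple[int, ...] = tuple(range(2, 13))
    n_perm: int = 999
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "spotclust_out"

    def __post_init__(self):
        if self.consensus_mode not in ("binary", "frequency"):
            raise ValueError(f"unknown consensus mode {self.consensus_mode!r}")
        if self.generator is None and (self.spot_table is None or self.annotation is None):
            raise ValueError("need spot_table+annotation paths or a generator config")


def default_targets(ann: SampleAnnotation) -> list[TargetCluster]:
    """One two-group contrast per species plus one per non-trivial level
    of each higher-clade factor (genus, subgenus, species_group)."""
    targets = []
    species = ann.factor("species")
    for sp in sorted(set(species)):
        targets.append(TargetCluster(f"species:{sp}", ann.samples_where(species=sp)))
    n = len(ann.sample_ids)
    for fac in ("genus", "subgenus", "species_group"):
        if fac not in ann.factors:
            continue
        col = ann.factor(fac)
        for level in sorted(set(col.dropna()) - {""}):
            members = ann.samples_where(**{fac: level})
            n_species = len(set(species[s] for s in members))
            if n_species >= 2 and 0 < len(members) < n:
                targets.append(TargetCluster(f"{fac}:{level}", members))
    return targets


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``cfg.out_dir``.

    Returns a manifest dict (also written as ``manifest.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "spotclust",
        "version": spotclust.__version__,
        "seed": cfg.seed,
        "settings": {
            "consensus_mode": cfg.consensus_mode,
            "scales": list(cfg.scales),
            "b_au": cfg.b_au,
            "b_felsenstein": cfg.b_felsenstein,
            "b_stability": cfg.b_stability,
            "k_range": list(cfg.k_range),
            "n_perm": cfg.n_perm,
            "alpha": cfg.alpha,
        },
        "warnings": [],
    }

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # ---- ingest ----------------------------------------------------------
    current = stage("ingest")
    try:
        truth = None
        if cfg.generator is not None:
            from spotclust.synthetic_data import generate

            m, ann, truth = generate(cfg.generator)
            manifest["input"] = {"synthetic": True, "generator_seed": cfg.generator.seed}
        else:
            data, ann = read_spot_table(cfg.spot_table, cfg.annotation)
            if isinstance(data, ReplicateTable):
                n_before = len(data.spot_ids)
                m = consolidate_replicates(data)
                manifest["warnings"].append(
                    f"replicate consolidation dropped {n_before - m.n_spots} spots"
                )
            else:
                m = data
            manifest["input"] = {
                "synthetic": False,
                "spot_table": str(cfg.spot_table),
                "annotation": str(cfg.annotation),
            }
        manifest["n_spots"] = m.n_spots
        manifest["n_samples"] = m.n_samples

        # ---- sample-level clustering + support ---------------------------
        current = stage("support")
        au_records, sample_tree = multiscale_bootstrap_support(
            m, method="upgma", scales=cfg.scales, b=cfg.b_au, seed=cfg.seed
        )
        support_table(au_records).to_csv(out / "support_sample_upgma.tsv", sep="\t", index=False)
        write_newick(
            annotate_tree_support(sample_tree, au_records, value="au"),
            out / "sample_upgma_au.nwk",
        )
        bp_records, sample_nj = felsenstein_bootstrap_support(
            m, b=cfg.b_felsenstein, seed=cfg.seed, method="nj"
        )
        support_table(bp_records).to_csv(out / "support_sample_nj.tsv", sep="\t", index=False)
        write_newick(
            annotate_tree_support(midpoint_root(sample_nj), bp_records, value="bp"),
            out / "sample_nj_bp.nwk",
        )

        # ---- species-level trees -----------------------------------------
        current = stage("species trees")
        if cfg.consensus_mode == "binary":
            cons = consensus_proteomes(m, ann, cfg.group_by)
            d_sp = jaccard_binary(cons)
        else:
            freq = occurrence_frequency(m, ann, cfg.group_by)
            d_sp = jaccard_quantitative(freq)
        distance_to_tsv(d_sp, out / "species_distances.tsv")
        species_nj = neighbor_joining(d_sp)
        write_newick(species_nj, out / "species_nj.nwk")
        write_newick(upgma(d_sp), out / "species_upgma.nwk")
        manifest["n_groups"] = len(d_sp.ids)

        # ---- stability ----------------------------------------------------
        current = stage("stability")
        ks = [k for k in cfg.k_range if k <= m.n_samples]
        stab = bootstrap_cluster_stability(
            m, k_range=ks, b=cfg.b_stability, seed=cfg.seed
        )
        stability_table(stab).to_csv(out / "stability.tsv", sep="\t", index=False)

        # ---- markers ------------------------------------------------------
        current = stage("markers")
        targets = default_targets(ann)
        records, summary = marker_table(
            m, targets, alpha=cfg.alpha, n_perm=cfg.n_perm, seed=cfg.seed
        )
        records.to_csv(out / "markers.tsv", sep="\t", index=False)
        summary.to_csv(out / "marker_summary.tsv", sep="\t", index=False)
        manifest["marker_targets"] = [t.name for t in targets]

        # ---- tree comparison ---------------------------------------------
        current = stage("tree comparison")
        ref = None
        if cfg.reference_tree is not None:
            ref = read_newick(cfg.reference_tree)
        elif truth is not None:
            ref = truth.tree
        if ref is not None:
            report = compare_trees(species_nj, ref, alpha=cfg.alpha)
            (out / "tree_comparison.json").write_text(
                json.dumps(report.to_dict(), indent=2)
            )
            distance_to_tsv(report.norm_cophenetic_1, out / "norm_cophenetic_proteome.tsv")
            distance_to_tsv(report.norm_cophenetic_2, out / "norm_cophenetic_reference.tsv")
            manifest["tree_comparison"] = {
                "rf": report.rf,
                "nrf": report.nrf,
                "cophenetic_correlation": report.cophenetic_corr,
            }
    except Exception as err:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline failed at stage {current!r}: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
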
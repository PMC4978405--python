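"""Orchestration of the full workflow with logging, manifests and seeding.

Stages: differential expression -> network reconstruction -> hub
identification -> enrichment (on the differential genes and on the hubs)
-> permutation evaluation against a reference interactome (if supplied).
Conditions yielding fewer than two differential genes, or no edge passing
the probability threshold, end with an explicit "no network obtained"
status and the graph stages are skipped gracefully.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import TimecourseExperiment
from . import io as io_formats
from .diffexpr import differential_expression, select_differential
from .enrichment import fisher_enrichment
from .evaluate import permutation_test
from .network import graph_density, reconstruct_gan
from .topology import centralities, select_hubs

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_NO_NETWORK = "no network obtained"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    expression: Path | str | None = None
    sample_sheet: Path | str | None = None
    gene_sets: Path | str | None = None
    reference_network: Path | str | None = None
    control_label: str = "control"
    treatment_label: str = "treatment"
    df: int = 3
    fdr: float = 0.05
    prob_threshold: float = 0.95
    hub_fraction: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    network_samples: str = "treatment"
    outdir: Path | str = "splinegan_run"

    def validate(self) -> None:
        if self.expression is None or self.sample_sheet is None:
            raise ValueError("expression matrix and sample sheet are required")
        for path in (self.expression, self.sample_sheet, self.gene_sets, self.reference_network):
            if path is not None and not Path(path).exists():
                raise ValueError(f"input file not found: {path}")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if not 0 < self.prob_threshold <= 1:
            raise ValueError("prob_threshold must lie in (0, 1]")
        if not 0 < self.hub_fraction <= 1:
            raise ValueError("hub_fraction must lie in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.network_samples not in ("treatment", "all"):
            raise ValueError("network_samples must be 'treatment' or 'all'")


def run_pipeline(config: PipelineConfig, experiment: TimecourseExperiment | None = None) -> dict:
    """Execute the workflow and write all tables plus a manifest under ``outdir``.

    ``experiment`` may be passed directly (e.g. from a simulation) in which
    case the expression/sample-sheet paths are not read.  Returns the
    manifest dictionary; the same content is written to ``manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("splinegan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, experiment, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, experiment: TimecourseExperiment | None, outdir: Path) -> dict:
    ss = np.random.SeedSequence(config.seed)
    eval_rng = np.random.default_rng(ss.spawn(1)[0])

    manifest: dict = {
        "package_version": __version__,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(config).items()
        },
        "status": STATUS_OK,
    }

    if experiment is None:
        config.validate()
        try:
            experiment = io_formats.load_experiment(
                config.expression, config.sample_sheet,
                config.control_label, config.treatment_label,
            )
        except Exception as err:
            raise StageError("load", err) from err
    manifest["n_genes_total"] = experiment.n_genes
    manifest["n_samples"] = len(experiment.samples)

    # --- differential expression -----------------------------------------
    try:
        de = differential_expression(experiment, df=config.df, fdr=config.fdr)
        de.table.to_csv(outdir / "diffexpr.tsv", sep="\t", index=False, float_format="%.6g")
        de_genes = select_differential(de.table, fdr=config.fdr)
        io_formats.write_gene_list(de_genes, outdir / "de_genes.txt")
    except Exception as err:
        raise StageError("diffexpr", err) from err
    manifest["n_genes_tested"] = len(de.fits.genes)
    manifest["n_genes_dropped_missing"] = de.n_dropped_missing
    manifest["n_de_genes"] = len(de_genes)
    manifest["moderation"] = {
        "prior_df": de.moderation.prior_df, "prior_var": de.moderation.prior_var,
    }
    universe = de.fits.genes

    collection = None
    if config.gene_sets is not None:
        collection = io_formats.read_gmt(config.gene_sets)
        enr_de = fisher_enrichment(set(de_genes) & set(universe), universe, collection, config.fdr)
        enr_de.to_csv(outdir / "enrichment_de.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["n_enriched_pathways_de"] = int(enr_de["significant"].sum()) if not enr_de.empty else 0

    if len(de_genes) < 2:
        logger.info("fewer than 2 differential genes; %s", STATUS_NO_NETWORK)
        manifest["status"] = STATUS_NO_NETWORK
        _write_manifest(manifest, outdir)
        return manifest

    # --- network reconstruction -------------------------------------------
    try:
        gan, edge_table, pcor = reconstruct_gan(
            experiment, de_genes, samples=config.network_samples,
            threshold=config.prob_threshold,
        )
        edge_table.table.to_csv(outdir / "edge_table.tsv", sep="\t", index=False, float_format="%.6g")
        io_formats.write_graph(gan, outdir / "network_edges.tsv", "edge_list")
    except Exception as err:
        raise StageError("network", err) from err
    manifest["shrinkage_lambda"] = pcor.shrinkage_lambda
    manifest["mixture"] = {"eta0": edge_table.eta0, "kappa": edge_table.kappa}
    manifest["n_network_input_genes"] = gan.n_input_genes
    manifest["n_nodes"] = gan.n_nodes
    manifest["n_edges"] = gan.n_edges

    if gan.is_empty:
        logger.info("no edge reached probability %.2f; %s", config.prob_threshold, STATUS_NO_NETWORK)
        manifest["status"] = STATUS_NO_NETWORK
        _write_manifest(manifest, outdir)
        return manifest
    manifest["density"] = (
        graph_density(gan.n_nodes, gan.n_edges) if gan.n_nodes >= 2 else None
    )

    # --- hubs ---------------------------------------------------------------
    try:
        cent = centralities(gan)
        hubs = select_hubs(cent, fraction=config.hub_fraction)
        cent["is_hub"] = cent["gene"].isin(hubs)
        cent.to_csv(outdir / "centrality.tsv", sep="\t", index=False, float_format="%.6g")
        io_formats.write_gene_list(hubs, outdir / "hubs.txt")
    except Exception as err:
        raise StageError("hubs", err) from err
    manifest["n_hubs"] = len(hubs)

    if collection is not None:
        try:
            enr_hub = fisher_enrichment(set(hubs), universe, collection, config.fdr)
            enr_hub.to_csv(outdir / "enrichment_hubs.tsv", sep="\t", index=False, float_format="%.6g")
            manifest["n_enriched_pathways_hubs"] = (
                int(enr_hub["significant"].sum()) if not enr_hub.empty else 0
            )
        except Exception as err:
            raise StageError("enrichment", err) from err

    # --- evaluation ---------------------------------------------------------
    if config.reference_network is not None:
        try:
            reference = io_formats.read_reference_network(config.reference_network)
            result = permutation_test(
                gan, reference, n_permutations=config.n_permutations, rng=eval_rng,
            )
            evaluation = {
                "n_overlap_nodes": result.n_overlap_nodes,
                "observed_common_edges": result.observed_common_edges,
                "percent_common": result.percent_common,
                "p_value": result.p_value,
                "n_permutations": result.n_permutations,
                "significant": result.significant,
            }
            (outdir / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
            manifest["evaluation"] = evaluation
        except Exception as err:
            raise StageError("evaluation", err) from err

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
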
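"""End-to-end orchestration: scoring → RSS/CSI → state regulons → networks →
CoreScore → signature/survival, with exports for every stage.

Stages run in the workflow order of the analysis: (1) integration QC on the
embedding, (2) regulon activity scoring, (3) RSS and CSI with module
clustering, (4) state-specific regulon selection, (5) fate-network
construction with CoreScore, (6) patient-level signature and survival
association (skipped with a notice when no cohort is supplied). The full run
is deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import io as rio
from .aucell import score_gene_sets
from .config import PipelineConfig
from .errors import RegfateError
from .networks import assemble_fate_network, intersect_core_genes
from .qc import qc_scores
from .specificity import cluster_modules, compute_csi, compute_rss_matrix
from .states import identify_state_regulons, state_mean_zscore
from .survival import survival_analysis
from .synthetic import (SyntheticDesign, generate_fate_drivers,
                        generate_single_cell_dataset, generate_survival_cohort)

logger = logging.getLogger("regfate")


@dataclass
class PipelineResults:
    cell_table: pd.DataFrame | None = None
    activity: pd.DataFrame | None = None
    rss: pd.DataFrame | None = None
    csi: pd.DataFrame | None = None
    modules: pd.Series | None = None
    state_summary_z: pd.DataFrame | None = None
    state_calls: pd.DataFrame | None = None
    core_genes: dict = field(default_factory=dict)
    networks: dict = field(default_factory=dict)       # fate -> nx.DiGraph
    node_tables: dict = field(default_factory=dict)    # fate -> DataFrame
    signature: dict | None = None


def load_inputs(config: PipelineConfig):
    """Load and harmonise all declared inputs; see io.align_inputs for rules."""
    expression = rio.read_expression(config.expression_path)
    cell_table = rio.read_cell_table(config.cells_path)
    regulons = rio.read_gmt(config.regulons_path)
    expression, cell_table, regulons = rio.align_inputs(expression, cell_table, regulons)
    drivers = rio.read_drivers(config.drivers_path) if config.drivers_path else None
    cohort = None
    if config.cohort_expression_path and config.cohort_survival_path:
        cohort = rio.read_cohort(config.cohort_expression_path,
                                 config.cohort_survival_path)
    return expression, cell_table, regulons, drivers, cohort


def simulate_inputs(config: PipelineConfig):
    """Generate the synthetic inputs declared by the config's synthetic block."""
    params = dict(config.synthetic)
    params.setdefault("seed", config.seed)
    design = SyntheticDesign(**params)
    expression, cell_table, regulons, truth = generate_single_cell_dataset(design)
    drivers = generate_fate_drivers(truth, regulons,
                                    overlap_fraction=design.driver_overlap_fraction,
                                    seed=design.seed + 1,
                                    all_genes=list(expression.columns))
    signature_genes = truth.state_specific_regulons.get(config.signature_fate, [])
    cohort = generate_survival_cohort(
        n_patients=300, signature_genes=signature_genes or list(regulons)[:10],
        beta=truth.true_log_hazard, censoring_rate=0.3, seed=design.seed + 2)
    return expression, cell_table, regulons, drivers, cohort, truth


def run_pipeline(config: PipelineConfig, inputs=None) -> PipelineResults:
    """Execute all stages; ``inputs`` overrides file loading (used by simulate)."""
    if inputs is None:
        if config.expression_path:
            expression, cell_table, regulons, drivers, cohort = load_inputs(config)
        else:
            expression, cell_table, regulons, drivers, cohort, _ = simulate_inputs(config)
    else:
        expression, cell_table, regulons, drivers, cohort = inputs

    results = PipelineResults()
    stage = "integration_qc"
    try:
        logger.info("[%s] %d cells, k=%d", stage, len(cell_table), config.k_neighbors)
        results.cell_table = qc_scores(cell_table, k=config.k_neighbors)

        stage = "activity_scoring"
        logger.info("[%s] scoring %d regulons on %s matrix", stage, len(regulons),
                    expression.shape)
        results.activity = score_gene_sets(
            expression, regulons, top_fraction=config.aucell_top_fraction,
            seed=config.seed)
        variances = results.activity.var(axis=0, ddof=0)
        flat = variances[variances == 0].index
        if len(flat) > 0:
            logger.warning("dropping %d regulons with constant activity: %s",
                           len(flat), list(flat[:5]))
            results.activity = results.activity.drop(columns=flat)

        stage = "regulon_specificity"
        states_vec = results.cell_table["state"]
        results.rss = compute_rss_matrix(results.activity, states_vec,
                                         sqrt_jsd=config.sqrt_jsd)
        results.csi = compute_csi(results.activity)
        n_modules = min(config.n_modules, results.csi.shape[0])
        results.modules = cluster_modules(results.csi, n_modules=n_modules)

        stage = "state_activity"
        summary = state_mean_zscore(results.activity, states_vec, z_mode=config.z_mode)
        results.state_summary_z = summary.z
        results.state_calls = identify_state_regulons(
            summary, z_threshold=config.z_threshold, alpha=config.wilcoxon_alpha)
        if not results.state_calls["selected"].any():
            logger.warning("state-regulon table is empty at z_threshold=%g (%s mode)",
                           config.z_threshold, config.z_mode)

        stage = "fate_networks"
        if drivers is not None:
            results.core_genes = intersect_core_genes(
                results.state_calls, regulons, drivers,
                fdr_threshold=config.fdr_threshold)
            for fate, core in sorted(results.core_genes.items()):
                graph, nodes = assemble_fate_network(
                    fate, core, results.state_calls, regulons, results.modules,
                    core_fraction=config.core_fraction,
                    collapse_degree=config.collapse_degree)
                results.networks[fate] = graph
                results.node_tables[fate] = nodes
                logger.info("[%s] %s: %d nodes, %d edges", stage, fate,
                            graph.number_of_nodes(), graph.number_of_edges())
        else:
            logger.info("[%s] no driver table supplied; stage skipped", stage)

        stage = "clinical_signature"
        if cohort is not None:
            cohort_expr, cohort_surv = cohort
            genes = _signature_genes(results, config)
            if genes:
                results.signature = survival_analysis(cohort_expr, cohort_surv, genes)
            else:
                logger.warning("[%s] no signature genes available; stage skipped", stage)
        else:
            logger.info("[%s] no cohort supplied; stage skipped", stage)
    except RegfateError as exc:
        raise RegfateError(f"stage {stage} failed: {exc}") from exc
    return results


def _signature_genes(results: PipelineResults, config: PipelineConfig) -> list[str]:
    """TF nodes of the signature fate's network, falling back to its selected regulons."""
    fate = config.signature_fate
    graph = results.networks.get(fate)
    if graph is not None and graph.number_of_nodes() > 0:
        return sorted(v for v in graph.nodes if graph.nodes[v].get("kind") == "TF")
    calls = results.state_calls
    if calls is not None:
        return sorted(calls.loc[(calls["state"] == fate) & calls["selected"], "regulon"])
    return []


def export_results(results: PipelineResults, outdir: str | Path,
                   config: PipelineConfig | None = None) -> list[Path]:
    """Write every computed artifact as TSV/GraphML; byte-identical on re-export."""
    outdir = rio.ensure_writable(outdir)
    written: list[Path] = []

    def emit(frame, name, index=True):
        path = outdir / name
        rio.write_table(frame, path, index=index)
        written.append(path)

    if results.cell_table is not None:
        emit(results.cell_table, "cell_table_qc.tsv")
    if results.activity is not None:
        emit(results.activity, "activity_matrix.tsv")
    if results.rss is not None:
        emit(results.rss, "rss_matrix.tsv")
    if results.csi is not None:
        emit(results.csi, "csi_matrix.tsv")
    if results.modules is not None:
        emit(results.modules.to_frame(), "regulon_modules.tsv")
    if results.state_summary_z is not None:
        emit(results.state_summary_z, "state_zscore_matrix.tsv")
    if results.state_calls is not None:
        emit(results.state_calls, "state_regulon_calls.tsv", index=False)
    for fate, graph in sorted(results.networks.items()):
        base = outdir / f"network_{fate}"
        rio.write_network(graph, base)
        written.extend([base.with_suffix(".graphml"), base.with_suffix(".edges.tsv")])
        emit(results.node_tables[fate], f"network_{fate}_nodes.tsv")
    if results.signature is not None:
        sig = results.signature
        emit(sig["scores"].to_frame().join(sig["quartiles"]), "signature_scores.tsv")
        summary_rows = [
            ("OS", "univariable", "signature", sig["cox_univariable"].loc["signature", "HR"],
             sig["cox_univariable"].loc["signature", "HR_lower95"],
             sig["cox_univariable"].loc["signature", "HR_upper95"],
             sig["cox_univariable"].loc["signature", "p"]),
        ]
        for var in sig["cox_multivariable"].index:
            row = sig["cox_multivariable"].loc[var]
            summary_rows.append(("OS", "multivariable", var, row["HR"],
                                 row["HR_lower95"], row["HR_upper95"], row["p"]))
        summary_rows.append(("OS", "logrank_Q4_vs_Q1", "signature",
                             sig["logrank_chi2"], float("nan"), float("nan"),
                             sig["logrank_p"]))
        summary_rows.append(("stage", "kruskal_wallis", "signature",
                             sig["stage_statistic"], float("nan"), float("nan"),
                             sig["stage_p"]))
        emit(pd.DataFrame(summary_rows,
                          columns=["endpoint", "model", "variable", "HR_or_stat",
                                   "lower95", "upper95", "p"]),
             "survival_summary.tsv", index=False)

    if config is not None:
        # outdir is a location, not an analysis parameter: leaving it out keeps
        # manifests identical across runs of the same analysis
        manifest = {
            "config": {k: v for k, v in config.to_dict().items() if k != "outdir"},
            "seed": config.seed,
            "networkx": nx.__version__,
            "pandas": pd.__version__,
        }
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(manifest["config"], sort_keys=True, default=str).encode()
        ).hexdigest()
        path = outdir / "run_manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        written.append(path)
    return written
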
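"""Fate-specific regulatory networks, topology metrics and CoreScore.

For each terminal fate, the targets of its state-specific regulons are
intersected with that fate's driver genes (FDR below threshold) to give a core
gene set; the network has a directed edge TF → g for every selected regulon TF
and surviving target g. Five node topology metrics (in-degree, out-degree,
betweenness, closeness, clustering coefficient) are z-scored across nodes and
averaged with equal weights into a composite CoreScore; the top
``ceil(core_fraction × n_nodes)`` nodes (default 30%) are flagged as core
regulatory nodes.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("regfate")

DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_CORE_FRACTION = 0.30
METRIC_COLUMNS = ["in_degree", "out_degree", "betweenness", "closeness", "clustering"]


def intersect_core_genes(state_calls: pd.DataFrame, regulons: dict[str, list[str]],
                         drivers: pd.DataFrame,
                         fdr_threshold: float = DEFAULT_FDR_THRESHOLD) -> dict[str, set[str]]:
    """Per-fate core gene sets: selected-regulon targets ∩ sub-threshold drivers.

    TF genes themselves are included when they appear in the fate's driver set.
    A fate with no selected regulons yields an empty set with a warning.
    """
    selected = state_calls[state_calls["selected"]]
    fates = sorted(set(state_calls["state"]) | set(drivers["fate"]))
    out: dict[str, set[str]] = {}
    for fate in fates:
        tfs = selected.loc[selected["state"] == fate, "regulon"].tolist()
        if not tfs:
            logger.warning("fate %s has no selected regulons; core set empty", fate)
            out[fate] = set()
            continue
        candidates = {g for tf in tfs for g in regulons.get(tf, [])} | set(tfs)
        fate_drivers = drivers[(drivers["fate"] == fate) & (drivers["fdr"] < fdr_threshold)]
        out[fate] = candidates & set(fate_drivers["gene"])
    return out


def build_network(fate: str, core_genes: set[str], state_calls: pd.DataFrame,
                  regulons: dict[str, list[str]],
                  modules: pd.Series | None = None) -> nx.DiGraph:
    """Directed TF → target graph restricted to the fate's core gene set.

    Edges run from each selected regulon TF to its targets inside the core
    set (TF–TF edges arise when one TF is in another's target list and in the
    core set); duplicate (TF, target) pairs collapse; TFs with no surviving
    targets are dropped. Node attributes: kind ("TF" or "target") and module
    (from the regulon module assignment; targets get their module later, from
    the highest-CoreScore regulating TF — see ``assign_target_modules``).
    """
    graph = nx.DiGraph(fate=fate)
    selected = state_calls[(state_calls["selected"]) & (state_calls["state"] == fate)]
    tfs = list(selected["regulon"])
    for tf in tfs:
        targets = sorted(set(regulons.get(tf, [])) & core_genes - {tf})
        if not targets:
            continue
        module = str(modules[tf]) if modules is not None and tf in modules.index else ""
        graph.add_node(tf, kind="TF", module=module)
        for g in targets:
            if g not in graph:
                graph.add_node(g, kind="TF" if g in tfs else "target", module="")
            graph.add_edge(tf, g)
    return graph


def topology_metrics(graph: nx.DiGraph) -> pd.DataFrame:
    """Per-node in/out-degree, betweenness, closeness and clustering coefficient.

    Betweenness uses exact shortest-path counting on the directed graph,
    normalised by (n−1)(n−2); closeness uses incoming shortest paths with the
    Wasserman–Faust disconnected-component scaling (0 for unreachable nodes);
    the clustering coefficient is computed on the undirected projection.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("network is empty")
    nodes = list(graph.nodes)
    if len(nodes) == 1:
        return pd.DataFrame(0.0, index=pd.Index(nodes, name="node"), columns=METRIC_COLUMNS)
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    closeness = nx.closeness_centrality(graph, wf_improved=True)
    clustering = nx.clustering(graph.to_undirected())
    table = pd.DataFrame(
        {
            "in_degree": [graph.in_degree(v) for v in nodes],
            "out_degree": [graph.out_degree(v) for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "clustering": [clustering[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return table


def core_score(metrics: pd.DataFrame, core_fraction: float = DEFAULT_CORE_FRACTION,
               collapse_degree: bool = False) -> pd.DataFrame:
    """Composite CoreScore and core flags.

    Each metric is z-scored across nodes (population SD; a zero-SD metric
    contributes all-zero z) and the CoreScore is their unweighted mean.
    ``collapse_degree`` merges in/out-degree into a single total-degree metric
    (the 4-metric variant). Core nodes are the top ceil(core_fraction × n) by
    CoreScore, ties broken lexicographically by node name.
    """
    if metrics.shape[0] < 1:
        raise ValidationError("metric table is empty")
    if not (0.0 < core_fraction <= 1.0):
        raise ValidationError(f"core_fraction must lie in (0, 1], got {core_fraction!r}")
    table = metrics.copy()
    if collapse_degree:
        cols = pd.DataFrame({"degree": table["in_degree"] + table["out_degree"]})
        for c in ("betweenness", "closeness", "clustering"):
            cols[c] = table[c]
    else:
        cols = table[METRIC_COLUMNS]

    values = cols.to_numpy(dtype=float)
    mu = values.mean(axis=0, keepdims=True)
    sd = values.std(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (values - mu) / sd, 0.0)
    table["corescore"] = z.mean(axis=1)

    n = table.shape[0]
    n_core = math.ceil(core_fraction * n)
    # deterministic ordering: CoreScore descending, node name ascending on ties
    order = table.assign(_name=table.index.astype(str)) \
                 .sort_values(["corescore", "_name"], ascending=[False, True], kind="stable")
    core_nodes = set(order.index[:n_core])
    if np.allclose(table["corescore"], 0.0):
        logger.warning("degenerate CoreScore: all nodes identical; core set is the "
                       "first %d node names lexicographically", n_core)
    table["core"] = [v in core_nodes for v in table.index]
    return table


def assign_target_modules(graph: nx.DiGraph, scored: pd.DataFrame) -> None:
    """Give each target node the module of its highest-CoreScore regulating TF."""
    for v in graph.nodes:
        if graph.nodes[v].get("module"):
            continue
        regulators = [u for u in graph.predecessors(v)
                      if graph.nodes[u].get("module")]
        if regulators:
            best = max(regulators, key=lambda u: (scored.loc[u, "corescore"], u))
            graph.nodes[v]["module"] = graph.nodes[best]["module"]


def assemble_fate_network(fate: str, core_genes: set[str], state_calls: pd.DataFrame,
                          regulons: dict[str, list[str]],
                          modules: pd.Series | None = None,
                          core_fraction: float = DEFAULT_CORE_FRACTION,
                          collapse_degree: bool = False,
                          core_tfs_only: bool = False) -> tuple[nx.DiGraph, pd.DataFrame]:
    """Build the fate network, compute metrics + CoreScore, annotate nodes.

    Returns (graph, node table). An empty core set yields an empty graph and
    an empty node table (valid, not an error). Target genes are eligible as
    core regulatory nodes by default; ``core_tfs_only`` restricts the top-30%
    cut to TF nodes (useful on near-bipartite networks, where incoming-path
    metrics favour targets).
    """
    graph = build_network(fate, core_genes, state_calls, regulons, modules)
    if graph.number_of_nodes() == 0:
        return graph, pd.DataFrame(columns=METRIC_COLUMNS + ["corescore", "core"])
    scored = core_score(topology_metrics(graph), core_fraction=core_fraction,
                        collapse_degree=collapse_degree)
    if core_tfs_only:
        tfs = [v for v in scored.index if graph.nodes[v]["kind"] == "TF"]
        n_core = math.ceil(core_fraction * len(tfs))
        ranked = scored.loc[tfs].assign(_name=lambda t: t.index.astype(str)) \
            .sort_values(["corescore", "_name"], ascending=[False, True], kind="stable")
        core_nodes = set(ranked.index[:n_core])
        scored["core"] = [v in core_nodes for v in scored.index]
    assign_target_modules(graph, scored)
    for v in graph.nodes:
        graph.nodes[v]["corescore"] = float(scored.loc[v, "corescore"])
        graph.nodes[v]["core"] = bool(scored.loc[v, "core"])
        for m in METRIC_COLUMNS:
            graph.nodes[v][m] = float(scored.loc[v, m])
    scored["kind"] = [graph.nodes[v]["kind"] for v in scored.index]
    scored["module"] = [graph.nodes[v]["module"] for v in scored.index]
    return graph, scored
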
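"""Synthetic single-cell, fate-driver and survival-cohort generators with planted ground truth.

Every downstream stage of the pipeline (activity scoring, specificity metrics,
state-specific regulon selection, fate networks, survival signatures) can be
exercised against data whose answers are known by construction: which regulons
are active in which terminal state, which TFs are hubs, which genes drive each
fate, and the true log-hazard of the planted survival signature.

The expression model is deliberately simple — a log-normal baseline with a
multiplicative log-normal shift on planted regulon targets in their home state —
because every downstream operation is rank- or mean-based and does not depend on
a realistic count model.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

#: default terminal-state proportions; deliberately unequal so that group-size
#: sensitive normalisation choices are stressed.
DEFAULT_STATE_PROPORTIONS = (0.40, 0.35, 0.25)

#: multiplicative log-shift applied to planted regulon targets in their home
#: state; large enough that, at zero activity noise, a planted regulon's
#: recovery-curve score in its home state strictly dominates all other states.
PLANTED_LOG_SHIFT = 2.0


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of the synthetic single-cell dataset.

    Defaults describe the standard study design used throughout the test
    suite: 3,000 cells, 1,000 genes, three terminal states (fate0/fate1/fate2)
    in proportions (0.40, 0.35, 0.25), 100 regulons of which 10 per state are
    planted as state-specific.
    """

    n_cells: int = 3000
    n_genes: int = 1000
    n_states: int = 3
    n_samples: int = 4
    n_tissues: int = 2
    n_regulons: int = 100
    n_state_specific_per_state: int = 10
    regulon_size_range: tuple[int, int] = (10, 30)
    activity_noise_sd: float = 0.2
    driver_overlap_fraction: float = 0.8
    seed: int = 0
    state_proportions: tuple[float, ...] | None = None
    confounded_batches: bool = False

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "n_states", "n_samples",
                     "n_tissues", "n_regulons", "n_state_specific_per_state"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value <= 0:
                raise ParameterError(f"{name} must be a positive integer, got {value!r}")
        lo, hi = self.regulon_size_range
        if lo <= 0 or hi < lo:
            raise ParameterError(
                f"regulon_size_range must be a non-empty positive interval, got {self.regulon_size_range!r}")
        if hi >= self.n_genes:
            raise ParameterError("regulon_size_range upper bound must be below n_genes")
        if not (self.activity_noise_sd >= 0 and math.isfinite(self.activity_noise_sd)):
            raise ParameterError(f"activity_noise_sd must be a finite non-negative real, got {self.activity_noise_sd!r}")
        if not (0.0 <= self.driver_overlap_fraction <= 1.0):
            raise ParameterError(
                f"driver_overlap_fraction must lie in [0, 1], got {self.driver_overlap_fraction!r}")
        if self.n_state_specific_per_state * self.n_states > self.n_regulons:
            raise ParameterError(
                "n_state_specific_per_state × n_states exceeds n_regulons "
                f"({self.n_state_specific_per_state} × {self.n_states} > {self.n_regulons})")
        if self.state_proportions is not None:
            props = self.state_proportions
            if len(props) != self.n_states:
                raise ParameterError("state_proportions length must equal n_states")
            if any(p <= 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
                raise ParameterError("state_proportions must be positive and sum to 1")

    @property
    def proportions(self) -> tuple[float, ...]:
        if self.state_proportions is not None:
            return self.state_proportions
        if self.n_states == len(DEFAULT_STATE_PROPORTIONS):
            return DEFAULT_STATE_PROPORTIONS
        return tuple([1.0 / self.n_states] * self.n_states)

    def state_names(self) -> list[str]:
        return [f"fate{s}" for s in range(self.n_states)]


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring downstream."""

    state_specific_regulons: dict[str, list[str]]
    hub_tfs: dict[str, list[str]]
    true_log_hazard: float = 0.6
    regulon_states: dict[str, str] = field(default_factory=dict)

    def planted_regulons(self) -> set[str]:
        return {r for regs in self.state_specific_regulons.values() for r in regs}


def _assign_states(design: SyntheticDesign) -> np.ndarray:
    """Deterministic block assignment matching the design proportions exactly."""
    counts = [int(round(p * design.n_cells)) for p in design.proportions]
    counts[-1] = design.n_cells - sum(counts[:-1])
    labels = np.repeat(np.arange(design.n_states), counts)
    return labels


def generate_single_cell_dataset(
    design: SyntheticDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]], GroundTruth]:
    """Generate (expression, cell table, regulons, ground truth).

    Expression is cells × genes (non-negative reals, rounded to 4 decimals).
    The cell table carries sample, tissue, state and 2-D embedding columns.
    Regulons map TF gene names to target-gene lists; the first
    ``n_state_specific_per_state × n_states`` regulons are planted as
    state-specific (their targets and TF co-upregulated in the home state).
    Deterministic for a fixed design (including its seed).
    """
    rng = np.random.default_rng(design.seed)
    n_c, n_g = design.n_cells, design.n_genes

    genes = [f"g{j:04d}" for j in range(n_g)]
    cells = [f"cell{i:05d}" for i in range(n_c)]
    tf_genes = genes[: design.n_regulons]
    non_tf = genes[design.n_regulons:]

    # --- regulon definitions -------------------------------------------------
    lo, hi = design.regulon_size_range
    regulons: dict[str, list[str]] = {}
    n_planted = design.n_state_specific_per_state * design.n_states
    # planted regulons draw mutually disjoint target sets, and background
    # regulons avoid planted targets where possible, so a target upregulated
    # in one state is never wired to a decoy or another state's regulon
    # (clean, recoverable ground truth)
    disjoint_pool = list(non_tf)
    for r, tf in enumerate(tf_genes):
        # hubs (first planted regulon of each state) get the largest target sets
        is_hub = r < n_planted and (r % design.n_state_specific_per_state) == 0
        size = hi if is_hub else int(rng.integers(lo, hi + 1))
        if r < n_planted and len(disjoint_pool) >= size:
            targets = list(rng.choice(disjoint_pool, size=size, replace=False))
            disjoint_pool = [g for g in disjoint_pool if g not in set(targets)]
        else:
            pool = list(disjoint_pool) if len(disjoint_pool) >= size else list(non_tf)
            # small chance of wiring a background TF into the target list
            # (TF->TF edges in downstream networks)
            if rng.random() < 0.3:
                decoy_tfs = [t for t in tf_genes[n_planted:] if t != tf]
                if len(decoy_tfs) >= 2:
                    pool = pool + list(rng.choice(decoy_tfs, size=2, replace=False))
            targets = list(rng.choice(pool, size=min(size, len(pool)), replace=False))
        regulons[tf] = sorted(targets)

    state_names = design.state_names()
    planted: dict[str, list[str]] = {s: [] for s in state_names}
    regulon_states: dict[str, str] = {}
    for r in range(n_planted):
        state = state_names[r // design.n_state_specific_per_state]
        planted[state].append(tf_genes[r])
        regulon_states[tf_genes[r]] = state
    hub_tfs = {s: [planted[s][0]] for s in state_names if planted[s]}

    # --- expression ----------------------------------------------------------
    state_idx = _assign_states(design)
    gene_mu = rng.normal(0.0, 0.5, size=n_g)
    expr = rng.lognormal(mean=gene_mu[None, :], sigma=0.4, size=(n_c, n_g))

    gene_pos = {g: j for j, g in enumerate(genes)}
    for s, state in enumerate(state_names):
        rows = np.flatnonzero(state_idx == s)
        cols = sorted({gene_pos[g]
                       for tf in planted[state]
                       for g in regulons[tf] + [tf]})
        if not cols:
            continue
        noise = rng.normal(0.0, design.activity_noise_sd, size=(rows.size, len(cols)))
        expr[np.ix_(rows, cols)] *= np.exp(PLANTED_LOG_SHIFT + noise)
    expr = np.round(expr, 4)

    expression = pd.DataFrame(expr, index=cells, columns=genes)

    # --- cell table ----------------------------------------------------------
    if design.confounded_batches:
        samples = [f"S{state_idx[i] % design.n_samples}" for i in range(n_c)]
    else:
        samples = [f"S{k}" for k in rng.integers(0, design.n_samples, size=n_c)]
    tissues = [f"T{state_idx[i] % design.n_tissues}" for i in range(n_c)]

    angles = 2.0 * np.pi * state_idx / design.n_states
    centers = 10.0 * np.column_stack([np.cos(angles), np.sin(angles)])
    coords = centers + rng.normal(0.0, 1.0, size=(n_c, 2))

    cell_table = pd.DataFrame(
        {
            "cell_id": cells,
            "sample": samples,
            "tissue": tissues,
            "state": [state_names[s] for s in state_idx],
            "embedding_1": np.round(coords[:, 0], 6),
            "embedding_2": np.round(coords[:, 1], 6),
        }
    ).set_index("cell_id")

    truth = GroundTruth(
        state_specific_regulons=planted,
        hub_tfs=hub_tfs,
        regulon_states=regulon_states,
    )
    return expression, cell_table, regulons, truth


def generate_fate_drivers(
    ground_truth: GroundTruth,
    regulons: dict[str, list[str]],
    fdr_range: tuple[float, float] = (0.001, 0.049),
    overlap_fraction: float = 0.8,
    n_decoys_per_fate: int = 40,
    seed: int = 0,
    all_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Emit a per-fate fate-driving gene table (gene, fate, fdr).

    For each fate, ``overlap_fraction`` of the planted regulons' target genes
    (plus the planted TF genes themselves, so TFs can appear in the driver set)
    receive an FDR drawn from ``fdr_range``; decoy drivers receive FDR ≥ 0.05.
    """
    if not regulons:
        raise InputError("regulon set is empty")
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ParameterError(f"overlap_fraction must lie in [0, 1], got {overlap_fraction!r}")
    lo, hi = fdr_range
    if not (0.0 < lo <= hi < 0.05):
        raise ParameterError(f"fdr_range must lie inside (0, 0.05), got {fdr_range!r}")

    rng = np.random.default_rng(seed)
    regulon_gene_pool = {g for tf, tg in regulons.items() for g in tg} | set(regulons)
    if all_genes is None:
        all_genes = sorted(regulon_gene_pool)

    rows: list[tuple[str, str, float]] = []
    for fate in sorted(ground_truth.state_specific_regulons):
        tfs = ground_truth.state_specific_regulons[fate]
        pool = sorted({g for tf in tfs for g in regulons[tf]} | set(tfs))
        n_true = int(round(overlap_fraction * len(pool)))
        chosen = sorted(rng.choice(pool, size=n_true, replace=False)) if n_true else []
        for g in chosen:
            rows.append((g, fate, float(rng.uniform(lo, hi))))
        # decoys: genes outside the planted pool, or planted genes with FDR >= 0.05
        outside = [g for g in all_genes if g not in pool]
        n_decoy = min(n_decoys_per_fate, len(outside))
        if n_decoy:
            for g in rng.choice(outside, size=n_decoy, replace=False):
                rows.append((str(g), fate, float(rng.uniform(0.05, 1.0))))
        for g in pool:
            if g not in chosen:
                rows.append((g, fate, float(rng.uniform(0.05, 1.0))))
    return pd.DataFrame(rows, columns=["gene", "fate", "fdr"])


def generate_survival_cohort(
    n_patients: int,
    signature_genes: list[str],
    beta: float = 0.6,
    censoring_rate: float = 0.3,
    seed: int = 0,
    n_noise_genes: int = 50,
    baseline_hazard: float = 1.0 / 1000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a bulk cohort (patients × genes) with a planted survival effect.

    A latent per-patient score z ~ N(0, 1) drives both the signature genes
    (expression = z + noise) and the hazard h0·exp(beta·z); censoring is
    independent exponential tuned to the requested rate. Returns
    (expression, survival) with survival columns time, event, stage, age.
    """
    if n_patients <= 1:
        raise ParameterError(f"n_patients must exceed 1, got {n_patients!r}")
    if not math.isfinite(beta):
        raise ParameterError(f"beta must be finite, got {beta!r}")
    if not (0.0 <= censoring_rate < 1.0):
        raise ParameterError(f"censoring_rate must lie in [0, 1), got {censoring_rate!r}")
    if not signature_genes:
        raise InputError("signature_genes is empty")

    rng = np.random.default_rng(seed)
    patients = [f"patient{i:04d}" for i in range(n_patients)]
    z = rng.normal(0.0, 1.0, size=n_patients)

    cols: dict[str, np.ndarray] = {}
    for g in signature_genes:
        cols[g] = z + rng.normal(0.0, 0.5, size=n_patients)
    for j in range(n_noise_genes):
        cols[f"noise{j:03d}"] = rng.normal(0.0, 1.0, size=n_patients)
    expression = pd.DataFrame(cols, index=patients)

    rate = baseline_hazard * np.exp(beta * z)
    event_time = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        c_rate = baseline_hazard * censoring_rate / (1.0 - censoring_rate)
        censor_time = rng.exponential(1.0 / c_rate, size=n_patients)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time = event_time
        event = np.ones(n_patients, dtype=int)

    survival = pd.DataFrame(
        {
            "time": np.round(np.maximum(time, 1e-6), 4),
            "event": event,
            "stage": rng.choice(["I", "II", "III", "IV"], size=n_patients,
                                p=[0.5, 0.25, 0.15, 0.10]),
            "age": np.round(rng.normal(60.0, 10.0, size=n_patients), 1),
        },
        index=pd.Index(patients, name="patient_id"),
    )
    return expression, survival


def generate_hub_network(
    n_nodes: int = 40,
    n_hubs: int = 2,
    seed: int = 0,
    background_out_degree: int = 2,
) -> tuple[nx.DiGraph, set[str]]:
    """A directed TF→target network with planted high-connectivity hubs.

    Hubs get top-decile out-degree (edges to a large fraction of nodes) and
    sit on many shortest paths; background TFs get a few random edges.
    Returns (graph, hub node names).
    """
    if n_nodes < n_hubs + 4:
        raise ParameterError("n_nodes too small for the requested hubs")
    rng = np.random.default_rng(seed)
    nodes = [f"n{j:03d}" for j in range(n_nodes)]
    hubs = set(nodes[:n_hubs])
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for h in sorted(hubs):
        targets = rng.choice([v for v in nodes if v != h],
                             size=max(3, int(0.6 * n_nodes)), replace=False)
        for t in targets:
            g.add_edge(h, str(t))
    for v in nodes[n_hubs:]:
        # sparse background wiring; half the nodes also feed into a hub, so
        # hubs sit on many shortest paths (high betweenness), not just fan out
        targets = list(rng.choice([w for w in nodes if w != v],
                                  size=background_out_degree, replace=False))
        if rng.random() < 0.5:
            targets.append(str(rng.choice(sorted(hubs))))
        for t in targets:
            g.add_edge(v, str(t))
    return g, hubs


def design_to_dict(design: SyntheticDesign) -> dict:
    return dataclasses.asdict(design)
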
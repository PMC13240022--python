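"""Rank-based gene-set activity scoring (AUC of the recovery curve).

For each cell, genes are ordered by decreasing expression; a gene set's score
is the area under its cumulative recovery curve over the top ``T = floor(
top_fraction × n_genes)`` ranks, normalised by the maximum achievable area
(all set genes packed at the very top). Scores are therefore rank-based,
bounded in [0, 1], and invariant to any monotone transformation of a cell's
expression values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("regfate")

DEFAULT_TOP_FRACTION = 0.05


@dataclass
class GeneRanking:
    """Per-cell gene ordering by decreasing expression.

    ``order[c]`` is the permutation of gene indices for cell ``c`` (best gene
    first); ``rank[c, j]`` is the 1-based rank of gene ``j`` in cell ``c``.
    Ties are broken by a single seeded random key over genes (``tie_key``),
    recorded so the ranking can be reproduced exactly.
    """

    genes: list[str]
    order: np.ndarray        # (n_cells, n_genes) int
    rank: np.ndarray         # (n_cells, n_genes) int, 1-based
    tie_key: np.ndarray      # (n_genes,) the seeded tie-breaking permutation
    seed: int

    @property
    def n_cells(self) -> int:
        return self.order.shape[0]

    @property
    def n_genes(self) -> int:
        return self.order.shape[1]


def rank_genes_per_cell(expression: pd.DataFrame, seed: int = 0) -> GeneRanking:
    """Rank genes by decreasing expression within each cell.

    Ties (including all-zero cells) are resolved by a seeded random
    permutation of gene indices shared across cells, so two cells with
    identical expression vectors always receive identical rankings.
    """
    if expression.shape[1] == 0:
        raise ValidationError("expression matrix has zero genes")
    values = np.asarray(expression.values, dtype=float)
    if np.any(values < 0):
        raise ValidationError("expression must be non-negative")

    rng = np.random.default_rng(seed)
    tie_key = rng.permutation(expression.shape[1])

    # lexsort: primary key -expression (descending), secondary the seeded key
    order = np.lexsort((np.broadcast_to(tie_key, values.shape), -values), axis=1)
    rank = np.empty_like(order)
    row_idx = np.arange(values.shape[0])[:, None]
    rank[row_idx, order] = np.arange(1, values.shape[1] + 1)[None, :]
    return GeneRanking(genes=list(expression.columns), order=order, rank=rank,
                       tie_key=tie_key, seed=seed)


def aucell_score(
    ranking: GeneRanking,
    gene_set: list[str],
    top_fraction: float = DEFAULT_TOP_FRACTION,
    normalize_max: bool = True,
) -> np.ndarray:
    """Score one gene set for every cell; returns an array in [0, 1].

    The recovery curve counts cumulative gene-set hits over ranks 1..T,
    T = floor(top_fraction × n_genes). With ``normalize_max`` (default) the
    area is divided by the maximum achievable area for (|set|, T) so a set
    packed at the top scores exactly 1; otherwise by T·|set|.

    A gene set with no genes in the ranking yields NaN scores with a warning
    (missing, not zero).
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValidationError(f"top_fraction must lie in (0, 1], got {top_fraction!r}")
    n_genes = ranking.n_genes
    t = int(np.floor(top_fraction * n_genes))
    if t < 1:
        raise ValidationError("top_fraction too small: floor(top_fraction × n_genes) < 1")

    pos = {g: j for j, g in enumerate(ranking.genes)}
    idx = [pos[g] for g in dict.fromkeys(gene_set) if g in pos]
    if not idx:
        warnings.warn("gene set has no genes in the ranking; scored as missing")
        return np.full(ranking.n_cells, np.nan)
    s = len(idx)

    ranks = ranking.rank[:, idx]                     # (cells, s), 1-based
    inside = ranks <= t
    # area under the step curve = sum over hits of (T - rank + 1)
    area = np.where(inside, t - ranks + 1, 0).sum(axis=1).astype(float)
    if normalize_max:
        # all hits packed at the top: sum_{r=1..T} min(r, s)
        if s >= t:
            max_area = t * (t + 1) / 2.0
        else:
            max_area = s * (s + 1) / 2.0 + s * (t - s)
    else:
        max_area = float(t * s)
    return area / max_area


def score_gene_sets(
    expression: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    top_fraction: float = DEFAULT_TOP_FRACTION,
    seed: int = 0,
    normalize_max: bool = True,
) -> pd.DataFrame:
    """Activity matrix (cells × set names) for a collection of gene sets."""
    names = list(gene_sets)
    if len(set(names)) != len(names):
        raise ValidationError("duplicate gene-set names")
    ranking = rank_genes_per_cell(expression, seed=seed)
    cols = {}
    for name in names:
        scores = aucell_score(ranking, gene_sets[name], top_fraction=top_fraction,
                              normalize_max=normalize_max)
        if np.all(np.isnan(scores)):
            logger.warning("gene set %s has no genes in the matrix; column omitted", name)
            continue
        cols[name] = scores
    out = pd.DataFrame(cols, index=expression.index)
    out.attrs["top_fraction"] = top_fraction
    return out


def score_programs(
    expression: pd.DataFrame,
    programs: dict[str, list[str]],
    cell_table: pd.DataFrame | None = None,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    seed: int = 0,
) -> pd.DataFrame:
    """Score differentiation programs (e.g. HB1, HB2, FH1, FH2, AH) per cell.

    When the cell table marks unassigned cells (state is NA or "unassigned"),
    scoring is restricted to cells confidently assigned to a terminal state.
    """
    expr = expression
    if cell_table is not None and "state" in cell_table.columns:
        state = cell_table.loc[expression.index, "state"]
        assigned = state.notna() & (state.astype(str) != "unassigned")
        if not assigned.all():
            logger.info("restricting program scoring to %d/%d assigned cells",
                        int(assigned.sum()), len(assigned))
            expr = expression.loc[assigned.values]
    return score_gene_sets(expr, programs, top_fraction=top_fraction, seed=seed)
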
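"""State-level activity summaries and state-specific regulon selection.

A regulon is called state-specific when its activity is significantly elevated
in one terminal state compared with the others: z above a threshold (default
1.5) and one-sided Wilcoxon rank-sum p below alpha (default 0.05) for the
state-versus-rest comparison of per-cell activity.

Two z conventions are exposed, because the axis of standardisation changes
what the threshold can select:

- ``states``: z across the k state means of each regulon (population SD).
  With k states, |z| is bounded by sqrt(k−1) — for 3 states sqrt(2) ≈ 1.414,
  so a 1.5 threshold can never select anything. This mode exists to make the
  bound explicit.
- ``cellwise`` (default): z-score each regulon across all cells first, then
  average the per-cell z within each state. The mean z over a state holding
  fraction p of the cells is itself bounded by sqrt((1−p)/p), so a 1.5
  threshold is attainable only for states holding under ~30.8% of the cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger("regfate")

DEFAULT_Z_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.05
EXACT_MAX_N = 12


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann–Whitney U rank-sum test with midrank ties.

    Uses exact enumeration when n1 + n2 ≤ 12 and there are no ties, otherwise
    the normal approximation with tie and continuity corrections. Returns
    (U statistic for x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class StateActivitySummary:
    """Mean activity, z-values and one-sided rank-sum p per (regulon, state)."""

    means: pd.DataFrame   # regulons × states
    z: pd.DataFrame       # regulons × states (mode-dependent)
    p: pd.DataFrame       # regulons × states, one-sided greater state-vs-rest
    z_mode: str


def state_mean_zscore(activity: pd.DataFrame, state_labels,
                      z_mode: str = "cellwise") -> StateActivitySummary:
    """Per-state mean activity with mode-dependent z-values and rank-sum p.

    Degenerate (zero-SD) rows or columns yield z = 0.
    """
    if z_mode not in ("states", "cellwise"):
        raise ValidationError(f"unknown z_mode {z_mode!r}")
    labels = pd.Series(np.asarray(state_labels), index=activity.index)
    states = sorted(labels.unique())
    if len(states) < 2:
        raise ValidationError("need at least 2 states")

    masks = {s: (labels == s).to_numpy() for s in states}
    values = activity.to_numpy(dtype=float)
    means = pd.DataFrame(
        {s: values[masks[s]].mean(axis=0) for s in states}, index=activity.columns)

    if z_mode == "states":
        m = means.to_numpy()
        mu = m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, keepdims=True)  # population SD across the k means
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (m - mu) / sd, 0.0)
        z = pd.DataFrame(z, index=means.index, columns=means.columns)
    else:
        mu = values.mean(axis=0, keepdims=True)
        sd = values.std(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            zcells = np.where(sd > 0, (values - mu) / sd, 0.0)
        z = pd.DataFrame(
            {s: zcells[masks[s]].mean(axis=0) for s in states}, index=activity.columns)

    pvals = pd.DataFrame(index=activity.columns, columns=states, dtype=float)
    for j, regulon in enumerate(activity.columns):
        col = values[:, j]
        for s in states:
            in_state = col[masks[s]]
            rest = col[~masks[s]]
            _, p = wilcoxon_rank_sum(in_state, rest, alternative="greater")
            pvals.loc[regulon, s] = p
    means.index.name = z.index.name = pvals.index.name = "regulon"
    return StateActivitySummary(means=means, z=z, p=pvals, z_mode=z_mode)


def identify_state_regulons(summary: StateActivitySummary,
                            z_threshold: float = DEFAULT_Z_THRESHOLD,
                            alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Call state-specific high-activity regulons.

    Each regulon is evaluated in its best state (argmax z, first state on
    ties) and selected there iff z > z_threshold and one-sided p < alpha; a
    regulon can therefore select in at most one state. Returns a table
    (regulon, state, z, p, selected) covering every regulon's best state.
    """
    z = summary.z
    k = z.shape[1]
    rows = []
    for regulon in z.index:
        zr = z.loc[regulon]
        state = zr.index[int(np.argmax(zr.to_numpy()))]
        zv = float(zr[state])
        pv = float(summary.p.loc[regulon, state])
        rows.append((regulon, state, zv, pv, bool(zv > z_threshold and pv < alpha)))
    calls = pd.DataFrame(rows, columns=["regulon", "state", "z", "p", "selected"])

    if summary.z_mode == "states" and z_threshold >= np.sqrt(k - 1):
        warnings.warn(
            f"z_threshold={z_threshold} is unattainable in 'states' mode with "
            f"{k} states (max |z| = sqrt({k - 1}) ≈ {np.sqrt(k - 1):.4f}); "
            "no regulon can be selected")
    if not calls["selected"].any():
        logger.warning("no state-specific regulons selected at z>%g, p<%g",
                       z_threshold, alpha)
    return calls


def compare_program_activity(program_scores: pd.DataFrame, state_labels) -> pd.DataFrame:
    """All pairwise two-sided rank-sum comparisons of program activity between states.

    Returns a long table (program, state_a, state_b, U, p); state pairs where
    either group has fewer than 2 cells are skipped with a warning.
    """
    labels = pd.Series(np.asarray(state_labels), index=program_scores.index)
    states = sorted(labels.unique())
    rows = []
    for program in program_scores.columns:
        col = program_scores[program].to_numpy(dtype=float)
        for i, sa in enumerate(states):
            for sb in states[i + 1:]:
                a = col[(labels == sa).to_numpy()]
                b = col[(labels == sb).to_numpy()]
                if a.size < 2 or b.size < 2:
                    logger.warning("skipping %s: state pair (%s, %s) has <2 cells",
                                   program, sa, sb)
                    continue
                u, p = wilcoxon_rank_sum(a, b, alternative="two-sided")
                rows.append((program, sa, sb, u, p))
    return pd.DataFrame(rows, columns=["program", "state_a", "state_b", "U", "p"])


def state_expression_summary(expression: pd.DataFrame, genes: list[str],
                             state_labels) -> pd.DataFrame:
    """Per-(gene, state) mean expression and fraction of expressing cells.

    The expressing fraction (expression > 0) is the dot-size quantity of the
    usual dot-plot display; unknown genes are dropped with a warning.
    """
    present = [g for g in genes if g in expression.columns]
    missing = [g for g in genes if g not in expression.columns]
    if missing:
        logger.warning("dropping %d unknown genes: %s", len(missing), missing[:5])
    labels = pd.Series(np.asarray(state_labels), index=expression.index)
    rows = []
    for state in sorted(labels.unique()):
        sub = expression.loc[(labels == state).to_numpy(), present]
        mean = sub.mean(axis=0)
        prevalence = (sub > 0).mean(axis=0)
        for g in present:
            rows.append((g, state, float(mean[g]), float(prevalence[g])))
    return pd.DataFrame(rows, columns=["gene", "state", "mean_expression", "fraction_expressing"])
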
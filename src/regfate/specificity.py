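"""Regulon specificity (RSS) and co-activity specificity (CSI) metrics.

RSS compares a regulon's per-cell activity distribution P_R (activity
normalised to sum 1 over cells) against the normalised indicator distribution
P_C of a cell state via the Jensen–Shannon divergence:

    JSD(P_R, P_C) = H((P_R + P_C)/2) − (H(P_R) + H(P_C))/2,   RSS = 1 − JSD

with base-2 logarithms (so JSD, RSS ∈ [0, 1]) and the convention 0·log 0 = 0.
RSS = 1 exactly when the normalised activity equals the state indicator.
The RSS literature sometimes uses 1 − sqrt(JSD); that variant is available
via ``sqrt_jsd=True``.

CSI asks, for a pair of regulons (A, B), how many of the other N−2 regulons i
correlate with A or B more weakly than A and B correlate with each other:
m_i = 1 iff PCC(A,i) < PCC(A,B) or PCC(B,i) < PCC(A,B); CSI(A,B) = Σ m_i/(N−2).

Modules are obtained by average-linkage agglomerative clustering on the
distance 1 − CSI, cut into ``n_modules`` clusters labelled Module 1..k by
decreasing size.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError

logger = logging.getLogger("regfate")

DEFAULT_N_MODULES = 7


def _entropy_base2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def compute_rss(activity: np.ndarray, state_mask: np.ndarray, sqrt_jsd: bool = False) -> float:
    """RSS of one regulon's per-cell activity for one cell state."""
    a = np.asarray(activity, dtype=float)
    mask = np.asarray(state_mask, dtype=bool)
    if a.ndim != 1 or mask.shape != a.shape:
        raise ValidationError("activity and state_mask must be 1-D and aligned")
    if mask.sum() == 0:
        raise ValidationError("empty state")
    total = a.sum()
    if not (total > 0):
        raise ValidationError("undefined distribution: activity sums to zero")
    if np.any(a < 0):
        raise ValidationError("activity must be non-negative")

    p_r = a / total
    p_c = mask / mask.sum()
    m = 0.5 * (p_r + p_c)
    jsd = _entropy_base2(m) - 0.5 * (_entropy_base2(p_r) + _entropy_base2(p_c))
    jsd = min(max(jsd, 0.0), 1.0)  # clip fp jitter at the boundaries
    return 1.0 - (np.sqrt(jsd) if sqrt_jsd else jsd)


def compute_rss_matrix(activity: pd.DataFrame, state_labels, sqrt_jsd: bool = False) -> pd.DataFrame:
    """RSS for every (regulon, state); per-regulon failures become NaN with a warning."""
    labels = pd.Series(np.asarray(state_labels), index=activity.index)
    states = sorted(labels.unique())
    out = pd.DataFrame(index=activity.columns, columns=states, dtype=float)
    for regulon in activity.columns:
        col = activity[regulon].to_numpy(dtype=float)
        for state in states:
            mask = (labels == state).to_numpy()
            try:
                out.loc[regulon, state] = compute_rss(col, mask, sqrt_jsd=sqrt_jsd)
            except ValidationError as exc:
                logger.warning("RSS undefined for regulon %s, state %s: %s", regulon, state, exc)
                out.loc[regulon, state] = np.nan
    out.index.name = "regulon"
    return out


def compute_csi(activity: pd.DataFrame) -> pd.DataFrame:
    """Connection specificity index for every regulon pair (diagonal 1)."""
    n = activity.shape[1]
    if n < 3:
        raise ValidationError(f"CSI needs at least 3 regulons, got {n}")
    values = activity.to_numpy(dtype=float)
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = activity.columns[np.flatnonzero(sd == 0)][0]
        raise ValidationError(f"zero-variance activity column: {bad}")

    pcc = np.corrcoef(values, rowvar=False)
    csi = np.empty((n, n), dtype=float)
    for a in range(n):
        # m_i = 1 iff PCC(a,i) < PCC(a,b) or PCC(b,i) < PCC(a,b), i ∉ {a,b}
        less_a = pcc[a][None, :] < pcc[a][:, None]          # (b, i): PCC(a,i) < PCC(a,b)
        less_b = pcc < pcc[a][:, None]                      # (b, i): PCC(b,i) < PCC(a,b)
        hit = less_a | less_b
        hit[:, a] = False
        hit[np.arange(n), np.arange(n)] = False
        csi[a] = hit.sum(axis=1) / (n - 2)
    np.fill_diagonal(csi, 1.0)
    return pd.DataFrame(csi, index=activity.columns, columns=activity.columns)


def cluster_modules(csi: pd.DataFrame, n_modules: int = DEFAULT_N_MODULES) -> pd.Series:
    """Cut average-linkage clustering of 1 − CSI into modules.

    Returns a Series regulon → "Module k", modules numbered by decreasing
    size (ties by first occurrence); deterministic.
    """
    n = csi.shape[0]
    if n_modules > n:
        raise ValidationError(f"n_modules={n_modules} exceeds number of regulons {n}")
    if n_modules < 1:
        raise ValidationError("n_modules must be ≥ 1")

    dist = 1.0 - csi.to_numpy(dtype=float)
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)
    np.maximum(dist, 0.0, out=dist)
    if n_modules == n:
        raw = np.arange(1, n + 1)
    else:
        z = linkage(squareform(dist, checks=False), method="average")
        raw = fcluster(z, t=n_modules, criterion="maxclust")

    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], int(np.flatnonzero(raw == c)[0])))
    rename = {c: f"Module {i + 1}" for i, c in enumerate(order)}
    return pd.Series([rename[c] for c in raw], index=csi.index, name="module")


def module_csi_contrast(csi: pd.DataFrame, modules: pd.Series) -> tuple[float, float]:
    """(mean within-module CSI, mean between-module CSI) over off-diagonal pairs."""
    values = csi.to_numpy(dtype=float)
    same = (modules.to_numpy()[:, None] == modules.to_numpy()[None, :])
    off = ~np.eye(len(modules), dtype=bool)
    within = values[same & off]
    between = values[~same]
    w = float(within.mean()) if within.size else np.nan
    b = float(between.mean()) if between.size else np.nan
    return w, b
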
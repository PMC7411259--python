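"""lncRNA-mRNA co-expression network construction.

Edges connect a lncRNA and an mRNA when the Pearson correlation of their
expression profiles satisfies |r| >= 0.7 and p <= 0.05 (both inclusive, as
the thresholds are worded). With only four timepoint samples the two filters
are genuinely independent: |r| = 0.8 at n = 4 has p = 0.2 and is rejected by
the p filter alone.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the exact two-sided small-n p-value.

    p comes from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom
    (equivalently the beta form used by scipy); |r| = 1 returns p = 0 by
    continuity. Constant input raises ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant vectors")
    res = stats.pearsonr(x, y)
    r = float(np.clip(res.statistic, -1.0, 1.0))
    p = 0.0 if abs(r) == 1.0 else float(res.pvalue)
    return r, p


def _pearson_p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for given r and sample size (scipy's beta formulation)."""
    ab = n / 2.0 - 1.0
    dist = stats.beta(ab, ab, loc=-1, scale=2)
    p = 2.0 * dist.sf(np.abs(r))
    return np.where(np.abs(r) >= 1.0, 0.0, np.clip(p, 0.0, 1.0))


def build_network(
    lnc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    r_min: float = 0.7,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """All lncRNA x mRNA pairs passing both correlation filters.

    Expression matrices are genes x samples and must share sample columns;
    correlations are computed over the shared columns in lnc_expr's order.
    Constant rows cannot be correlated and are skipped with a log message.
    Returns a frame with columns lnc_id, mrna_id, r, p, sign sorted by
    (lnc_id, mrna_id).
    """
    shared = [c for c in lnc_expr.columns if c in set(mrna_expr.columns)]
    if not shared:
        raise ValueError("expression matrices share no sample columns")
    n = len(shared)
    if n < 3:
        raise ValueError("need at least 3 shared samples for correlation p-values")
    X = lnc_expr[shared].to_numpy(dtype=float)
    Y = mrna_expr[shared].to_numpy(dtype=float)
    xs = X.std(axis=1)
    ys = Y.std(axis=1)
    if (xs == 0).any():
        log.warning("skipping %d constant lncRNA profile(s)", int((xs == 0).sum()))
    if (ys == 0).any():
        log.warning("skipping %d constant mRNA profile(s)", int((ys == 0).sum()))
    Zx = np.where(xs[:, None] > 0, (X - X.mean(1, keepdims=True)), 0.0)
    Zy = np.where(ys[:, None] > 0, (Y - Y.mean(1, keepdims=True)), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Zx @ Zy.T) / np.outer(xs, ys) / n
    R = np.clip(R, -1.0, 1.0)
    P = _pearson_p_from_r(R, n)
    valid = np.outer(xs > 0, ys > 0)
    keep = valid & (np.abs(R) >= r_min) & (P <= p_max)
    li, mi = np.nonzero(keep)
    df = pd.DataFrame(
        {
            "lnc_id": lnc_expr.index.to_numpy()[li],
            "mrna_id": mrna_expr.index.to_numpy()[mi],
            "r": R[li, mi],
            "p": P[li, mi],
        }
    )
    df["sign"] = np.where(df["r"] > 0, "positive", "negative")
    return df.sort_values(["lnc_id", "mrna_id"], ignore_index=True)


def select_subnetwork(
    edges: pd.DataFrame,
    focus_mrnas: Iterable[str],
    known_mrnas: Iterable[str] | None = None,
) -> tuple[list[str], pd.DataFrame, dict[str, int]]:
    """Induced bipartite subnetwork around a set of focus mRNAs.

    The subnetwork contains the focus mRNAs plus every lncRNA co-expressed
    with at least one of them. Focus ids absent from ``known_mrnas`` (when
    given) are skipped with a log message; focus mRNAs without any edge stay
    in the node list with degree 0.
    """
    focus = sorted(set(focus_mrnas))
    if not focus:
        raise ValueError("focus mRNA set is empty")
    if known_mrnas is not None:
        known = set(known_mrnas)
        skipped = [m for m in focus if m not in known]
        if skipped:
            log.warning("focus mRNAs not in network: %s", skipped)
        focus = [m for m in focus if m in known]
    sub = edges[edges["mrna_id"].isin(focus)].sort_values(
        ["lnc_id", "mrna_id"], ignore_index=True
    )
    nodes = sorted(set(focus) | set(sub["lnc_id"]))
    counts = {"n_nodes": len(nodes), "n_edges": len(sub)}
    return nodes, sub, counts
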
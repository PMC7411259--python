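"""Differential-expression screen for unreplicated NB count time courses.

The screen follows the early-DESeq recipe for designs with one library per
condition: median-of-ratios size factors, a blind method-of-moments dispersion
estimate pooled across all samples with a fitted mean-dispersion trend, and a
conditioned negative-binomial exact test per contrast. Screening applies the
triple threshold p < 0.05, FDR < 0.05, FC > 2 with strict inequalities, and
the cross-contrast intersection keeps direction-consistent genes only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .types import CommonSet, ContrastResult, CountMatrix

log = logging.getLogger(__name__)

# log-space tolerance used to count probability ties in the exact test
_TIE_EPS = 1e-12


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def estimate_size_factors(
    counts: pd.DataFrame | CountMatrix, fallback: bool = False
) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over genes of k_ij / (geometric mean of gene i across
    samples). By default only genes with all-positive counts enter the
    median; ``fallback=True`` instead computes each gene's geometric mean
    over its positive entries and takes the median over positive ratios
    (needed for very sparse matrices).
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    k = df.to_numpy(dtype=float)
    if k.size == 0:
        raise ValueError("empty count matrix")
    with np.errstate(divide="ignore"):
        logk = np.log(k)
    allpos = np.isfinite(logk).all(axis=1)
    if not fallback:
        if not allpos.any():
            raise ValueError(
                "no gene has positive counts in every sample; rerun with "
                "fallback=True to ignore zeros per gene"
            )
        loggm = logk[allpos].mean(axis=1)
        ratios = logk[allpos] - loggm[:, None]
        s = np.exp(np.median(ratios, axis=0))
    else:
        anypos = np.isfinite(logk).any(axis=1)
        if not anypos.any():
            raise ValueError("all-zero count matrix")
        sub = logk[anypos]
        loggm = np.nanmean(np.where(np.isfinite(sub), sub, np.nan), axis=1)
        ratios = sub - loggm[:, None]
        s = np.exp(np.nanmedian(np.where(np.isfinite(ratios), ratios, np.nan), axis=0))
        if not np.isfinite(s).all():
            raise ValueError("a sample has no positive counts; cannot normalize")
    return pd.Series(s, index=df.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionFit:
    """Per-gene dispersions plus the fitted mean-dispersion trend.

    ``alpha`` holds the final per-gene values under the requested sharing
    mode; ``alpha_hat`` the raw method-of-moments estimates; ``trend`` the
    (a1, a0) coefficients of alpha(m) = a1/m + a0.
    """

    alpha: pd.Series
    alpha_hat: pd.Series
    trend: tuple[float, float]
    sharing: str

    def trend_at(self, mean: np.ndarray) -> np.ndarray:
        a1, a0 = self.trend
        with np.errstate(divide="ignore"):
            v = a1 / np.asarray(mean, dtype=float) + a0
        return np.clip(np.where(np.asarray(mean) > 0, v, 0.0), 0.0, None)


def _fit_trend(
    m: np.ndarray, ah: np.ndarray, sel: np.ndarray, n_iter: int = 5
) -> tuple[float, float]:
    """Least-squares fit of alpha(m) = a1/m + a0 with upward-outlier trimming.

    Strongly differential genes carry blind alpha-hat values far above the
    bulk (their variance is dominated by the condition effect); iteratively
    excluding points more than 3 robust sd above the fit keeps them from
    inflating the trend, the same idea as the outlier-excluded trend fits of
    standard DE packages.
    """
    sel = sel.copy()
    if sel.sum() == 0:
        return 0.0, 0.0
    if sel.sum() == 1:
        return 0.0, float(ah[sel][0])
    a1 = a0 = 0.0
    for _ in range(n_iter):
        X = np.column_stack([1.0 / m[sel], np.ones(int(sel.sum()))])
        coef, *_ = np.linalg.lstsq(X, ah[sel], rcond=None)
        a1, a0 = float(coef[0]), float(coef[1])
        with np.errstate(divide="ignore"):
            pred = np.where(m > 0, a1 / np.where(m > 0, m, 1.0) + a0, 0.0)
        resid = ah - np.clip(pred, 0.0, None)
        r = resid[sel]
        s = 1.4826 * np.median(np.abs(r - np.median(r)))
        new = sel & (resid <= 3.0 * max(s, 1e-6))
        if new.sum() == sel.sum() or new.sum() < 10:
            break
        sel = new
    return a1, a0


def estimate_dispersions(
    counts: pd.DataFrame | CountMatrix,
    size_factors: pd.Series,
    mode: str = "blind",
    sharing: str = "maximum",
) -> DispersionFit:
    """Method-of-moments NB dispersion with a fitted 1/m trend.

    On normalized counts q_ij = k_ij / s_j, the gene-wise estimate is
    alpha_hat_i = max(0, (v_i - m_i) / m_i^2). ``mode="blind"`` pools all
    samples regardless of condition (the only option without replicates);
    ``mode="replicates"`` pools within-timepoint variances. The trend
    alpha(m) = a1/m + a0 is fitted by least squares on genes with
    alpha_hat > 0. ``sharing="maximum"`` returns max(alpha_hat, trend);
    ``sharing="fit_only"`` returns the trend value alone, which is the
    appropriate choice for unreplicated designs where alpha_hat of a truly
    changing gene is inflated by its own signal.
    """
    if mode not in ("blind", "pooled", "replicates"):
        raise ValueError(f"unknown mode {mode!r}")
    if sharing not in ("maximum", "fit_only"):
        raise ValueError(f"unknown sharing {sharing!r}")
    if isinstance(counts, CountMatrix):
        df, meta = counts.counts, counts.sample_meta
    else:
        df, meta = counts, None
    if df.shape[1] < 2:
        raise ValueError("dispersion estimation requires at least 2 samples")
    q = df.to_numpy(dtype=float) / size_factors.reindex(df.columns).to_numpy()
    m = q.mean(axis=1)
    if mode == "replicates":
        if meta is None:
            raise ValueError("mode='replicates' requires a CountMatrix with sample_meta")
        groups = meta.loc[df.columns, "timepoint"].to_numpy()
        resid = np.zeros_like(q)
        for g in np.unique(groups):
            cols = groups == g
            resid[:, cols] = q[:, cols] - q[:, cols].mean(axis=1, keepdims=True)
        dof = q.shape[1] - len(np.unique(groups))
        if dof < 1:
            raise ValueError("mode='replicates' needs replicated timepoints")
        v = (resid**2).sum(axis=1) / dof
    else:
        v = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ah = np.where(m > 0, (v - m) / m**2, 0.0)
    ah = np.clip(np.nan_to_num(ah, nan=0.0, posinf=0.0), 0.0, None)

    pos = (ah > 0) & (m > 0)
    a1, a0 = _fit_trend(m, ah, pos)
    fit = DispersionFit(
        alpha=pd.Series(index=df.index, dtype=float),
        alpha_hat=pd.Series(ah, index=df.index),
        trend=(a1, a0),
        sharing=sharing,
    )
    trend_vals = fit.trend_at(m)
    final = np.maximum(ah, trend_vals) if sharing == "maximum" else trend_vals
    fit.alpha = pd.Series(final, index=df.index, name="alpha")
    return fit


# ---------------------------------------------------------------------------
# the exact test
# ---------------------------------------------------------------------------

def _nb_logpmf(k: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    if mu <= 0:
        out = np.full(np.shape(k), -np.inf)
        out[np.asarray(k) == 0] = 0.0
        return out
    if alpha == 0:
        return stats.poisson.logpmf(k, mu)
    r = 1.0 / alpha
    return stats.nbinom.logpmf(k, r, r / (r + mu))


def nb_exact_test(
    kA: int, kB: int, sA: float = 1.0, sB: float = 1.0, alpha: float = 0.0
) -> float:
    """Conditioned NB exact test for two single count observations.

    Conditional on the total K = kA + kB, sums the probabilities of all
    splits (a, K - a) no more likely than the observed one, where each side
    is NB with mean q * s (q the pooled normalized mean) and dispersion
    alpha; alpha = 0 uses the Poisson mass. Returns a two-sided p in [0, 1].
    """
    if kA < 0 or kB < 0 or int(kA) != kA or int(kB) != kB:
        raise ValueError("counts must be non-negative integers")
    if sA <= 0 or sB <= 0:
        raise ValueError("size factors must be positive")
    if alpha < 0:
        raise ValueError("dispersion must be non-negative")
    kA, kB = int(kA), int(kB)
    K = kA + kB
    if K == 0:
        return 1.0
    q = 0.5 * (kA / sA + kB / sB)
    a = np.arange(K + 1)
    lp = _nb_logpmf(a, q * sA, alpha) + _nb_logpmf(a, q * sB, alpha)[::-1]
    lobs = lp[kA]
    from scipy.special import logsumexp

    num = logsumexp(lp[lp <= lobs + _TIE_EPS])
    den = logsumexp(lp)
    return float(min(1.0, np.exp(num - den)))


def bh_adjust(pvals: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving by index)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-contrast testing and screening
# ---------------------------------------------------------------------------

def test_contrast(
    counts: CountMatrix,
    size_factors: pd.Series,
    dispersions: pd.Series,
    ref: str,
    test: str,
) -> pd.DataFrame:
    """Exact-test table for one (reference, test) timepoint contrast.

    With replicates, counts and size factors are summed within each group
    before testing. Genes with zero counts on both sides get NaN p. The
    reported log2 fold change uses normalized counts with pseudocount 1.
    """
    ref_samples = counts.samples_for(ref)
    test_samples = counts.samples_for(test)
    if not ref_samples or not test_samples:
        raise ValueError(f"contrast ({ref}, {test}) has no samples")
    kA = counts.counts[ref_samples].sum(axis=1).to_numpy()
    kB = counts.counts[test_samples].sum(axis=1).to_numpy()
    sA = float(size_factors.loc[ref_samples].sum())
    sB = float(size_factors.loc[test_samples].sum())
    alpha = dispersions.reindex(counts.counts.index).to_numpy()

    qA, qB = kA / sA, kB / sB
    base_mean = 0.5 * (qA + qB)
    log2fc = np.log2((qB + 1.0) / (qA + 1.0))
    p = np.full(len(kA), np.nan)
    for i in range(len(kA)):
        if kA[i] + kB[i] == 0:
            continue
        p[i] = nb_exact_test(int(kA[i]), int(kB[i]), sA, sB, float(alpha[i]))
    return pd.DataFrame(
        {"base_mean": base_mean, "log2fc": log2fc, "p": p},
        index=counts.counts.index,
    )


def adjust_table(
    table: pd.DataFrame, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Add BH-adjusted ``fdr``, within ``groups`` (e.g. biotype) separately.

    Only tested genes (finite p) enter each BH denominator.
    """
    out = table.copy()
    out["fdr"] = np.nan
    tested = out["p"].notna()
    if groups is None:
        idx = out.index[tested]
        if len(idx):
            out.loc[idx, "fdr"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    else:
        grp = groups.reindex(out.index)
        for _, members in grp.groupby(grp):
            idx = members.index[tested.loc[members.index]]
            if len(idx):
                out.loc[idx, "fdr"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    return out


def screen_contrast(
    table: pd.DataFrame,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    fdr_max: float = 0.05,
) -> tuple[frozenset[str], frozenset[str]]:
    """Triple-threshold screen with strict inequalities.

    up: p < p_max and fdr < fdr_max and log2fc > log2(fc_min); down uses
    log2fc < -log2(fc_min). A direction column is added in place.
    """
    if fc_min <= 0 or p_max <= 0 or fdr_max <= 0:
        raise ValueError("thresholds must be positive")
    lfc_min = np.log2(fc_min)
    sig = (table["p"] < p_max) & (table["fdr"] < fdr_max)
    up = sig & (table["log2fc"] > lfc_min)
    down = sig & (table["log2fc"] < -lfc_min)
    table["direction"] = np.where(up, "up", np.where(down, "down", "ns"))
    return frozenset(table.index[up]), frozenset(table.index[down])


def run_contrast(
    counts: CountMatrix,
    size_factors: pd.Series,
    dispersions: pd.Series,
    ref: str,
    test: str,
    biotypes: pd.Series | None = None,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    fdr_max: float = 0.05,
) -> ContrastResult:
    """Test, adjust (per biotype population) and screen one contrast."""
    table = test_contrast(counts, size_factors, dispersions, ref, test)
    table = adjust_table(table, groups=biotypes)
    screen_contrast(table, fc_min=fc_min, p_max=p_max, fdr_max=fdr_max)
    return ContrastResult(contrast=(ref, test), table=table)


# ---------------------------------------------------------------------------
# cross-contrast intersection
# ---------------------------------------------------------------------------

def intersect_contrasts(
    screened: Sequence[ContrastResult] | Sequence[tuple[Iterable[str], Iterable[str]]],
    names: Sequence[str] | None = None,
) -> CommonSet:
    """Direction-consistent intersection plus full Venn region counts.

    common_up / common_down are the genes up (down) in every contrast;
    ``mixed`` collects genes significant everywhere with inconsistent
    direction. Venn regions are keyed by '&'-joined contrast names over the
    per-contrast significant (up or down) sets.
    """
    if len(screened) < 2:
        raise ValueError("need at least 2 contrasts to intersect")
    ups: list[frozenset[str]] = []
    downs: list[frozenset[str]] = []
    labels: list[str] = []
    for i, item in enumerate(screened):
        if isinstance(item, ContrastResult):
            ups.append(item.up)
            downs.append(item.down)
            labels.append(item.name)
        else:
            u, d = item
            ups.append(frozenset(u))
            downs.append(frozenset(d))
            labels.append(names[i] if names else f"contrast{i + 1}")
    common_up = frozenset.intersection(*ups)
    common_down = frozenset.intersection(*downs)
    sigs = [u | d for u, d in zip(ups, downs)]
    everywhere = frozenset.intersection(*sigs)
    mixed = everywhere - common_up - common_down

    venn: dict[str, int] = {}
    union = frozenset.union(*sigs)
    membership = {g: tuple(g in s for s in sigs) for g in union}
    for pattern in sorted({v for v in membership.values()}):
        key = "&".join(l for l, m in zip(labels, pattern) if m)
        venn[key] = sum(1 for v in membership.values() if v == pattern)
    return CommonSet(
        common_up=common_up, common_down=common_down, mixed=mixed, venn_counts=venn
    )


# ---------------------------------------------------------------------------
# hierarchical clustering for reporting
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    leaf_order: list[str]
    linkage: np.ndarray
    dropped: list[str]


def hierarchical_cluster(expr: pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering on 1 - Pearson distance of z-scored rows.

    Rows are sorted by id first so that the tree (and the leaf order) is
    deterministic with an id-ascending tie-break; constant rows are dropped
    with a warning.
    """
    expr = expr.sort_index()
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    keep = sd > 0
    dropped = list(expr.index[~keep])
    if dropped:
        log.warning("dropping %d constant row(s): %s", len(dropped), dropped[:5])
    expr = expr.loc[keep]
    vals = vals[keep]
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 non-constant rows to cluster")
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    dist = pdist(z, metric="correlation")  # 1 - Pearson r
    Z = linkage(dist, method="average")
    order = [expr.index[i] for i in leaves_list(Z)]
    return ClusterResult(leaf_order=order, linkage=Z, dropped=dropped)


def normalized_log_expression(
    counts: CountMatrix, size_factors: pd.Series
) -> pd.DataFrame:
    """log2(normalized count + 1), the transform used for clustering and
    co-expression."""
    q = counts.counts.div(size_factors.reindex(counts.counts.columns), axis=1)
    return np.log2(q + 1.0)
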
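"""Positional classification of lncRNAs and cis-regulation candidates.

A lncRNA is labeled by the first matching rule against the coding
annotation: intronic (contained in an intron), antisense (exon overlap on
the opposite strand), sense-overlapping (gene-body overlap on the same
strand), bidirectional (no overlap, 5' ends within 1 kb on opposite
strands), intergenic (nearest coding gene more than 5 kb away), otherwise
undefined. Cis candidates are coding genes whose loci fall within a fixed
window (default 100 kb) up- or downstream of a lncRNA and whose expression
correlates significantly with it.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .coexpr import pearson_with_p
from .types import GeneFeature

log = logging.getLogger(__name__)

CLASS_LABELS = (
    "sense_overlapping",
    "intergenic",
    "intronic",
    "bidirectional",
    "antisense",
    "undefined",
)

BIDIRECTIONAL_MAX = 1_000  # bp between 5' ends, inclusive
INTERGENIC_MIN = 5_000  # bp clearance, exclusive


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def feature_distance(a: GeneFeature, b: GeneFeature) -> int:
    """Gap between nearest ends in bp; 0 if the intervals overlap."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def classify_lncrna(
    lnc: GeneFeature,
    coding: Sequence[GeneFeature],
    bidirectional_max: int = BIDIRECTIONAL_MAX,
    intergenic_min: int = INTERGENIC_MIN,
) -> str:
    """Positional class of one lncRNA against same-chromosome coding genes.

    Rule order is fixed; the first match wins. Genes without an annotated
    exon list count as single-exon (whole body exonic, no introns).
    """
    if lnc.strand not in ("+", "-"):
        log.warning("lncRNA %s has unknown strand; classified as undefined", lnc.id)
        return "undefined"
    near = [g for g in coding if g.chrom == lnc.chrom]

    # 1: contained in an intron of any coding gene, either strand
    for g in near:
        if lnc.start >= g.start and lnc.end <= g.end:
            if not any(
                _overlap(lnc.start, lnc.end, es, ee) for es, ee in g.exon_intervals()
            ):
                return "intronic"
    # 2: overlaps a coding exon on the opposite strand
    for g in near:
        if g.strand in ("+", "-") and g.strand != lnc.strand:
            if any(
                _overlap(lnc.start, lnc.end, es, ee) for es, ee in g.exon_intervals()
            ):
                return "antisense"
    # 3: overlaps a coding gene body on the same strand
    for g in near:
        if g.strand == lnc.strand and _overlap(lnc.start, lnc.end, g.start, g.end):
            return "sense_overlapping"
    # 4: divergent pair - no body overlap anywhere, 5' ends within 1 kb on
    # opposite strands
    if not any(_overlap(lnc.start, lnc.end, g.start, g.end) for g in near):
        for g in near:
            if g.strand in ("+", "-") and g.strand != lnc.strand:
                if abs(lnc.five_prime - g.five_prime) <= bidirectional_max:
                    return "bidirectional"
    # 5: intergenic if the nearest coding gene is far enough away
    if not near or min(feature_distance(lnc, g) for g in near) > intergenic_min:
        return "intergenic"
    return "undefined"


def classify_all(
    features: Iterable[GeneFeature],
    bidirectional_max: int = BIDIRECTIONAL_MAX,
    intergenic_min: int = INTERGENIC_MIN,
) -> pd.Series:
    """Classify every lncRNA in an annotation; returns a Series by lnc id."""
    feats = list(features)
    coding_by_chrom: dict[str, list[GeneFeature]] = defaultdict(list)
    for f in feats:
        if f.biotype == "coding":
            coding_by_chrom[f.chrom].append(f)
    out = {}
    for f in feats:
        if f.biotype == "lncRNA":
            out[f.id] = classify_lncrna(
                f,
                coding_by_chrom.get(f.chrom, []),
                bidirectional_max=bidirectional_max,
                intergenic_min=intergenic_min,
            )
    return pd.Series(out, name="class", dtype=object).sort_index()


def chromosome_distribution(
    features: Iterable[GeneFeature], chroms: Sequence[str] | None = None
) -> pd.Series:
    """Feature counts per chromosome, reporting zeros for listed chroms."""
    feats = list(features)
    counts: dict[str, int] = {c: 0 for c in (chroms or [])}
    for f in feats:
        counts[f.chrom] = counts.get(f.chrom, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def find_cis_pairs(
    lncs: Sequence[GeneFeature],
    coding: Sequence[GeneFeature],
    expr: pd.DataFrame,
    window: int = 100_000,
    corr_p_max: float = 0.05,
) -> pd.DataFrame:
    """Coding genes within ``window`` bp of a lncRNA with correlated expression.

    Both filters are inclusive: gap distance <= window and Pearson
    p <= corr_p_max. ``expr`` holds one expression row per gene id (any
    monotone transform; the correlation is computed on it as given). Pairs
    whose expression rows are missing are skipped with a log message.
    Output is sorted by (lnc_id, gene_id), so it is invariant to input order.
    """
    coding_by_chrom: dict[str, list[GeneFeature]] = defaultdict(list)
    for g in coding:
        if g.biotype == "coding":
            coding_by_chrom[g.chrom].append(g)
    rows = []
    for lnc in lncs:
        if lnc.biotype != "lncRNA":
            continue
        if lnc.id not in expr.index:
            log.warning("no expression row for lncRNA %s; skipped", lnc.id)
            continue
        x = expr.loc[lnc.id].to_numpy(dtype=float)
        for g in coding_by_chrom.get(lnc.chrom, []):
            d = feature_distance(lnc, g)
            if d > window:
                continue
            if g.id not in expr.index:
                log.warning("no expression row for gene %s; pair skipped", g.id)
                continue
            y = expr.loc[g.id].to_numpy(dtype=float)
            try:
                r, p = pearson_with_p(x, y)
            except ValueError:
                log.warning("constant expression for pair (%s, %s); skipped", lnc.id, g.id)
                continue
            if p <= corr_p_max:
                rows.append((lnc.id, g.id, d, r, p))
    df = pd.DataFrame(rows, columns=["lnc_id", "gene_id", "distance", "r", "p"])
    return df.sort_values(["lnc_id", "gene_id"], ignore_index=True)
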
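"""Hypergeometric enrichment engine and TF-mediated trans-regulation.

One upper-tail hypergeometric test serves three consumers: functional-term
enrichment of the common DE mRNAs (GO/KEGG-style collections supplied as
GMT), pathway-gene bipartite networks, and TF-lncRNA association, where each
lncRNA's co-expressed coding genes are intersected with every TF target set.
The TF binary network keeps the top 200 (p, FDR)-significant pairs sorted by
p; the ternary network expands the top 10 pairs to their overlap genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneSetCollection
from .de import bh_adjust

log = logging.getLogger(__name__)


def hypergeom_upper_tail(N: int, M: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, M, n).

    N: universe size, M: set size, n: query size, k: overlap. k = 0 returns
    exactly 1.
    """
    for name, v in (("N", N), ("M", M), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if M > N or n > N or k > min(M, n):
        raise ValueError(f"infeasible hypergeometric arguments N={N} M={M} n={n} k={k}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, M, n))
    return min(1.0, max(p, 0.0))


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query against every set in a collection.

    Query genes outside the universe are dropped with a log message; sets
    with no overlap are not reported. FDR is BH across the reported sets.
    Results are ranked by enrichment score es = (k/n)/(M/N) descending with
    ties broken by p ascending, then set name.
    """
    coll = collection.restricted()
    N = len(coll.universe)
    if N == 0:
        raise ValueError("empty background universe")
    q = set(query)
    dropped = q - coll.universe
    if dropped:
        log.warning("%d query gene(s) outside the universe dropped", len(dropped))
    q &= coll.universe
    n = len(q)
    rows = []
    for name in sorted(coll.sets):
        s = coll.sets[name]
        M = len(s)
        overlap = sorted(q & s)
        k = len(overlap)
        if k < 1 or M == 0:
            continue
        p = hypergeom_upper_tail(N, M, n, k)
        es = (k / n) / (M / N)
        rows.append((name, N, M, n, k, p, es, ",".join(overlap)))
    df = pd.DataFrame(
        rows, columns=["set", "N", "M", "n", "k", "p", "es", "overlap_ids"]
    )
    if len(df):
        df["fdr"] = bh_adjust(df["p"].to_numpy())
        df["neg_log10_p"] = -np.log10(np.clip(df["p"], 1e-300, None))
        df = df.sort_values(
            ["es", "p", "set"], ascending=[False, True, True], ignore_index=True
        )
    else:
        df["fdr"] = []
        df["neg_log10_p"] = []
    if top_n is not None:
        df = df.head(top_n).reset_index(drop=True)
    return df


def pathway_gene_network(
    results: pd.DataFrame, min_k: int = 1
) -> tuple[nx.Graph, pd.Series]:
    """Bipartite set-gene membership graph from enrichment results.

    Nodes carry a ``kind`` attribute ("set" or "gene"); the returned Series
    gives each gene's pathway-degree (in how many reported sets it appears).
    """
    if results.empty:
        raise ValueError("no enrichment results to build a network from")
    G = nx.Graph()
    for _, row in results.iterrows():
        if row["k"] < min_k:
            continue
        G.add_node(row["set"], kind="set")
        for g in str(row["overlap_ids"]).split(","):
            if g:
                G.add_node(g, kind="gene")
                G.add_edge(row["set"], g)
    genes = [v for v, d in G.nodes(data=True) if d["kind"] == "gene"]
    degrees = pd.Series({g: G.degree(g) for g in genes}, dtype=int).sort_values(
        ascending=False
    )
    return G, degrees


def lnc_coexpressed_geneset(lnc_id: str, coexpr_edges: pd.DataFrame) -> frozenset[str]:
    """The coding genes co-expressed with one lncRNA under the network
    thresholds already applied to the edge list."""
    if lnc_id not in set(coexpr_edges["lnc_id"]):
        log.warning("lncRNA %s has no co-expression partners", lnc_id)
        return frozenset()
    return frozenset(coexpr_edges.loc[coexpr_edges["lnc_id"] == lnc_id, "mrna_id"])


@dataclass
class TFNetwork:
    """TF-lncRNA binary pairs and TF-lncRNA-gene ternary triples.

    ``binary`` has columns tf, lnc, k, n, M, p, fdr sorted by
    (p, tf, lnc); ``ternary`` expands the leading pairs into one row per
    overlap gene.
    """

    binary: pd.DataFrame
    ternary: pd.DataFrame
    all_pairs: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


_PAIR_COLS = ["tf", "lnc", "k", "n", "M", "p", "fdr"]


def tf_network_for_group(
    lnc_ids: Iterable[str],
    coexpr_edges: pd.DataFrame,
    tf_sets: GeneSetCollection,
    p_max: float = 0.01,
    fdr_max: float = 0.01,
    top_binary: int = 200,
    top_ternary: int = 10,
) -> TFNetwork:
    """TF association network for one group of lncRNAs.

    Every (TF, lncRNA) pair is tested for enrichment of the lncRNA's
    co-expressed coding genes in the TF's target set against the coding
    universe; BH runs over all pairs of the group. Pairs with p < p_max and
    fdr < fdr_max (strict) are sorted by (p, tf, lnc); the binary network is
    the top ``top_binary`` prefix and the ternary network expands the top
    ``top_ternary`` prefix of the same list.
    """
    if len(tf_sets) == 0:
        raise ValueError("empty TF target collection")
    coll = tf_sets.restricted()
    N = len(coll.universe)
    if N == 0:
        raise ValueError("empty coding universe")
    rows = []
    overlaps: dict[tuple[str, str], tuple[str, ...]] = {}
    for lnc in sorted(set(lnc_ids)):
        geneset = lnc_coexpressed_geneset(lnc, coexpr_edges) & coll.universe
        n = len(geneset)
        for tf in sorted(coll.sets):
            targets = coll.sets[tf]
            M = len(targets)
            ov = tuple(sorted(geneset & targets))
            k = len(ov)
            p = hypergeom_upper_tail(N, M, n, k)
            rows.append((tf, lnc, k, n, M, p))
            overlaps[(tf, lnc)] = ov
    pairs = pd.DataFrame(rows, columns=_PAIR_COLS[:-1])
    if pairs.empty:
        empty_b = pd.DataFrame(columns=_PAIR_COLS)
        empty_t = pd.DataFrame(columns=["tf", "lnc", "gene"])
        return TFNetwork(binary=empty_b, ternary=empty_t, all_pairs=pairs)
    pairs["fdr"] = bh_adjust(pairs["p"].to_numpy())
    sig = pairs[(pairs["p"] < p_max) & (pairs["fdr"] < fdr_max)]
    sig = sig.sort_values(["p", "tf", "lnc"], ignore_index=True)
    binary = sig.head(top_binary).reset_index(drop=True)
    trows = []
    for _, row in sig.head(top_ternary).iterrows():
        for g in overlaps[(row["tf"], row["lnc"])]:
            trows.append((row["tf"], row["lnc"], g))
    ternary = pd.DataFrame(trows, columns=["tf", "lnc", "gene"])
    return TFNetwork(binary=binary, ternary=ternary, all_pairs=pairs)


def build_tf_networks(
    lnc_groups: Mapping[str, Iterable[str]],
    coexpr_edges: pd.DataFrame,
    tf_sets: GeneSetCollection,
    p_max: float = 0.01,
    fdr_max: float = 0.01,
    top_binary: int = 200,
    top_ternary: int = 10,
) -> dict[str, TFNetwork]:
    """TF networks per lncRNA direction group (e.g. {"up": ..., "down": ...})."""
    return {
        group: tf_network_for_group(
            ids,
            coexpr_edges,
            tf_sets,
            p_max=p_max,
            fdr_max=fdr_max,
            top_binary=top_binary,
            top_ternary=top_ternary,
        )
        for group, ids in lnc_groups.items()
    }
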
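"""PPI network filtering, hub calling and MCODE-style module detection.

Interaction edges arrive as a STRING-dialect TSV (protein1, protein2,
combined_score). Scores on the 0-1000 integer scale are auto-detected and
rescaled to [0, 1]; edges at confidence >= 0.7 (inclusive) survive the
filter. Hubs are nodes with degree strictly greater than 10 in the
DE-induced subgraph. Module detection follows the seeded, weight-guided
MCODE procedure at the classical parameters (degree cutoff 2, node score
cutoff 0.2, k-core 2, max depth 100).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .types import Module

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# loading and filtering
# ---------------------------------------------------------------------------

def filter_interactions(
    edges: Iterable[tuple[str, str, float]], min_conf: float = 0.7
) -> nx.Graph:
    """Confidence-filtered simple graph from scored edge records.

    Scores with max > 1 are taken to be on the 0-1000 integer scale and
    divided by 1000. Self-loops are dropped (count logged); duplicate pairs
    collapse to their maximum confidence. The filter is inclusive.
    """
    best: dict[tuple[str, str], float] = {}
    n_self = 0
    records = list(edges)
    if records:
        max_score = max(s for _, _, s in records)
        scale = 1000.0 if max_score > 1 else 1.0
    else:
        scale = 1.0
    for a, b, s in records:
        conf = s / scale
        if not (0.0 <= conf <= 1.0):
            raise ValueError(f"confidence {conf} outside [0, 1] for edge ({a}, {b})")
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a <= b else (b, a)
        if conf > best.get(key, -1.0):
            best[key] = conf
    if n_self:
        log.info("dropped %d self-loop(s)", n_self)
    G = nx.Graph()
    for (a, b), conf in best.items():
        if conf >= min_conf:
            G.add_edge(a, b, confidence=conf)
    return G


def load_and_filter(path: str | Path, min_conf: float = 0.7) -> nx.Graph:
    """Parse a STRING-dialect TSV and apply the confidence filter.

    A single header line is tolerated; any other unparseable line raises
    with its line number.
    """
    records: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ValueError(f"malformed interaction line {i}: {line!r}")
            try:
                score = float(parts[2])
            except ValueError:
                if i == 1:  # header
                    continue
                raise ValueError(f"malformed interaction line {i}: {line!r}") from None
            records.append((parts[0], parts[1], score))
    return filter_interactions(records, min_conf=min_conf)


def induce_de_subgraph(
    graph: nx.Graph, de_genes: Iterable[str], drop_isolated: bool = True
) -> tuple[nx.Graph, dict[str, int]]:
    """Subgraph on the DE genes present in the network.

    Isolated nodes are dropped by default; the counts dict reports nodes,
    edges and how many isolated nodes were removed.
    """
    keep = set(de_genes) & set(graph.nodes)
    H = graph.subgraph(keep).copy()
    isolated = [v for v in H.nodes if H.degree(v) == 0]
    if drop_isolated:
        H.remove_nodes_from(isolated)
    counts = {
        "n_nodes": H.number_of_nodes(),
        "n_edges": H.number_of_edges(),
        "n_isolated_dropped": len(isolated) if drop_isolated else 0,
    }
    return H, counts


def find_hubs(
    graph: nx.Graph, min_degree_exclusive: int = 10
) -> list[tuple[str, int]]:
    """Nodes with degree strictly greater than the cutoff.

    Sorted by degree descending, then id ascending.
    """
    hubs = [(v, d) for v, d in graph.degree() if d > min_degree_exclusive]
    return sorted(hubs, key=lambda t: (-t[1], t[0]))


# ---------------------------------------------------------------------------
# MCODE-style module detection
# ---------------------------------------------------------------------------

def _mcode_weights(graph: nx.Graph, degree_cutoff: int) -> dict[str, float]:
    """Vertex weight: highest k-core number of the closed neighborhood times
    the density of the closed-neighborhood subgraph.

    Nodes with degree below the degree cutoff get weight 0, removing noise
    vertices from seeding and expansion.
    """
    w: dict[str, float] = {}
    for v in graph.nodes:
        if graph.degree(v) < degree_cutoff:
            w[v] = 0.0
            continue
        nbhd = list(graph.neighbors(v)) + [v]
        H = graph.subgraph(nbhd)
        core = nx.core_number(H)
        k_max = max(core.values())
        w[v] = k_max * nx.density(H)
    return w


def mcode(
    graph: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = False,
) -> list[Module]:
    """Seeded, weight-guided detection of dense modules.

    Prediction repeatedly seeds at the highest-weight unassigned vertex
    (ties broken by id ascending) and breadth-first adds unassigned
    neighbors u with weight(u) > weight(seed) * (1 - node_score_cutoff), to
    at most ``max_depth`` steps from the seed. Candidates whose induced
    subgraph contains no ``k_core``-core are discarded, so the surviving
    modules are connected, pairwise disjoint and dense. Score is
    density * node count; modules come back sorted by score descending.
    ``haircut=True`` additionally trims module nodes of degree < 2 within
    the module.
    """
    if graph.number_of_nodes() == 0:
        return []
    if any(graph.has_edge(v, v) for v in graph.nodes):
        raise ValueError("graph must be simple (no self-loops)")
    weights = _mcode_weights(graph, degree_cutoff)
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    assigned: set[str] = set()
    modules: list[Module] = []
    for seed in order:
        if seed in assigned:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for v in frontier:
                for u in graph.neighbors(v):
                    if u in members or u in assigned:
                        continue
                    if weights[u] > threshold:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        assigned |= members
        sub = graph.subgraph(members)
        if haircut:
            trimmed = [v for v in sub.nodes if sub.degree(v) < 2]
            members -= set(trimmed)
            if not members:
                continue
            sub = graph.subgraph(members)
        core = nx.core_number(sub) if sub.number_of_nodes() else {}
        if not core or max(core.values()) < k_core:
            continue
        density = nx.density(sub)
        modules.append(
            Module(
                members=frozenset(members),
                seed=seed,
                density=density,
                score=density * len(members),
            )
        )
    return sorted(modules, key=lambda m: (-m.score, tuple(sorted(m.members))))


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard overlap between two node sets."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def best_module_match(
    planted: Sequence[Iterable[str]], found: Sequence[Module]
) -> list[float]:
    """For each planted module, the best Jaccard overlap among found ones."""
    return [
        max((jaccard(p, m.members) for m in found), default=0.0) for p in planted
    ]
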
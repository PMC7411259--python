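"""Readers and writers for the plain-text interchange formats.

Internal coordinates are 0-based half-open; the GTF writer converts to its
1-based inclusive convention, BED stays 0-based. The GTF subset carries gene
lines only (attributes gene_id, gene_biotype); exon structure travels in
BED12 blocks when needed.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .types import CountMatrix, GeneFeature, GeneSetCollection


# ---------------------------------------------------------------------------
# counts and sample sheet
# ---------------------------------------------------------------------------

def write_counts_tsv(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def write_sample_sheet(cm: CountMatrix, path: str | Path) -> None:
    cm.sample_meta.loc[cm.sample_ids].to_csv(path, sep="\t", index_label="sample")


def read_counts(
    counts_path: str | Path, sample_sheet_path: str | Path
) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(sample_sheet_path, sep="\t", index_col="sample")
    meta["timepoint"] = meta["timepoint"].astype(str)
    return CountMatrix(counts=counts, sample_meta=meta)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def write_gtf(features: Iterable[GeneFeature], path: str | Path) -> None:
    """Gene-line-only GTF subset (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for f in features:
            attrs = f'gene_id "{f.id}"; gene_biotype "{f.biotype}";'
            fh.write(
                f"{f.chrom}\tlncscreen\tgene\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9 or parts[2] != "gene":
                raise ValueError(f"unsupported GTF line {i}: {line!r}")
            attrs = dict(_GTF_ATTR.findall(parts[8]))
            feats.append(
                GeneFeature(
                    id=attrs["gene_id"],
                    biotype=attrs.get("gene_biotype", "coding"),
                    chrom=parts[0],
                    strand=parts[6],
                    start=int(parts[3]) - 1,
                    end=int(parts[4]),
                )
            )
    return feats


def write_bed(
    features: Iterable[GeneFeature], path: str | Path, blocks: bool = False
) -> None:
    """BED6, or BED12 with exon blocks when ``blocks=True``."""
    with open(path, "w") as fh:
        for f in features:
            base = f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}"
            if not blocks:
                fh.write(base + "\n")
                continue
            exons = f.exon_intervals()
            sizes = ",".join(str(e - s) for s, e in exons)
            starts = ",".join(str(s - f.start) for s, _ in exons)
            fh.write(
                base
                + f"\t{f.start}\t{f.end}\t0\t{len(exons)}\t{sizes},\t{starts},\n"
            )


def read_bed(
    path: str | Path, biotype: str = "coding"
) -> list[GeneFeature]:
    """Read BED6 or BED12; block fields reconstruct exon intervals."""
    feats = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            p = line.split("\t")
            if len(p) not in (6, 12):
                raise ValueError(f"unsupported BED line {i}: {line!r}")
            start = int(p[1])
            exons = None
            if len(p) == 12:
                sizes = [int(x) for x in p[10].rstrip(",").split(",")]
                offs = [int(x) for x in p[11].rstrip(",").split(",")]
                exons = tuple(
                    (start + o, start + o + s) for o, s in zip(offs, sizes)
                )
            feats.append(
                GeneFeature(
                    id=p[3],
                    biotype=biotype,
                    chrom=p[0],
                    strand=p[5],
                    start=start,
                    end=int(p[2]),
                    exons=exons,
                )
            )
    return feats


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.kind}\t{genes}\n".rstrip("\t ") + "\n")


def read_gmt(
    path: str | Path,
    universe: Iterable[str] | None = None,
    kind: str = "term",
) -> GeneSetCollection:
    """Read a GMT file; universe defaults to the union of all sets."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            p = line.split("\t")
            if len(p) < 2:
                raise ValueError(f"malformed GMT line {i}: {line!r}")
            sets[p[0]] = frozenset(g for g in p[2:] if g)
    uni = (
        frozenset(universe)
        if universe is not None
        else frozenset().union(*sets.values())
        if sets
        else frozenset()
    )
    return GeneSetCollection(sets=sets, universe=uni, kind=kind)


# ---------------------------------------------------------------------------
# interactions and network exports
# ---------------------------------------------------------------------------

def write_interactions_tsv(graph: nx.Graph, path: str | Path) -> None:
    """STRING-dialect TSV with combined_score on the 0-1000 integer scale."""
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            score = int(round(graph.edges[a, b]["confidence"] * 1000))
            fh.write(f"{a}\t{b}\t{score}\n")


def write_sif(
    edges: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    """Simple interaction format: source, relation, target per line."""
    with open(path, "w") as fh:
        for a, rel, b in edges:
            fh.write(f"{a}\t{rel}\t{b}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


# ---------------------------------------------------------------------------
# truth JSON
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return [_jsonable(o) for o in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def write_truth_json(design, path: str | Path) -> None:
    """Serialize a PlantedDesign (ground truth) to JSON."""
    from dataclasses import asdict

    raw = asdict(design)
    out = {}
    for key, val in raw.items():
        if key in ("per_contrast_up", "per_contrast_down"):
            out[key] = {
                "|".join(map(str, k)): sorted(v) for k, v in val.items()
            }
        else:
            out[key] = _jsonable(val)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth_json(path: str | Path):
    from .synthetic import PlantedDesign

    with open(path) as fh:
        raw = json.load(fh)
    for key in ("per_contrast_up", "per_contrast_down"):
        raw[key] = {
            tuple(k.split("|")): frozenset(v) for k, v in raw[key].items()
        }
    raw["common_up"] = frozenset(raw["common_up"])
    raw["common_down"] = frozenset(raw["common_down"])
    raw["timepoints"] = tuple(raw["timepoints"])
    raw["mu_range"] = tuple(raw["mu_range"])
    raw["planted_modules"] = tuple(frozenset(m) for m in raw["planted_modules"])
    raw["planted_hubs"] = tuple(raw["planted_hubs"])
    raw["enriched_tfs"] = {k: tuple(v) for k, v in raw["enriched_tfs"].items()}
    return PlantedDesign(**raw)
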
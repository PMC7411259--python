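"""End-to-end orchestration of the screen from a single configuration.

Stages run in a fixed order (synthesize/ingest -> DE -> intersect ->
classify -> co-express -> cis -> enrich -> trans -> PPI); every threshold is
a named config default and is logged into the run report together with the
seed, so an identical config and seed reproduce a byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpr, de, enrich, genomic, io, ppi, synthetic
from .types import CountMatrix, GeneSetCollection

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "de",
    "classify",
    "coexpr",
    "cis",
    "enrich",
    "trans",
    "ppi",
)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one run.

    In synthetic mode the generator provides every input; otherwise the
    five file paths must point at existing inputs.
    """

    synthetic: bool = True
    seed: int = 0
    outdir: str = "lncscreen_out"
    # file-mode inputs
    counts_path: str | None = None
    sample_sheet_path: str | None = None
    annotation_path: str | None = None
    tf_gmt_path: str | None = None
    term_gmt_path: str | None = None
    interactions_path: str | None = None
    # screen thresholds
    fc_min: float = 2.0
    p_max: float = 0.05
    fdr_max: float = 0.05
    dispersion_sharing: str = "fit_only"
    # networks
    r_min: float = 0.7
    corr_p_max: float = 0.05
    cis_window: int = 100_000
    tf_p: float = 0.01
    tf_fdr: float = 0.01
    top_binary: int = 200
    top_ternary: int = 10
    # PPI
    ppi_conf: float = 0.7
    hub_degree: int = 10
    mcode_degree_cutoff: int = 2
    mcode_node_score_cutoff: float = 0.2
    mcode_k_core: int = 2
    mcode_max_depth: int = 100
    # reporting
    top_terms: int = 20
    make_plots: bool = False
    design_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("fc_min", "p_max", "fdr_max", "r_min", "corr_p_max",
                     "tf_p", "tf_fdr", "ppi_conf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.cis_window <= 0 or self.top_binary <= 0 or self.top_ternary <= 0:
            raise ValueError("window and top-N settings must be positive")
        if not self.synthetic:
            for name in ("counts_path", "sample_sheet_path", "annotation_path",
                         "tf_gmt_path", "term_gmt_path", "interactions_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} required in file mode: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def with_overrides(self, pairs: list[str]) -> "PipelineConfig":
        """Apply 'key=value' overrides (YAML-parsed values)."""
        d = asdict(self)
        for pair in pairs:
            key, _, val = pair.partition("=")
            if key not in d:
                raise KeyError(f"unknown config key {key!r}")
            d[key] = yaml.safe_load(val)
        return PipelineConfig(**d)


def validate_inputs(
    counts: CountMatrix,
    annotation,
    collections: list[GeneSetCollection] = (),
) -> list[tuple[str, str]]:
    """Cross-reference and sanity diagnostics: (level, message) records.

    Duplicated gene ids are fatal; count genes absent from the annotation
    are a warning.
    """
    diags: list[tuple[str, str]] = []
    ids = [f.id for f in annotation]
    if len(ids) != len(set(ids)):
        diags.append(("fatal", "duplicated gene ids in annotation"))
    if counts.counts.index.has_duplicates:
        diags.append(("fatal", "duplicated gene ids in counts"))
    missing = sorted(set(counts.gene_ids) - set(ids))
    if missing:
        diags.append(
            ("warning", f"{len(missing)} count gene(s) absent from annotation: "
             f"{missing[:5]}")
        )
    for coll in collections:
        outside = sorted(coll.universe - set(counts.gene_ids))
        if outside:
            diags.append(
                ("warning",
                 f"{len(outside)} {coll.kind} universe gene(s) not in counts")
            )
    return diags


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the pipeline; returns the report dict and writes artifacts.

    ``stages`` limits which artifact groups are written; the computation
    always runs in dependency order. The report is written to
    ``<outdir>/report.json`` deterministically (sorted keys, no wall-clock
    content).
    """
    stages = tuple(stages) if stages is not None else STAGES
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config": asdict(config)}

    # -- ingest / synthesize -------------------------------------------------
    if config.synthetic:
        bundle = synthetic.generate_bundle(
            seed=config.seed,
            design=(
                synthetic.default_design(config.seed, **config.design_overrides)
                if config.design_overrides
                else None
            ),
        )
        counts, annotation = bundle.counts, bundle.annotation
        tf_sets, term_sets = bundle.tf_sets, bundle.term_sets
        interactions = bundle.interactions
        if "simulate" in stages:
            ind = out / "inputs"
            ind.mkdir(exist_ok=True)
            io.write_counts_tsv(counts, ind / "counts.tsv")
            io.write_sample_sheet(counts, ind / "samples.tsv")
            io.write_gtf(annotation, ind / "annotation.gtf")
            io.write_bed(annotation, ind / "annotation.bed12", blocks=True)
            io.write_gmt(tf_sets, ind / "tf_targets.gmt")
            io.write_gmt(term_sets, ind / "terms.gmt")
            io.write_interactions_tsv(interactions, ind / "interactions.tsv")
            io.write_truth_json(bundle.truth, ind / "truth.json")
            report["input_checksums"] = {
                p.name: _sha256(p) for p in sorted(ind.iterdir())
            }
    else:
        counts = io.read_counts(config.counts_path, config.sample_sheet_path)
        ann_path = Path(config.annotation_path)
        annotation = (
            io.read_gtf(ann_path) if ann_path.suffix == ".gtf" else io.read_bed(ann_path)
        )
        coding_ids = frozenset(f.id for f in annotation if f.biotype == "coding")
        tf_sets = io.read_gmt(config.tf_gmt_path, universe=coding_ids, kind="tf_targets")
        term_sets = io.read_gmt(config.term_gmt_path, universe=coding_ids, kind="term")
        interactions = ppi.load_and_filter(config.interactions_path, min_conf=0.0)

    diags = validate_inputs(counts, annotation, [tf_sets, term_sets])
    report["validation"] = [list(d) for d in diags]
    if any(level == "fatal" for level, _ in diags):
        raise ValueError(f"fatal input problems: {diags}")

    biotype = pd.Series({f.id: f.biotype for f in annotation}).reindex(counts.gene_ids)
    feats = {f.id: f for f in annotation}

    # -- DE screen -----------------------------------------------------------
    sf = de.estimate_size_factors(counts)
    disp = de.estimate_dispersions(counts, sf, mode="blind",
                                   sharing=config.dispersion_sharing)
    tps = counts.timepoints()
    contrasts = [(tps[0], t) for t in tps[1:]]
    results = [
        de.run_contrast(
            counts, sf, disp.alpha, ref, test, biotypes=biotype,
            fc_min=config.fc_min, p_max=config.p_max, fdr_max=config.fdr_max,
        )
        for ref, test in contrasts
    ]
    common = de.intersect_contrasts(results)
    logx = de.normalized_log_expression(counts, sf)

    de_tallies = {
        r.name: {
            "up": len(r.up),
            "down": len(r.down),
            "up_lncRNA": sum(1 for g in r.up if biotype.get(g) == "lncRNA"),
            "down_lncRNA": sum(1 for g in r.down if biotype.get(g) == "lncRNA"),
        }
        for r in results
    }
    report["de"] = {
        "size_factors": {s: round(float(v), 6) for s, v in sf.items()},
        "dispersion_trend": [round(v, 6) for v in disp.trend],
        "contrasts": de_tallies,
        "venn": dict(common.venn_counts),
        "common_up": len(common.common_up),
        "common_down": len(common.common_down),
        "mixed": len(common.mixed),
    }
    if "de" in stages:
        for r in results:
            r.table.round(6).to_csv(out / f"de_{r.name}.tsv", sep="\t",
                                    index_label="gene_id")
        with open(out / "venn.json", "w") as fh:
            json.dump(dict(common.venn_counts), fh, indent=2, sort_keys=True)
        rows = (
            [(g, "up") for g in sorted(common.common_up)]
            + [(g, "down") for g in sorted(common.common_down)]
            + [(g, "mixed") for g in sorted(common.mixed)]
        )
        pd.DataFrame(rows, columns=["gene_id", "direction"]).to_csv(
            out / "common_sets.tsv", sep="\t", index=False
        )
        de_genes = sorted(common.common_up | common.common_down)
        if len(de_genes) >= 2:
            clust = de.hierarchical_cluster(logx.loc[de_genes])
            pd.Series(clust.leaf_order, name="gene_id").to_csv(
                out / "cluster_order.tsv", sep="\t", index=False
            )

    common_lnc_up = frozenset(g for g in common.common_up if biotype.get(g) == "lncRNA")
    common_lnc_down = frozenset(
        g for g in common.common_down if biotype.get(g) == "lncRNA"
    )
    common_mrna_up = frozenset(g for g in common.common_up if biotype.get(g) == "coding")
    common_mrna_down = frozenset(
        g for g in common.common_down if biotype.get(g) == "coding"
    )
    common_lncs = sorted(common_lnc_up | common_lnc_down)
    common_mrnas = sorted(common_mrna_up | common_mrna_down)

    # -- positional classification -------------------------------------------
    lnc_feats = [feats[g] for g in common_lncs if g in feats]
    classes = genomic.classify_all(
        [f for f in annotation if f.biotype == "coding"] + lnc_feats
    )
    chrom_counts = genomic.chromosome_distribution(
        lnc_feats, chroms=sorted({f.chrom for f in annotation})
    )
    report["classification"] = {
        "tally": {k: int(v) for k, v in classes.value_counts().sort_index().items()},
        "per_chromosome": {k: int(v) for k, v in chrom_counts.items()},
    }
    if "classify" in stages:
        classes.rename("class").to_csv(out / "lnc_classes.tsv", sep="\t",
                                       index_label="lnc_id")
        chrom_counts.rename("n").to_csv(out / "lnc_chromosomes.tsv", sep="\t",
                                        index_label="chrom")

    # -- co-expression network -----------------------------------------------
    if common_lncs and common_mrnas:
        edges = coexpr.build_network(
            logx.loc[common_lncs], logx.loc[common_mrnas],
            r_min=config.r_min, p_max=config.corr_p_max,
        )
    else:
        edges = pd.DataFrame(columns=["lnc_id", "mrna_id", "r", "p", "sign"])
    report["coexpression"] = {
        "n_edges": len(edges),
        "n_lnc": int(edges["lnc_id"].nunique()) if len(edges) else 0,
        "n_mrna": int(edges["mrna_id"].nunique()) if len(edges) else 0,
    }
    if "coexpr" in stages:
        edges.round(6).to_csv(out / "coexpr_edges.tsv", sep="\t", index=False)
        io.write_sif(
            ((r.lnc_id, r.sign, r.mrna_id) for r in edges.itertuples()),
            out / "coexpr.sif",
        )

    # -- cis candidates --------------------------------------------------------
    cis = genomic.find_cis_pairs(
        lnc_feats,
        [f for f in annotation if f.biotype == "coding"],
        logx,
        window=config.cis_window,
        corr_p_max=config.corr_p_max,
    )
    report["cis"] = {"n_pairs": len(cis),
                     "n_lnc": int(cis["lnc_id"].nunique()) if len(cis) else 0}
    if "cis" in stages:
        cis.round(6).to_csv(out / "cis_pairs.tsv", sep="\t", index=False)

    # -- term enrichment -------------------------------------------------------
    enr = enrich.enrich(common_mrnas, term_sets) if common_mrnas else pd.DataFrame()
    report["enrichment"] = {
        "n_sets_tested": len(enr),
        "top_sets": list(enr["set"].head(config.top_terms)) if len(enr) else [],
    }
    if "enrich" in stages:
        head = enr.head(config.top_terms) if len(enr) else enr
        enr.round(6).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        if len(head):
            G, degrees = enrich.pathway_gene_network(head)
            io.write_graphml(G, out / "pathway_gene_network.graphml")
            degrees.rename("pathway_degree").to_csv(
                out / "gene_pathway_degree.tsv", sep="\t", index_label="gene_id"
            )

    # -- TF trans networks -----------------------------------------------------
    tf_nets = enrich.build_tf_networks(
        {"up": sorted(common_lnc_up), "down": sorted(common_lnc_down)},
        edges,
        tf_sets,
        p_max=config.tf_p,
        fdr_max=config.tf_fdr,
        top_binary=config.top_binary,
        top_ternary=config.top_ternary,
    )
    report["trans"] = {
        grp: {
            "binary_pairs": len(net.binary),
            "binary_tfs": int(net.binary["tf"].nunique()) if len(net.binary) else 0,
            "ternary_rows": len(net.ternary),
        }
        for grp, net in tf_nets.items()
    }
    if "trans" in stages:
        for grp, net in tf_nets.items():
            net.binary.round(8).to_csv(out / f"tf_binary_{grp}.tsv", sep="\t",
                                       index=False)
            net.ternary.to_csv(out / f"tf_ternary_{grp}.tsv", sep="\t", index=False)
            io.write_sif(
                ((r.tf, "regulates", r.lnc) for r in net.binary.itertuples()),
                out / f"tf_binary_{grp}.sif",
            )

    # -- PPI ---------------------------------------------------------------------
    filtered = ppi.filter_interactions(
        ((a, b, d["confidence"]) for a, b, d in interactions.edges(data=True)),
        min_conf=config.ppi_conf,
    )
    de_sub, sub_counts = ppi.induce_de_subgraph(filtered, common_mrnas)
    hubs = ppi.find_hubs(de_sub, min_degree_exclusive=config.hub_degree)
    modules = ppi.mcode(
        de_sub,
        degree_cutoff=config.mcode_degree_cutoff,
        node_score_cutoff=config.mcode_node_score_cutoff,
        k_core=config.mcode_k_core,
        max_depth=config.mcode_max_depth,
    )
    report["ppi"] = {
        "filtered_nodes": filtered.number_of_nodes(),
        "filtered_edges": filtered.number_of_edges(),
        "de_subgraph": sub_counts,
        "hubs": [[h, int(d)] for h, d in hubs],
        "modules": [
            {"n": len(m.members), "score": round(m.score, 4), "seed": m.seed}
            for m in modules
        ],
    }
    if "ppi" in stages:
        io.write_sif(
            ((a, "pp", b) for a, b in sorted(tuple(sorted(e)) for e in de_sub.edges)),
            out / "ppi_de_subgraph.sif",
        )
        io.write_graphml(de_sub, out / "ppi_de_subgraph.graphml")
        pd.DataFrame(hubs, columns=["gene_id", "degree"]).to_csv(
            out / "ppi_hubs.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [
                (i + 1, round(m.score, 6), round(m.density, 6),
                 ",".join(sorted(m.members)))
                for i, m in enumerate(modules)
            ],
            columns=["module", "score", "density", "members"],
        ).to_csv(out / "ppi_modules.tsv", sep="\t", index=False)

    if config.make_plots and results:
        from . import plots

        plots.volcano(results[0].table, out / f"volcano_{results[0].name}.png")
        de_genes = sorted(common.common_up | common.common_down)
        if len(de_genes) >= 2:
            plots.heatmap(logx.loc[de_genes], out / "heatmap_common.png")
        plots.venn_barplot(common.venn_counts, out / "venn_regions.png")

    report["version"] = _package_version()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _package_version() -> str:
    from . import __version__

    return __version__
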
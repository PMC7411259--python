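"""Generator correctness: determinism, planted classes, counts, TF sets,
interaction structure."""

import numpy as np
import pytest

from lncscreen import de, genomic, ppi, synthetic
from lncscreen.synthetic import (
    GenomeSpec,
    PlacementError,
    PlantedDesign,
    default_design,
    generate_annotation,
    generate_counts,
    generate_interactions,
    generate_tf_targets,
)

SMALL_GENOME = GenomeSpec(chrom_names=("chr1", "chr2"),
                          chrom_lengths=(18_000_000, 18_000_000))


class TestDesign:
    def test_common_sets_subset_of_every_contrast(self):
        d = default_design(3)
        for c in d.contrasts():
            assert d.common_up <= d.per_contrast_up[c]
            assert d.common_down <= d.per_contrast_down[c]

    def test_class_counts_sum_to_n_lnc(self):
        d = default_design(0)
        assert sum(d.lnc_class_counts.values()) == d.n_lnc

    def test_inconsistent_common_sets_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            PlantedDesign(
                per_contrast_up={("0h", "8h"): frozenset()},
                common_up=frozenset({"CG00001"}),
            )

    def test_unknown_planted_gene_rejected(self):
        with pytest.raises(ValueError, match="not in design"):
            PlantedDesign(
                per_contrast_up={("0h", "8h"): frozenset({"NOPE"})},
            )

    def test_zero_timepoints_rejected(self):
        with pytest.raises(ValueError):
            PlantedDesign(timepoints=())


class TestAnnotation:
    def test_no_lncrnas_gives_coding_only(self):
        d = default_design(0, n_coding=50, n_lnc=0)
        ann = generate_annotation(SMALL_GENOME, d)
        assert len(ann) == 50
        assert all(f.biotype == "coding" for f in ann)

    def test_same_seed_identical_annotation(self):
        d1 = default_design(7, n_coding=100, n_lnc=30)
        d2 = default_design(7, n_coding=100, n_lnc=30)
        a1 = generate_annotation(SMALL_GENOME, d1)
        a2 = generate_annotation(SMALL_GENOME, d2)
        assert a1 == a2

    def test_planted_classes_recovered_by_classifier(self):
        d = default_design(5, n_coding=200, n_lnc=60)
        ann = generate_annotation(SMALL_GENOME, d)
        got = genomic.classify_all(ann).value_counts().to_dict()
        want = {k: v for k, v in d.lnc_class_counts.items() if v > 0}
        assert got == want

    def test_intergenic_clearance_verified_directly(self):
        d = default_design(
            2, n_coding=40, n_lnc=3,
            lnc_class_counts={"intergenic": 3},
        )
        ann = generate_annotation(SMALL_GENOME, d)
        coding = [f for f in ann if f.biotype == "coding"]
        for f in ann:
            if f.biotype != "lncRNA":
                continue
            dmin = min(
                genomic.feature_distance(f, g)
                for g in coding if g.chrom == f.chrom
            )
            assert dmin > genomic.INTERGENIC_MIN
            assert genomic.classify_lncrna(f, coding) == "intergenic"

    def test_coding_genes_non_overlapping(self):
        d = default_design(1, n_coding=300, n_lnc=0)
        ann = generate_annotation(SMALL_GENOME, d)
        by_chrom = {}
        for f in ann:
            by_chrom.setdefault(f.chrom, []).append(f)
        for feats in by_chrom.values():
            feats.sort(key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                assert a.end <= b.start

    def test_infeasible_genome_raises_placement_error(self):
        tiny = GenomeSpec(chrom_names=("chr1",), chrom_lengths=(100_000,))
        d = default_design(0, n_coding=500, n_lnc=0)
        with pytest.raises(PlacementError):
            generate_annotation(tiny, d)


class TestCounts:
    def test_poisson_limit_variance_mean_ratio(self):
        # alpha = 0, no planted DE, equal depths -> Poisson counts
        d = default_design(
            0, n_coding=2500, n_lnc=0, dispersion=0.0, depth_sd=0.0,
            per_contrast_up={}, per_contrast_down={},
            common_up=frozenset(), common_down=frozenset(),
        )
        ann = generate_annotation(
            GenomeSpec(chrom_names=("c1", "c2", "c3"),
                       chrom_lengths=(70_000_000,) * 3), d)
        cm = generate_counts(ann, d)
        k = cm.counts.to_numpy(float)
        m = k.mean(axis=1)
        v = k.var(axis=1, ddof=1)
        ratio = v[m > 0] / m[m > 0]
        # the sample variance is unbiased, so the ratio averages to 1 (its
        # median sits near 0.79 because a 3-df variance estimate is skewed)
        assert abs(ratio.mean() - 1.0) < 0.1

    def test_planted_fold_change_visible(self):
        # an 8-fold planted common_up gene shows a normalized FC(32h/0h) > 2
        # in at least 95% of count draws
        d = default_design(0, n_coding=200, n_lnc=20, effect_log2fc=3.0)
        ann = generate_annotation(SMALL_GENOME, d)
        g = sorted(d.common_by_biotype()["up"]["coding"])[0]
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            cm = generate_counts(ann, d, rng=np.random.default_rng([seed, 2]))
            sf = de.estimate_size_factors(cm)
            q = cm.counts.div(sf, axis=1)
            hits += (q.loc[g, "32h"] + 1) / (q.loc[g, "0h"] + 1) > 2
        assert hits / n_seeds >= 0.95

    def test_depth_factors_recorded(self):
        d = default_design(0, n_coding=50, n_lnc=0)
        ann = generate_annotation(SMALL_GENOME, d)
        cm = generate_counts(ann, d)
        assert set(d.depth_factors) == set(cm.sample_ids)
        assert set(d.baseline_mu) == set(cm.gene_ids)

    def test_replicates_option(self):
        d = default_design(0, n_coding=50, n_lnc=0, n_replicates=2)
        ann = generate_annotation(SMALL_GENOME, d)
        cm = generate_counts(ann, d)
        assert len(cm.sample_ids) == 8
        assert len(cm.samples_for("8h")) == 2

    def test_same_seed_identical_counts(self):
        d1 = default_design(9, n_coding=60, n_lnc=10)
        d2 = default_design(9, n_coding=60, n_lnc=10)
        ann1 = generate_annotation(SMALL_GENOME, d1)
        ann2 = generate_annotation(SMALL_GENOME, d2)
        c1 = generate_counts(ann1, d1)
        c2 = generate_counts(ann2, d2)
        assert c1.counts.equals(c2.counts)

    def test_invalid_design_params_rejected(self):
        with pytest.raises(ValueError):
            default_design(0, dispersion=-1)
        with pytest.raises(ValueError):
            default_design(0, n_replicates=0)
        with pytest.raises(ValueError):
            default_design(0, n_replicates=1.5)


class TestTFTargets:
    def _ann(self, d):
        return generate_annotation(SMALL_GENOME, d)

    def test_enriched_tf_overlaps_planted_commons(self):
        d = default_design(3, n_coding=400, n_lnc=40)
        ann = self._ann(d)
        coll = generate_tf_targets(ann, d, n_tf=10)
        up_core = d.common_by_biotype()["up"]["coding"]
        tf = d.enriched_tfs["up"][0]
        overlap = len(coll.sets[tf] & up_core)
        assert overlap >= int(0.5 * len(up_core)) - 1

    def test_zero_overlap_fraction_gives_chance_level(self):
        d = default_design(3, n_coding=400, n_lnc=40)
        ann = self._ann(d)
        coll = generate_tf_targets(ann, d, n_tf=10, overlap_fraction=0.0)
        up_core = d.common_by_biotype()["up"]["coding"]
        for tf in d.enriched_tfs["up"]:
            # at chance, overlap ~ M*|core|/N ~ 1; far below the planted 50%
            assert len(coll.sets[tf] & up_core) <= len(up_core) // 2

    def test_set_size_exceeding_universe_errors(self):
        d = default_design(0, n_coding=50, n_lnc=0)
        ann = self._ann(d)
        with pytest.raises(ValueError):
            generate_tf_targets(ann, d, n_tf=2, set_size_range=(60, 70))

    def test_n_tf_must_be_positive(self):
        d = default_design(0, n_coding=50, n_lnc=0)
        with pytest.raises(ValueError):
            generate_tf_targets(self._ann(d), d, n_tf=0)

    def test_empty_collection_gmt_round_trip(self, tmp_path):
        from lncscreen import io
        from lncscreen.types import GeneSetCollection

        coll = GeneSetCollection({}, frozenset(), "tf_targets")
        path = tmp_path / "empty.gmt"
        io.write_gmt(coll, path)
        back = io.read_gmt(path, kind="tf_targets")
        assert back.sets == {}


class TestInteractions:
    def _ann(self, n=100, seed=0):
        d = default_design(seed, n_coding=n, n_lnc=0)
        return d, generate_annotation(SMALL_GENOME, d)

    def test_no_structure_no_background_empty(self):
        d, ann = self._ann()
        G = generate_interactions(ann, background_p=0.0, design=d)
        assert G.number_of_edges() == 0

    def test_planted_clique_survives_filter(self):
        d, ann = self._ann()
        ids = [f.id for f in ann][:6]
        G = generate_interactions(
            ann, planted_modules=[frozenset(ids)], background_p=0.0,
            module_density=1.0, design=d,
        )
        filt = ppi.filter_interactions(
            ((a, b, dd["confidence"]) for a, b, dd in G.edges(data=True))
        )
        assert filt.subgraph(ids).number_of_edges() == 15

    def test_planted_hub_degree_in_de_subgraph(self):
        d, ann = self._ann()
        ids = [f.id for f in ann]
        de_set = frozenset(ids[:30])
        G = generate_interactions(
            ann, hubs={ids[40]: (12, de_set)}, background_p=0.0, design=d,
        )
        filt = ppi.filter_interactions(
            ((a, b, dd["confidence"]) for a, b, dd in G.edges(data=True))
        )
        sub, _ = ppi.induce_de_subgraph(filt, set(de_set) | {ids[40]})
        assert sub.degree(ids[40]) >= 12 > 11

    def test_overlapping_modules_rejected(self):
        d, ann = self._ann()
        ids = [f.id for f in ann]
        with pytest.raises(ValueError, match="disjoint"):
            generate_interactions(
                ann,
                planted_modules=[frozenset(ids[:5]), frozenset(ids[4:9])],
                design=d,
            )

    def test_excess_hub_demand_rejected(self):
        d, ann = self._ann()
        ids = [f.id for f in ann]
        with pytest.raises(ValueError, match="demand"):
            generate_interactions(
                ann, hubs={ids[0]: (50, frozenset(ids[:10]))}, design=d
            )


class TestBundle:
    def test_bundle_ids_consistent(self, bundle):
        ann_ids = {f.id for f in bundle.annotation}
        assert set(bundle.counts.gene_ids) <= ann_ids
        assert bundle.tf_sets.universe <= ann_ids

    def test_bundle_deterministic(self, bundle):
        again = synthetic.generate_bundle(seed=1)
        assert again.counts.counts.equals(bundle.counts.counts)
        assert again.annotation == bundle.annotation
        assert again.tf_sets.sets == bundle.tf_sets.sets
        assert set(again.interactions.edges) == set(bundle.interactions.edges)

    def test_truth_json_round_trip(self, bundle, tmp_path):
        from lncscreen import io

        path = tmp_path / "truth.json"
        io.write_truth_json(bundle.truth, path)
        back = io.read_truth_json(path)
        assert back.common_up == bundle.truth.common_up
        assert back.per_contrast_down == bundle.truth.per_contrast_down
        assert back.planted_modules == bundle.truth.planted_modules
        assert back.enriched_tfs == bundle.truth.enriched_tfs
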
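"""Pathway completeness, phototrophy rules, PGC detection and synteny."""

import numpy as np
import pytest

from caulotraits import (
    ClusterRegion,
    PathwayDef,
    PlantedPGCSpec,
    call_phototroph,
    cluster_synteny,
    detect_gene_cluster,
    pathway_completeness,
    screen_genomes,
    simulate_annotated_genomes,
)
from caulotraits.phototrophy import (
    CBB_CLUSTER_GENES,
    CBB_PATHWAY,
    DEFAULT_RULES,
    PGC_CORE_ORDER,
)

from oracles import brute_force_adjacency, brute_force_pathway

PGC_FAMILIES = {f for f, _ in PGC_CORE_ORDER} | {f for f, _ in CBB_CLUSTER_GENES}
FULL_GENE_SET = PGC_FAMILIES


class TestPathwayCompleteness:
    def test_empty_set_is_zero(self):
        frac, steps = pathway_completeness(set(), CBB_PATHWAY)
        assert frac == 0.0 and not any(steps.values())

    def test_all_steps_satisfied_is_one(self):
        frac, _ = pathway_completeness({f for f, _ in CBB_CLUSTER_GENES}, CBB_PATHWAY)
        assert frac == 1.0

    def test_alternative_ids_satisfy_a_step(self):
        # pgk is an accepted alternative to cbbK for the kinase step
        _, steps = pathway_completeness({"pgk"}, CBB_PATHWAY)
        assert steps["phosphoglycerate_kinase"]

    def test_multisubunit_step_needs_all_subunits(self):
        _, steps = pathway_completeness({"cbbL"}, CBB_PATHWAY)
        assert not steps["rubisco"]

    def test_matches_brute_force_on_random_subsets(self):
        rng = np.random.default_rng(23)
        universe = sorted({g for alts in CBB_PATHWAY.steps.values() for a in alts for g in a})
        raw_steps = {k: [set(a) for a in v] for k, v in CBB_PATHWAY.steps.items()}
        for _ in range(50):
            subset = {g for g in universe if rng.random() < 0.5}
            frac, steps = pathway_completeness(subset, CBB_PATHWAY)
            exp_frac, exp_steps = brute_force_pathway(subset, raw_steps)
            assert frac == pytest.approx(exp_frac) and steps == exp_steps

    def test_monotone_under_union(self):
        rng = np.random.default_rng(5)
        universe = sorted({g for alts in CBB_PATHWAY.steps.values() for a in alts for g in a})
        for _ in range(20):
            small = {g for g in universe if rng.random() < 0.3}
            extra = {g for g in universe if rng.random() < 0.3}
            f1, _ = pathway_completeness(small, CBB_PATHWAY)
            f2, _ = pathway_completeness(small | extra, CBB_PATHWAY)
            assert f2 >= f1

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            PathwayDef(name="empty", steps={})


class TestCallPhototroph:
    def test_complete_gene_set_is_photoautotroph(self):
        call = call_phototroph(FULL_GENE_SET)
        assert call.level == "photoautotroph_potential"
        assert call.cbb_completeness == 1.0

    def test_missing_rubisco_flags_near_complete(self):
        call = call_phototroph(FULL_GENE_SET - {"cbbL", "cbbS"})
        assert call.level == "phototroph"
        assert "near_complete_cbb_missing_rubisco" in call.flags

    def test_missing_pufl_is_none(self):
        call = call_phototroph(FULL_GENE_SET - {"pufL"})
        assert call.level == "none"

    def test_bch_threshold_gates_the_call(self):
        few_bch = {"pufL", "pufM", "bchB", "bchC", "bchD"}  # only 3 bch
        assert call_phototroph(few_bch).level == "none"
        assert call_phototroph(few_bch | {"bchE"}).level == "phototroph"

    def test_malformed_rules_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            call_phototroph(FULL_GENE_SET, {"rc_core": ["pufL", "pufM"]})


class TestDetectGeneCluster:
    def test_planted_cluster_exact_boundaries(self):
        annotations, truths = simulate_annotated_genomes(
            PlantedPGCSpec(genes_per_genome=500, with_cbb=True, seed=1)
        )
        (region,) = detect_gene_cluster(annotations[0], PGC_FAMILIES)
        truth = truths[0].regions[0]
        assert (region.first_index, region.last_index) == (
            truth["first_index"],
            truth["last_index"],
        )
        assert not region.left_at_contig_end and not region.right_at_contig_end

    def test_split_cluster_two_edge_flagged_regions(self):
        annotations, _ = simulate_annotated_genomes(
            PlantedPGCSpec(genes_per_genome=300, split_at=12, seed=2)
        )
        regions = detect_gene_cluster(annotations[0], PGC_FAMILIES)
        assert len(regions) == 2
        by_contig = {r.contig_id: r for r in regions}
        assert by_contig["G000_c1"].right_at_contig_end
        assert by_contig["G000_c2"].left_at_contig_end

    def test_scattered_genes_no_cluster(self):
        annotations, _ = simulate_annotated_genomes(
            PlantedPGCSpec(genes_per_genome=2000, scatter=True, seed=3)
        )
        assert detect_gene_cluster(annotations[0], PGC_FAMILIES, min_members=5) == []

    def test_gap_tolerance_and_member_coverage_monotone(self):
        annotations, _ = simulate_annotated_genomes(
            PlantedPGCSpec(genes_per_genome=400, seed=4)
        )
        covered = []
        for gap in (0, 2, 5, 10):
            regions = detect_gene_cluster(annotations[0], PGC_FAMILIES, max_gap=gap, min_members=1)
            covered.append(sum(r.n_members for r in regions))
        assert covered == sorted(covered)

    def test_invariant_to_noncategory_relabeling(self):
        annotations, _ = simulate_annotated_genomes(
            PlantedPGCSpec(genes_per_genome=300, seed=5)
        )
        ann = annotations[0]
        relabeled = ann.genes.copy()
        mask = ~relabeled.family_id.isin(PGC_FAMILIES)
        relabeled.loc[mask, "family_id"] = "zz_other"
        from caulotraits import GenomeAnnotation

        other = GenomeAnnotation(genome_id=ann.genome_id, genes=relabeled)
        a = detect_gene_cluster(ann, PGC_FAMILIES)
        b = detect_gene_cluster(other, PGC_FAMILIES)
        assert [(r.first_index, r.last_index) for r in a] == [
            (r.first_index, r.last_index) for r in b
        ]


class TestClusterSynteny:
    def region(self, families, strands=None, contig="c1"):
        strands = strands or ["+"] * len(families)
        return ClusterRegion(
            contig_id=contig,
            first_index=0,
            last_index=len(families) - 1,
            families=tuple(families),
            strands=tuple(strands),
        )

    def test_identical_regions_score_max(self):
        r = self.region(["pufL", "pufM", "pufH", "bchC"])
        score = cluster_synteny(r, r)
        assert score["adjacency_conservation"] == 1.0
        assert score["orientation_agreement"] == 1.0

    def test_disjoint_regions_score_zero(self):
        a = self.region(["pufL", "pufM"])
        b = self.region(["bchC", "bchD"])
        score = cluster_synteny(a, b)
        assert score["shared_families"] == 0
        assert score["adjacency_conservation"] == 0.0

    def test_internal_inversion_matches_brute_force(self):
        a = self.region(["g1", "g2", "g3", "g4", "g5"])
        # invert the g2..g4 block: order reversed, strands flipped
        b = self.region(
            ["g1", "g4", "g3", "g2", "g5"], strands=["+", "-", "-", "-", "+"]
        )
        score = cluster_synteny(a, b)
        shared = set(a.families) & set(b.families)
        assert score["adjacency_conservation"] == pytest.approx(
            brute_force_adjacency(list(a.families), list(b.families), shared)
        )
        # block-internal neighbors survive the inversion; flanking pairs break
        assert score["adjacency_conservation"] == pytest.approx(0.5)

    def test_orientation_relative_to_majority_frame(self):
        a = self.region(["g1", "g2", "g3"], strands=["+", "+", "-"])
        # whole cluster on the opposite strand: relative orientations agree
        b = self.region(["g1", "g2", "g3"], strands=["-", "-", "+"])
        score = cluster_synteny(a, b)
        assert score["orientation_agreement"] == 1.0


class TestScreenGenomes:
    def cohort(self, n_with=2, n_without=18):
        with_pgc = []
        if n_with:
            with_pgc, _ = simulate_annotated_genomes(
                PlantedPGCSpec(n_genomes=n_with, genes_per_genome=200, with_cbb=True, seed=6)
            )
        without = []
        if n_without:
            without, _ = simulate_annotated_genomes(
                PlantedPGCSpec(n_genomes=n_without, genes_per_genome=200, pgc_gene_order=(), seed=7)
            )
        families = {}
        for i, ann in enumerate(with_pgc):
            families[f"P{i:02d}"] = ann.family_set
        for i, ann in enumerate(without):
            families[f"N{i:02d}"] = ann.family_set
        return families

    def test_planted_fraction_recovered(self):
        table, frac = screen_genomes(self.cohort(2, 18))
        assert frac == pytest.approx(0.10)
        assert (table[table.level != "none"].genome_id.str.startswith("P")).all()

    def test_all_or_none(self):
        _, frac0 = screen_genomes(self.cohort(0, 10))
        assert frac0 == 0.0
        _, frac1 = screen_genomes(self.cohort(5, 0))
        assert frac1 == 1.0

    def test_duplicate_genome_ids_rejected(self):
        annotations, _ = simulate_annotated_genomes(
            PlantedPGCSpec(n_genomes=1, genes_per_genome=100, seed=8)
        )
        with pytest.raises(ValueError, match="duplicate"):
            screen_genomes(annotations + annotations)


def test_scatter_null_property():
    """Shuffling gene order removes clusters in nearly all randomizations."""
    hits = 0
    n = 40
    for seed in range(n):
        annotations, _ = simulate_annotated_genomes(
            PlantedPGCSpec(genes_per_genome=2000, scatter=True, seed=seed)
        )
        if detect_gene_cluster(annotations[0], PGC_FAMILIES, min_members=5):
            hits += 1
    assert hits / n <= 0.05
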
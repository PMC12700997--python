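"""RBH selection, evidence-coded matrices, clade aggregation, genome sizes."""

import numpy as np
import pandas as pd
import pytest

from caulotraits import (
    GenomeRecord,
    PresenceMatrix,
    aggregate_by_clade,
    build_matrix,
    environment_summary,
    estimated_genome_size,
    rbh_pairs,
)
from caulotraits.matrix import ABSENT, BOTH, KO_ONLY, RBH_ONLY

from oracles import brute_force_clade_means, brute_force_rbh


def hits(rows):
    return pd.DataFrame(rows, columns=["query_id", "subject_id", "bitscore", "e_value"])


class TestRBH:
    def test_mutual_best_pair_emitted(self):
        ab = hits([("a1", "b1", 200.0, 1e-50)])
        ba = hits([("b1", "a1", 190.0, 1e-48)])
        assert rbh_pairs(ab, ba) == {("a1", "b1")}

    def test_non_reciprocal_best_dropped(self):
        ab = hits([("a1", "b1", 200.0, 1e-50)])
        ba = hits([("b1", "a2", 300.0, 1e-60), ("b1", "a1", 100.0, 1e-20)])
        assert rbh_pairs(ab, ba) == set()

    def test_evalue_filter_applied_before_best(self):
        # best-scoring hit fails the e-value cut; runner-up must win
        ab = hits([("a1", "b1", 500.0, 1.0), ("a1", "b2", 100.0, 1e-30)])
        ba = hits([("b2", "a1", 90.0, 1e-25)])
        assert rbh_pairs(ab, ba) == {("a1", "b2")}

    def test_deterministic_tie_breaks(self):
        ab = hits([("a1", "b2", 100.0, 1e-30), ("a1", "b1", 100.0, 1e-30)])
        ba = hits([("b1", "a1", 100.0, 1e-30), ("b2", "a1", 100.0, 1e-30)])
        # equal bitscore and e-value: lexicographically smallest subject wins
        assert rbh_pairs(ab, ba) == {("a1", "b1")}

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(17)
        for rep in range(5):
            a_ids = [f"a{i}" for i in range(20)]
            b_ids = [f"b{i}" for i in range(20)]
            rows_ab, rows_ba = [], []
            for a in a_ids:
                for b in rng.choice(b_ids, size=8, replace=False):
                    rows_ab.append((a, b, float(rng.integers(50, 500)), float(10.0 ** -rng.integers(1, 60))))
            for b in b_ids:
                for a in rng.choice(a_ids, size=8, replace=False):
                    rows_ba.append((b, a, float(rng.integers(50, 500)), float(10.0 ** -rng.integers(1, 60))))
            got = rbh_pairs(hits(rows_ab), hits(rows_ba))
            assert got == brute_force_rbh(rows_ab, rows_ba)
            # partial matching: each id participates in at most one pair
            a_used = [a for a, _ in got]
            b_used = [b for _, b in got]
            assert len(a_used) == len(set(a_used)) and len(b_used) == len(set(b_used))

    def test_malformed_rows_reported(self):
        ab = hits([("a1", "b1", np.inf, 1e-5)])
        with pytest.raises(ValueError, match="malformed"):
            rbh_pairs(ab, hits([("b1", "a1", 100.0, 1e-5)]))


class TestBuildMatrix:
    FAMS = {
        "flagellum": {"ko": ["K02556"], "ref": ["CC_0793"]},
        "holdfast": {"ko": ["K99999"], "ref": ["CC_2277"]},
    }

    def test_evidence_codes(self):
        matrix = build_matrix(
            ko_tables={"g1": {"K02556"}, "g2": set(), "g3": {"K02556"}},
            rbh_maps={"g1": set(), "g2": {"CC_0793"}, "g3": {"CC_0793", "CC_2277"}},
            family_defs=self.FAMS,
        )
        assert matrix.codes.loc["g1", "flagellum"] == KO_ONLY
        assert matrix.codes.loc["g2", "flagellum"] == RBH_ONLY
        assert matrix.codes.loc["g3", "flagellum"] == BOTH
        assert matrix.codes.loc["g1", "holdfast"] == ABSENT
        assert matrix.codes.loc["g3", "holdfast"] == RBH_ONLY

    def test_presence_is_union_of_channels(self):
        matrix = build_matrix(
            ko_tables={"g1": {"K02556"}},
            rbh_maps={"g1": set()},
            family_defs=self.FAMS,
        )
        assert bool(matrix.presence.loc["g1", "flagellum"])
        assert not bool(matrix.presence.loc["g1", "holdfast"])

    def test_family_without_ids_rejected(self):
        with pytest.raises(ValueError, match="empty_family"):
            build_matrix({"g": set()}, {"g": set()}, {"empty_family": {"ko": [], "ref": []}})

    def test_monotone_under_added_evidence(self):
        base = build_matrix({"g": set()}, {"g": set()}, self.FAMS)
        more = build_matrix({"g": {"K02556"}}, {"g": {"CC_2277"}}, self.FAMS)
        assert (more.presence.to_numpy() >= base.presence.to_numpy()).all()


class TestAggregation:
    def test_simple_fraction(self):
        pres = pd.DataFrame(
            {"f": [True, False, False, False]}, index=["a", "b", "c", "d"]
        )
        matrix = PresenceMatrix.from_presence(pres)
        out = aggregate_by_clade(matrix, {g: "clade1" for g in pres.index})
        assert out.loc["clade1", "f"] == pytest.approx(0.25)

    def test_unmapped_genome_listed(self):
        matrix = PresenceMatrix.from_presence(pd.DataFrame({"f": [True]}, index=["a"]))
        with pytest.raises(ValueError, match="a"):
            aggregate_by_clade(matrix, {})

    def test_singleton_clade_reproduces_binary_row(self):
        rng = np.random.default_rng(3)
        pres = pd.DataFrame(
            rng.random((4, 6)) < 0.5,
            index=list("abcd"),
            columns=[f"f{i}" for i in range(6)],
        )
        matrix = PresenceMatrix.from_presence(pres)
        out = aggregate_by_clade(matrix, {g: g for g in pres.index})
        assert (out.loc[list("abcd")].to_numpy() == pres.to_numpy().astype(float)).all()

    def test_matches_brute_force_group_means(self):
        rng = np.random.default_rng(9)
        genomes = [f"g{i}" for i in range(50)]
        pres = pd.DataFrame(
            rng.random((50, 20)) < 0.6, index=genomes, columns=[f"f{i}" for i in range(20)]
        )
        clade_map = {g: f"c{rng.integers(5)}" for g in genomes}
        out = aggregate_by_clade(PresenceMatrix.from_presence(pres), clade_map)
        expected = brute_force_clade_means(pres, clade_map)
        for clade, fams in expected.items():
            for fam, val in fams.items():
                assert out.loc[clade, fam] == pytest.approx(val)
        assert ((out.to_numpy() >= 0) & (out.to_numpy() <= 1)).all()


class TestFamilyDefs:
    def test_shipped_defaults_load_and_build(self):
        from caulotraits.matrix import load_family_defs

        defs = load_family_defs()
        assert {"flgH", "creS", "pufM", "cbbL"} <= set(defs)
        assert all(d.get("ko") or d.get("ref") for d in defs.values())
        matrix = build_matrix(
            ko_tables={"g1": {"K08929", "K18642"}},
            rbh_maps={"g1": {"CC_1873"}},
            family_defs=defs,
        )
        assert matrix.codes.loc["g1", "pufM"] == KO_ONLY
        assert matrix.codes.loc["g1", "creS"] == BOTH


class TestGenomeSize:
    def test_formula(self):
        assert estimated_genome_size(GenomeRecord("g", 4_000_000, 1.0)) == 4_000_000
        assert estimated_genome_size(GenomeRecord("g", 2_000_000, 0.5)) == 4_000_000

    def test_percent_autodetected(self):
        with pytest.warns(UserWarning, match="percent"):
            assert estimated_genome_size(GenomeRecord("g", 1_000_000, 50.0)) == 2_000_000

    def test_zero_completeness_rejected(self):
        with pytest.raises(ValueError):
            estimated_genome_size(GenomeRecord("g", 1_000_000, 0.0))

    def test_estimate_never_below_assembly(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            size = float(rng.integers(1_000_000, 6_000_000))
            comp = float(rng.uniform(0.5, 1.0))
            est = estimated_genome_size(GenomeRecord("g", size, comp))
            assert est >= size
            assert (est == size) == (comp == 1.0)


class TestEnvironmentSummary:
    def records(self):
        cats = ["terrestrial"] * 3 + ["aquatic_freshwater"] * 6 + ["weird_habitat"]
        return [
            GenomeRecord(f"g{i}", 4e6, 1.0, environment_category=c, family="Caulobacteraceae")
            for i, c in enumerate(cats)
        ]

    def test_fractions_sum_to_one_and_match_tally(self):
        fractions, sizes = environment_summary(self.records())
        row = fractions.loc["Caulobacteraceae"]
        assert row.sum() == pytest.approx(1.0)
        assert row["terrestrial"] == pytest.approx(0.3)
        assert row["unclassified"] == pytest.approx(0.1)  # unknown category mapped

    def test_single_category(self):
        recs = [GenomeRecord("g", 4e6, 1.0, environment_category="terrestrial", family="F")]
        fractions, _ = environment_summary(recs)
        assert fractions.loc["F", "terrestrial"] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            environment_summary([])
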
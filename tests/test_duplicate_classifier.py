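"""Singleton segregation, family clustering, positional classification."""

import itertools

import pytest

from paraminer.alignment_scores import Hit, SelfScoreRecord, self_score_table
from paraminer.duplicate_classifier import (
    ClassifierParams,
    cluster_duplicates,
    score_group_confidence,
    segregate_singletons,
)
from paraminer.thresholding_qc import ThresholdDecision

from conftest import collinear_catalog, make_catalog


def decision_score(cutoff):
    return ThresholdDecision(method="busco_auto", score_cutoff=cutoff, self_simcut=None)


def rec(gid, self_bits=None, best=None, best_bits=None, best_sim=None):
    return SelfScoreRecord(
        gene_id=gid, self_bitscore=self_bits, second_best_subject=best,
        second_best_bitscore=best_bits, second_best_similarity=best_sim,
    )


class TestSegregation:
    def test_no_self_hit_is_singleton(self):
        table = {"g1": rec("g1")}
        singles, dups = segregate_singletons(table, decision_score(0.5))
        assert singles == {"g1"} and dups == set()

    def test_only_self_hit_is_singleton(self):
        table = {"g1": rec("g1", self_bits=200.0)}
        singles, _ = segregate_singletons(table, decision_score(0.0))
        assert singles == {"g1"}

    def test_norm_score_at_benchmark_cutoff(self):
        table = {"g1": rec("g1", 200.0, "g2", 140.0, 90.0)}  # norm 0.70
        _, dups = segregate_singletons(table, decision_score(0.696))
        assert dups == {"g1"}
        singles, _ = segregate_singletons(table, decision_score(0.71))
        assert singles == {"g1"}

    def test_zero_zero_manual_cutoffs_make_any_hit_a_duplicate(self):
        decision = ThresholdDecision(method="manual", score_cutoff=0.0, self_simcut=0.0)
        table = {
            "hit": rec("hit", 200.0, "x", 1.0, 1.0),
            "lonely": rec("lonely", 200.0),
            "absent": rec("absent"),
        }
        singles, dups = segregate_singletons(table, decision)
        assert dups == {"hit"}
        assert singles == {"lonely", "absent"}

    def test_manual_mode_requires_both_cutoffs(self):
        decision = ThresholdDecision(method="manual", score_cutoff=0.5, self_simcut=50.0)
        table = {
            "both": rec("both", 100.0, "x", 60.0, 70.0),
            "score_only": rec("score_only", 100.0, "x", 60.0, 30.0),
            "sim_only": rec("sim_only", 100.0, "x", 40.0, 70.0),
        }
        singles, dups = segregate_singletons(table, decision)
        assert dups == {"both"}
        assert singles == {"score_only", "sim_only"}

    def test_similarity_fallback_uses_similarity_only(self):
        decision = ThresholdDecision(method="similarity_fallback", score_cutoff=None, self_simcut=50.0)
        table = {"g": rec("g", 100.0, "x", 10.0, 80.0)}  # norm 0.1 but sim 80
        _, dups = segregate_singletons(table, decision)
        assert dups == {"g"}

    def test_conservation_identity(self):
        table = {
            f"g{i}": rec(f"g{i}", 100.0, "x", 100.0 * (i % 10) / 10, 50.0)
            for i in range(200)
        }
        singles, dups = segregate_singletons(table, decision_score(0.5))
        assert len(singles) + len(dups) == 200
        assert singles.isdisjoint(dups)

    def test_raising_cutoff_never_increases_duplicates(self):
        table = {
            f"g{i}": rec(f"g{i}", 100.0, "x", float(i), 50.0) for i in range(100)
        }
        sizes = [
            len(segregate_singletons(table, decision_score(c))[1])
            for c in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


def hits_for(pairs, bits=95.0, self_bits=100.0):
    """Symmetric passing hits for the given pairs plus self hits."""
    genes = sorted({g for p in pairs for g in p})
    hits = [Hit(g, g, 100.0, 1e-30, self_bits) for g in genes]
    for a, b in pairs:
        hits.append(Hit(a, b, 90.0, 1e-30, bits))
        hits.append(Hit(b, a, 90.0, 1e-30, bits))
    return hits


def classify(catalog, pairs, mode="overlap", proximity=10, cutoff=0.5):
    genes = {g for p in pairs for g in p}
    hits = hits_for(pairs)
    return cluster_duplicates(
        genes, hits, decision_score(cutoff), catalog,
        ClassifierParams(proximity=proximity, mode=mode),
    )


class TestClustering:
    def test_four_consecutive_genes_form_one_tandem_group(self):
        catalog = collinear_catalog(6)
        pairs = list(itertools.combinations(["g001", "g002", "g003", "g004"], 2))
        partition = classify(catalog, pairs)
        assert len(partition.groups) == 1
        g = partition.groups[0]
        assert g.klass == "tandem"
        assert g.members == ["g001", "g002", "g003", "g004"]
        assert g.confidence == "high"

    def test_pair_with_five_intervening_genes_is_proximal(self):
        catalog = collinear_catalog(10)
        partition = classify(catalog, [("g002", "g008")], proximity=10)
        assert [g.klass for g in partition.groups] == ["proximal"]
        assert partition.groups[0].members == ["g002", "g008"]

    def test_pair_beyond_proximity_is_dispersed(self):
        catalog = collinear_catalog(20)
        partition = classify(catalog, [("g000", "g015")], proximity=10)
        assert [g.klass for g in partition.groups] == ["dispersed"]

    def test_cross_contig_pair_is_dispersed(self):
        catalog = make_catalog([("a", "c1", 1, 50), ("b", "c2", 1, 50)])
        partition = classify(catalog, [("a", "b")])
        assert [g.klass for g in partition.groups] == ["dispersed"]

    def test_mixed_family_overlap_mode_emits_tandem_plus_dispersed_with_relationship(self):
        catalog = make_catalog(
            [("A", "c1", 1, 50), ("B", "c1", 100, 150), ("C", "c2", 1, 50)]
        )
        pairs = [("A", "B"), ("A", "C"), ("B", "C")]
        partition = classify(catalog, pairs, mode="overlap")
        by_class = {g.klass: g for g in partition.groups}
        assert set(by_class) == {"tandem", "dispersed"}
        assert by_class["tandem"].members == ["A", "B"]
        # tandem run collapsed to its representative in the dispersed link
        assert by_class["dispersed"].members == ["A", "C"]
        assert len(partition.relationships) == 1
        group_ids, shared = next(iter(partition.relationships.values()))
        assert set(group_ids) == {g.group_id for g in partition.groups}
        assert shared == ["A"]

    def test_mixed_family_strict_mode_is_one_mixed_group_with_subclasses(self):
        catalog = make_catalog(
            [("A", "c1", 1, 50), ("B", "c1", 100, 150), ("C", "c2", 1, 50)]
        )
        partition = classify(catalog, [("A", "B"), ("A", "C"), ("B", "C")], mode="strict")
        assert len(partition.groups) == 1
        g = partition.groups[0]
        assert g.klass == "mixed"
        assert g.member_subclass == {"A": "tandem", "B": "tandem", "C": "dispersed"}

    def test_strict_mode_partitions_duplicates(self):
        catalog = collinear_catalog(30)
        pairs = [("g000", "g001"), ("g010", "g013"), ("g020", "g029")]
        partition = classify(catalog, pairs, mode="strict", proximity=5)
        seen = [m for g in partition.groups for m in g.members]
        assert sorted(seen) == sorted(set(seen))  # disjoint
        assert set(seen) == partition.duplicates

    def test_overlap_mode_groups_cover_all_grouped_duplicates(self):
        catalog = make_catalog(
            [("A", "c1", 1, 50), ("B", "c1", 100, 150), ("C", "c2", 1, 50)]
        )
        partition = classify(catalog, [("A", "B"), ("A", "C"), ("B", "C")])
        covered = {m for g in partition.groups for m in g.members}
        assert covered <= partition.duplicates

    def test_tandem_pairs_always_satisfy_proximity_predicate(self):
        catalog = collinear_catalog(8)
        pairs = list(itertools.combinations(["g002", "g003", "g004"], 2))
        partition = classify(catalog, pairs, proximity=1)
        tandem = next(g for g in partition.groups if g.klass == "tandem")
        for a, b in itertools.combinations(tandem.members, 2):
            gap = abs(catalog.order_index[a] - catalog.order_index[b]) - 1
            assert gap <= 1

    def test_missing_catalog_gene_raises(self):
        catalog = collinear_catalog(3)
        with pytest.raises(ValueError, match="missing from catalog"):
            cluster_duplicates(
                {"ghost"}, [], decision_score(0.5), catalog, ClassifierParams()
            )


class TestConfidence:
    def pairs(self, edges):
        return {frozenset(e) for e in edges}

    def test_full_clique_is_high(self):
        members = ["a", "b", "c"]
        edges = self.pairs([("a", "b"), ("a", "c"), ("b", "c")])
        assert score_group_confidence(members, edges) == "high"

    def test_half_connected_is_moderate(self):
        members = ["a", "b", "c", "d"]  # 3 of 6 pairs
        edges = self.pairs([("a", "b"), ("b", "c"), ("c", "d")])
        assert score_group_confidence(members, edges) == "moderate"

    def test_path_of_five_is_low(self):
        members = list("abcde")  # 4 of 10 pairs
        edges = self.pairs([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
        assert score_group_confidence(members, edges) == "low"


def test_planted_truth_recovered_exactly(bundle):
    """Noise-free synthetic fixture: classes match the planted truth."""
    from paraminer.alignment_scores import load_hits
    from paraminer.annotation_io import collapse_isoforms, parse_annotation, read_fasta

    models, report = parse_annotation(bundle.gff3)
    assert report.passed
    catalog = collapse_isoforms(models, read_fasta(bundle.protein_fasta), "protein")
    hits = load_hits(bundle.hit_table)
    table = self_score_table(hits, catalog)
    decision = decision_score(0.5)
    singles, dups = segregate_singletons(table, decision)
    partition = cluster_duplicates(dups, hits, decision, catalog, ClassifierParams())

    truth_by_members = {
        frozenset(meta["members"]): meta["class"]
        for meta in bundle.truth.families.values()
    }
    got_by_members = {frozenset(g.members): g.klass for g in partition.groups}
    assert got_by_members == truth_by_members
    assert all(m in singles for m in bundle.truth.markers)
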
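"""BRH detection, in-paralog rules and the triangulation stage machine."""

from __future__ import annotations

import random

import pytest

from oracles import brute_force_stage_machine
from triortho.cluster import (best_reciprocal_hits, cluster_all_levels,
                              cluster_at_level, in_paralogs,
                              triangulate_and_cluster)
from triortho.io import read_taxonomy
from triortho.model import BRHEdge, InParalogLink, SimilarityHit, TaxonomyLevel
from triortho.simulate import truth_at_level
from conftest import random_stage_instance


def _hit(q, s, score):
    return SimilarityHit(query_id=q, subject_id=s, raw_score=score,
                         pct_identity=50.0, aln_len=100,
                         q_start=1, q_end=100, s_start=1, s_end=100)


def _sym(q, s, score):
    return [_hit(q, s, score), _hit(s, q, score)]


class TestBestReciprocalHits:
    GENOME_OF = {"a": "A", "a2": "A", "b": "B", "b1": "B", "b2": "B",
                 "c": "B"}

    def test_mutual_unique_best_yields_edge(self):
        hits = _sym("a", "b", 100)
        edges = best_reciprocal_hits(hits, self.GENOME_OF)
        assert len(edges) == 1
        assert edges[0].genes == ("a", "b")
        assert edges[0].score == 100

    def test_reciprocity_failure_yields_nothing(self):
        # b's best hit in A is a2 (120), so a<->b is not reciprocal
        hits = _sym("a", "b", 100) + _sym("a2", "b", 120)
        edges = best_reciprocal_hits(hits, self.GENOME_OF)
        assert [e.genes for e in edges] == [("a2", "b")]

    def test_ties_kept_both_edges(self):
        hits = _sym("a", "b1", 100) + _sym("a", "b2", 100)
        edges = best_reciprocal_hits(hits, self.GENOME_OF)
        assert [e.genes for e in edges] == [("a", "b1"), ("a", "b2")]

    def test_edge_score_is_min_of_directions(self):
        hits = [_hit("a", "b", 100), _hit("b", "a", 90)]
        edges = best_reciprocal_hits(hits, self.GENOME_OF)
        assert edges[0].score == 90

    def test_intra_genome_hits_ignored(self):
        hits = _sym("b1", "b2", 500)
        assert best_reciprocal_hits(hits, self.GENOME_OF) == []


class TestInParalogs:
    GENOME_OF = {"g": "A", "h": "A", "b": "B", "c": "C"}

    def test_intra_above_brh_linked(self):
        edges = [BRHEdge(gene_a="b", gene_b="g", score=120, identity=50)]
        hits = _sym("g", "h", 150)
        links = in_paralogs(hits, edges, self.GENOME_OF, {"A", "B"})
        assert len(links) == 1
        assert links[0].gene == "h" and links[0].anchor == "g"

    def test_equal_score_not_linked(self):
        edges = [BRHEdge(gene_a="b", gene_b="g", score=120, identity=50),
                 BRHEdge(gene_a="c", gene_b="h", score=120, identity=50)]
        hits = _sym("g", "h", 120)
        assert in_paralogs(hits, edges, self.GENOME_OF,
                           {"A", "B", "C"}) == []

    def test_no_brh_anywhere_no_link(self):
        hits = _sym("g", "h", 500)
        assert in_paralogs(hits, [], self.GENOME_OF, {"A", "B"}) == []

    def test_threshold_is_most_distant_partner(self):
        # g's BRH scores: 200 to genome B, 90 to genome C; a duplicate
        # produced between the two speciations scores in between.
        edges = [BRHEdge(gene_a="b", gene_b="g", score=200, identity=80),
                 BRHEdge(gene_a="c", gene_b="g", score=90, identity=40),
                 BRHEdge(gene_a="c", gene_b="h", score=85, identity=38)]
        hits = _sym("g", "h", 150)
        links = in_paralogs(hits, edges, self.GENOME_OF, {"A", "B", "C"})
        assert len(links) == 1  # 150 > min(T(g)=90, T(h)=85)

    def test_level_dependence_of_links(self):
        # a1 pairs with b (120); a2 pairs only with c (90); intra 100.
        genome_of = {"a1": "A", "a2": "A", "b": "B", "c": "C"}
        hits = (_sym("a1", "b", 120) + _sym("a2", "c", 90)
                + _sym("a1", "a2", 100))
        edges_ab = best_reciprocal_hits(
            [h for h in hits if genome_of[h.query_id] in "AB"
             and genome_of[h.subject_id] in "AB"], genome_of)
        assert in_paralogs(hits, edges_ab, genome_of, {"A", "B"}) == []
        edges_root = best_reciprocal_hits(hits, genome_of)
        links = in_paralogs(hits, edges_root, genome_of, {"A", "B", "C"})
        assert [(l.gene, l.anchor) for l in links] == [("a2", "a1")]


LEVEL3 = TaxonomyLevel(level_id="L", member_genomes=frozenset("ABC"))
LEVEL4 = TaxonomyLevel(level_id="L", member_genomes=frozenset("ABCD"))
LEVEL2 = TaxonomyLevel(level_id="L", member_genomes=frozenset("AB"))


def _edge(a, b, score=100):
    a, b = sorted((a, b))
    return BRHEdge(gene_a=a, gene_b=b, score=score, identity=50.0)


class TestTriangulateAndCluster:
    def test_single_triangle_single_group(self):
        genome_of = {"a": "A", "b": "B", "c": "C"}
        edges = [_edge("a", "b"), _edge("a", "c"), _edge("b", "c")]
        res = triangulate_and_cluster(edges, [], LEVEL3, genome_of)
        assert [set(g.members) for g in res.groups] == [{"a", "b", "c"}]

    def test_two_genomes_degenerate_to_pair_groups(self):
        genome_of = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        edges = [_edge("a1", "b1"), _edge("a2", "b2")]
        res = triangulate_and_cluster(edges, [], LEVEL2, genome_of)
        assert sorted(sorted(g.members) for g in res.groups) == \
            [["a1", "b1"], ["a2", "b2"]]

    def test_triangles_sharing_edge_merge(self):
        genome_of = {"a": "A", "b": "B", "c": "C", "d": "D"}
        edges = [_edge("a", "b"), _edge("a", "c"), _edge("b", "c"),
                 _edge("a", "d"), _edge("b", "d")]
        res = triangulate_and_cluster(edges, [], LEVEL4, genome_of)
        assert [set(g.members) for g in res.groups] == [{"a", "b", "c", "d"}]

    def test_cross_cluster_edge_without_triangle_does_not_merge(self):
        genome_of = {"a": "A", "b": "B", "c": "C",
                     "x": "A", "y": "B", "z": "C"}
        edges = [_edge("a", "b"), _edge("a", "c"), _edge("b", "c"),
                 _edge("x", "y"), _edge("x", "z"), _edge("y", "z"),
                 _edge("a", "y", score=999)]  # bridge, no triangle support
        res = triangulate_and_cluster(edges, [], LEVEL3, genome_of)
        assert sorted(sorted(g.members) for g in res.groups) == \
            [["a", "b", "c"], ["x", "y", "z"]]
        assert [e.genes for e in res.unverified_edges] == [("a", "y")]

    def test_in_paralog_attaches_and_pulls_its_group(self):
        genome_of = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c": "C"}
        edges = [_edge("a1", "b1"), _edge("a1", "c"), _edge("b1", "c"),
                 _edge("a2", "b2")]
        links = [InParalogLink(gene="a2", anchor="a1", score=150)]
        res = triangulate_and_cluster(edges, links, LEVEL3, genome_of)
        assert [set(g.members) for g in res.groups] == \
            [{"a1", "a2", "b1", "b2", "c"}]

    def test_expansion_reattaches_absorbed_copies(self):
        genome_of = {"a": "A", "b": "B", "c": "C"}
        edges = [_edge("a", "b"), _edge("a", "c"), _edge("b", "c")]
        res = triangulate_and_cluster(edges, [], LEVEL3, genome_of,
                                      expansion={"a": ["a_copy"]})
        assert [set(g.members) for g in res.groups] == \
            [{"a", "a_copy", "b", "c"}]

    def test_gene_outside_level_errors(self):
        genome_of = {"a": "A", "z": "Z"}
        with pytest.raises(ValueError, match="outside level"):
            triangulate_and_cluster([_edge("a", "z")], [], LEVEL2, genome_of)

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_brute_force_on_random_instances(self, trial):
        rng = random.Random(1000 + trial)
        for _ in range(30):
            edges, links, genome_of = random_stage_instance(rng)
            level = TaxonomyLevel(level_id="L",
                                  member_genomes=frozenset(genome_of.values())
                                  if len(set(genome_of.values())) >= 2
                                  else frozenset({"A", "B"}))
            res = triangulate_and_cluster(edges, links, level, genome_of)
            got = {g.members for g in res.groups}
            expected = brute_force_stage_machine(edges, links, genome_of)
            assert got == expected


class TestLevels:
    def test_partition_property_every_level(self, small_bundle):
        sim = small_bundle.sim
        groups = cluster_all_levels(small_bundle.hits, sim.taxonomy,
                                    sorted(sim.taxonomy.levels),
                                    sim.genome_of, small_bundle.expansion)
        for level_id, gs in groups.items():
            seen: set[str] = set()
            for g in gs:
                assert not (seen & g.members), f"overlap at {level_id}"
                seen |= g.members

    def test_child_groups_nest_in_parent_groups(self, small_bundle):
        # clean data: groups at a child level refine the parent level
        sim = small_bundle.sim
        groups = cluster_all_levels(small_bundle.hits, sim.taxonomy,
                                    ["AB", "ABCD", "ROOT"], sim.genome_of,
                                    small_bundle.expansion)
        for child, parent in (("AB", "ABCD"), ("ABCD", "ROOT")):
            parent_of_gene = {g: grp.og_id for grp in groups[parent]
                              for g in grp.members}
            n_ok = 0
            for grp in groups[child]:
                parents = {parent_of_gene.get(g) for g in grp.members}
                if len(parents) == 1 and None not in parents:
                    n_ok += 1
            assert n_ok / len(groups[child]) >= 0.99

    def test_shuffled_hits_change_nothing(self, small_bundle):
        sim = small_bundle.sim
        ref = cluster_all_levels(small_bundle.hits, sim.taxonomy,
                                 ["ROOT", "AB"], sim.genome_of,
                                 small_bundle.expansion)
        shuffled = list(small_bundle.hits)
        random.Random(9).shuffle(shuffled)
        alt = cluster_all_levels(shuffled, sim.taxonomy, ["ROOT", "AB"],
                                 sim.genome_of, small_bundle.expansion)
        for lv in ref:
            assert [(g.og_id, g.members) for g in ref[lv]] == \
                   [(g.og_id, g.members) for g in alt[lv]]

    def test_single_genome_level_rejected(self):
        with pytest.raises(ValueError):
            TaxonomyLevel(level_id="X", member_genomes=frozenset({"A"}))

    def test_ground_truth_recovered_on_small_clean_data(self, small_bundle):
        sim = small_bundle.sim
        res = cluster_at_level(small_bundle.hits,
                               sim.taxonomy.level("ROOT"), sim.genome_of,
                               small_bundle.expansion)
        truth = truth_at_level(sim, "ROOT")
        assert {g.members for g in res.groups} == set(truth.blocks.values())
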
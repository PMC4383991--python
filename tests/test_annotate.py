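"""Phyletic profiles, evolutionary rates, architectures, siblings, queries."""

from __future__ import annotations

import pytest

from triortho.annotate import (brh_baseline, evolutionary_rate,
                               gene_architecture, phyletic_profile,
                               query_by_profile, sibling_groups)
from triortho.cluster import best_reciprocal_hits, cluster_at_level
from triortho.model import BRHEdge, OrthologGroup, TaxonomyLevel

LEVEL4 = TaxonomyLevel(level_id="L", member_genomes=frozenset("ABCD"))


def _group(members, og_id="OGL_000001"):
    return OrthologGroup(og_id=og_id, level_id="L", members=frozenset(members))


class TestPhyleticProfile:
    GENOME_OF = {"a1": "A", "a2": "A", "b1": "B", "c1": "C", "d1": "D"}

    def test_all_single_copy(self):
        prof, uni, dup, cls = phyletic_profile(
            _group({"a1", "b1", "c1", "d1"}), LEVEL4, self.GENOME_OF)
        assert prof.counts == {"A": 1, "B": 1, "C": 1, "D": 1}
        assert (uni, dup, cls) == (1.0, 0.0, "single_copy_in_all")

    def test_patchy_with_duplication(self):
        prof, uni, dup, cls = phyletic_profile(
            _group({"a1", "a2", "b1", "c1"}), LEVEL4, self.GENOME_OF)
        assert prof.counts == {"A": 2, "B": 1, "C": 1, "D": 0}
        assert uni == pytest.approx(0.75)
        assert dup == pytest.approx(1 / 3)
        assert cls == "patchy"

    def test_present_vs_multi_copy_classes(self):
        g6 = dict(self.GENOME_OF, a2="A", b2="B", c2="C", d2="D")
        _, _, _, cls = phyletic_profile(
            _group({"a1", "a2", "b1", "c1", "d1"}), LEVEL4, g6)
        assert cls == "present_in_all"
        _, _, dup, cls = phyletic_profile(
            _group({"a1", "a2", "b1", "b2", "c1", "c2", "d1", "d2"}),
            LEVEL4, g6)
        assert cls == "multi_copy_in_all"
        assert dup == 1.0

    def test_counts_sum_to_group_size(self):
        prof, *_ = phyletic_profile(
            _group({"a1", "a2", "b1"}), LEVEL4, self.GENOME_OF)
        assert sum(prof.counts.values()) == 3


class TestEvolutionaryRate:
    GENOME_OF = {"a1": "A", "b1": "B", "c1": "C"}

    def test_identity_equal_to_baseline_gives_one(self):
        base = {frozenset("AB"): 80.0, frozenset("AC"): 70.0,
                frozenset("BC"): 75.0}
        ident = {("a1", "b1"): 80.0, ("a1", "c1"): 70.0, ("b1", "c1"): 75.0}
        rate = evolutionary_rate(_group({"a1", "b1", "c1"}), ident, base,
                                 self.GENOME_OF)
        assert rate == pytest.approx(1.0)

    def test_single_pair_ratio(self):
        rate = evolutionary_rate(_group({"a1", "b1"}),
                                 {("a1", "b1"): 40.0},
                                 {frozenset("AB"): 80.0}, self.GENOME_OF)
        assert rate == pytest.approx(0.5)

    def test_single_genome_group_undefined(self):
        genome_of = {"a1": "A", "a2": "A"}
        rate = evolutionary_rate(_group({"a1", "a2"}),
                                 {("a1", "a2"): 99.0}, {}, genome_of)
        assert rate is None

    def test_pairs_without_baseline_skipped(self):
        ident = {("a1", "b1"): 40.0, ("a1", "c1"): 90.0}
        rate = evolutionary_rate(_group({"a1", "b1", "c1"}), ident,
                                 {frozenset("AB"): 80.0}, self.GENOME_OF)
        assert rate == pytest.approx(0.5)  # A-C pair has no baseline

    def test_rate_near_one_on_simulated_single_copy_groups(self, clean_bundle):
        sim = clean_bundle.sim
        level = sim.taxonomy.level("ROOT")
        res = cluster_at_level(clean_bundle.hits, level, sim.genome_of,
                               clean_bundle.expansion)
        edges = best_reciprocal_hits(clean_bundle.hits, sim.genome_of)
        base = brh_baseline(edges, sim.genome_of)
        rates = [evolutionary_rate(g, clean_bundle.hits, base, sim.genome_of)
                 for g in res.groups]
        rates = [r for r in rates if r is not None]
        assert len(rates) == len(res.groups)
        mean = sum(rates) / len(rates)
        assert abs(mean - 1.0) <= 0.05


META = {
    "a1": ("A", 100, 4, ("D1",)),
    "b1": ("B", 102, 4, ("D1",)),
    "c1": ("C", 98, 5, ("D1", "D2")),
    "d1": ("D", 400, None, ()),
}


class TestGeneArchitecture:
    def test_uniform_lengths(self):
        meta = {g: ("A", 100, None, ()) for g in ("x", "y", "z")}
        arch = gene_architecture(_group({"x", "y", "z"}), meta)
        assert arch.length_median == 100
        assert arch.length_sd == 0
        assert arch.deviants == ()
        assert arch.exon_median is None

    def test_gross_outlier_hidden_by_plain_sd_caught_by_mad(self):
        group = _group({"a1", "b1", "c1", "d1"})
        plain = gene_architecture(group, META)
        assert plain.length_median == pytest.approx(101.0)
        assert "d1" not in plain.deviants  # 400 inflates the SD it hides in
        robust = gene_architecture(group, META, robust=True)
        assert robust.deviants == ("d1",)

    def test_single_member(self):
        arch = gene_architecture(_group({"a1"}), META)
        assert arch.length_median == 100
        assert arch.length_sd == 0

    def test_no_metadata_errors(self):
        with pytest.raises(ValueError, match="no metadata"):
            gene_architecture(_group({"zz"}), META)


class TestSiblingGroups:
    def test_shared_domain_two_organisms_each(self):
        meta = {"a1": ("A", 100, None, ("D",)), "b1": ("B", 100, None, ("D",)),
                "c1": ("C", 100, None, ("D",)), "e1": ("E", 100, None, ("D",))}
        x = _group({"a1", "b1"}, "OGX")
        y = _group({"c1", "e1"}, "OGY")
        rels = sibling_groups([x, y], meta)
        assert len(rels) == 1
        assert rels[0].shared_domains == {"D"}
        assert {rels[0].group_a, rels[0].group_b} == {"OGX", "OGY"}

    def test_one_organism_in_second_group_fails(self):
        meta = {"a1": ("A", 100, None, ("D",)), "b1": ("B", 100, None, ("D",)),
                "c1": ("C", 100, None, ("D",)), "c2": ("C", 100, None, ())}
        rels = sibling_groups([_group({"a1", "b1"}, "OGX"),
                               _group({"c1", "c2"}, "OGY")], meta)
        assert rels == []

    def test_two_genes_one_organism_counts_once(self):
        # domain twice in genome A only: organisms == 1, not 2
        meta = {"a1": ("A", 100, None, ("D",)), "a2": ("A", 100, None, ("D",)),
                "c1": ("C", 100, None, ("D",)), "e1": ("E", 100, None, ("D",))}
        rels = sibling_groups([_group({"a1", "a2"}, "OGX"),
                               _group({"c1", "e1"}, "OGY")], meta)
        assert rels == []

    def test_symmetric_irreflexive(self):
        meta = {"a1": ("A", 100, None, ("D",)), "b1": ("B", 100, None, ("D",)),
                "c1": ("C", 100, None, ("D",)), "e1": ("E", 100, None, ("D",))}
        rels = sibling_groups([_group({"a1", "b1"}, "OGX"),
                               _group({"c1", "e1"}, "OGY")], meta)
        for r in rels:
            assert r.group_a != r.group_b
            assert r.group_a < r.group_b  # canonical, each pair once


class TestProfileQueries:
    GENOME_OF = {"a1": "A", "a2": "A", "b1": "B", "c1": "C", "d1": "D"}

    def test_class_query(self):
        genome_of = dict(self.GENOME_OF, x1="C")
        groups = [_group({"a1", "b1", "c1", "d1"}, "OG1"),
                  _group({"a2", "x1"}, "OG2")]
        assert query_by_profile(groups, LEVEL4, genome_of,
                                "single_copy_in_all") == ["OG1"]

    def test_pattern_query_absence(self):
        groups = [_group({"a1", "b1", "c1", "d1"}, "OG1"),
                  _group({"b1", "c1"}, "OG2")]
        assert query_by_profile(groups, LEVEL4, self.GENOME_OF,
                                "A=0") == ["OG2"]
        assert query_by_profile(groups, LEVEL4, self.GENOME_OF,
                                "A=1,B>=1") == ["OG1"]

    def test_empty_result_valid(self):
        groups = [_group({"a1", "b1"}, "OG1")]
        assert query_by_profile(groups, LEVEL4, self.GENOME_OF, "A>=5") == []

    def test_unknown_class_errors(self):
        with pytest.raises(ValueError, match="unknown profile class"):
            query_by_profile([], LEVEL4, self.GENOME_OF, "sometimes_copy")
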
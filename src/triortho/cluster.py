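"""Ortholog delineation: BRH detection, in-paralogs, triangulation clustering.

The delineation is a three-step procedure run independently at every
requested taxonomy level:

1. **Best reciprocal hits (BRH).**  For each genome pair, a gene's best
   hit set in the partner genome is every gene attaining its maximal raw
   alignment score (ties kept).  An undirected edge is formed when two
   genes are in each other's best hit sets.

2. **In-paralogs.**  Within-genome matches scoring strictly higher than
   the best inter-genome BRH of either gene are post-speciation
   duplications (co-orthologs) and are linked to the clustered copy.

3. **Triangulation + clustering.**  BRH edges corroborated by a third
   genome (triangles) seed clusters; remaining edges extend or form
   two-gene groups, cross-cluster edges without triangle support never
   merge clusters; in-paralog links then attach duplicates, and collapsed
   near-identical copies are re-expanded.

A naive connected-components closure over the same edges is available for
comparison (``closure="naive"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf
from typing import Iterable, Mapping, Sequence

from .io import Taxonomy, assign_group_ids
from .model import BRHEdge, InParalogLink, OrthologGroup, SimilarityHit, TaxonomyLevel


# ---------------------------------------------------------------------------
# Step 1: best reciprocal hits

def _directed_best(hits: Iterable[SimilarityHit],
                   genome_of: Mapping[str, str]
                   ) -> tuple[dict[tuple[str, str], set[str]],
                              dict[tuple[str, str], SimilarityHit]]:
    """Per (query gene, target genome): the set of best-scoring subjects.

    Returns (best-hit sets, best directed hit per ordered gene pair).
    """
    best_score: dict[tuple[str, str], int] = {}
    best_set: dict[tuple[str, str], set[str]] = {}
    pair_hit: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        tg = genome_of[h.subject_id]
        key = (h.query_id, tg)
        pk = (h.query_id, h.subject_id)
        if pk not in pair_hit or h.raw_score > pair_hit[pk].raw_score:
            pair_hit[pk] = h
        s = best_score.get(key)
        if s is None or h.raw_score > s:
            best_score[key] = h.raw_score
            best_set[key] = {h.subject_id}
        elif h.raw_score == s:
            best_set[key].add(h.subject_id)
    return best_set, pair_hit


def best_reciprocal_hits(hits: Sequence[SimilarityHit],
                         genome_of: Mapping[str, str],
                         genome_pair: tuple[str, str] | None = None
                         ) -> list[BRHEdge]:
    """BRH edges, either for one genome pair or for all pairs present.

    Only inter-genome hits participate.  An edge's score is the minimum of
    the two directed raw scores and its identity the mean of the two
    directed percent identities.
    """
    inter = [h for h in hits
             if genome_of[h.query_id] != genome_of[h.subject_id]]
    if genome_pair is not None:
        ga, gb = genome_pair
        inter = [h for h in inter
                 if {genome_of[h.query_id], genome_of[h.subject_id]} == {ga, gb}]
    best_set, pair_hit = _directed_best(inter, genome_of)
    edges: list[BRHEdge] = []
    for (a, tg), subjects in best_set.items():
        for b in subjects:
            if a >= b:
                continue  # canonical orientation; the pass below covers b<a
            back = best_set.get((b, genome_of[a]), set())
            if a in back:
                h_ab = pair_hit[(a, b)]
                h_ba = pair_hit.get((b, a))
                if h_ba is None:
                    continue  # one direction missing entirely: not reciprocal
                edges.append(BRHEdge(
                    gene_a=a, gene_b=b,
                    score=min(h_ab.raw_score, h_ba.raw_score),
                    identity=(h_ab.pct_identity + h_ba.pct_identity) / 2.0))
    edges.sort(key=lambda e: (e.gene_a, e.gene_b))
    return edges


# ---------------------------------------------------------------------------
# Step 2: in-paralogs

def in_paralogs(hits: Sequence[SimilarityHit],
                brh_edges: Sequence[BRHEdge],
                genome_of: Mapping[str, str],
                level_genomes: frozenset[str] | set[str]
                ) -> list[InParalogLink]:
    """Within-genome links scoring above the level-defining BRH scores.

    A duplication is co-orthologous at a level when it postdates the
    level's LCA radiation, i.e. when the two copies are more similar to
    each other than orthologs are across the deepest speciation of the
    level.  Accordingly, for gene x let T(x) be the *minimum over partner
    genomes* of x's best BRH edge score to that genome (+inf when x has
    no BRH edge at all, so unanchored genes never recruit paralogs).  For
    an intra-genome pair (g, h) with raw score s a link is emitted iff
    s > min(T(g), T(h)); the lower-T gene becomes the attached ``gene``,
    the other the ``anchor``.

    Comparing against the most distant partner rather than the best one
    is what lets a duplicate that arose between two speciations be
    recognized as an in-paralog at the older level while still splitting
    into separate groups at the younger one.
    """
    per_genome: dict[tuple[str, str], float] = {}  # (gene, partner genome)
    for e in brh_edges:
        ga, gb = genome_of[e.gene_a], genome_of[e.gene_b]
        for g, partner in ((e.gene_a, gb), (e.gene_b, ga)):
            key = (g, partner)
            per_genome[key] = max(per_genome.get(key, -inf), e.score)
    t: dict[str, float] = {}
    for (g, _partner), score in per_genome.items():
        t[g] = min(t.get(g, inf), score)

    def T(x: str) -> float:
        return t.get(x, inf)

    intra: dict[tuple[str, str], int] = {}
    for h in hits:
        gq, gs = genome_of[h.query_id], genome_of[h.subject_id]
        if gq != gs or gq not in level_genomes:
            continue
        a, b = sorted((h.query_id, h.subject_id))
        key = (a, b)
        if key not in intra or h.raw_score > intra[key]:
            intra[key] = h.raw_score

    links: list[InParalogLink] = []
    for (g, h), s in sorted(intra.items()):
        tg, th = T(g), T(h)
        if s <= min(tg, th):
            continue
        # the anchor must be a BRH-anchored gene; a copy with no BRH at
        # all is always the attached duplicate
        if tg == inf:
            gene, anchor = g, h
        elif th == inf:
            gene, anchor = h, g
        elif tg < th:
            gene, anchor = g, h
        elif th < tg:
            gene, anchor = h, g
        else:
            gene, anchor = max(g, h), min(g, h)
        links.append(InParalogLink(gene=gene, anchor=anchor, score=s))
    return links


# ---------------------------------------------------------------------------
# Step 3: triangulation + clustering

class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def add(self, x: str) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: str) -> str:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


@dataclass
class ClusteringResult:
    groups: list[OrthologGroup]
    unverified_edges: list[BRHEdge] = field(default_factory=list)


def _enumerate_triangles(edges: Sequence[BRHEdge],
                         genome_of: Mapping[str, str]
                         ) -> tuple[list[tuple[str, str, str]], set[tuple[str, str]]]:
    """All BRH triangles spanning three distinct genomes.

    Returns the triangles and the set of (canonical) edges lying in at
    least one triangle.
    """
    adj: dict[str, set[str]] = {}
    for e in edges:
        adj.setdefault(e.gene_a, set()).add(e.gene_b)
        adj.setdefault(e.gene_b, set()).add(e.gene_a)
    triangles: list[tuple[str, str, str]] = []
    in_triangle: set[tuple[str, str]] = set()
    for e in edges:
        a, b = e.gene_a, e.gene_b
        for c in adj[a] & adj[b]:
            if c <= b:
                continue  # enumerate each triangle once with a < b < c
            if len({genome_of[a], genome_of[b], genome_of[c]}) != 3:
                continue
            triangles.append((a, b, c))
            in_triangle.update([(a, b), (a, c), (b, c)])
    return triangles, in_triangle


def triangulate_and_cluster(brh_edges: Sequence[BRHEdge],
                            in_links: Sequence[InParalogLink],
                            level: TaxonomyLevel,
                            genome_of: Mapping[str, str],
                            expansion: Mapping[str, Iterable[str]] | None = None
                            ) -> ClusteringResult:
    """The staged triangle-seed + verified-merge clustering.

    Stage 1 unions every BRH triangle (three genes, three distinct genomes,
    all three pairwise edges).  Stage 2 processes the remaining edges in
    descending score order: an edge touching one cluster attaches its free
    endpoint(s); an edge bridging two clusters merges nothing (it lacks
    triangle support and is recorded as unverified); an isolated edge forms
    a two-gene group.  Stage 3 attaches in-paralog links to their anchors'
    groups, strongest first, iterated to a fixpoint so chains resolve.
    Stage 4 re-expands collapsed near-identical copies.
    """
    for e in brh_edges:
        for g in e.genes:
            if genome_of[g] not in level.member_genomes:
                raise ValueError(
                    f"gene {g} (genome {genome_of[g]}) outside level "
                    f"{level.level_id}")

    uf = _UnionFind()
    assigned: set[str] = set()

    triangles, in_triangle = _enumerate_triangles(brh_edges, genome_of)
    for a, b, c in triangles:
        for g in (a, b, c):
            uf.add(g)
        uf.union(a, b)
        uf.union(a, c)
        assigned.update((a, b, c))

    unverified: list[BRHEdge] = []
    rest = [e for e in brh_edges if (e.gene_a, e.gene_b) not in in_triangle]
    rest.sort(key=lambda e: (-e.score, e.gene_a, e.gene_b))
    for e in rest:
        a, b = e.genes
        a_in, b_in = a in assigned, b in assigned
        if not a_in and not b_in:
            uf.add(a)
            uf.add(b)
            uf.union(a, b)
            assigned.update((a, b))
        elif a_in != b_in:
            free, held = (b, a) if a_in else (a, b)
            uf.add(free)
            uf.union(free, held)
            assigned.add(free)
        else:
            if uf.find(a) != uf.find(b):
                unverified.append(e)

    # Stage 3: attach in-paralogs to their anchors' groups.  A link whose
    # gene already sits in a group (e.g. a duplicate with its own BRH
    # partners) pulls that whole group along: the duplicate's orthologs
    # are co-orthologs of the anchor's.  Iterate so a link whose anchor is
    # attached by a weaker link still resolves; order within a pass is
    # strongest-first.
    links = sorted(in_links, key=lambda l: (-l.score, l.gene, l.anchor))
    changed = True
    while changed:
        changed = False
        for l in links:
            if l.anchor not in assigned:
                continue
            if l.gene not in assigned:
                uf.add(l.gene)
                uf.union(l.gene, l.anchor)
                assigned.add(l.gene)
                changed = True
            elif uf.find(l.gene) != uf.find(l.anchor):
                uf.union(l.gene, l.anchor)
                changed = True

    clusters: dict[str, set[str]] = {}
    for g in assigned:
        clusters.setdefault(uf.find(g), set()).add(g)

    if expansion:
        for members in clusters.values():
            extra = [a for rep in list(members)
                     for a in expansion.get(rep, ())]
            members.update(extra)

    member_sets = [frozenset(m) for m in clusters.values()]
    edge_lookup: dict[frozenset[str], set[tuple[str, str]]] = {}
    for ms in member_sets:
        edge_lookup[ms] = {(e.gene_a, e.gene_b) for e in brh_edges
                           if e.gene_a in ms and e.gene_b in ms}
    groups = assign_group_ids(
        level.level_id, member_sets,
        {ms: frozenset(es) for ms, es in edge_lookup.items()})
    return ClusteringResult(groups=groups, unverified_edges=unverified)


def naive_closure(brh_edges: Sequence[BRHEdge],
                  in_links: Sequence[InParalogLink],
                  level: TaxonomyLevel,
                  genome_of: Mapping[str, str],
                  expansion: Mapping[str, Iterable[str]] | None = None
                  ) -> ClusteringResult:
    """Plain connected components over BRH edges, then in-paralog attachment."""
    uf = _UnionFind()
    assigned: set[str] = set()
    for e in brh_edges:
        uf.add(e.gene_a)
        uf.add(e.gene_b)
        uf.union(e.gene_a, e.gene_b)
        assigned.update(e.genes)
    links = sorted(in_links, key=lambda l: (-l.score, l.gene, l.anchor))
    changed = True
    while changed:
        changed = False
        for l in links:
            if l.anchor not in assigned:
                continue
            if l.gene not in assigned:
                uf.add(l.gene)
                uf.union(l.gene, l.anchor)
                assigned.add(l.gene)
                changed = True
            elif uf.find(l.gene) != uf.find(l.anchor):
                uf.union(l.gene, l.anchor)
                changed = True
    clusters: dict[str, set[str]] = {}
    for g in assigned:
        clusters.setdefault(uf.find(g), set()).add(g)
    if expansion:
        for members in clusters.values():
            members.update(a for rep in list(members)
                           for a in expansion.get(rep, ()))
    groups = assign_group_ids(level.level_id,
                              [frozenset(m) for m in clusters.values()])
    return ClusteringResult(groups=groups)


# ---------------------------------------------------------------------------
# Per-level orchestration

def cluster_at_level(hits: Sequence[SimilarityHit],
                     level: TaxonomyLevel,
                     genome_of: Mapping[str, str],
                     expansion: Mapping[str, Iterable[str]] | None = None,
                     closure: str = "triangulate") -> ClusteringResult:
    """Run BRH -> in-paralog -> clustering on hits restricted to a level."""
    absorbed = ({g for acc in expansion.values() for g in acc}
                if expansion else set())
    level_hits = [
        h for h in hits
        if genome_of[h.query_id] in level.member_genomes
        and genome_of[h.subject_id] in level.member_genomes
        and h.query_id not in absorbed and h.subject_id not in absorbed
    ]
    edges = best_reciprocal_hits(level_hits, genome_of)
    links = in_paralogs(level_hits, edges, genome_of, level.member_genomes)
    fn = triangulate_and_cluster if closure == "triangulate" else naive_closure
    if closure not in ("triangulate", "naive"):
        raise ValueError(f"unknown closure mode {closure!r}")
    return fn(edges, links, level, genome_of, expansion)


def cluster_all_levels(hits: Sequence[SimilarityHit],
                       taxonomy: Taxonomy,
                       requested_levels: Sequence[str],
                       genome_of: Mapping[str, str],
                       expansion: Mapping[str, Iterable[str]] | None = None,
                       closure: str = "triangulate"
                       ) -> dict[str, list[OrthologGroup]]:
    """Delineate orthologous groups at every requested level independently.

    BRH detection, in-paralog thresholds and triangulation are all re-run
    per level: the in-paralog threshold T(x) depends on which genomes are
    in the species set, so a pair may be co-orthologous at an old level but
    not at a younger one.
    """
    out: dict[str, list[OrthologGroup]] = {}
    for level_id in requested_levels:
        level = taxonomy.level(level_id)
        out[level_id] = cluster_at_level(
            hits, level, genome_of, expansion, closure).groups
    return out


def fraction_clustered(groups: Iterable[OrthologGroup],
                       all_genes: Iterable[str]) -> float:
    """Headline statistic: fraction of genes placed in some group."""
    clustered = {g for grp in groups for g in grp.members}
    universe = set(all_genes)
    return len(clustered & universe) / len(universe) if universe else 0.0
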
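# Methods

This note documents the models, conventions and numerical choices behind
`triortho`, in the order the pipeline applies them, together with what the
synthetic-data tests do and do not demonstrate.

## Input model

Each genome contributes one protein per gene — the longest isoform, with
equal-length ties broken toward the lexicographically smallest isoform id
(a deterministic, order-independent convention; the choice of tie-break is
ours). Sequences use the 20 canonical amino acids plus X; other letters are
mapped to X with a logged warning. The taxonomy is a rooted Newick tree
whose labeled internal nodes are the available levels of orthology; a
level's genome set is the leaf closure of its node, and every level must
contain at least two genomes.

## Pairwise similarity

All-vs-all comparison uses Smith–Waterman local alignment (Biopython's
`PairwiseAligner` in local mode) with BLOSUM62 and affine gaps in the BLAST
convention: a gap of length L costs `gap_open + L·gap_extend`, defaults
11/1. These are ordinary protein-search defaults; the delineation method
itself does not depend on them beyond monotonicity of scores in similarity.
Raw score (not bit score or E-value) ranks hits: it is
database-size-independent and sufficient for reciprocal-best comparisons
within a fixed dataset. Reported hits must reach `min_score` 50 and span at
least `min_overlap` = 0.5 of the shorter sequence, which suppresses
single-domain matches that would otherwise seed spurious reciprocal edges.
Percent identity is identical columns over alignment columns (gap columns
included). When co-optimal alignments exist the traceback is made
orientation-canonical (the lexicographically smaller sequence is always the
query), so identity and coordinates are exactly symmetric.

A shared-k-mer screen (k = 4, ≥ 3 shared words, skipped for peptides
shorter than 2k) precedes alignment, in the spirit of BLAST word seeding;
homologs at the identity levels relevant here share dozens of 4-mers, while
the screen removes ~99 % of unrelated pairs. `prefilter_min_kmers=0`
forces an exhaustive sweep. Hits may also be supplied precomputed via the
hits TSV, so any external aligner producing BLAST-tabular-like output can
stand in.

Near-identical within-genome copies (recent duplicates, split gene models)
are collapsed before clustering by greedy longest-first clustering — each
gene joins the first current representative to which a hit shows ≥ 97 %
identity over ≥ 0.9 of the shorter sequence, the strategy CD-HIT uses.
Greedy absorption requires a direct hit to the representative (no
transitive chaining). Absorbed genes re-enter their representative's final
group after clustering. Thresholds are conventions, configurable.

## Delineation

**BRH edges.** Per genome pair, a gene's best-hit set is every partner
gene attaining its maximal raw score — ties are kept, so a recent duplicate
tied at the top yields multiple edges. An edge requires reciprocity; its
score is the min of the two directed scores, its identity their mean.

**In-paralogs.** For gene x, T(x) is the *minimum over partner genomes* of
x's best BRH score to that genome (+∞ if x has no BRH at all). An
intra-genome pair (g, h) scoring s is linked iff s > min(T(g), T(h)),
strict. Rationale: a duplication belongs to a level when it postdates the
level's LCA, i.e. when the copies are closer to each other than orthologs
are across the level's deepest radiation — hence the comparison against the
most distant partner, not the best one. Taking the per-genome *best* BRH
as the reference would make a duplicate that arose between two speciations
invisible at every level; under the minimum convention it is correctly
absorbed at the older level and split at the younger one. Strictness
avoids absorbing exact ties whose timing is undecidable. The gene of a
link is the copy with the lower T (the weakly-anchored duplicate); a copy
with no BRH at all is always the attached gene, and a gene with no BRH
edge has T = +∞ so it can never recruit paralogs on its own — such genes
remain unclustered singletons, which is expected (a real catalog clusters
~90 % of genes, not all).

**Triangulation clustering.** The staged machine: (1) every BRH triangle
— three genes in three distinct genomes with all three edges — seeds or
merges a cluster; (2) the remaining edges, strongest first, attach free
endpoints to existing clusters or form two-gene groups, but an edge
bridging two clusters merges nothing (it lacks third-genome support and is
recorded as *unverified*); (3) in-paralog links attach their gene to the
anchor's group, strongest first and iterated to a fixpoint — a gene that
already carries its own group (its duplicate-specific BRH partners) pulls
that group along, since its orthologs are co-orthologs of the anchor's;
(4) collapsed copies are re-expanded. With two genomes no triangles exist
and the machine degrades to plain BRH pairs plus in-paralog attachment. A
naive connected-components closure over the same edges is available
(`closure="naive"`) for comparison; the triangulated variant exists to
resist chaining through promiscuous genes. Both are deterministic for any
hits-file row order: all stages process sorted inputs, and ties break
lexicographically (cluster ordinals: descending size, then smallest
member).

Every level is computed independently on the hits restricted to its
genomes; BRH sets and T thresholds genuinely change with the species set,
so per-level recomputation is not an optimization shortcut but part of the
semantics.

## Annotations

Universality = genomes with ≥ 1 member / genomes at the level.
Duplicability = genomes with ≥ 2 members / genomes with ≥ 1 member — the
denominator is *present* genomes because duplicate retention is
conditional on presence; this convention (like the copy-number class
boundaries) is ours and is stated here because no formula is standard.
The copy-number class is `single_copy_in_all` (all counts exactly 1),
`multi_copy_in_all` (all ≥ 2), `present_in_all` (all ≥ 1) or `patchy`.

The evolutionary rate of a group is the mean over inter-species member
pairs of identity(i, j) divided by the mean identity of all BRH edges of
the same genome pair at the level. Pairs without a stored alignment, or in
genome pairs with no BRH baseline, are skipped rather than re-aligned (a
performance contract); the rate is undefined for single-genome groups.
By construction the rate is 1.0 in expectation when members are typical
BRH pairs.

Gene architecture reports median and *population* SD (n denominator, so a
single-member group has SD 0) of protein length and, where metadata
provides it, exon count. Members whose length deviates from the median by
more than k = 3 spreads are flagged (never removed). The default spread is
the SD floored at 1 aa; a robust mode uses 1.4826·MAD instead — the plain
SD is inflated by the very outlier it should catch, so the robust mode is
the one that flags a single gross deviant (both are offered because the
flagging threshold is a convention, not a measurement).

Sibling relations connect two groups when at least one common domain is
carried by ≥ 2 distinct organisms (genome ids, not genes) in *each* group.
Profile queries accept a class name or a comma-separated per-genome
pattern (`A=1,B>=2,C=0`).

## Benchmarking

The prediction is restricted to the reference universe; reference genes
left unassigned count as singleton blocks for Variation of Information but
are *not* candidate clusters for event classification — a group the method
barely clusters should classify as Missed, not as a Split into one-gene
pieces. Per reference group, the best cluster maximizes F1 (ties: larger
intersection, then lexicographic id; fixed purely for determinism).
Precedence is Exact → Akin (p, r > 0.85) → Fused → Split → Missed
(r < 0.5) → Complex; Fused/Split precede Missed because a group split into
several clean pieces can have best-cluster recall below 0.5 yet be a clean
Split. Fused: one predicted cluster recalls > 85 % of ≥ 2 reference
groups whose summed precision in it exceeds 85 %; fuse events count the
co-fused groups beyond the first. Split is symmetric (pieces with > 85 %
precision towards the group, jointly recalling > 85 %); split events count
the pieces. Event-counting granularity is a documented convention — the
published tables this mirrors do not pin it down.

VI uses base-2 logarithms by default (bits); natural log is an option
since published values do not state the base. Identical partitions return
exactly 0 (short-circuited to avoid floating-point residue). VI is
symmetric, satisfies the triangle inequality, and is bounded by
log2(universe size); the tests verify all three on random partitions.

## Simulator

The simulator is the package's study-condition generator, not a fixture:
families evolve independently down the species tree; each starts from a
root sequence drawn i.i.d. uniformly over the 20 amino acids, with length
~ N(300, 50²) floored at 30 aa. Along a branch of length t (expected
substitutions/site) each lineage undergoes duplication and loss as Poisson
processes (rates per unit branch length); substitutions redraw each site
from the background with probability 1 − e^(−t), so sister sequences at
total divergence t have expected identity e^(−t) + (1 − e^(−t))·Σf². There
is no rate heterogeneity, no indels, no domain-level events and no
horizontal transfer: alignment-free identity stays interpretable and the
BRH machinery is stressed without a phylogenetics stack. Consequences for
what the tests show: passing on this substrate demonstrates the
correctness of the delineation logic under clean, length-conserving
divergence — it does not certify behavior on real proteomes with indels,
domain shuffling, composition bias or fragmented gene models. Exon counts
are drawn once per family (uniform 1–10) and inherited; each family
carries a private domain id, and optionally the first k family pairs share
an extra domain so sibling relations exist by design.

Ground truth records, at every labeled internal node, one group per
gene-lineage copy present at that node (its extant descendants). Nesting
across levels is exact by construction and asserted on every simulation.

## Study conditions used by the tests and the acceptance script

* Six genomes on a three-level tree with per-branch lengths 0.05–0.1
  (pairwise identities ≈ 70–87 %), 100 families, seed 42: the *clean*
  condition (no duplication/loss) for exact-recovery and annotation
  identities, and the *turnover* condition (duplication 0.1, loss 0.05)
  for event-class recovery and self-benchmarks.
* Aligner check: 500 random pairs of length ≤ 40 against a naive
  full-matrix Gotoh DP, exact score equality.
* Cluster-machine check: 200 random edge/link instances of ≤ 12 genes over
  3–4 genomes against a set-scanning brute-force closure, exact equality.
* Level semantics: a three-genome tree with a long internal branch
  (duplication rate 0.35), selecting families whose single duplication
  falls strictly inside the middle of the AB stem (20–80 % of the branch).
  The window excludes two genuinely non-identifiable boundary cases: a
  duplication at the very top of the branch leaves the copies as diverged
  as cross-species orthologs (the in-paralog inequality approaches an
  exact tie), and one at the very bottom leaves them indistinguishable
  from post-speciation duplicates (reciprocal-best ties at the child
  level).

These sizes keep the whole suite within a couple of minutes on one CPU
while leaving the statistical assertions (recovery ≥ 95 % / ≥ 80 %, rate
within 1.0 ± 0.05) comfortably away from their thresholds.

## Known limitations

* The clustering rules are one concrete, deterministic realization of
  "triangulate and cluster"; other rule sets satisfying the same informal
  description exist. The brute-force oracle pins down *this* semantics.
* Raw-score ranking ignores alignment-length effects that E-values would
  model; irrelevant at desk scale, worth revisiting for heterogeneous
  sequence lengths.
* The greedy collapse depends on the length-then-id visiting order (as
  does CD-HIT); it is deterministic but not an optimal clustering.
* Exon counts and domains arrive only via the metadata TSV; there is no
  gene-model parsing, and no external functional annotation sources are
  integrated.
* Stage resumption hashes file contents; it does not track partial writes
  (a killed run should be restarted with a clean output directory or will
  simply recompute the affected stage).
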
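"""Evolutionary annotations of orthologous groups.

For each group at a level: the phyletic profile (per-genome copy numbers)
with its universality and duplicability summaries; a normalized
evolutionary rate (mean inter-species identity of members divided by the
BRH-average identity of the corresponding genome pair, so 1.0 is the
lineage-average pace); gene-architecture summaries (median/SD of protein
length and exon count, with deviant members flagged); and sibling-group
relations through shared domain content.  Copy-number profile queries over
the computed annotations are also provided.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import BRHEdge, GroupAnnotation, OrthologGroup, SimilarityHit, TaxonomyLevel

PROFILE_CLASSES = ("single_copy_in_all", "multi_copy_in_all",
                   "present_in_all", "patchy")


@dataclass(frozen=True)
class PhyleticProfile:
    """Per-genome copy numbers of one group over a level's genomes."""

    counts: Mapping[str, int]

    @property
    def n_present(self) -> int:
        return sum(1 for c in self.counts.values() if c >= 1)

    @property
    def n_duplicated(self) -> int:
        return sum(1 for c in self.counts.values() if c >= 2)


def phyletic_profile(group: OrthologGroup, level: TaxonomyLevel,
                     genome_of: Mapping[str, str]
                     ) -> tuple[PhyleticProfile, float, float, str]:
    """Profile plus (universality, duplicability, copy-number class).

    Universality is the fraction of the level's genomes with at least one
    member; duplicability the fraction of *present* genomes carrying two
    or more members — duplicate retention is conditional on presence.
    """
    counts = {g: 0 for g in sorted(level.member_genomes)}
    for gene in group.members:
        genome = genome_of[gene]
        if genome not in counts:
            raise ValueError(
                f"group {group.og_id}: member {gene} from genome {genome} "
                f"outside level {level.level_id}")
        counts[genome] += 1
    prof = PhyleticProfile(counts=counts)
    n_genomes = len(level.member_genomes)
    universality = prof.n_present / n_genomes
    duplicability = (prof.n_duplicated / prof.n_present
                     if prof.n_present else 0.0)
    values = list(counts.values())
    if all(c == 1 for c in values):
        cls = "single_copy_in_all"
    elif all(c >= 2 for c in values):
        cls = "multi_copy_in_all"
    elif all(c >= 1 for c in values):
        cls = "present_in_all"
    else:
        cls = "patchy"
    return prof, universality, duplicability, cls


def brh_baseline(edges: Iterable[BRHEdge],
                 genome_of: Mapping[str, str]) -> dict[frozenset[str], float]:
    """Mean BRH percent identity per genome pair (the rate denominator)."""
    acc: dict[frozenset[str], list[float]] = {}
    for e in edges:
        pair = frozenset((genome_of[e.gene_a], genome_of[e.gene_b]))
        acc.setdefault(pair, []).append(e.identity)
    return {pair: sum(v) / len(v) for pair, v in acc.items()}


def evolutionary_rate(group: OrthologGroup,
                      hits: Sequence[SimilarityHit] | Mapping[tuple[str, str], float],
                      baseline: Mapping[frozenset[str], float],
                      genome_of: Mapping[str, str]) -> float | None:
    """Mean of member-pair identity over the genome-pair BRH baseline.

    Averages identity(i, j) / baseline(genome(i), genome(j)) over all
    inter-species member pairs with a stored alignment; pairs whose genome
    pair has no baseline, or without a stored alignment, are skipped.
    Returns ``None`` when no pair qualifies (e.g. single-genome groups).
    """
    if isinstance(hits, Mapping):
        ident = dict(hits)
    else:
        ident = {}
        members = group.members
        for h in hits:
            if h.query_id in members and h.subject_id in members:
                a, b = sorted((h.query_id, h.subject_id))
                # mean of the two directions when both are stored
                if (a, b) in ident:
                    ident[(a, b)] = (ident[(a, b)] + h.pct_identity) / 2.0
                else:
                    ident[(a, b)] = h.pct_identity
    ratios: list[float] = []
    members = sorted(group.members)
    for i, gi in enumerate(members):
        for gj in members[i + 1:]:
            ga, gb = genome_of[gi], genome_of[gj]
            if ga == gb:
                continue
            pair = frozenset((ga, gb))
            if pair not in baseline:
                continue
            pid = ident.get((gi, gj) if gi < gj else (gj, gi))
            if pid is None:
                continue
            ratios.append(pid / baseline[pair])
    if not ratios:
        return None
    return sum(ratios) / len(ratios)


@dataclass
class ArchitectureSummary:
    length_median: float
    length_sd: float
    exon_median: float | None
    exon_sd: float | None
    deviants: tuple[str, ...]


def gene_architecture(group: OrthologGroup,
                      metadata: Mapping[str, tuple[str, int, int | None, tuple[str, ...]]],
                      k: float = 3.0, robust: bool = False
                      ) -> ArchitectureSummary:
    """Median/SD of protein length and exon count; flag length deviants.

    SDs are population SDs (n denominator) so single-member groups are
    well defined with sd 0.  A member is a deviant when its length differs
    from the median by more than ``k`` spreads, where the spread is the SD
    (floored at 1 aa) or, with ``robust=True``, 1.4826 x MAD — the robust
    mode is the one that catches a single gross outlier, which inflates
    the plain SD enough to hide itself.
    """
    lengths: dict[str, int] = {}
    exons: list[int] = []
    for gene in sorted(group.members):
        meta = metadata.get(gene)
        if meta is None:
            continue
        _, length, exon, _ = meta
        lengths[gene] = length
        if exon is not None:
            exons.append(exon)
    if not lengths:
        raise ValueError(f"no metadata covers any member of {group.og_id}")
    lvals = list(lengths.values())
    lmed = statistics.median(lvals)
    lsd = statistics.pstdev(lvals)
    if robust:
        mad = statistics.median(abs(v - lmed) for v in lvals)
        spread = max(1.4826 * mad, 1.0)
    else:
        spread = max(lsd, 1.0)
    deviants = tuple(g for g, v in sorted(lengths.items())
                     if abs(v - lmed) > k * spread)
    emed = statistics.median(exons) if exons else None
    esd = statistics.pstdev(exons) if exons else None
    return ArchitectureSummary(length_median=float(lmed), length_sd=lsd,
                               exon_median=emed, exon_sd=esd,
                               deviants=deviants)


@dataclass(frozen=True)
class SiblingRelation:
    group_a: str
    group_b: str
    shared_domains: frozenset[str]


def sibling_groups(groups: Sequence[OrthologGroup],
                   metadata: Mapping[str, tuple[str, int, int | None, tuple[str, ...]]]
                   ) -> list[SiblingRelation]:
    """Group pairs sharing a domain carried by >= 2 organisms in each.

    Organisms are distinct genome ids, not genes: a domain present twice
    in one genome counts once.
    """
    dom_orgs: dict[str, dict[str, set[str]]] = {}  # og -> domain -> genomes
    for grp in groups:
        per: dict[str, set[str]] = {}
        for gene in grp.members:
            meta = metadata.get(gene)
            if meta is None:
                continue
            genome, _, _, domains = meta
            for d in domains:
                per.setdefault(d, set()).add(genome)
        dom_orgs[grp.og_id] = per
    qualified: dict[str, set[str]] = {
        og: {d for d, orgs in per.items() if len(orgs) >= 2}
        for og, per in dom_orgs.items()
    }
    out: list[SiblingRelation] = []
    ids = sorted(qualified)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            shared = qualified[a] & qualified[b]
            if shared:
                out.append(SiblingRelation(group_a=a, group_b=b,
                                           shared_domains=frozenset(shared)))
    return out


def annotate_level(groups: Sequence[OrthologGroup],
                   level: TaxonomyLevel,
                   hits: Sequence[SimilarityHit],
                   edges: Sequence[BRHEdge],
                   genome_of: Mapping[str, str],
                   metadata: Mapping[str, tuple[str, int, int | None, tuple[str, ...]]] | None = None,
                   robust_deviants: bool = False) -> list[GroupAnnotation]:
    """Compute the full annotation block for every group at one level."""
    base = brh_baseline(edges, genome_of)
    siblings: dict[str, set[str]] = {}
    if metadata:
        for rel in sibling_groups(groups, metadata):
            siblings.setdefault(rel.group_a, set()).add(rel.group_b)
            siblings.setdefault(rel.group_b, set()).add(rel.group_a)
    out: list[GroupAnnotation] = []
    for grp in groups:
        _, universality, duplicability, cls = phyletic_profile(
            grp, level, genome_of)
        rate = evolutionary_rate(grp, hits, base, genome_of)
        arch = None
        if metadata and any(g in metadata for g in grp.members):
            arch = gene_architecture(grp, metadata, robust=robust_deviants)
        out.append(GroupAnnotation(
            og_id=grp.og_id,
            universality=universality,
            duplicability=duplicability,
            copy_number_class=cls,
            evol_rate=rate,
            length_median=arch.length_median if arch else None,
            length_sd=arch.length_sd if arch else None,
            exon_median=arch.exon_median if arch else None,
            exon_sd=arch.exon_sd if arch else None,
            deviants=arch.deviants if arch else (),
            sibling_group_ids=frozenset(siblings.get(grp.og_id, set()))))
    return out


# ---------------------------------------------------------------------------
# Copy-number profile queries

_PATTERN_RE = re.compile(r"^\s*(?P<genome>[^=<>!\s]+)\s*(?P<op>>=|<=|=|>|<)\s*(?P<n>\d+)\s*$")
_OPS = {
    "=": lambda a, b: a == b,
    ">": lambda a, b: a > b,
    "<": lambda a, b: a < b,
    ">=": lambda a, b: a >= b,
    "<=": lambda a, b: a <= b,
}


def query_by_profile(groups: Sequence[OrthologGroup],
                     level: TaxonomyLevel,
                     genome_of: Mapping[str, str],
                     query: str) -> list[str]:
    """Select group ids by copy-number class or per-genome pattern.

    ``query`` is either a predefined class name (``single_copy_in_all``,
    ``multi_copy_in_all``, ``present_in_all``, ``patchy``) or a
    comma-separated pattern of per-genome constraints such as
    ``"A=1,B>=2,C=0"``.
    """
    if "," not in query and _PATTERN_RE.match(query) is None:
        if query not in PROFILE_CLASSES:
            raise ValueError(
                f"unknown profile class {query!r}; expected one of "
                f"{PROFILE_CLASSES} or a pattern like 'A=1,B>=2'")
        out = []
        for grp in groups:
            _, _, _, cls = phyletic_profile(grp, level, genome_of)
            if cls == query:
                out.append(grp.og_id)
        return sorted(out)
    constraints = []
    for clause in query.split(","):
        m = _PATTERN_RE.match(clause)
        if m is None:
            raise ValueError(f"malformed profile pattern clause {clause!r}")
        genome = m.group("genome")
        if genome not in level.member_genomes:
            raise ValueError(f"genome {genome!r} not at level {level.level_id}")
        constraints.append((genome, _OPS[m.group("op")], int(m.group("n"))))
    out = []
    for grp in groups:
        prof, _, _, _ = phyletic_profile(grp, level, genome_of)
        if all(op(prof.counts[g], n) for g, op, n in constraints):
            out.append(grp.og_id)
    return sorted(out)
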
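"""Readers and writers for every on-disk format the pipeline touches.

Formats (all plain text, all TSVs carry a single '#'-prefixed header line):

* protein FASTA, one file per genome, header first token ``gene`` or
  ``gene|isoform``;
* Newick taxonomy with labeled internal nodes (the orthology levels);
* hits TSV (BLAST-tabular-like): query_id, subject_id, raw_score,
  pct_identity, aln_len, q_start, q_end, s_start, s_end;
* clusters TSV: level_id, og_id, gene_id, genome_id;
* metadata TSV: gene_id, genome_id, protein_length, exon_count, domains;
* reference-clusters TSV: refog_id, gene_id.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO

from .model import GeneRecord, Genome, OrthologGroup, SimilarityHit, TaxonomyLevel, sanitize_sequence

log = logging.getLogger(__name__)

HITS_COLUMNS = [
    "query_id", "subject_id", "raw_score", "pct_identity",
    "aln_len", "q_start", "q_end", "s_start", "s_end",
]


# ---------------------------------------------------------------------------
# FASTA

def read_genome_fasta(path: str | Path, genome_id: str) -> tuple[Genome, list[GeneRecord]]:
    """Read one genome's proteome, keeping only the longest isoform per gene.

    Headers are ``gene_id`` or ``gene_id|isoform_id``.  Length ties between
    isoforms are broken toward the lexicographically smallest isoform id;
    two same-length isoforms with *different* sequences under a bare
    (isoform-less) duplicate header are a hard error.
    """
    best: dict[str, tuple[str, str | None]] = {}  # gene_id -> (seq, isoform_id)
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        token = rec.id
        gene_id, _, isoform = token.partition("|")
        isoform_id = isoform or None
        seq = sanitize_sequence(str(rec.seq), gene_id, log.warning)
        if not seq:
            raise ValueError(f"{path}: empty sequence for record {token}")
        if gene_id not in best:
            best[gene_id] = (seq, isoform_id)
            continue
        cur_seq, cur_iso = best[gene_id]
        if isoform_id is None and cur_iso is None:
            if seq != cur_seq and len(seq) == len(cur_seq):
                raise ValueError(
                    f"{path}: duplicate gene id {gene_id} with conflicting "
                    "equal-length sequences"
                )
        if len(seq) > len(cur_seq):
            best[gene_id] = (seq, isoform_id)
        elif len(seq) == len(cur_seq):
            # tie: lexicographically smallest isoform id wins
            if isoform_id is not None and (cur_iso is None or isoform_id < cur_iso):
                if cur_iso is not None:
                    best[gene_id] = (seq, isoform_id)
    if n == 0:
        raise ValueError(f"{path}: empty FASTA file")
    records = [
        GeneRecord(gene_id=g, genome_id=genome_id, sequence=s)
        for g, (s, _) in sorted(best.items())
    ]
    genome = Genome(genome_id=genome_id, gene_ids={r.gene_id for r in records})
    return genome, records


def write_genome_fasta(records: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in sorted(records, key=lambda r: r.gene_id):
            fh.write(f">{rec.gene_id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Taxonomy

class Taxonomy:
    """A rooted species tree whose labeled internal nodes are orthology levels.

    ``levels`` maps each internal-node label to a :class:`TaxonomyLevel`
    whose genome set is the leaf closure of the node.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.genomes: set[str] = set()
        self.levels: dict[str, TaxonomyLevel] = {}
        self.parent_of: dict[str, str | None] = {}
        seen: set[str] = set()
        for node in tree.preorder_node_iter():
            label = _node_label(node)
            if label is not None:
                if label in seen:
                    raise ValueError(f"duplicate taxonomy label: {label}")
                seen.add(label)
            if node.is_leaf():
                if label is None:
                    raise ValueError("taxonomy has an unlabeled leaf")
                self.genomes.add(label)
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            label = _node_label(node)
            if label is None:
                continue  # unlabeled internal nodes are simply not levels
            leaves = frozenset(_node_label(l) for l in node.leaf_iter())
            self.levels[label] = TaxonomyLevel(level_id=label, member_genomes=leaves)
            anc = node.parent_node
            parent_label = None
            while anc is not None:
                parent_label = _node_label(anc)
                if parent_label is not None:
                    break
                anc = anc.parent_node
            self.parent_of[label] = parent_label

    @property
    def root_level(self) -> TaxonomyLevel:
        root_label = _node_label(self.tree.seed_node)
        if root_label is None or root_label not in self.levels:
            raise ValueError("taxonomy root node is not a labeled level")
        return self.levels[root_label]

    def level(self, level_id: str) -> TaxonomyLevel:
        if level_id not in self.levels:
            raise KeyError(
                f"requested level {level_id!r} is not a labeled internal node "
                f"of the taxonomy (available: {sorted(self.levels)})"
            )
        return self.levels[level_id]


def _node_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or None


def read_taxonomy(path_or_string: str | Path) -> Taxonomy:
    """Parse a Newick taxonomy; internal node labels name the levels."""
    src = str(path_or_string)
    if src.lstrip().startswith("(") or src.rstrip().endswith(";"):
        tree = dendropy.Tree.get(data=src, schema="newick",
                                 suppress_internal_node_taxa=True)
    else:
        tree = dendropy.Tree.get(path=src, schema="newick",
                                 suppress_internal_node_taxa=True)
    return Taxonomy(tree)


# ---------------------------------------------------------------------------
# Hits TSV

def write_hits_tsv(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(HITS_COLUMNS) + "\n")
        for h in sorted(hits, key=lambda h: (h.query_id, h.subject_id)):
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.raw_score}\t"
                f"{h.pct_identity:.2f}\t{h.aln_len}\t{h.q_start}\t{h.q_end}\t"
                f"{h.s_start}\t{h.s_end}\n"
            )


def read_hits_tsv(path: str | Path) -> list[SimilarityHit]:
    df = pd.read_csv(path, sep="\t", comment=None, header=None, skiprows=1,
                     names=HITS_COLUMNS,
                     dtype={"query_id": str, "subject_id": str})
    hits = []
    for row in df.itertuples(index=False):
        try:
            hits.append(SimilarityHit(
                query_id=row.query_id, subject_id=row.subject_id,
                raw_score=int(row.raw_score), pct_identity=float(row.pct_identity),
                aln_len=int(row.aln_len), q_start=int(row.q_start),
                q_end=int(row.q_end), s_start=int(row.s_start),
                s_end=int(row.s_end)))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed hits row {row}: {exc}") from exc
    return hits


# ---------------------------------------------------------------------------
# Clusters TSV

def assign_group_ids(level_id: str, member_sets: Iterable[frozenset[str]],
                     seed_edges: Mapping[frozenset[str], frozenset] | None = None
                     ) -> list[OrthologGroup]:
    """Assign deterministic ids ``OG<level>_<ordinal>``.

    Ordinals follow descending group size, ties broken by the
    lexicographically smallest member.
    """
    ordered = sorted(set(member_sets), key=lambda s: (-len(s), min(s)))
    groups = []
    for i, members in enumerate(ordered, start=1):
        edges = frozenset() if seed_edges is None else seed_edges.get(members, frozenset())
        groups.append(OrthologGroup(
            og_id=f"OG{level_id}_{i:06d}", level_id=level_id,
            members=members, seed_edges=edges))
    return groups


def write_clusters_tsv(groups_by_level: Mapping[str, list[OrthologGroup]],
                       path: str | Path,
                       gene_genome: Mapping[str, str]) -> None:
    rows = []
    for level_id, groups in groups_by_level.items():
        for g in groups:
            for gene in g.members:
                rows.append((level_id, g.og_id, gene, gene_genome[gene]))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("#level_id\tog_id\tgene_id\tgenome_id\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")


def read_clusters_tsv(path: str | Path
                      ) -> tuple[dict[str, list[OrthologGroup]], dict[str, str]]:
    """Read clusters; returns (groups per level, gene -> genome map).

    Enforces the partition invariant: a gene may not appear in two groups
    at the same level.
    """
    members: dict[tuple[str, str], set[str]] = {}
    gene_genome: dict[str, str] = {}
    assigned: dict[str, str] = {}  # (level, gene) -> og
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: malformed clusters row "
                                 f"(expected 4 columns, got {len(parts)})")
            level_id, og_id, gene_id, genome_id = parts
            key = f"{level_id}\x00{gene_id}"
            if key in assigned and assigned[key] != og_id:
                raise ValueError(
                    f"{path}:{lineno}: gene {gene_id} appears in two groups "
                    f"({assigned[key]}, {og_id}) at level {level_id}")
            assigned[key] = og_id
            members.setdefault((level_id, og_id), set()).add(gene_id)
            gene_genome[gene_id] = genome_id
    out: dict[str, list[OrthologGroup]] = {}
    for (level_id, og_id), genes in sorted(members.items()):
        out.setdefault(level_id, []).append(OrthologGroup(
            og_id=og_id, level_id=level_id, members=frozenset(genes)))
    return out, gene_genome


# ---------------------------------------------------------------------------
# Metadata TSV

def write_metadata_tsv(records: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tgenome_id\tprotein_length\texon_count\tdomains\n")
        for r in sorted(records, key=lambda r: r.gene_id):
            exon = "NA" if r.exon_count is None else str(r.exon_count)
            fh.write(f"{r.gene_id}\t{r.genome_id}\t{r.protein_length}\t"
                     f"{exon}\t{';'.join(r.domains)}\n")


def read_metadata_tsv(path: str | Path
                      ) -> dict[str, tuple[str, int, int | None, tuple[str, ...]]]:
    """Return gene_id -> (genome_id, protein_length, exon_count, domains)."""
    out: dict[str, tuple[str, int, int | None, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: malformed metadata row")
            gene_id, genome_id, length_s, exon_s, domains_s = parts
            try:
                length = int(length_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer protein_length {length_s!r}"
                ) from exc
            exon = None if exon_s == "NA" else int(exon_s)
            domains = tuple(d for d in domains_s.split(";") if d)
            out[gene_id] = (genome_id, length, exon, domains)
    return out


# ---------------------------------------------------------------------------
# Reference clusters TSV

def write_refogs_tsv(refogs: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#refog_id\tgene_id\n")
        for refog_id in sorted(refogs):
            for gene in sorted(refogs[refog_id]):
                fh.write(f"{refog_id}\t{gene}\n")


def read_refogs_tsv(path: str | Path) -> dict[str, frozenset[str]]:
    blocks: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: malformed reference row")
            blocks.setdefault(parts[0], set()).add(parts[1])
    return {k: frozenset(v) for k, v in blocks.items()}


# ---------------------------------------------------------------------------
# Collapse map TSV (representative -> absorbed genes)

def write_collapse_map_tsv(expansion: Mapping[str, Iterable[str]],
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#representative_id\tabsorbed_id\n")
        for rep in sorted(expansion):
            for gene in sorted(expansion[rep]):
                fh.write(f"{rep}\t{gene}\n")


def read_collapse_map_tsv(path: str | Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: malformed collapse-map row")
            out.setdefault(parts[0], []).append(parts[1])
    return {k: sorted(v) for k, v in out.items()}
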
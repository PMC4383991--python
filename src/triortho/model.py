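"""Core domain types of the ortholog-delineation pipeline.

The pipeline operates on proteomes (one protein per gene, the longest
isoform), compares them all-vs-all by local alignment, and clusters
best-reciprocal hits (BRHs) plus in-paralogs into orthologous groups at
taxonomy-defined levels.  These dataclasses are the in-memory currency
shared by every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 20 canonical amino acids; anything else is mapped to X on input.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_AA = frozenset(CANONICAL_AA + "X")


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene, represented by its longest isoform."""

    gene_id: str
    genome_id: str
    sequence: str | None = None
    protein_length: int = 0
    exon_count: int | None = None
    domains: tuple[str, ...] = ()  # ordered N- to C-terminus

    def __post_init__(self) -> None:
        if self.sequence is not None:
            if not self.sequence:
                raise ValueError(f"empty sequence for gene {self.gene_id}")
            if self.protein_length and self.protein_length != len(self.sequence):
                raise ValueError(
                    f"protein_length {self.protein_length} != sequence length "
                    f"{len(self.sequence)} for gene {self.gene_id}"
                )
            if not self.protein_length:
                object.__setattr__(self, "protein_length", len(self.sequence))
        if self.exon_count is not None and self.exon_count < 1:
            raise ValueError(f"exon_count must be >= 1 for gene {self.gene_id}")


@dataclass
class Genome:
    """A genome: a taxonomy leaf plus the set of its gene identifiers."""

    genome_id: str
    gene_ids: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class TaxonomyLevel:
    """An internal node of the species tree defining a level of orthology.

    Orthology is relative to a last common ancestor; every labeled internal
    node of the taxonomy is a candidate level, and ``member_genomes`` is the
    leaf closure under that node.
    """

    level_id: str
    member_genomes: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.member_genomes) < 2:
            raise ValueError(
                f"level {self.level_id} has {len(self.member_genomes)} genome(s); "
                "a level of orthology needs at least 2"
            )


@dataclass(frozen=True)
class SimilarityHit:
    """A directed scored local-alignment result between two distinct genes.

    Coordinates are 1-based inclusive on the unaligned sequences, following
    the BLAST tabular convention; ``aln_len`` counts alignment columns
    including gap columns.
    """

    query_id: str
    subject_id: str
    raw_score: int
    pct_identity: float
    aln_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise ValueError(f"self-hit for gene {self.query_id}")
        if self.raw_score < 0:
            raise ValueError("raw_score must be >= 0")
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError("alignment coordinates must satisfy start <= end")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("pct_identity must be in [0, 100]")


@dataclass(frozen=True)
class BRHEdge:
    """An undirected best-reciprocal-hit edge between genes of two genomes.

    ``score`` is the minimum of the two directed raw scores; ``identity``
    the mean of the two directed percent identities.  Gene ids are stored
    in lexicographic order so the edge has a canonical form.
    """

    gene_a: str
    gene_b: str
    score: int
    identity: float

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("BRHEdge requires gene_a < gene_b")

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class InParalogLink:
    """A within-genome link: ``gene`` duplicated after the speciations that
    define the level, so it co-clusters with ``anchor``."""

    gene: str
    anchor: str
    score: int


@dataclass
class OrthologGroup:
    """A level-tagged set of genes descending from one LCA gene."""

    og_id: str
    level_id: str
    members: frozenset[str]
    seed_edges: frozenset[tuple[str, str]] = frozenset()


@dataclass
class GroupAnnotation:
    """Evolutionary annotations of one orthologous group at one level."""

    og_id: str
    universality: float
    duplicability: float
    copy_number_class: str
    evol_rate: float | None = None
    length_median: float | None = None
    length_sd: float | None = None
    exon_median: float | None = None
    exon_sd: float | None = None
    deviants: tuple[str, ...] = ()
    sibling_group_ids: frozenset[str] = frozenset()


@dataclass
class BenchmarkRecord:
    """Per-reference-group confusion metrics and event class."""

    refog_id: str
    best_cluster_id: str | None
    precision: float
    recall: float
    f1: float
    event: str
    n_split_events: int = 0
    n_fuse_events: int = 0


def sanitize_sequence(seq: str, gene_id: str, warn) -> str:
    """Uppercase ``seq`` and map non-canonical letters to X.

    ``warn`` is called once per offending gene with a message; the pipeline
    passes a logger, tests may pass a collector.
    """
    seq = seq.upper().replace("*", "").replace("-", "")
    if not set(seq) <= ALLOWED_AA:
        bad = sorted(set(seq) - ALLOWED_AA)
        warn(f"gene {gene_id}: mapping non-canonical letters {bad} to X")
        seq = "".join(c if c in ALLOWED_AA else "X" for c in seq)
    return seq
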
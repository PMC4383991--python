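"""All-vs-all protein comparison by Smith–Waterman local alignment.

The aligner is Biopython's :class:`Bio.Align.PairwiseAligner` in local mode
with an affine gap model.  Gap penalties follow the BLAST convention: a gap
of length L costs ``gap_open + L * gap_extend`` (existence plus per-residue
extension), with BLOSUM62 / 11 / 1 defaults.

Because an exhaustive quadratic sweep wastes almost all of its time on
unrelated pairs, :func:`all_vs_all` first screens every candidate pair with
a shared k-mer count (a word filter in the spirit of BLAST seeding); only
pairs passing the screen are aligned.  The screen is configurable and can
be disabled (``prefilter_min_kmers=0``) for an exhaustive run.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .model import GeneRecord, SimilarityHit

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and reporting parameters for the all-vs-all stage.

    ``min_overlap`` is the fraction of the *shorter* sequence the local
    alignment must span for the hit to be reported; it guards against
    single-domain matches seeding spurious reciprocal-best edges.
    """

    matrix_name: str = "blosum62"
    gap_open: int = 11
    gap_extend: int = 1
    min_score: int = 50
    min_overlap: float = 0.5
    prefilter_k: int = 4
    prefilter_min_kmers: int = 3  # 0 disables the k-mer screen

    def __post_init__(self) -> None:
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if not 0 < self.min_overlap <= 1:
            raise ValueError("min_overlap must be in (0, 1]")


@dataclass(frozen=True)
class CollapseParams:
    """Thresholds for collapsing near-identical within-genome gene copies."""

    identity_threshold: float = 97.0
    coverage_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 100:
            raise ValueError("identity_threshold must be in (0, 100]")


def make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(
        params.matrix_name.upper())
    # BLAST convention: gap of length L costs open + L*extend; Biopython
    # charges open_gap_score on the first gapped column and extend after.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _identity_and_span(alignment) -> tuple[int, int, int, int, int, int]:
    """Return (identical, columns, q_start, q_end, s_start, s_end).

    Coordinates are 1-based inclusive; columns include gap columns between
    the first and last aligned pair.
    """
    qa, sa = alignment.aligned
    qseq, sseq = alignment.sequences
    identical = 0
    matched = 0
    for (qs, qe), (ss, se) in zip(qa, sa):
        matched += qe - qs
        for i in range(qe - qs):
            if qseq[qs + i] == sseq[ss + i]:
                identical += 1
    q_start, q_end = qa[0][0], qa[-1][1]
    s_start, s_end = sa[0][0], sa[-1][1]
    gaps = (q_end - q_start - matched) + (s_end - s_start - matched)
    columns = matched + gaps
    return identical, columns, q_start + 1, q_end, s_start + 1, s_end


def smith_waterman(seq_a: str, seq_b: str, params: AlignmentParams,
                   aligner: Align.PairwiseAligner | None = None
                   ) -> SimilarityHit | None:
    """Optimal local alignment of two protein sequences.

    Returns ``None`` when the raw score falls below ``params.min_score`` or
    the alignment spans less than ``params.min_overlap`` of the shorter
    sequence.  Gene ids on the returned hit are placeholders ("query",
    "subject"); :func:`all_vs_all` rewrites them.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner(params)
    # canonical orientation so co-optimal traceback ties resolve the same
    # way for (a, b) and (b, a) and identity is exactly symmetric
    flipped = (len(seq_a), seq_a) > (len(seq_b), seq_b)
    qa, qb = (seq_b, seq_a) if flipped else (seq_a, seq_b)
    score = aligner.score(qa, qb)
    if score < params.min_score or score <= 0:
        return None
    alignment = next(iter(aligner.align(qa, qb)))
    identical, columns, q_start, q_end, s_start, s_end = _identity_and_span(alignment)
    if flipped:
        q_start, q_end, s_start, s_end = s_start, s_end, q_start, q_end
    shorter = min(len(seq_a), len(seq_b))
    span = min(q_end - q_start + 1, s_end - s_start + 1)
    if span / shorter < params.min_overlap:
        return None
    return SimilarityHit(
        query_id="query", subject_id="subject",
        raw_score=int(score),
        pct_identity=100.0 * identical / columns,
        aln_len=columns,
        q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end)


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    if len(seq) < k:
        return frozenset((seq,))
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def _swap(hit: SimilarityHit, query_id: str, subject_id: str) -> SimilarityHit:
    return SimilarityHit(
        query_id=query_id, subject_id=subject_id,
        raw_score=hit.raw_score, pct_identity=hit.pct_identity,
        aln_len=hit.aln_len,
        q_start=hit.s_start, q_end=hit.s_end,
        s_start=hit.q_start, s_end=hit.q_end)


def all_vs_all(records: Sequence[GeneRecord],
               params: AlignmentParams | None = None) -> list[SimilarityHit]:
    """Align every unordered pair of distinct genes, inter- and intra-genome.

    The substitution matrix is symmetric, so each pair is aligned once and
    both directed hits are emitted.  Output is sorted by
    (query_id, subject_id) and contains no self-hits.
    """
    params = params or AlignmentParams()
    recs = sorted(records, key=lambda r: r.gene_id)
    if len({r.gene_id for r in recs}) != len(recs):
        raise ValueError("duplicate gene ids in all-vs-all input")
    aligner = make_aligner(params)
    use_filter = params.prefilter_min_kmers > 0
    kmers = {r.gene_id: _kmer_set(r.sequence, params.prefilter_k)
             for r in recs} if use_filter else {}
    hits: list[SimilarityHit] = []
    n_aligned = 0
    for ra, rb in itertools.combinations(recs, 2):
        if use_filter:
            shared = len(kmers[ra.gene_id] & kmers[rb.gene_id])
            # short peptides cannot meet an absolute word count; always align
            shortest = min(len(ra.sequence), len(rb.sequence))
            if shortest > 2 * params.prefilter_k and shared < params.prefilter_min_kmers:
                continue
        n_aligned += 1
        hit = smith_waterman(ra.sequence, rb.sequence, params, aligner)
        if hit is None:
            continue
        hits.append(SimilarityHit(
            query_id=ra.gene_id, subject_id=rb.gene_id,
            raw_score=hit.raw_score, pct_identity=hit.pct_identity,
            aln_len=hit.aln_len, q_start=hit.q_start, q_end=hit.q_end,
            s_start=hit.s_start, s_end=hit.s_end))
        hits.append(_swap(hit, rb.gene_id, ra.gene_id))
    log.info("all-vs-all: %d genes, %d pairs aligned, %d hits",
             len(recs), n_aligned, len(hits))
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits


def collapse_similar_copies(records: Sequence[GeneRecord],
                            hits: Iterable[SimilarityHit],
                            cparams: CollapseParams | None = None
                            ) -> tuple[list[str], dict[str, list[str]]]:
    """Greedy longest-first collapsing of near-identical copies in one genome.

    Genes are visited in descending length (ties: lexicographic id).  Each
    gene joins the first current representative to which an intra-genome hit
    shows >= ``identity_threshold`` percent identity over >=
    ``coverage_threshold`` of the shorter sequence; otherwise it opens a new
    representative.  Returns (representatives, representative -> absorbed).

    This deliberately mirrors greedy incremental clustering (the CD-HIT
    strategy) rather than transitive closure: absorption requires a direct
    qualifying hit to the representative itself.
    """
    cparams = cparams or CollapseParams()
    genomes = {r.genome_id for r in records}
    if len(genomes) > 1:
        raise ValueError("collapse operates on a single genome at a time")
    length = {r.gene_id: r.protein_length for r in records}
    pair_hits: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        if h.query_id in length and h.subject_id in length:
            key = (h.query_id, h.subject_id)
            if key not in pair_hits or h.raw_score > pair_hits[key].raw_score:
                pair_hits[key] = h
    order = sorted(records, key=lambda r: (-r.protein_length, r.gene_id))
    reps: list[str] = []
    expansion: dict[str, list[str]] = {}
    for rec in order:
        joined = False
        for rep in reps:
            h = pair_hits.get((rec.gene_id, rep)) or pair_hits.get((rep, rec.gene_id))
            if h is None:
                continue
            shorter = min(length[rec.gene_id], length[rep])
            span = min(h.q_end - h.q_start + 1, h.s_end - h.s_start + 1)
            if (h.pct_identity >= cparams.identity_threshold
                    and span / shorter >= cparams.coverage_threshold):
                expansion[rep].append(rec.gene_id)
                joined = True
                break
        if not joined:
            reps.append(rec.gene_id)
            expansion[rec.gene_id] = []
    return reps, {r: sorted(a) for r, a in expansion.items()}


def collapse_all_genomes(records: Sequence[GeneRecord],
                         hits: Sequence[SimilarityHit],
                         cparams: CollapseParams | None = None
                         ) -> dict[str, list[str]]:
    """Run :func:`collapse_similar_copies` per genome; merged expansion map."""
    by_genome: dict[str, list[GeneRecord]] = {}
    for r in records:
        by_genome.setdefault(r.genome_id, []).append(r)
    genome_of = {r.gene_id: r.genome_id for r in records}
    intra = [h for h in hits
             if genome_of.get(h.query_id) == genome_of.get(h.subject_id)]
    expansion: dict[str, list[str]] = {}
    for genome_id in sorted(by_genome):
        _, exp = collapse_similar_copies(by_genome[genome_id], intra, cparams)
        expansion.update(exp)
    return expansion


def filter_hits_to_representatives(hits: Iterable[SimilarityHit],
                                   expansion: Mapping[str, Iterable[str]]
                                   ) -> list[SimilarityHit]:
    """Drop hits touching absorbed (non-representative) genes."""
    absorbed = {g for absorbed in expansion.values() for g in absorbed}
    return [h for h in hits
            if h.query_id not in absorbed and h.subject_id not in absorbed]
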
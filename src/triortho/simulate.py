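"""Synthetic proteomes with known ortholog ground truth.

Gene families evolve independently down a species tree with branch lengths
in expected substitutions per site.  Each family starts from one root
sequence drawn i.i.d. from a fixed amino-acid frequency vector.  Along
every branch a lineage experiences duplication and loss events as Poisson
processes (``dup_rate`` / ``loss_rate`` events per unit branch length);
a duplication copies the lineage in place, both copies evolving on
independently, and a loss terminates it.  Substitutions follow a simple
per-site replacement process: over time t each site is redrawn from the
frequency vector with probability 1 - exp(-t) (no rate heterogeneity, no
indels), so expected identity between two sequences separated by total
time t is exp(-t) + (1 - exp(-t)) * sum(f_i^2) and decays monotonically.

Ground truth follows the LCA definition of orthology: at each labeled
internal node (level) of the tree, every gene-lineage copy present at
that node founds one truth group containing its extant descendants.  A
duplication *above* a node therefore yields two groups at that node but
one group at older levels — the hierarchy the delineation pipeline is
supposed to recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .benchmark import Partition
from .io import Taxonomy, read_taxonomy
from .model import CANONICAL_AA, GeneRecord

_AA = np.frombuffer(CANONICAL_AA.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation run.

    ``species_tree`` is Newick with labeled internal nodes and branch
    lengths; ``root_length`` is the (mean, sd) of the Gaussian from which
    family root protein lengths are drawn (floored at 30 aa).
    """

    species_tree: str
    n_families: int = 100
    root_length: tuple[float, float] = (300.0, 50.0)
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    seed: int = 42
    n_sibling_family_pairs: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class SimEvent:
    family_id: str
    branch_to: str   # label of the node the branch leads into
    kind: str        # "dup" or "loss"
    time: float = 0.0      # position along the branch, from its top
    branch_length: float = 0.0


@dataclass
class SimulationResult:
    records: list[GeneRecord]
    taxonomy: Taxonomy
    truth: dict[str, dict[str, frozenset[str]]]  # level -> group -> genes
    events: list[SimEvent]
    config: SimConfig

    @property
    def genome_of(self) -> dict[str, str]:
        return {r.gene_id: r.genome_id for r in self.records}


def _substitute(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Redraw each site from the background frequencies with p = 1 - e^-t."""
    if t <= 0:
        return seq.copy()
    p = 1.0 - np.exp(-t)
    mask = rng.random(seq.size) < p
    out = seq.copy()
    n = int(mask.sum())
    if n:
        out[mask] = rng.integers(0, 20, size=n)
    return out


def _node_label(node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or ""


def _evolve_branch(seq: np.ndarray, length: float, cfg: SimConfig,
                   rng: np.random.Generator,
                   log_event: Callable[[str, float], None]) -> list[np.ndarray]:
    """Carry one lineage through a branch; return surviving copies at its end."""
    total = cfg.dup_rate + cfg.loss_rate
    out: list[np.ndarray] = []

    def go(s: np.ndarray, remaining: float) -> None:
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if wait >= remaining:
            out.append(_substitute(s, remaining, rng))
            return
        s2 = _substitute(s, wait, rng)
        if rng.random() < cfg.dup_rate / total:
            log_event("dup", length - (remaining - wait))
            go(s2, remaining - wait)
            go(s2, remaining - wait)
        else:
            log_event("loss", length - (remaining - wait))

    go(seq, length)
    return out


def simulate(config: SimConfig) -> SimulationResult:
    """Evolve ``n_families`` families down the species tree.

    Deterministic for a fixed seed: the single generator is consumed in a
    fixed traversal order.  Exon counts are drawn once per family (uniform
    1..10) and inherited unchanged; every family carries a family-specific
    domain, and the first ``n_sibling_family_pairs`` disjoint family pairs
    additionally share a domain so sibling relations exist by design.
    """
    taxonomy = read_taxonomy(config.species_tree)
    tree = taxonomy.tree
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise ValueError("species tree must have branch lengths on every branch")
    rng = np.random.default_rng(config.seed)

    records: list[GeneRecord] = []
    truth: dict[str, dict[str, frozenset[str]]] = {lv: {} for lv in taxonomy.levels}
    events: list[SimEvent] = []
    copy_counter: dict[tuple[str, str], int] = {}   # (level, family) -> ordinal
    gene_counter: dict[tuple[str, str], int] = {}   # (genome, family) -> ordinal

    shared_domain: dict[int, str] = {}
    for k in range(config.n_sibling_family_pairs):
        i, j = 2 * k, 2 * k + 1
        if j >= config.n_families:
            break
        shared_domain[i] = shared_domain[j] = f"DSH{k + 1:03d}"

    mean, sd = config.root_length

    for fam_idx in range(config.n_families):
        family_id = f"F{fam_idx + 1:04d}"
        length = max(30, int(round(rng.normal(mean, sd))))
        root_seq = rng.integers(0, 20, size=length)
        exon_count = int(rng.integers(1, 11))
        domains = [f"DF{fam_idx + 1:04d}"]
        if fam_idx in shared_domain:
            domains.append(shared_domain[fam_idx])

        def descend(node, seq: np.ndarray) -> list[str]:
            """One gene copy sitting at ``node``; returns its extant genes."""
            label = _node_label(node)
            if node.is_leaf():
                key = (label, family_id)
                gene_counter[key] = gene_counter.get(key, 0) + 1
                gene_id = f"{label}_{family_id}_{gene_counter[key]}"
                records.append(GeneRecord(
                    gene_id=gene_id, genome_id=label,
                    sequence=_AA[seq].tobytes().decode(),
                    exon_count=exon_count, domains=tuple(domains)))
                return [gene_id]
            descendants: list[str] = []
            for child in node.child_nodes():
                child_label = _node_label(child)
                surviving = _evolve_branch(
                    seq, child.edge.length, config, rng,
                    lambda kind, at, _cl=child_label, _bl=child.edge.length:
                        events.append(SimEvent(
                            family_id=family_id, branch_to=_cl, kind=kind,
                            time=at, branch_length=_bl)))
                for s in surviving:
                    descendants.extend(descend(child, s))
            if label in taxonomy.levels and descendants:
                key = (label, family_id)
                copy_counter[key] = copy_counter.get(key, 0) + 1
                gid = f"{family_id}_{label}_c{copy_counter[key]}"
                truth[label][gid] = frozenset(descendants)
            return descendants

        descend(tree.seed_node, root_seq)

    return SimulationResult(records=records, taxonomy=taxonomy,
                            truth=truth, events=events, config=config)


def truth_at_level(result: SimulationResult, level_id: str) -> Partition:
    """Ground-truth partition at one level, as a benchmark reference.

    The universe is every extant gene in a genome under the level whose
    family survives there; groups are the per-LCA-copy descendant sets.
    """
    if level_id not in result.taxonomy.levels:
        raise KeyError(f"unknown level {level_id!r}")
    blocks = {gid: genes for gid, genes in result.truth[level_id].items()}
    universe = frozenset(g for genes in blocks.values() for g in genes)
    return Partition(blocks=dict(sorted(blocks.items())), universe=universe)


def write_simulation(result: SimulationResult, outdir) -> dict[str, str]:
    """Write per-genome FASTA, metadata TSV, truth TSV and the tree Newick."""
    from pathlib import Path

    from .io import write_genome_fasta, write_metadata_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_genome: dict[str, list[GeneRecord]] = {}
    for r in result.records:
        by_genome.setdefault(r.genome_id, []).append(r)
    paths: dict[str, str] = {}
    for genome_id in sorted(by_genome):
        p = outdir / f"{genome_id}.fasta"
        write_genome_fasta(by_genome[genome_id], p)
        paths[f"fasta:{genome_id}"] = str(p)
    meta_path = outdir / "meta.tsv"
    write_metadata_tsv(result.records, meta_path)
    paths["metadata"] = str(meta_path)
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("#level_id\tfamily_group_id\tgene_id\n")
        for level_id in sorted(result.truth):
            for gid in sorted(result.truth[level_id]):
                for gene in sorted(result.truth[level_id][gid]):
                    fh.write(f"{level_id}\t{gid}\t{gene}\n")
    paths["truth"] = str(truth_path)
    tree_path = outdir / "tree.nwk"
    with open(tree_path, "w") as fh:
        fh.write(result.taxonomy.tree.as_string(schema="newick",
                                                suppress_rooting=True))
    paths["taxonomy"] = str(tree_path)
    return paths


def read_truth_tsv(path) -> dict[str, dict[str, frozenset[str]]]:
    out: dict[str, dict[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: malformed truth row")
            level_id, gid, gene = parts
            out.setdefault(level_id, {}).setdefault(gid, set()).add(gene)
    return {lv: {g: frozenset(s) for g, s in d.items()} for lv, d in out.items()}
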
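"""Shared fixtures: synthetic study datasets generated at test time."""

from __future__ import annotations

import random
from dataclasses import dataclass

import pytest

from triortho.align import all_vs_all, collapse_all_genomes
from triortho.model import BRHEdge, InParalogLink, SimilarityHit
from triortho.simulate import SimConfig, SimulationResult, simulate

# Six genomes, three nested levels; branch lengths give ~70-87% pairwise
# identity between genomes — diverged enough to stress the aligner, close
# enough that homologs stay well above the reporting thresholds.
SIX_GENOME_TREE = ("(((A:0.08,B:0.08)AB:0.06,(C:0.08,D:0.08)CD:0.06)ABCD:0.05,"
                   "(E:0.1,F:0.1)EF:0.09)ROOT;")


@dataclass
class SimBundle:
    sim: SimulationResult
    hits: list[SimilarityHit]
    expansion: dict[str, list[str]]


def _bundle(**kwargs) -> SimBundle:
    sim = simulate(SimConfig(species_tree=SIX_GENOME_TREE, **kwargs))
    hits = all_vs_all(sim.records)
    expansion = collapse_all_genomes(sim.records, hits)
    return SimBundle(sim=sim, hits=hits, expansion=expansion)


@pytest.fixture(scope="session")
def clean_bundle() -> SimBundle:
    """100 single-copy families, no duplication or loss, seed 42."""
    return _bundle(n_families=100, dup_rate=0.0, loss_rate=0.0, seed=42)


@pytest.fixture(scope="session")
def turnover_bundle() -> SimBundle:
    """100 families with duplication 0.1 and loss 0.05 per unit branch."""
    return _bundle(n_families=100, dup_rate=0.1, loss_rate=0.05, seed=42)


@pytest.fixture(scope="session")
def small_bundle() -> SimBundle:
    """20 clean families — cheap substrate for module-level tests."""
    return _bundle(n_families=20, dup_rate=0.0, loss_rate=0.0, seed=11)


# ---------------------------------------------------------------------------
# Random instance generators for oracle comparisons

def random_stage_instance(rng: random.Random):
    """A random BRH-edge/in-paralog instance on <= 12 genes, 3-4 genomes."""
    n_genomes = rng.choice([3, 4])
    genomes = [chr(ord("A") + i) for i in range(n_genomes)]
    n_genes = rng.randint(4, 12)
    genes = []
    genome_of = {}
    for i in range(n_genes):
        g = f"{genomes[i % n_genomes]}g{i:02d}"
        genes.append(g)
        genome_of[g] = genomes[i % n_genomes]
    edges = []
    for a, b in __import__("itertools").combinations(sorted(genes), 2):
        if genome_of[a] == genome_of[b]:
            continue
        if rng.random() < 0.35:
            edges.append(BRHEdge(gene_a=a, gene_b=b,
                                 score=rng.randint(60, 200),
                                 identity=rng.uniform(30, 100)))
    links = []
    for a, b in __import__("itertools").combinations(sorted(genes), 2):
        if genome_of[a] != genome_of[b]:
            continue
        if rng.random() < 0.25:
            gene, anchor = (a, b) if rng.random() < 0.5 else (b, a)
            links.append(InParalogLink(gene=gene, anchor=anchor,
                                       score=rng.randint(60, 250)))
    return edges, links, genome_of


def random_partition(rng: random.Random, universe: list[str]):
    """A uniformly random labeled partition of ``universe``."""
    blocks: dict[str, set[str]] = {}
    n_blocks = rng.randint(1, len(universe))
    for x in universe:
        blocks.setdefault(f"b{rng.randint(1, n_blocks)}", set()).add(x)
    return {k: frozenset(v) for k, v in blocks.items()}
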
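"""Benchmarking a predicted clustering against a reference clustering.

Three complementary views of agreement:

* per-reference-group precision / recall / F1 against the best-matching
  predicted cluster;
* a six-way event classification per reference group — Exact, Akin,
  Fused, Split, Missed, Complex — with split/fuse event counts;
* Variation of Information (VI), an information-theoretic distance
  between the two partitions (0 iff identical; it is a true metric).

Before comparison the prediction is restricted to the reference universe
(the genes the reference covers); universe genes in no block become
singleton blocks so both partitions cover the same elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .model import BenchmarkRecord


@dataclass
class Partition:
    """A partition of a universe into disjoint labeled blocks.

    Universe elements absent from every block are treated as singleton
    blocks (labeled ``singleton:<element>``) by :meth:`with_singletons`.
    """

    blocks: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for bid, block in self.blocks.items():
            if not block:
                raise ValueError(f"empty block {bid}")
            if seen & block:
                raise ValueError("partition blocks are not disjoint")
            seen |= block
        if not seen <= self.universe:
            raise ValueError("block elements outside the universe")

    @classmethod
    def from_blocks(cls, blocks: Mapping[str, Iterable[str]],
                    universe: Iterable[str] | None = None) -> "Partition":
        bl = {k: frozenset(v) for k, v in blocks.items()}
        uni = (frozenset(universe) if universe is not None
               else frozenset(x for b in bl.values() for x in b))
        return cls(blocks=bl, universe=uni)

    def with_singletons(self) -> "Partition":
        covered = frozenset(x for b in self.blocks.values() for x in b)
        blocks = dict(self.blocks)
        for x in sorted(self.universe - covered):
            blocks[f"singleton:{x}"] = frozenset((x,))
        return Partition(blocks=blocks, universe=self.universe)


def restrict_to_universe(pred: Partition,
                         ref_universe: Iterable[str]) -> Partition:
    """Intersect every predicted block with the reference universe.

    Empty intersections are dropped; universe elements left unassigned
    become singletons on demand (see :meth:`Partition.with_singletons`).
    """
    uni = frozenset(ref_universe)
    blocks = {}
    for bid, block in pred.blocks.items():
        inter = block & uni
        if inter:
            blocks[bid] = inter
    return Partition(blocks=blocks, universe=uni)


def confusion(refog: frozenset[str], cluster: frozenset[str]
              ) -> tuple[float, float, float]:
    """Precision, recall and F1 of one cluster against one reference group."""
    if not cluster:
        raise ValueError("empty cluster")
    tp = len(refog & cluster)
    precision = tp / len(cluster)
    recall = tp / len(refog)
    f1 = (0.0 if precision + recall == 0
          else 2 * precision * recall / (precision + recall))
    return precision, recall, f1


# ---------------------------------------------------------------------------
# Event classification

THRESH = 0.85     # precision/recall threshold for Akin/Fused/Split
MISS_RECALL = 0.5  # a reference group recalled below this is Missed


def _best_cluster(refog: frozenset[str], pred: Partition
                  ) -> tuple[str | None, float, float, float]:
    best = (None, 0.0, 0.0, 0.0)
    best_key: tuple | None = None
    for cid in sorted(pred.blocks):
        p, r, f1 = confusion(refog, pred.blocks[cid])
        inter = len(refog & pred.blocks[cid])
        key = (-f1, -inter, cid)
        if best_key is None or key < best_key:
            best_key = key
            best = (cid, p, r, f1)
    return best


def classify_events(ref: Partition, pred: Partition
                    ) -> list[BenchmarkRecord]:
    """Classify every reference group into one of six event classes.

    Precedence: Exact -> Akin -> Fused -> Split -> Missed -> Complex.
    Fused/Split are tested before Missed because a group split into many
    clean pieces can have best-cluster recall below 0.5 and still be a
    well-understood Split rather than a miss.  Classification sees only
    genuine predicted clusters: universe elements the prediction leaves
    unassigned count as singleton blocks for VI but are not candidate
    best clusters or split pieces (a group the method barely clusters is
    a Miss, not a Split into one-gene pieces).

    * Exact: best cluster has precision == recall == 1.
    * Akin: best cluster has precision > 0.85 and recall > 0.85.
    * Fused: some predicted cluster recalls > 0.85 of this group *and* of
      at least one other reference group, and the summed precision of the
      cluster over the co-fused groups exceeds 0.85; fuse events count the
      co-fused groups beyond the first.
    * Split: at least two predicted clusters each consist almost purely
      (precision > 0.85) of this group's genes and jointly recall > 0.85
      of it; split events count the pieces.
    * Missed: best-cluster recall < 0.5.
    * Complex: anything else.
    """
    if not ref.blocks:
        raise ValueError("empty reference partition")
    records: list[BenchmarkRecord] = []
    for refog_id in sorted(ref.blocks):
        refog = ref.blocks[refog_id]
        cid, p, r, f1 = _best_cluster(refog, pred)
        event = None
        n_split = n_fuse = 0
        if p == 1.0 and r == 1.0:
            event = "Exact"
        elif p > THRESH and r > THRESH:
            event = "Akin"
        if event is None:
            # Fused: look for a cluster recalling >85% of this and other groups
            for c in sorted(pred.blocks):
                block = pred.blocks[c]
                cofused = [
                    rid for rid in sorted(ref.blocks)
                    if len(ref.blocks[rid] & block) / len(ref.blocks[rid]) > THRESH
                ]
                if refog_id in cofused and len(cofused) >= 2:
                    summed_p = sum(len(ref.blocks[rid] & block)
                                   for rid in cofused) / len(block)
                    if summed_p > THRESH:
                        event = "Fused"
                        n_fuse = len(cofused) - 1
                        break
        if event is None:
            # Split: clean pieces of this group across >= 2 clusters
            pieces = [
                c for c in sorted(pred.blocks)
                if len(refog & pred.blocks[c]) / len(pred.blocks[c]) > THRESH
                and refog & pred.blocks[c]
            ]
            if len(pieces) >= 2:
                joint_recall = sum(len(refog & pred.blocks[c])
                                   for c in pieces) / len(refog)
                if joint_recall > THRESH:
                    event = "Split"
                    n_split = len(pieces)
        if event is None:
            event = "Missed" if r < MISS_RECALL else "Complex"
        records.append(BenchmarkRecord(
            refog_id=refog_id, best_cluster_id=cid,
            precision=p, recall=r, f1=f1, event=event,
            n_split_events=n_split, n_fuse_events=n_fuse))
    return records


# ---------------------------------------------------------------------------
# Variation of Information

def variation_of_information(x: Partition, y: Partition,
                             log_base: float = 2.0) -> float:
    """VI(X, Y) = H(X) + H(Y) - 2 I(X; Y) over a shared universe.

    Unassigned universe elements count as singleton blocks in both
    partitions.  Base-2 logarithms by default (bits); natural log
    available via ``log_base=math.e``.
    """
    if not x.universe or x.universe != y.universe:
        raise ValueError("partitions must share a non-empty universe")
    xs = x.with_singletons()
    ys = y.with_singletons()
    if sorted(xs.blocks.values(), key=sorted) == \
            sorted(ys.blocks.values(), key=sorted):
        return 0.0  # identical partitions: exactly zero, no FP residue
    n = len(x.universe)
    logb = math.log(log_base)

    def h(part: Partition) -> float:
        tot = 0.0
        for b in part.blocks.values():
            p = len(b) / n
            tot -= p * math.log(p) / logb
        return tot

    mi = 0.0
    ylookup: dict[str, frozenset[str]] = ys.blocks
    for bx in xs.blocks.values():
        px = len(bx) / n
        for by in ylookup.values():
            inter = len(bx & by)
            if inter == 0:
                continue
            pxy = inter / n
            py = len(by) / n
            mi += pxy * math.log(pxy / (px * py)) / logb
    vi = h(xs) + h(ys) - 2 * mi
    return max(vi, 0.0)  # clip tiny negative rounding residue


# ---------------------------------------------------------------------------
# Full comparison

@dataclass
class ComparisonResult:
    records: list[BenchmarkRecord]
    event_counts: dict[str, int]
    total_split_events: int
    total_fuse_events: int
    vi: float
    n_clusters_pred: int

    def summary_row(self) -> dict[str, object]:
        """A Table-2-shaped summary for one method."""
        ge85 = lambda attr: sum(1 for r in self.records
                                if getattr(r, attr) >= THRESH)
        ec = self.event_counts
        return {
            "n_clusters": self.n_clusters_pred,
            "refogs_f1_ge85": ge85("f1"),
            "refogs_precision_ge85": ge85("precision"),
            "refogs_recall_ge85": ge85("recall"),
            "exact": ec.get("Exact", 0),
            "akin": ec.get("Akin", 0),
            "fused": ec.get("Fused", 0),
            "fuse_events": self.total_fuse_events,
            "split": ec.get("Split", 0),
            "split_events": self.total_split_events,
            "complex": ec.get("Complex", 0),
            "missed": ec.get("Missed", 0),
        }


def compare(ref: Partition, pred: Partition,
            log_base: float = 2.0,
            drop_unassigned: bool = False) -> ComparisonResult:
    """Restrict, classify and score a prediction against a reference.

    ``drop_unassigned=True`` removes reference-universe genes the
    prediction leaves unclustered from the universe instead of counting
    them as singleton blocks (an alternative convention; it inflates
    recall and shrinks VI).
    """
    restricted = restrict_to_universe(pred, ref.universe)
    if drop_unassigned:
        covered = frozenset(x for b in restricted.blocks.values() for x in b)
        restricted = Partition(blocks=dict(restricted.blocks), universe=covered)
        ref_blocks = {k: v & covered for k, v in ref.blocks.items()}
        ref = Partition(blocks={k: v for k, v in ref_blocks.items() if v},
                        universe=covered)
    records = classify_events(ref, restricted)
    counts: dict[str, int] = {}
    for r in records:
        counts[r.event] = counts.get(r.event, 0) + 1
    vi = variation_of_information(ref, restricted, log_base=log_base)
    return ComparisonResult(
        records=records,
        event_counts=counts,
        total_split_events=sum(r.n_split_events for r in records),
        total_fuse_events=sum(r.n_fuse_events for r in records),
        vi=vi,
        n_clusters_pred=len(restricted.with_singletons().blocks))
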
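"""Independent reference implementations used to check the package.

These are deliberately naive and share no code with the implementation:
a full-matrix affine-gap local-alignment DP, and a set-scanning version
of the staged clustering machine, plus a cell-sum Variation of
Information computed straight from the contingency table.
"""

from __future__ import annotations

import itertools
import math

from Bio.Align import substitution_matrices

_BL62 = substitution_matrices.load("BLOSUM62")


def naive_local_score(a: str, b: str, gap_open: int = 11,
                      gap_extend: int = 1) -> int:
    """Full-matrix Gotoh local alignment; gap of length L costs
    gap_open + L * gap_extend."""
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    NEG = -10 ** 9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (move along b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            s = _BL62[a[i - 1]][b[j - 1]]
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return int(best)


def brute_force_stage_machine(edges, links, genome_of):
    """Set-scanning realization of the triangle-seeded clustering.

    Returns the set of member frozensets.  Mirrors the specified
    semantics with entirely different mechanics (no union-find).
    """
    edgeset = {(e.gene_a, e.gene_b) for e in edges}
    genes = sorted({g for e in edges for g in (e.gene_a, e.gene_b)}
                   | {l.gene for l in links} | {l.anchor for l in links})
    tris = []
    for a, b, c in itertools.combinations(genes, 3):
        if ({(a, b), (a, c), (b, c)} <= edgeset
                and len({genome_of[a], genome_of[b], genome_of[c]}) == 3):
            tris.append({a, b, c})
    clusters: list[set[str]] = [set(t) for t in tris]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    tri_edges = set()
    for t in tris:
        x, y, z = sorted(t)
        tri_edges |= {(x, y), (x, z), (y, z)}

    def find(g):
        for c in clusters:
            if g in c:
                return c
        return None

    rest = [e for e in edges if (e.gene_a, e.gene_b) not in tri_edges]
    rest.sort(key=lambda e: (-e.score, e.gene_a, e.gene_b))
    for e in rest:
        ca, cb = find(e.gene_a), find(e.gene_b)
        if ca is None and cb is None:
            clusters.append({e.gene_a, e.gene_b})
        elif ca is None:
            cb.add(e.gene_a)
        elif cb is None:
            ca.add(e.gene_b)
        # else: cross-cluster edge without triangle support -> no merge

    ordered_links = sorted(links, key=lambda l: (-l.score, l.gene, l.anchor))
    changed = True
    while changed:
        changed = False
        for l in ordered_links:
            ca = find(l.anchor)
            if ca is None:
                continue
            cg = find(l.gene)
            if cg is None:
                ca.add(l.gene)
                changed = True
            elif cg is not ca:
                ca |= cg
                clusters.remove(cg)
                changed = True
    return {frozenset(c) for c in clusters}


def vi_from_contingency(blocks_x, blocks_y, n, log_base=2.0):
    """VI computed cell-by-cell from the contingency table."""
    logb = math.log(log_base)
    hx = -sum((len(b) / n) * math.log(len(b) / n) / logb for b in blocks_x)
    hy = -sum((len(b) / n) * math.log(len(b) / n) / logb for b in blocks_y)
    mi = 0.0
    for bx in blocks_x:
        for by in blocks_y:
            k = len(set(bx) & set(by))
            if k:
                mi += (k / n) * math.log((k / n) / ((len(bx) / n) * (len(by) / n))) / logb
    return hx + hy - 2 * mi
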
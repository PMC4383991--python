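"""Evolutionary annotations: phyletic profiles, rates, architectures.

Clusters a small simulated dataset at the root level, annotates every
group and prints the annotation block of the first few, then runs a
copy-number profile query.
"""

from triortho.align import all_vs_all
from triortho.annotate import annotate_level, query_by_profile
from triortho.cluster import best_reciprocal_hits, cluster_at_level
from triortho.io import write_metadata_tsv, read_metadata_tsv
from triortho.simulate import SimConfig, simulate

TREE = "(((A:0.08,B:0.08)AB:0.06,C:0.14)ABC:0.05,D:0.19)ROOT;"
sim = simulate(SimConfig(species_tree=TREE, n_families=30, dup_rate=0.15,
                         loss_rate=0.1, seed=8, n_sibling_family_pairs=3))
hits = all_vs_all(sim.records)
level = sim.taxonomy.level("ROOT")
res = cluster_at_level(hits, level, sim.genome_of)
edges = best_reciprocal_hits(hits, sim.genome_of)

import tempfile, pathlib
with tempfile.TemporaryDirectory() as td:
    meta_path = pathlib.Path(td) / "meta.tsv"
    write_metadata_tsv(sim.records, meta_path)
    metadata = read_metadata_tsv(meta_path)

annotations = annotate_level(res.groups, level, hits, edges,
                             sim.genome_of, metadata)
for a in annotations[:5]:
    print(f"{a.og_id}: universality={a.universality:.2f} "
          f"duplicability={a.duplicability:.2f} class={a.copy_number_class} "
          f"rate={a.evol_rate:.3f} len_median={a.length_median:.0f} "
          f"siblings={sorted(a.sibling_group_ids)}")
# universality: fraction of genomes represented; duplicability: fraction
# of represented genomes with >1 copy; rate 1.0 = lineage-average
# divergence; siblings share a domain in >=2 organisms of each group.

single = query_by_profile(res.groups, level, sim.genome_of,
                          "single_copy_in_all")
absent_in_d = query_by_profile(res.groups, level, sim.genome_of, "D=0")
print(f"{len(single)} groups single-copy in all genomes; "
      f"{len(absent_in_d)} groups absent from genome D")
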
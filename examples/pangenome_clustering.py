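"""Cluster simulated proteomes into ortholog families and partition the
pan-genome into core / distributed / unique genes.

Prints the family count and the partition sizes; core genes are present in
every genome, unique genes in exactly one.
"""

from pansel import build_similarity_graph, classify_pangenome, mcl_cluster
from pansel.synthetic_data import SimConfig, simulate_proteomes

proteomes, truth = simulate_proteomes(
    SimConfig(seed=7, n_core_families=10, n_accessory_families=20,
              n_selected_genes=0, codon_length=60))
print(f"{len(proteomes)} genomes, "
      f"{sum(len(p.proteins) for p in proteomes)} proteins")

graph = build_similarity_graph(proteomes)
families = mcl_cluster(graph)
partition = classify_pangenome(families, len(proteomes))

print(f"{len(families)} gene families")
print(f"partition: {partition.counts}")
print(f"true family count: {len(truth.family_members)} "
      "(clusters should match at this low divergence)")
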
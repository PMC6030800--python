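"""Detect co-prescription modules in a synthetic corpus with known structure.

Generates 312 prescriptions over 255 herbs planted in three modules (58, 86
and 111 herbs), builds the weighted co-occurrence network (edge weight =
number of prescriptions containing both herbs) and partitions it with the
seeded Louvain optimizer at resolution 1.0. With 90% within-module herb
draws the planted modules are essentially perfectly recovered; Q is the
modularity of the recovered partition.
"""

from herbnet import SyntheticConfig, build_cooccurrence_network, generate_corpus, louvain_partition

corpus, truth = generate_corpus(SyntheticConfig(seed=1))
network = build_cooccurrence_network(corpus)
partition = louvain_partition(network, resolution=1.0, seed=1)

print(f"network: {network.graph.number_of_nodes()} connected herbs, "
      f"{network.graph.number_of_edges()} edges, {len(network.isolated)} isolated")
sizes = partition.sizes()
print(f"modules: {len(sizes)} with sizes {[sizes[k] for k in sorted(sizes)]} "
      f"(planted: {list(truth.modules.values()).count(1)}, "
      f"{list(truth.modules.values()).count(2)}, "
      f"{list(truth.modules.values()).count(3)})")
print(f"modularity Q = {partition.q:.3f} at resolution {partition.resolution}")
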
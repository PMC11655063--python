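"""CDRH3 sequence-similarity networks of the most diverse clonotypes.

Nodes are clones; edges join clones of one clonotype whose CDRH3s differ at
exactly one amino acid (likely somatic variants).  Node degree measures how
densely a clonotype explored its local sequence neighbourhood.
"""

from organrep import (
    cluster_clonotypes,
    clonotype_networks,
    degree_distribution,
    simulate_repertoire,
    study_config,
    write_graphml,
)

rep = simulate_repertoire(study_config("3x", seed=42)).for_mouse("m1")
cluster_clonotypes(rep.clones, 0.90)

nets = clonotype_networks(rep, "m1", k=5)
graphs = [g for per_organ in nets.values() for g in per_organ.values()]
print(f"built {len(graphs)} networks (5 most diverse clonotypes x {len(nets)} organs)")

dist = degree_distribution(graphs)
print("fraction of clones per node degree:", {d: round(f, 3) for d, f in dist.items()})

biggest = max(graphs, key=lambda g: g.number_of_nodes())
write_graphml(biggest, "/tmp/organrep_network.graphml")
print(
    f"largest network: {biggest.number_of_nodes()} clones / "
    f"{biggest.number_of_edges()} edges -> /tmp/organrep_network.graphml"
)
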
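"""Parse SMILES into featurized molecular graphs.

Heavy atoms become nodes (hydrogens fold into a per-atom count), bonds
become symmetric directed edge pairs, and aromaticity is kept exactly as
written in the SMILES — benzene written in lowercase stays aromatic.
"""

from seqscreen import batch_graphs, smiles_to_graph
from seqscreen.molgraph import NODE_FEATURE_NAMES

for smiles in ("C", "CC", "c1ccccc1", "CCOCCC(=O)O"):
    g = smiles_to_graph(smiles)
    aromatic = int(g.node_features[:, NODE_FEATURE_NAMES.index("aromatic")].sum())
    print(f"{smiles:>14}: {g.n_nodes} nodes, {g.n_edges} directed edges, "
          f"{aromatic} aromatic atoms")

batch = batch_graphs([smiles_to_graph("C"), smiles_to_graph("CC")])
print("batched membership:", batch.membership.tolist())
# Each node keeps a pointer to its source graph so pooling can separate
# ligands again after they are processed together.
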
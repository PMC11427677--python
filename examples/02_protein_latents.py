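"""Per-residue protein latents from the frozen toy embedder.

The model cross-attends to latent matrices from several encoder depths.
The toy embedder is deterministic and frozen: the same sequence always
yields bitwise-identical latents, and a cache guarantees one embedding
computation per protein per screen.
"""

from seqscreen import EmbeddingCache, ToyEmbedder, concat_chains, embed_sequence

embedder = ToyEmbedder()
sequence = concat_chains(["ACDEFGHIKLMNPQRSTVWY", "MKVLAWHWHYC"])
stack = embed_sequence(sequence, [0, 1, 2, 3], embedder)
print(f"sequence of {stack.seq_len} residues ->",
      f"{len(stack.layers)} latent layers of shape {stack.layers[0].shape}")

cache = EmbeddingCache()
for _ in range(250):  # screening 250 ligands re-uses one embedding
    cache.get_or_compute(sequence, [0, 1, 2, 3], embedder)
print("backend calls for a 250-ligand screen:", cache.backend_calls)
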
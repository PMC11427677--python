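# seqscreen

Structure-free virtual screening from sequence alone.

Most screening-power methods need a 3D structure and a docked pose before
they can score a ligand. `seqscreen` implements the alternative: a ligand's
molecular graph is encoded by attention-based graph convolutions, each graph
node is then "unwrapped" into a query token that cross-attends to frozen
per-residue latents of a protein language model (PLM), and five heads
predict four binding affinities (pKi, pKd, pIC50, pEC50 on the −log10 molar
scale, `p = −log10(x_nM/10⁹)`) plus a binder-vs-decoy classifier logit.
The classifier is the screening score: trained to separate true
protein–ligand pairs from randomly re-paired decoys, its logit ranks a
chemical library against a target (forward screening) or a proteome against
a ligand (reverse screening), with no structure, pocket, or docking step.

The package provides, as an importable library with a thin CLI:

- **`seqscreen.molgraph`** — SMILES → featurized heavy-atom graphs
  (aromaticity kept exactly as written, no re-perception), batching.
- **`seqscreen.plm`** — frozen per-residue latents from several encoder
  depths behind one interface: a deterministic toy embedder for desk-scale
  work, an optional adapter to a real PLM, chain concatenation, FASTA I/O
  and an embedding cache (one embedding per protein per screen).
- **`seqscreen.model`** — the network: GATv2-style convolutions,
  cross-attention graph blocks, commutative pooling (learnable commutative
  monoid / sum / mean), five heads, temperature-scaled clipped logit.
- **`seqscreen.training`** — interaction tables (Ki/Kd/IC50/EC50 in nM, any
  subset present), decoy sampling, the masked Huber(δ=2) +
  binary-cross-entropy objective with exact zero-gradient guarantees for
  absent labels and decoy regression terms, AdamW with cosine decay,
  record-level 90/2/8 splitting, and the >90%-identity homology filter
  (reference-length convention) for zero-shot evaluation.
- **`seqscreen.screening`** — forward/reverse screening drivers and the
  early-recognition metric stack: enrichment factor, success rate, BEDROC
  (Truchon–Bayly, α = 80.5 by default), AUROC, per-target aggregation and
  reverse-screening rank summaries.
- **`seqscreen.synthetic`** — a generator of BindingDB-like datasets with a
  planted motif↔pharmacophore binding rule, so every claim is testable
  end-to-end without downloads.
- **`seqscreen.benchmark`** — the reference desk-scale study conditions
  tying the above together.

## The model in brief

For a ligand graph with node states H and protein latents Z_l from encoder
depths l ∈ {l₁..l₄}, each block computes

    H ← H + GATv2(H, E)                        (edge-featured convolution)
    H ← LayerNorm(H + MHA(Q=H, K=V=Z_l))       (cross-attention graph block)
    H ← LayerNorm(H + FFN(H))                  (pointwise, leaky-ReLU α=0.05)

then nodes are pooled per graph and five two-layer heads read the pooled
vector. The classifier logit is multiplied by exp(τ) (τ trainable, init
0.07) and clipped to ±100. Training minimizes

    L = Σ_present Huber_δ=2(p̂ − p) + BCE(σ(logit), 1 − is_decoy)

where absent affinity labels, and all four regression terms of decoy
records, are omitted from the graph entirely — they contribute exactly zero
loss *and* exactly zero gradient. Roughly half the training pairs are
decoys: ligands drawn from the same table that no entry pairs with the
target protein. The PLM is frozen throughout; the network runs on a small
self-contained numpy autodiff engine (`seqscreen.autodiff`).

## Worked example

`examples/03_train_and_screen.py` trains a one-block model on a small
planted-rule dataset and screens a trained target at 5% actives:

```
dataset: 288 records, 8 proteins, 4 motif classes
training loss 3.49 -> 0.17 over 400 steps
screen on a trained target: AUROC 1.000, EF@5% 20.0, BEDROC(80.5) 1.000
```

AUROC 1.0 means every true binder outscored every decoy; EF@5% = 20 is the
maximum enrichment possible at 5% actives (all five actives in the top five
ranks); BEDROC(α=80.5) = 1 is perfect early recognition. The other examples
cover graph construction, embedding caching, and the homology filter.

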
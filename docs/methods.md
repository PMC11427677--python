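# Methods

## Problem setting

Virtual screening asks: given a protein target and a library of small
molecules, which molecules bind? `seqscreen` answers from sequence alone.
A ligand is represented as a heavy-atom graph, a protein as frozen
per-residue latents from a protein language model (PLM), and a network
trained on protein–ligand interaction tables scores each pair. Because the
score that matters for screening is *discrimination* (does this molecule
bind this target at all?) rather than potency regression, the network is
trained with two objectives at once: regress the measured affinities where
they exist, and classify true pairs against randomly re-paired decoys. The
classifier logit is the screening score; the affinity heads are exposed for
comparison and consistently enrich less — the package's acceptance suite
verifies this qualitative ordering on synthetic data.

## Architecture

Ligand nodes carry a one-hot element (C, N, O, S, P, F, Cl, Br, I, other),
an aromatic flag, formal charge, implicit-hydrogen count and degree; edges
carry a bond-order one-hot (single/double/triple/aromatic), each bond as
two directed edges. Aromaticity is taken exactly as the SMILES is written —
no kekulization or aromaticity re-perception — so the featurization is a
pure function of the input string. Stereo markers are parsed but not
featurized. SMILES are used as given, without canonicalization.

Node features are projected to `d_hidden` (default 64) and pass through
`n_blocks` blocks, one per attended encoder depth, ascending (default four
blocks; with a real 33-layer PLM the preset depths are 1/11/21/31, with the
4-layer toy embedder 0/1/2/3). Each block:

1. **GATv2-style convolution** with edge features in the attention logit
   and self-loops, residual added. Single-headed; attention is the
   "dynamic" form (logit = aᵀ·leaky-ReLU(W_src h_i + W_dst h_j + W_e e)).
2. **Cross-attention graph block**: every node becomes a query token over
   the protein's residues (multi-head scaled dot-product, default 4 heads);
   a learned affine adapts the latent width to `d_hidden` per block; output
   is residual-added and layer-normalized (post-norm; a pre-norm flag
   exists). Masked residues receive exactly zero attention weight (−10³⁰
   additive logit mask, which underflows to exact zero after softmax).
   Dropout 0.1 on attention weights during training.
3. **Pointwise feed-forward** (two layers, leaky-ReLU α = 0.05), post-norm
   residual.

Nodes pool per graph: `sum` and `mean` are exactly permutation-invariant;
`lcm` applies a learned binary operator over a balanced binary tree. The
operator acts on the symmetric functions (a+b, a⊙b) of its arguments, so it
is commutative *by construction*; tree-shape dependence under node
permutation remains and is measured rather than asserted. The five heads
are independent two-layer perceptrons. The classifier's raw logit is
multiplied by exp(τ) — τ a trainable scalar stored un-exponentiated,
initialized at 0.07 — then hard-clipped to ±100 (gradient zero outside the
clip), at training and inference alike.

**Initialization.** All affines are Xavier-normal, except the
cross-attention query/key projections, which start 4× wider. With Xavier
q/k the initial attention over ~50 residues is nearly uniform, every
protein reads as approximately its mean residue latent (which concentrates
across random sequences), and the gradient into the attention maps is too
small to ever differentiate proteins at desk scale; the wider start breaks
that symmetry. This is an optimization choice, not a change of model class.

## Training

AdamW (lr 1e-4, weight decay 1e-3 by default), cosine decay to zero with no
warm-up, batch size 1 with gradient accumulation (default 256 micro-steps
per update). Per micro-step, with probability 0.5 the ligand is replaced by
a decoy — a SMILES drawn uniformly from the loaded ligands and rejected (up
to 100 retries) if any dataset entry pairs it with the same protein
sequence — and the record is marked `is_decoy`. Loss terms: Huber δ = 2 per
present affinity label (absent labels and all four regression terms of
decoys are omitted from the loss graph, hence exactly zero gradient — the
test suite checks this by autodiff inspection, not tolerance), plus binary
cross-entropy on the scaled, clipped logit. Reported training/validation
losses average only the non-omitted terms. Sequences longer than 2048
residues are excluded from training only; screening imposes no length
cutoff. Affinities ingest from BindingDB-style TSV in nM; entries with
'<'/'>' qualifiers are dropped (exact values only), duplicates are kept as
independent records, and values normalize as −log10(x/10⁹).

For zero-shot evaluation against external targets, training records whose
protein exceeds 90% identity to any evaluation sequence are removed.
Identity is the optimal global-alignment match count divided by the
*reference* sequence length, with match = 1, mismatch = 0, gap = 0 — under
that scoring the optimal score equals the longest-common-subsequence
length, which is what the test oracle computes independently.

## The toy embedder

Desk-scale work cannot ship a 650M-parameter PLM, so the package includes a
frozen deterministic stand-in with the two properties that matter for the
method: per-residue latents that are (i) contextual — a residue's latent
reflects its local k-mer, so short motifs are linearly decodable — and
(ii) consistent — the same k-mer maps to nearly the same latent wherever it
occurs, as conserved motifs do in real PLM latents. Each residue starts as
one-hot ⊕ sinusoidal position encoding (damped ×0.05 so position perturbs
but does not dominate), projected to `d_embed` = 128; each of 4 frozen
layers applies a seeded random affine over the residue's ±1 window followed
by ReLU, and emits the result standardized per residue (as layer-normalized
PLM hidden states are). Depth widens the receptive field to a (2l+1)-mer.
All weights derive from one module-level seed constant, so independently
constructed embedders agree bitwise across processes. A linear probe on
mean-pooled latents separates the four planted motif classes with ~99%
accuracy — the package treats >95% as the precondition for blaming the
model rather than the representation.

What the toy embedder does *not* model: evolutionary context, long-range
structure signals, or any learned biology. Passing tests with it shows the
architecture and training loop can extract a sequence-local binding
determinant through cross-attention; it says nothing about performance on
real proteins with a real PLM, for which the `ESM2Embedder` adapter exists
but is untested here.

## Synthetic data

The generator plants a known binding rule in BindingDB-shaped data: K = 4
sequence motifs (6-mers over the standard alphabet) paired with 4
pharmacophores (carboxylate `C(=O)O`, amine `N`, nitrile `C#N`, thiol `S`)
appended to short alkyl/ether scaffolds, so every emitted SMILES is
valence-valid and the pharmacophore is literally a substring. A protein is
a uniform random sequence (48–64 residues) with one motif written over a
random window (replacement keeps length fixed); a true pair's affinity is
the motif's base pK (8.5/7.5/9.0/8.0) + N(0, 0.3), identical across the
four label slots before masking; each slot then goes missing independently
(Ki 0.6, Kd 0.8, IC50 0.25, EC50 0.85 — mirroring IC50's dominance in
public assay tables), and a record with all four slots missing is dropped
(~10% of draws). Missing-label patterns, decoy sampling, and screening
benchmarks (n actives carrying the matching pharmacophore among decoys
carrying mismatched ones or bare scaffolds) all derive from this rule.

Deliberately absent: real chemistry diversity, inter-lab assay noise, and
DUD-E-style property-matched decoys. The ligand vocabulary is small (8
scaffolds × 5 terminal options), so the discrimination task is carried
almost entirely by the protein side — which is the capability the
cross-attention exists to provide.

## Reference desk-scale conditions

`seqscreen.benchmark` fixes the study conditions used by the acceptance
suite and script: 80 proteins × 25 ligands (~1800 records after label
masking), the 4-block model at `d_hidden` 64 with sum pooling, lr 1e-3,
accumulation 16, 1800 iterations (~29k samples) — smaller accumulation and
a larger learning rate than the library defaults, sized for this dataset.
Model selection is *protein-disjoint*: two proteins per motif class are
held out entirely, their true records plus an equal number of sampled
decoys form the validation set, and the checkpoint with the best validation
loss is returned. Selecting on a record-level split would reward
memorizing training proteins; the screening claim is about unseen ones.
Forward evaluation screens eight freshly generated proteins (two per motif)
at 5% actives; reverse evaluation ranks 50 fresh proteins for twenty
held-out ligands. Under the planted rule *every* protein carrying the
ligand's motif is a true binder, so reverse-screening recognition is scored
on the best-ranked motif-matched protein; ranks of the specific cognate
protein feed the top-k and cumulative-pair summaries.

## Numerical choices

- EF/success-rate subset size: `ceil(fraction·N)` — never empty at small
  fractions. Ties in any ranking break by input order (stable sort);
  documented because EF at small cutoffs is tie-sensitive.
- BEDROC: rank-based min-max normalization of S = Σ exp(−α·rᵢ/N); the best
  and worst extremes are geometric sums evaluated in closed form, so the
  best possible ranking scores exactly 1 and the worst exactly 0. Default
  α = 80.5. The tests compare against direct summation at 1e-10.
- AUROC is the Mann–Whitney probability (ties ½), delegated to
  scikit-learn; tests verify against exhaustive pair enumeration.
- Benchmark aggregation is the unweighted mean across targets.
- The autodiff engine is float64 throughout; softmax subtracts a detached
  maximum; BCE is computed from the logit via softplus for stability.
- Checkpoints carry a format version and refuse to load mismatches.

## Limitations

- The numpy engine is single-threaded and unbatched across proteins;
  training beyond ~10⁵ samples or real PLM widths is out of its scope.
- The learnable-commutative-monoid pooling is implemented and tested for
  commutativity, but the reference conditions train with sum pooling;
  training stability of `lcm` at desk scale was not characterized.
- The real-PLM adapter is provided untested (no such model ships here).
- Synthetic decoys are label-noisy in one corner: a sampled training decoy
  can, rarely, carry the target's matching pharmacophore if that exact
  SMILES never co-occurs with the protein in the table — the same noise the
  decoy-by-resampling construction has on real data.
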
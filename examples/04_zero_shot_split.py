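"""Homology-aware training-set filtering for zero-shot evaluation.

Before evaluating on external targets, training proteins that are near-
duplicates of any evaluation protein are removed: identity is the optimal
global-alignment match count divided by the *reference* (evaluation)
sequence length, and records above 90% against any reference are dropped.
"""

import numpy as np

from seqscreen import AffinityLabels, InteractionRecord, alignment_identity, homology_filter

rng = np.random.default_rng(7)
alphabet = list("ACDEFGHIKLMNPQRSTVW")
reference = "".join(rng.choice(alphabet, size=100))

homolog = list(reference)
for pos in (5, 30, 55, 80, 95):
    homolog[pos] = "Y"
homolog = "".join(homolog)

unrelated = "".join(rng.choice(list("Y"), size=80))
records = [
    InteractionRecord(homolog, "CCO", AffinityLabels(pKi=9.0)),
    InteractionRecord(unrelated, "CCN", AffinityLabels(pIC50=7.0)),
]
print(f"homolog identity vs reference: {alignment_identity(homolog, reference):.2f}")
print(f"unrelated identity vs reference: {alignment_identity(unrelated, reference):.2f}")
kept = homology_filter(records, [reference], threshold=0.90)
print(f"records kept at the 90% threshold: {len(kept)} of {len(records)}")
# Only the unrelated protein survives: the 95%-identical homolog would leak
# evaluation information into training.
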
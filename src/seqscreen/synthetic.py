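"""Synthetic interaction data with a planted, recoverable binding rule.

The generator emulates the statistical shape of a public binding database
(protein sequence + ligand SMILES + any subset of four affinities) while
keeping full control of the ground truth: K sequence motifs are paired with
K chemical pharmacophores, a protein carries exactly one motif (written
over a random background sequence at a random position), and a ligand
binds a protein iff it carries the matching pharmacophore.  True-pair
affinities are the motif's base pK plus Gaussian noise; each of the four
label slots is then independently masked missing at a configurable rate,
mimicking the sparse Ki/Kd/IC50/EC50 coverage of real assay tables.

Ligands are short alkyl/ether scaffolds with the pharmacophore appended as
a terminal functional group, so every emitted SMILES is valence-valid by
construction, and the pharmacophore is literally a substring of the SMILES.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .plm import AMINO_ACIDS, write_fasta
from .training import (
    AffinityLabels,
    InteractionRecord,
    build_binder_index,
    normalize_affinity,
    write_interaction_table,
)

DEFAULT_MOTIFS = ("WHWHYC", "DEDEDK", "KRKRHM", "FYFWYV")
DEFAULT_PHARMACOPHORES = ("C(=O)O", "N", "C#N", "S")
DEFAULT_BASE_AFFINITY = (8.5, 7.5, 9.0, 8.0)

#: Alkyl/ether scaffolds; any pharmacophore can be appended to any of them.
SCAFFOLDS = ("CC", "CCC", "CCCC", "CCCCC", "COC", "CCOC", "CCOCC", "CCCOC")


@dataclass
class PlantedRule:
    """The ground-truth binding rule: motif k ↔ pharmacophore k.

    ``base_affinity`` is in pK units (-log10 molar); ``noise_sd`` is the
    assay noise on that scale; ``missing_rates`` gives, per label slot, the
    probability that the slot is unreported (defaults mirror the relative
    abundance of IC50 >> Ki > Kd > EC50 in public assay tables).
    """

    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    pharmacophores: tuple[str, ...] = DEFAULT_PHARMACOPHORES
    base_affinity: tuple[float, ...] = DEFAULT_BASE_AFFINITY
    noise_sd: float = 0.3
    missing_rates: dict = field(
        default_factory=lambda: {"pKi": 0.6, "pKd": 0.8, "pIC50": 0.25, "pEC50": 0.85}
    )

    @property
    def n_motifs(self) -> int:
        return len(self.motifs)

    def __post_init__(self):
        k = len(self.motifs)
        if k < 2:
            raise ValueError("a planted rule needs at least 2 motif classes")
        if len(self.pharmacophores) != k or len(self.base_affinity) != k:
            raise ValueError("motifs, pharmacophores and base_affinity must be parallel")
        for m in self.motifs:
            if not (5 <= len(m) <= 8):
                raise ValueError(f"motif {m!r} must be 5-8 residues long")
            if any(ch not in AMINO_ACIDS for ch in m):
                raise ValueError(f"motif {m!r} contains a non-standard residue")
        for i, a in enumerate(self.motifs):
            for b in self.motifs[i + 1 :]:
                if a in b or b in a:
                    raise ValueError(f"motifs {a!r} and {b!r} overlap as substrings")
        from .molgraph import smiles_to_graph

        for scaffold in SCAFFOLDS:
            for phg in self.pharmacophores:
                smiles_to_graph(scaffold + phg)  # raises if invalid


def random_protein(
    rng: np.random.Generator, motif: str, seq_len: int
) -> tuple[str, int]:
    """Uniform random sequence with the motif written over a random window
    (replacement, not insertion, so the length stays fixed)."""
    if seq_len < len(motif):
        raise ValueError("sequence shorter than the motif")
    background = rng.choice(list(AMINO_ACIDS), size=seq_len)
    pos = int(rng.integers(0, seq_len - len(motif) + 1))
    background[pos : pos + len(motif)] = list(motif)
    return "".join(background), pos


def active_smiles(rule: PlantedRule, motif_index: int, rng: np.random.Generator) -> str:
    scaffold = SCAFFOLDS[int(rng.integers(len(SCAFFOLDS)))]
    return scaffold + rule.pharmacophores[motif_index]


def decoy_smiles(rule: PlantedRule, motif_index: int, rng: np.random.Generator) -> str:
    """A ligand that does NOT match motif ``motif_index``: a bare scaffold
    or a scaffold carrying a mismatched pharmacophore."""
    scaffold = SCAFFOLDS[int(rng.integers(len(SCAFFOLDS)))]
    others = [i for i in range(rule.n_motifs) if i != motif_index]
    if rng.random() < 0.25:
        return scaffold
    return scaffold + rule.pharmacophores[int(rng.choice(others))]


@dataclass
class SyntheticDataset:
    records: list[InteractionRecord]
    binder_index: dict[str, set[str]]
    protein_motifs: dict[str, int]  # protein sequence -> motif index
    rule: PlantedRule
    seed: int


def generate_dataset(
    rule: PlantedRule,
    n_proteins: int = 40,
    ligands_per_protein: int = 50,
    seq_len_range: tuple[int, int] = (48, 64),
    seed: int = 0,
) -> SyntheticDataset:
    """Generate true-pair interaction records under the planted rule.

    Each protein gets ``ligands_per_protein`` matched ligands; the pK label
    is base_affinity[k] + N(0, noise_sd), identical across the four slots
    before masking; slots are masked missing independently at the
    configured rates, and a record with all four slots missing is dropped.
    Deterministic under the seed.
    """
    if rule.n_motifs < 2:
        raise ValueError("need at least two motif classes")
    if n_proteins < rule.n_motifs:
        raise ValueError("need at least one protein per motif class")
    rng = np.random.default_rng(seed)
    records: list[InteractionRecord] = []
    protein_motifs: dict[str, int] = {}
    for p in range(n_proteins):
        motif_index = p % rule.n_motifs  # balanced motif classes
        seq_len = int(rng.integers(seq_len_range[0], seq_len_range[1] + 1))
        sequence, _ = random_protein(rng, rule.motifs[motif_index], seq_len)
        protein_motifs[sequence] = motif_index
        for _ in range(ligands_per_protein):
            smiles = active_smiles(rule, motif_index, rng)
            pk = rule.base_affinity[motif_index] + rng.normal(0.0, rule.noise_sd)
            values = {}
            for name, rate in rule.missing_rates.items():
                if rng.random() >= rate:
                    values[name] = pk
            if not values:
                continue  # all four labels masked: record dropped
            records.append(
                InteractionRecord(
                    protein_sequence=sequence,
                    smiles=smiles,
                    labels=AffinityLabels(**values),
                )
            )
    return SyntheticDataset(
        records=records,
        binder_index=build_binder_index(records),
        protein_motifs=protein_motifs,
        rule=rule,
        seed=seed,
    )


def generate_screen(
    rule: PlantedRule,
    protein_index: int,
    n_actives: int = 5,
    n_decoys: int = 95,
    seed: int = 0,
) -> list[tuple[str, bool]]:
    """An actives/decoys benchmark list for one motif class.

    ``protein_index`` selects the motif class (index modulo K, matching
    :func:`generate_dataset`'s class assignment).  Actives carry the
    matching pharmacophore; decoys carry mismatched pharmacophores or bare
    scaffolds.  Returns (smiles, is_active) pairs, deterministic under the
    seed.
    """
    if n_actives < 1 or n_decoys < 1:
        raise ValueError("need at least one active and one decoy")
    rng = np.random.default_rng(seed)
    motif_index = protein_index % rule.n_motifs
    entries = [(active_smiles(rule, motif_index, rng), True) for _ in range(n_actives)]
    entries += [(decoy_smiles(rule, motif_index, rng), False) for _ in range(n_decoys)]
    order = rng.permutation(len(entries))
    return [entries[i] for i in order]


# -- file emission ---------------------------------------------------------------


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict:
    """Write the training TSV, a FASTA of proteins, and a JSON manifest
    recording rule, seed and counts; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_interaction_table(directory / "interactions.tsv", dataset.records)
    sequences = {
        f"protein_{i:04d}_motif{m}": seq
        for i, (seq, m) in enumerate(dataset.protein_motifs.items())
    }
    write_fasta(directory / "proteins.fasta", sequences)
    manifest = {
        "rule": asdict(dataset.rule),
        "seed": dataset.seed,
        "n_records": len(dataset.records),
        "n_proteins": len(dataset.protein_motifs),
        "n_unique_smiles": len({r.smiles for r in dataset.records}),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_screen(entries: list[tuple[str, bool]], directory: str | Path) -> None:
    """Write a screen as actives.smi / decoys.smi plus a labeled CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "actives.smi", "w") as fa, open(
        directory / "decoys.smi", "w"
    ) as fd:
        for smi, active in entries:
            (fa if active else fd).write(smi + "\n")
    with open(directory / "screen.csv", "w") as fh:
        fh.write("smiles,is_active\n")
        for smi, active in entries:
            fh.write(f"{smi},{int(active)}\n")
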
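"""SMILES parsing into featurized molecular graphs.

Ligands enter the model as heavy-atom graphs whose nodes are later treated
as attention tokens.  Parsing is done with RDKit but *without* sanitization,
so aromaticity is taken exactly as written in the SMILES string: lowercase
aromatic atoms stay aromatic and no kekulization or aromaticity
re-perception is applied.  Hydrogens are implicit and contribute a per-node
hydrogen-count feature.

Node features (:data:`NODE_FEATURE_NAMES`, in order):

* one-hot element over ``C, N, O, S, P, F, Cl, Br, I`` plus an ``other`` slot
* aromatic flag (0/1)
* formal charge (integer)
* implicit-hydrogen count
* heavy-atom degree

Edge features: one-hot bond order over ``single, double, triple, aromatic``.
Every chemical bond is stored as two directed edges with identical features.
Atom order follows SMILES token order (RDKit atom indices), so the same
string always produces byte-identical arrays.  Stereochemistry markers are
accepted by the parser but not featurized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
NODE_FEATURE_NAMES = tuple(
    [f"element_{e}" for e in ELEMENTS]
    + ["element_other", "aromatic", "formal_charge", "n_implicit_h", "degree"]
)
EDGE_FEATURE_NAMES = ("bond_single", "bond_double", "bond_triple", "bond_aromatic")

N_NODE_FEATURES = len(NODE_FEATURE_NAMES)
N_EDGE_FEATURES = len(EDGE_FEATURE_NAMES)

_BOND_SLOT = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be turned into a molecular graph."""


@dataclass(frozen=True)
class MolecularGraph:
    """A heavy-atom ligand graph.

    ``edge_index`` has shape [n_edges, 2] with directed (source, target)
    pairs; each bond contributes both directions with identical features.
    """

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray
    smiles: str

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[0]

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("a molecular graph needs at least one node")
        if self.n_edges and (
            self.edge_index.min() < 0 or self.edge_index.max() >= self.n_nodes
        ):
            raise ValueError("edge endpoint out of range")


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Raises :class:`SmilesParseError` (naming the offending string) on an
    empty or unparseable input.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    try:
        mol.UpdatePropertyCache(strict=False)
    except Exception as exc:  # pragma: no cover - rdkit internal failures
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}") from exc

    n = mol.GetNumAtoms()
    node_features = np.zeros((n, N_NODE_FEATURES), dtype=np.float64)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        symbol = atom.GetSymbol()
        slot = ELEMENTS.index(symbol) if symbol in ELEMENTS else len(ELEMENTS)
        node_features[i, slot] = 1.0
        node_features[i, len(ELEMENTS) + 1] = float(atom.GetIsAromatic())
        node_features[i, len(ELEMENTS) + 2] = float(atom.GetFormalCharge())
        node_features[i, len(ELEMENTS) + 3] = float(atom.GetNumImplicitHs())
        node_features[i, len(ELEMENTS) + 4] = float(atom.GetDegree())

    edges: list[tuple[int, int]] = []
    edge_rows: list[np.ndarray] = []
    for bond in mol.GetBonds():
        feat = np.zeros(N_EDGE_FEATURES, dtype=np.float64)
        slot = _BOND_SLOT.get(bond.GetBondType())
        if slot is None:
            # unknown bond order (e.g. dative); fall back to single
            slot = 0
        feat[slot] = 1.0
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.extend([(i, j), (j, i)])
        edge_rows.extend([feat, feat.copy()])

    edge_index = (
        np.asarray(edges, dtype=np.intp)
        if edges
        else np.zeros((0, 2), dtype=np.intp)
    )
    edge_features = (
        np.stack(edge_rows) if edge_rows else np.zeros((0, N_EDGE_FEATURES))
    )
    return MolecularGraph(node_features, edge_index, edge_features, smiles)


@dataclass(frozen=True)
class BatchedGraph:
    """Disjoint union of molecular graphs with a node→graph membership map."""

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray
    membership: np.ndarray  # node -> graph index
    graphs: tuple[MolecularGraph, ...] = field(repr=False)

    @property
    def n_graphs(self) -> int:
        return len(self.graphs)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


def batch_graphs(graphs: list[MolecularGraph]) -> BatchedGraph:
    """Concatenate graphs into one disjoint union; node indices are offset."""
    if not graphs:
        raise ValueError("cannot batch an empty list of graphs")
    node_blocks, edge_blocks, feat_blocks, members = [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        node_blocks.append(g.node_features)
        edge_blocks.append(g.edge_index + offset)
        feat_blocks.append(g.edge_features)
        members.append(np.full(g.n_nodes, gi, dtype=np.intp))
        offset += g.n_nodes
    return BatchedGraph(
        node_features=np.concatenate(node_blocks, axis=0),
        edge_index=np.concatenate(edge_blocks, axis=0),
        edge_features=np.concatenate(feat_blocks, axis=0),
        membership=np.concatenate(members),
        graphs=tuple(graphs),
    )


def unbatch_graphs(batch: BatchedGraph) -> list[MolecularGraph]:
    """Recover the original graphs from a batch, exactly."""
    out = []
    offset = 0
    for g in batch.graphs:
        n = g.n_nodes
        mask = (batch.edge_index[:, 0] >= offset) & (batch.edge_index[:, 0] < offset + n)
        out.append(
            MolecularGraph(
                node_features=batch.node_features[offset : offset + n].copy(),
                edge_index=batch.edge_index[mask] - offset,
                edge_features=batch.edge_features[mask].copy(),
                smiles=g.smiles,
            )
        )
        offset += n
    return out


# -- input readers ---------------------------------------------------------------


def read_smiles_file(path: str | Path) -> list[str]:
    """Read one SMILES per line; blank lines are skipped.

    If a line has whitespace-separated fields the first is the SMILES
    (the common ``SMILES name`` layout).
    """
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            out.append(line.split()[0])
    return out


def read_smiles_column(path: str | Path, column: str = "smiles") -> list[str]:
    """Read SMILES from a named column of a CSV/TSV file (separator sniffed)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep)
    if column not in frame.columns:
        raise KeyError(f"column {column!r} not found in {path}")
    return frame[column].astype(str).tolist()
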
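"""Frozen per-residue protein latents behind a uniform embedder interface.

The model cross-attends to per-residue latent matrices taken from several
depths of a protein encoder.  Two backends are provided:

* :class:`ToyEmbedder` — a deterministic, frozen random network used for all
  desk-scale work and tests.  Each residue is encoded as a one-hot vector
  concatenated with a sinusoidal position encoding, linearly projected, and
  passed through a stack of frozen random affine+tanh layers; "layers" of
  the stack play the role of encoder depths.  It is position- and
  composition-sensitive, so planted sequence motifs are linearly detectable
  in its latents.
* :class:`ESM2Embedder` — an optional adapter to a real pre-trained protein
  language model through HuggingFace Transformers, if that library is
  installed.  It is never required by the tests.

Embedders are frozen by construction: they expose no trainable parameters
and their outputs are plain numpy arrays, so no gradient can flow into them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"

#: Fixed seed constant for the default toy embedder, shared across processes.
TOY_EMBEDDER_SEED = 2024


@dataclass(frozen=True)
class ResidueEmbeddingStack:
    """Per-residue latents from several encoder depths of one protein.

    Every matrix has shape [len(sequence), d_embed]; ``layer_indices`` is
    strictly increasing and parallel to ``layers``.
    """

    layers: tuple[np.ndarray, ...]
    layer_indices: tuple[int, ...]
    sequence: str

    def __post_init__(self):
        if len(self.layers) != len(self.layer_indices):
            raise ValueError("layers and layer_indices must be parallel")
        if list(self.layer_indices) != sorted(set(self.layer_indices)):
            raise ValueError("layer_indices must be strictly increasing")
        for m in self.layers:
            if m.shape[0] != len(self.sequence):
                raise ValueError("latent row count must equal sequence length")

    @property
    def seq_len(self) -> int:
        return len(self.sequence)

    @property
    def d_embed(self) -> int:
        return self.layers[0].shape[1]

    def equals(self, other: "ResidueEmbeddingStack") -> bool:
        return (
            self.sequence == other.sequence
            and self.layer_indices == other.layer_indices
            and all(np.array_equal(a, b) for a, b in zip(self.layers, other.layers))
        )


def validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty protein sequence")
    for pos, ch in enumerate(sequence):
        if ch not in ALPHABET:
            raise ValueError(
                f"invalid residue {ch!r} at position {pos} (expected one of {ALPHABET})"
            )


def concat_chains(chain_sequences: list[str]) -> str:
    """Concatenate multi-chain sequences, in order, with no separator."""
    if not chain_sequences:
        raise ValueError("no chains given")
    for i, chain in enumerate(chain_sequences):
        if not chain:
            raise ValueError(f"chain {i} is empty")
    return "".join(chain_sequences)


class ToyEmbedder:
    """Frozen random per-residue encoder for desk-scale experiments.

    Each residue starts as (one-hot ⊕ damped sinusoidal position encoding)
    projected to ``d_embed``; every frozen layer then applies a random
    affine over the residue's ±1-residue window followed by a rectifier.
    Depth therefore widens the receptive field (layer ``l`` sees a
    (2l+1)-mer), so short sequence motifs become linearly decodable from
    the deeper latents — a desk-scale stand-in for the contextual latents
    of a real protein language model.  The position encoding is kept small
    relative to the residue identity so that the same k-mer maps to nearly
    the same latent wherever it occurs, as conserved motifs do in real
    protein-language-model latents, while still making latents
    position-sensitive.

    Parameters
    ----------
    d_embed:
        Width of every latent layer (default 128).
    n_layers:
        Number of frozen layers; valid ``layer_indices`` are 0..n_layers-1,
        where index ``i`` is the output of the (i+1)-th layer.
    seed:
        Seed for the frozen random weights.  The default is a module-level
        constant so independently constructed embedders agree bitwise.
    """

    def __init__(
        self,
        d_embed: int = 128,
        n_layers: int = 4,
        seed: int = TOY_EMBEDDER_SEED,
        d_position: int = 16,
        position_scale: float = 0.05,
    ):
        rng = np.random.default_rng(seed)
        self.d_embed = d_embed
        self.n_layers = n_layers
        self.d_position = d_position
        self.position_scale = position_scale
        d_in = len(ALPHABET) + d_position
        scale = 1.0 / np.sqrt(d_in)
        self._w_in = rng.normal(0.0, scale, size=(d_in, d_embed))
        window_scale = np.sqrt(2.0 / (3 * d_embed))
        self._weights = [
            rng.normal(0.0, window_scale, size=(3 * d_embed, d_embed))
            for _ in range(n_layers)
        ]
        self._biases = [rng.normal(0.0, 0.1, size=d_embed) for _ in range(n_layers)]

    @property
    def layer_count(self) -> int:
        return self.n_layers

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(self._w_in.tobytes())
        for w, b in zip(self._weights, self._biases):
            h.update(w.tobytes())
            h.update(b.tobytes())
        return h.hexdigest()

    def _input_encoding(self, sequence: str) -> np.ndarray:
        n = len(sequence)
        onehot = np.zeros((n, len(ALPHABET)))
        for i, ch in enumerate(sequence):
            onehot[i, ALPHABET.index(ch)] = 1.0
        pos = np.arange(n)[:, None]
        k = np.arange(self.d_position // 2)[None, :]
        angles = pos / (10000.0 ** (2 * k / self.d_position))
        pe = np.concatenate([np.sin(angles), np.cos(angles)], axis=1)
        return np.concatenate([onehot, self.position_scale * pe], axis=1)

    def layer_outputs(self, sequence: str) -> list[np.ndarray]:
        h = self._input_encoding(sequence) @ self._w_in
        outputs = []
        for w, b in zip(self._weights, self._biases):
            prev = np.vstack([h[:1], h[:-1]])  # edge positions repeat themselves
            nxt = np.vstack([h[1:], h[-1:]])
            window = np.concatenate([prev, h, nxt], axis=1)
            h = np.maximum(window @ w + b, 0.0)
            # emitted latents are standardized per residue, as the
            # layer-normalized hidden states of a real PLM are
            out = (h - h.mean(axis=1, keepdims=True)) / (
                h.std(axis=1, keepdims=True) + 1e-6
            )
            outputs.append(out)
        return outputs

    def embed(self, sequence: str, layer_indices: list[int]) -> ResidueEmbeddingStack:
        return embed_sequence(sequence, layer_indices, self)


def embed_sequence(
    sequence: str, layer_indices: list[int], backend
) -> ResidueEmbeddingStack:
    """Compute a :class:`ResidueEmbeddingStack` with a frozen backend.

    Deterministic: identical inputs yield bitwise-identical stacks.
    """
    validate_sequence(sequence)
    if not layer_indices:
        raise ValueError("layer_indices must be non-empty")
    n_layers = backend.layer_count
    for idx in layer_indices:
        if not (0 <= idx < n_layers):
            raise ValueError(
                f"layer index {idx} out of range for backend with {n_layers} layers"
            )
    outputs = backend.layer_outputs(sequence)
    return ResidueEmbeddingStack(
        layers=tuple(outputs[i] for i in layer_indices),
        layer_indices=tuple(layer_indices),
        sequence=sequence,
    )


class ESM2Embedder:
    """Adapter to a pre-trained ESM-2 protein language model (optional).

    Requires the ``transformers`` and ``torch`` packages; latents from the
    requested hidden layers are returned unchanged (no pooling or extra
    normalization), with special tokens stripped.
    """

    def __init__(self, model_name: str = "facebook/esm2_t33_650M_UR50D"):
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "ESM2Embedder requires the 'transformers' and 'torch' packages"
            ) from exc
        self._torch = torch
        self._tokenizer = AutoTokenizer.from_pretrained(model_name)
        self._model = AutoModel.from_pretrained(model_name, output_hidden_states=True)
        self._model.eval()
        for p in self._model.parameters():
            p.requires_grad_(False)

    @property
    def layer_count(self) -> int:  # pragma: no cover - optional dependency
        return self._model.config.num_hidden_layers + 1

    def layer_outputs(self, sequence: str):  # pragma: no cover - optional dependency
        torch = self._torch
        tokens = self._tokenizer(sequence, return_tensors="pt")
        with torch.no_grad():
            out = self._model(**tokens)
        # hidden_states[i] is the output of layer i (0 = embeddings); strip BOS/EOS
        return [h[0, 1 : len(sequence) + 1].numpy() for h in out.hidden_states]


# -- embedding cache -------------------------------------------------------------


class EmbeddingCache:
    """In-memory embedding store keyed by protein id, with an optional
    on-disk spill directory keyed by sequence hash.

    One embedding computation per protein per screen: :meth:`get_or_compute`
    only calls the backend on a miss and counts backend calls for auditing.
    """

    def __init__(self, directory: str | Path | None = None):
        self._store: dict[str, ResidueEmbeddingStack] = {}
        self._dir = Path(directory) if directory is not None else None
        if self._dir is not None:
            self._dir.mkdir(parents=True, exist_ok=True)
        self.backend_calls = 0

    @staticmethod
    def sequence_key(sequence: str, layer_indices: list[int]) -> str:
        tag = ",".join(map(str, layer_indices))
        return hashlib.sha256(f"{sequence}|{tag}".encode()).hexdigest()

    def put(self, protein_id: str, stack: ResidueEmbeddingStack) -> None:
        self._store[protein_id] = stack
        if self._dir is not None:
            key = self.sequence_key(stack.sequence, list(stack.layer_indices))
            np.savez(
                self._dir / f"{key}.npz",
                sequence=np.frombuffer(stack.sequence.encode(), dtype=np.uint8),
                layer_indices=np.asarray(stack.layer_indices),
                **{f"layer_{i}": m for i, m in enumerate(stack.layers)},
            )

    def get(self, protein_id: str) -> ResidueEmbeddingStack:
        if protein_id not in self._store:
            raise KeyError(f"no cached embedding for protein id {protein_id!r}")
        return self._store[protein_id]

    def evict(self, protein_id: str) -> None:
        self._store.pop(protein_id, None)

    def get_or_compute(
        self, sequence: str, layer_indices: list[int], backend
    ) -> ResidueEmbeddingStack:
        key = self.sequence_key(sequence, layer_indices)
        if key in self._store:
            return self._store[key]
        if self._dir is not None:
            path = self._dir / f"{key}.npz"
            if path.exists():
                with np.load(path) as data:
                    stack = ResidueEmbeddingStack(
                        layers=tuple(
                            data[f"layer_{i}"] for i in range(len(data["layer_indices"]))
                        ),
                        layer_indices=tuple(int(i) for i in data["layer_indices"]),
                        sequence=bytes(data["sequence"]).decode(),
                    )
                self._store[key] = stack
                return stack
        self.backend_calls += 1
        stack = embed_sequence(sequence, layer_indices, backend)
        self.put(key, stack)
        return stack


# -- FASTA I/O -------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences from FASTA; the description line up to the
    first whitespace is the id."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
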
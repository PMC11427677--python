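"""The screening network: graph attention convolutions interleaved with
cross-attention graph blocks over frozen protein latents, commutative
pooling, and five prediction heads.

Architecture
------------
Ligand node features are projected to ``d_hidden`` and then pass through
``n_blocks`` blocks, one per attended encoder depth (consumed in ascending
order).  Each block is

1. a GATv2-style dynamic-attention graph convolution over directed edges
   (edge features enter the attention logit; self-loops included), with a
   residual connection;
2. a *cross-attention graph block*: the graph is unwrapped so every node is
   an individual query token over the protein's per-residue keys/values
   (multi-head scaled dot-product attention, post-norm residual as in the
   original transformer decoder), then the graph is reconstructed;
3. a pointwise two-layer feed-forward network with leaky-ReLU, post-norm
   residual.

Nodes are then pooled per graph (learnable commutative monoid, sum or mean)
and five independent two-layer heads produce pKi, pKd, pIC50, pEC50 and a
raw binder-vs-decoy logit.  The logit is multiplied by ``exp(tau)`` — tau is
a trainable temperature initialized at 0.07 — and clipped to ±100.

The protein embedder is frozen and outside this module; it contributes no
trainable parameter, so its weights cannot change during training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat, gather_rows, layer_norm, segment_sum, softmax
from .molgraph import BatchedGraph, N_EDGE_FEATURES, N_NODE_FEATURES
from .plm import ResidueEmbeddingStack

CHECKPOINT_VERSION = 1

AFFINITY_HEADS = ("pKi", "pKd", "pIC50", "pEC50")
HEAD_NAMES = AFFINITY_HEADS + ("logit",)


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    ``encoder_layer_indices`` names the embedder depths cross-attended to,
    one per block, in ascending order; the default mirrors a deep
    protein-language-model backbone (layers 1, 11, 21, 31).  Desk-scale
    work with the toy embedder uses :func:`desk_config` (layers 0–3).
    """

    d_hidden: int = 64
    n_attention_heads: int = 4
    encoder_layer_indices: list[int] = field(default_factory=lambda: [1, 11, 21, 31])
    n_blocks: int = 4
    dropout: float = 0.1
    leaky_slope: float = 0.05
    tau_init: float = 0.07
    logit_clip: float = 100.0
    pooling: str = "lcm"
    pre_norm: bool = False
    d_latent: int = 64
    d_node: int = N_NODE_FEATURES
    d_edge: int = N_EDGE_FEATURES
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks != len(self.encoder_layer_indices):
            raise ValueError("n_blocks must equal len(encoder_layer_indices)")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.logit_clip <= 0:
            raise ValueError("logit_clip must be positive")
        if self.pooling not in ("lcm", "sum", "mean"):
            raise ValueError(f"unknown pooling mode {self.pooling!r}")
        if self.d_hidden % self.n_attention_heads:
            raise ValueError("d_hidden must be divisible by n_attention_heads")


def desk_config(**overrides) -> ModelConfig:
    """Small configuration paired with the 4-layer toy embedder."""
    defaults = dict(encoder_layer_indices=[0, 1, 2, 3], pooling="sum", d_latent=128)
    defaults.update(overrides)
    return ModelConfig(**defaults)


@dataclass(frozen=True)
class PredictionSet:
    """Model outputs for one protein–ligand pair.

    Affinities are on the -log10(molar) scale; ``probability`` is the
    sigmoid of the scaled, clipped binder-vs-decoy logit.
    """

    pKi: float
    pKd: float
    pIC50: float
    pEC50: float
    logit: float
    probability: float

    def score(self, name: str) -> float:
        return getattr(self, name)


# -- parameter initialization ----------------------------------------------------


def _affine(rng, d_in, d_out):
    scale = np.sqrt(2.0 / (d_in + d_out))
    return rng.normal(0.0, scale, size=(d_in, d_out)), np.zeros(d_out)


def init_parameters(config: ModelConfig) -> dict[str, Tensor]:
    """Build the trainable parameter dictionary (the embedder contributes
    nothing here — it is frozen by construction)."""
    rng = np.random.default_rng(config.seed)
    d = config.d_hidden
    params: dict[str, np.ndarray] = {}

    def put(name, *arrays):
        w, b = arrays
        params[name + ".w"] = w
        params[name + ".b"] = b

    put("input_proj", *_affine(rng, config.d_node, d))
    for blk in range(config.n_blocks):
        p = f"block{blk}."
        # GATv2 convolution
        put(p + "conv.src", *_affine(rng, d, d))
        put(p + "conv.dst", *_affine(rng, d, d))
        params[p + "conv.edge.w"], _ = _affine(rng, config.d_edge, d)
        params[p + "conv.attn"] = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, 1))
        # cross-attention graph block; query/key projections start wider
        # than Xavier so initial attention is non-uniform — with
        # near-uniform weights every protein reads as its average residue
        # and the gradient into the attention maps vanishes
        put(p + "xattn.adapter", *_affine(rng, config.d_latent, d))
        wq, bq = _affine(rng, d, d)
        wk, bk = _affine(rng, d, d)
        put(p + "xattn.q", 4.0 * wq, bq)
        put(p + "xattn.k", 4.0 * wk, bk)
        put(p + "xattn.v", *_affine(rng, d, d))
        put(p + "xattn.o", *_affine(rng, d, d))
        params[p + "xattn.ln.gamma"] = np.ones(d)
        params[p + "xattn.ln.beta"] = np.zeros(d)
        # feed-forward
        put(p + "ffn.fc1", *_affine(rng, d, d))
        put(p + "ffn.fc2", *_affine(rng, d, d))
        params[p + "ffn.ln.gamma"] = np.ones(d)
        params[p + "ffn.ln.beta"] = np.zeros(d)
    if config.pooling == "lcm":
        put("pool.fc1", *_affine(rng, 2 * d, d))
        put("pool.fc2", *_affine(rng, d, d))
    for head in HEAD_NAMES:
        put(f"head.{head}.fc1", *_affine(rng, d, d))
        put(f"head.{head}.fc2", *_affine(rng, d, 1))
    params["tau"] = np.asarray(config.tau_init, dtype=np.float64)
    return {k: Tensor(v, requires_grad=True) for k, v in params.items()}


# -- building blocks -------------------------------------------------------------


def _linear(x: Tensor, params: dict, name: str) -> Tensor:
    return x @ params[name + ".w"] + params[name + ".b"]


def cross_attention_graph_block(
    node_states: Tensor,
    residue_latents: Tensor,
    residue_mask: np.ndarray,
    params: dict,
    prefix: str = "",
    n_heads: int = 1,
    leaky_slope: float = 0.05,
    use_adapter: bool = True,
    use_residual_norm: bool = True,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    return_weights: bool = False,
):
    """Multi-head cross-attention where every graph node is a query token
    over protein residue keys/values.

    Masked residues (``residue_mask`` False) receive exactly zero attention
    weight.  The output is residual-added to the input and layer-normalized
    (post-norm) unless ``use_residual_norm`` is disabled (a test hook that
    exposes the bare attention output).  Node count, width and the graph's
    connectivity are untouched: attention treats nodes as a set of tokens
    and the caller reassembles them into the graph.
    """
    node_states = Tensor.lift(node_states)
    residue_latents = Tensor.lift(residue_latents)
    residue_mask = np.asarray(residue_mask, dtype=bool)
    if residue_mask.shape[0] != residue_latents.shape[0]:
        raise ValueError("residue_mask length must match residue_latents rows")
    if not residue_mask.any():
        raise ValueError("all residues are masked: no keys to attend to")

    d = node_states.shape[1]
    if d % n_heads:
        raise ValueError("width not divisible by the number of attention heads")
    d_head = d // n_heads

    latents = (
        _linear(residue_latents, params, prefix + "adapter")
        if use_adapter
        else residue_latents
    )
    if latents.shape[1] != d:
        raise ValueError(
            f"latent width {latents.shape[1]} does not match node width {d}"
        )
    q = _linear(node_states, params, prefix + "q")
    k = _linear(latents, params, prefix + "k")
    v = _linear(latents, params, prefix + "v")

    additive_mask = np.where(residue_mask, 0.0, -1e30)[None, :]
    head_outputs = []
    weights = []
    for h in range(n_heads):
        sl = slice(h * d_head, (h + 1) * d_head)
        qh, kh, vh = q[:, sl], k[:, sl], v[:, sl]
        logits = (qh @ kh.T) * (1.0 / np.sqrt(d_head))
        attn = softmax(logits, axis=-1, additive_mask=additive_mask)
        if dropout > 0 and rng is not None:
            keep = (rng.random(attn.shape) >= dropout) / (1.0 - dropout)
            attn = attn * Tensor(keep)
        weights.append(attn)
        head_outputs.append(attn @ vh)
    merged = concat(head_outputs, axis=1)
    out = _linear(merged, params, prefix + "o")
    if use_residual_norm:
        out = layer_norm(
            node_states + out,
            params[prefix + "ln.gamma"],
            params[prefix + "ln.beta"],
        )
    if return_weights:
        return out, [w.data for w in weights]
    return out


def graph_conv(
    node_states: Tensor,
    edge_index: np.ndarray,
    edge_features: np.ndarray,
    params: dict,
    prefix: str = "",
    leaky_slope: float = 0.05,
) -> Tensor:
    """GATv2-style dynamic-attention message passing over directed edges.

    Edge features enter the attention logit; self-loops (with zero edge
    features) are always included, so an isolated node reduces to its own
    transformed self-message.
    """
    node_states = Tensor.lift(node_states)
    n_nodes = node_states.shape[0]
    edge_index = np.asarray(edge_index, dtype=np.intp)
    if edge_index.size and edge_index.max() >= n_nodes:
        raise ValueError("dangling edge index")

    loops = np.stack([np.arange(n_nodes)] * 2, axis=1)
    loop_feats = np.zeros((n_nodes, edge_features.shape[1] if edge_features.size else params[prefix + "edge.w"].shape[0]))
    if edge_index.size:
        src = np.concatenate([edge_index[:, 0], loops[:, 0]])
        dst = np.concatenate([edge_index[:, 1], loops[:, 1]])
        efeat = np.concatenate([edge_features, loop_feats], axis=0)
    else:
        src, dst, efeat = loops[:, 0], loops[:, 1], loop_feats

    h_src = _linear(node_states, params, prefix + "src")
    h_dst = _linear(node_states, params, prefix + "dst")
    e_term = Tensor(efeat) @ params[prefix + "edge.w"]
    msg = gather_rows(h_src, src) + e_term  # message carried along each edge
    pre = (msg + gather_rows(h_dst, dst)).leaky_relu(leaky_slope)
    logits = (pre @ params[prefix + "attn"]).reshape(-1)

    # per-destination softmax over incoming edges (self-loop guarantees >= 1)
    shift = np.full(n_nodes, -np.inf)
    np.maximum.at(shift, dst, logits.data)
    exps = (logits - Tensor(shift[dst])).exp()
    denom = segment_sum(exps.reshape(-1, 1), dst, n_nodes)
    alpha = exps.reshape(-1, 1) / gather_rows(denom, dst)
    return segment_sum(alpha * msg, dst, n_nodes)


def _lcm_binary(a: Tensor, b: Tensor, params: dict, leaky_slope: float) -> Tensor:
    """Learned commutative binary operator: an MLP over the symmetric
    functions (a+b, a*b), hence f(a,b) == f(b,a) exactly."""
    sym = concat([a + b, a * b], axis=1)
    hidden = _linear(sym, params, "pool.fc1").leaky_relu(leaky_slope)
    return _linear(hidden, params, "pool.fc2")


def pool_nodes(
    node_states: Tensor,
    membership: np.ndarray,
    mode: str,
    params: dict | None = None,
    n_graphs: int | None = None,
    leaky_slope: float = 0.05,
) -> Tensor:
    """Reduce node rows to one vector per graph.

    ``sum``/``mean`` are exactly permutation-invariant; ``lcm`` applies a
    learned commutative binary operator over a balanced binary tree of each
    graph's nodes.
    """
    node_states = Tensor.lift(node_states)
    membership = np.asarray(membership, dtype=np.intp)
    if n_graphs is None:
        n_graphs = int(membership.max()) + 1 if membership.size else 0
    counts = np.bincount(membership, minlength=n_graphs)
    if (counts == 0).any():
        raise ValueError("every graph must contain at least one node")

    if mode == "sum":
        return segment_sum(node_states, membership, n_graphs)
    if mode == "mean":
        totals = segment_sum(node_states, membership, n_graphs)
        return totals / Tensor(counts[:, None].astype(np.float64))
    if mode == "lcm":
        if params is None:
            raise ValueError("lcm pooling requires parameters")
        pooled = []
        for g in range(n_graphs):
            rows = [node_states[i : i + 1] for i in np.flatnonzero(membership == g)]
            while len(rows) > 1:
                nxt = [
                    _lcm_binary(rows[i], rows[i + 1], params, leaky_slope)
                    for i in range(0, len(rows) - 1, 2)
                ]
                if len(rows) % 2:
                    nxt.append(rows[-1])
                rows = nxt
            pooled.append(rows[0])
        return concat(pooled, axis=0)
    raise ValueError(f"unknown pooling mode {mode!r}")


def scale_logit(raw_logit, tau, clip: float):
    """Multiply the raw classifier logit by exp(tau) and clamp to ±clip."""
    raw = raw_logit if isinstance(raw_logit, Tensor) else Tensor(raw_logit)
    if not np.all(np.isfinite(raw.data)):
        raise ValueError("non-finite logit")
    tau_t = tau if isinstance(tau, Tensor) else Tensor(tau)
    if not np.all(np.isfinite(tau_t.data)):
        raise ValueError("non-finite temperature")
    return (raw * tau_t.exp()).clip(-clip, clip)


# -- the full network ------------------------------------------------------------


class ScreeningModel:
    """Ties configuration, parameters and the frozen embedder together.

    ``forward_tensors`` keeps the autodiff graph (training);
    :meth:`predict` returns plain :class:`PredictionSet` values
    (deterministic in evaluation mode).
    """

    def __init__(self, config: ModelConfig, params: dict[str, Tensor] | None = None):
        self.config = config
        self.params = params if params is not None else init_parameters(config)
        self._dropout_rng = np.random.default_rng(config.seed + 1)

    # mode handling: dropout only when training
    def forward_tensors(
        self,
        batch: BatchedGraph,
        embeddings: ResidueEmbeddingStack,
        training: bool = False,
    ) -> dict[str, Tensor]:
        cfg = self.config
        if tuple(embeddings.layer_indices) != tuple(cfg.encoder_layer_indices):
            raise ValueError(
                "embedding stack layers "
                f"{embeddings.layer_indices} do not match configured "
                f"{tuple(cfg.encoder_layer_indices)}"
            )
        params = self.params
        mask = np.ones(embeddings.seq_len, dtype=bool)
        h = _linear(Tensor(batch.node_features), params, "input_proj")
        for blk in range(cfg.n_blocks):
            p = f"block{blk}."
            h = h + graph_conv(
                h, batch.edge_index, batch.edge_features, params,
                prefix=p + "conv.", leaky_slope=cfg.leaky_slope,
            )
            h = cross_attention_graph_block(
                h,
                Tensor(embeddings.layers[blk]),
                mask,
                params,
                prefix=p + "xattn.",
                n_heads=cfg.n_attention_heads,
                leaky_slope=cfg.leaky_slope,
                dropout=cfg.dropout if training else 0.0,
                rng=self._dropout_rng if training else None,
            )
            ff = _linear(h, params, p + "ffn.fc1").leaky_relu(cfg.leaky_slope)
            ff = _linear(ff, params, p + "ffn.fc2")
            h = layer_norm(h + ff, params[p + "ffn.ln.gamma"], params[p + "ffn.ln.beta"])

        pooled = pool_nodes(
            h, batch.membership, cfg.pooling, params,
            n_graphs=batch.n_graphs, leaky_slope=cfg.leaky_slope,
        )
        outputs: dict[str, Tensor] = {}
        for head in HEAD_NAMES:
            hid = _linear(pooled, params, f"head.{head}.fc1").leaky_relu(cfg.leaky_slope)
            outputs[head] = _linear(hid, params, f"head.{head}.fc2").reshape(-1)
        outputs["logit"] = scale_logit(outputs["logit"], params["tau"], cfg.logit_clip)
        return outputs

    def predict(
        self, batch: BatchedGraph, embeddings: ResidueEmbeddingStack
    ) -> list[PredictionSet]:
        out = self.forward_tensors(batch, embeddings, training=False)
        logits = out["logit"].data
        probs = 1.0 / (1.0 + np.exp(-logits))
        return [
            PredictionSet(
                pKi=float(out["pKi"].data[g]),
                pKd=float(out["pKd"].data[g]),
                pIC50=float(out["pIC50"].data[g]),
                pEC50=float(out["pEC50"].data[g]),
                logit=float(logits[g]),
                probability=float(probs[g]),
            )
            for g in range(batch.n_graphs)
        ]

    def parameter_names(self) -> list[str]:
        return sorted(self.params)

    def copy_parameters(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_parameter_values(self, values: dict[str, np.ndarray]) -> None:
        for k, v in values.items():
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    # -- checkpointing ----------------------------------------------------------

    def save(self, path) -> None:
        config_json = json.dumps(asdict(self.config))
        arrays = {f"param:{k}": v.data for k, v in self.params.items()}
        np.savez(
            path,
            checkpoint_version=np.asarray(CHECKPOINT_VERSION),
            config_json=np.frombuffer(config_json.encode(), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "ScreeningModel":
        with np.load(path) as data:
            version = int(data["checkpoint_version"])
            if version != CHECKPOINT_VERSION:
                raise ValueError(
                    f"checkpoint version {version} not supported "
                    f"(expected {CHECKPOINT_VERSION})"
                )
            config = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
            params = {
                key[len("param:") :]: Tensor(data[key], requires_grad=True)
                for key in data.files
                if key.startswith("param:")
            }
        return cls(config, params)
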
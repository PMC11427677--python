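"""Dataset handling and training: affinity normalization, decoy sampling,
the masked Huber + binary-cross-entropy objective, the AdamW/cosine
schedule, record-level splitting, and the homology filter used for
zero-shot evaluation.

Affinities (Ki, Kd, IC50, EC50, in nM) are normalized to the
-log10(molar) scale with ``-log10(x / 1e9)``.  Records may carry any subset
of the four labels; absent labels contribute *exactly zero* loss and zero
gradient, as do all four regression terms for decoy records, and reported
losses average only the non-zeroized terms.  Decoys are sampled at training
time by drawing another ligand from the dataset and rejecting it if any
entry pairs it with the same protein sequence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .model import AFFINITY_HEADS, ModelConfig, ScreeningModel
from .molgraph import batch_graphs, smiles_to_graph
from .plm import EmbeddingCache

LABEL_COLUMNS = {"pKi": "ki_nM", "pKd": "kd_nM", "pIC50": "ic50_nM", "pEC50": "ec50_nM"}


# -- records ---------------------------------------------------------------------


@dataclass
class AffinityLabels:
    """Optional normalized affinities (presence encoded as non-None)."""

    pKi: float | None = None
    pKd: float | None = None
    pIC50: float | None = None
    pEC50: float | None = None

    def present(self) -> dict[str, float]:
        return {
            name: getattr(self, name)
            for name in AFFINITY_HEADS
            if getattr(self, name) is not None
        }

    def __post_init__(self):
        for name, value in self.present().items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite affinity label {name}={value}")


@dataclass
class InteractionRecord:
    """One protein–ligand pair; decoys carry no usable affinity labels."""

    protein_sequence: str
    smiles: str
    labels: AffinityLabels = field(default_factory=AffinityLabels)
    is_decoy: bool = False

    def __post_init__(self):
        if not self.protein_sequence:
            raise ValueError("empty protein sequence")
        if not self.smiles:
            raise ValueError("empty SMILES")
        if not self.is_decoy and not self.labels.present():
            raise ValueError("non-decoy record needs at least one affinity label")


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-3
    huber_delta: float = 2.0
    accumulation_steps: int = 256
    batch_size: int = 1
    total_iterations: int = 100
    decoy_fraction: float = 0.5
    max_train_seq_len: int = 2048
    split_fractions: tuple[float, float, float] = (0.90, 0.02, 0.08)
    val_every: int = 10
    val_max_records: int = 200
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not (0 <= self.decoy_fraction <= 1):
            raise ValueError("decoy_fraction must be in [0, 1]")


# -- affinity normalization ------------------------------------------------------


def normalize_affinity(value_nM: float) -> float:
    """nM → -log10(molar): ``-log10(x / 1e9)`` (1 nM → 9.0)."""
    if not (isinstance(value_nM, (int, float)) and math.isfinite(value_nM)):
        raise ValueError(f"affinity must be finite, got {value_nM!r}")
    if value_nM <= 0:
        raise ValueError(f"affinity must be positive, got {value_nM}")
    return -math.log10(value_nM / 1e9)


def denormalize_affinity(p_value: float) -> float:
    """Inverse of :func:`normalize_affinity` (9.0 → 1 nM)."""
    return 1e9 * 10.0 ** (-p_value)


# -- BindingDB-style TSV I/O -----------------------------------------------------


def _parse_affinity_cell(cell) -> float | None:
    """Exact values only: entries with '>'/'<' qualifiers are dropped."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if not text or text.lower() == "nan":
        return None
    if text[0] in "<>":
        return None
    try:
        value = float(text)
    except ValueError:
        return None
    return value if value > 0 and math.isfinite(value) else None


def read_interaction_table(path: str | Path) -> list[InteractionRecord]:
    """Read a BindingDB-style TSV: columns ``protein_sequence``, ``smiles``,
    ``ki_nM``, ``kd_nM``, ``ic50_nM``, ``ec50_nM`` (blank = missing).

    Rows in which all four affinities are missing are dropped.  Duplicate
    protein–ligand entries are kept as independent records.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_sequence", "smiles"}
    if not required.issubset(frame.columns):
        raise ValueError(f"interaction table must contain columns {sorted(required)}")
    records = []
    for _, row in frame.iterrows():
        values = {}
        for head, col in LABEL_COLUMNS.items():
            raw = _parse_affinity_cell(row.get(col))
            if raw is not None:
                values[head] = normalize_affinity(raw)
        if not values:
            continue
        records.append(
            InteractionRecord(
                protein_sequence=str(row["protein_sequence"]).strip(),
                smiles=str(row["smiles"]).strip(),
                labels=AffinityLabels(**values),
            )
        )
    return records


def write_interaction_table(path: str | Path, records: list[InteractionRecord]) -> None:
    rows = []
    for rec in records:
        row = {"protein_sequence": rec.protein_sequence, "smiles": rec.smiles}
        for head, col in LABEL_COLUMNS.items():
            value = getattr(rec.labels, head)
            row[col] = "" if value is None else f"{denormalize_affinity(value):.6g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- decoy sampling --------------------------------------------------------------


def build_binder_index(records: list[InteractionRecord]) -> dict[str, set[str]]:
    """Map protein sequence → set of SMILES with at least one dataset entry."""
    index: dict[str, set[str]] = {}
    for rec in records:
        index.setdefault(rec.protein_sequence, set()).add(rec.smiles)
    return index


def sample_decoy(
    record: InteractionRecord,
    binder_index: dict[str, set[str]],
    ligand_pool: list[str],
    rng: np.random.Generator,
    max_retries: int = 100,
) -> str:
    """Draw a ligand uniformly from the pool, rejecting any SMILES that some
    dataset entry pairs with the record's protein; bounded retries."""
    bound = binder_index.get(record.protein_sequence, set())
    for _ in range(max_retries):
        candidate = ligand_pool[int(rng.integers(len(ligand_pool)))]
        if candidate not in bound:
            return candidate
    raise RuntimeError(
        f"could not sample a decoy after {max_retries} retries "
        "(every drawn ligand binds the target protein)"
    )


# -- loss ------------------------------------------------------------------------


def _huber(residual: Tensor, delta: float) -> Tensor:
    absres = residual.abs()
    quad = 0.5 * residual * residual
    lin = delta * (absres - delta / 2.0)
    small = (absres.data <= delta).astype(np.float64)
    return quad * Tensor(small) + lin * Tensor(1.0 - small)


def compute_loss(
    outputs: dict[str, Tensor],
    record: InteractionRecord,
    delta: float = 2.0,
    graph_slot: int = 0,
) -> tuple[Tensor, dict[str, float]]:
    """Masked multi-objective loss for one record.

    Regression terms are Huber(δ) over the *present* labels — for decoys all
    four regression terms are omitted entirely (exactly zero loss and zero
    gradient, because the omitted heads never enter the loss graph).  The
    classification term is binary cross-entropy on the scaled, clipped
    logit, with target 1 for a true binder and 0 for a decoy.  The returned
    breakdown also reports ``mean`` — the average over non-zeroized terms
    only, the quantity tracked as the training/validation loss.
    """
    terms: list[Tensor] = []
    breakdown: dict[str, float] = {}
    if not record.is_decoy:
        for name, label in record.labels.present().items():
            residual = outputs[name][graph_slot] - label
            term = _huber(residual, delta)
            terms.append(term)
            breakdown[name] = term.item()
    logit = outputs["logit"][graph_slot]
    target = 0.0 if record.is_decoy else 1.0
    # BCE from the logit: softplus(l) - y*l is stable for either class
    bce = logit.softplus() - target * logit
    terms.append(bce)
    breakdown["bce"] = bce.item()

    total = terms[0]
    for t in terms[1:]:
        total = total + t
    breakdown["total"] = total.item()
    breakdown["mean"] = breakdown["total"] / len(terms)
    return total * (1.0 / len(terms)), breakdown


# -- splitting -------------------------------------------------------------------


def split_dataset(
    records: list[InteractionRecord],
    fractions: tuple[float, float, float] = (0.90, 0.02, 0.08),
    seed: int = 0,
):
    """Record-level random split into (train, val, test): disjoint,
    exhaustive, reproducible under the seed."""
    if not records:
        raise ValueError("cannot split an empty dataset")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(records)
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    train_idx = order[:n_train]
    val_idx = order[n_train : n_train + n_val]
    test_idx = order[n_train + n_val :]
    pick = lambda idx: [records[i] for i in idx]
    return pick(train_idx), pick(val_idx), pick(test_idx)


# -- homology filter -------------------------------------------------------------


def alignment_identity(query: str, reference: str) -> float:
    """Fraction of the *reference* length matched under an optimal global
    alignment with match=1, mismatch=0, gap=0.

    With that scoring the optimal score is the length of the longest common
    subsequence, so identity = LCS(query, reference) / len(reference).
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner.score(query, reference) / len(reference)


def homology_filter(
    train_records: list[InteractionRecord],
    reference_sequences: list[str],
    threshold: float = 0.90,
) -> list[InteractionRecord]:
    """Drop training records whose protein exceeds ``threshold`` identity
    against ANY reference sequence (identity computed on the reference
    length), enabling zero-shot evaluation on the reference proteins."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if not reference_sequences:
        import warnings

        warnings.warn("empty reference set: homology filter is a no-op")
        return list(train_records)
    # identity depends only on the sequence: compute once per unique protein
    verdict: dict[str, bool] = {}
    for seq in {r.protein_sequence for r in train_records}:
        verdict[seq] = any(
            alignment_identity(seq, ref) > threshold for ref in reference_sequences
        )
    return [r for r in train_records if not verdict[r.protein_sequence]]


# -- optimization ----------------------------------------------------------------


class AdamW:
    """AdamW with decoupled weight decay over a named parameter dict."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-4,
        weight_decay: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self._m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self._v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self._t += 1
        for name, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self._m[name] = b1 * self._m[name] + (1 - b1) * g
            self._v[name] = b2 * self._v[name] + (1 - b2) * g * g
            m_hat = self._m[name] / (1 - b1**self._t)
            v_hat = self._v[name] / (1 - b2**self._t)
            p.data = p.data - lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data
            )


def cosine_lr(base_lr: float, iteration: int, total_iterations: int) -> float:
    """Cosine decay from ``base_lr`` to 0 with no warm-up."""
    frac = min(max(iteration / total_iterations, 0.0), 1.0)
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * frac))


# -- the training loop -----------------------------------------------------------


@dataclass
class TrainResult:
    model: ScreeningModel
    history: list[dict]
    best_val_loss: float
    decoy_count: int
    step_count: int


def _record_loss(model, cache, embedder, record, graph_cache, delta):
    graph = graph_cache.get(record.smiles)
    if graph is None:
        graph = batch_graphs([smiles_to_graph(record.smiles)])
        graph_cache[record.smiles] = graph
    stack = cache.get_or_compute(
        record.protein_sequence, model.config.encoder_layer_indices, embedder
    )
    outputs = model.forward_tensors(graph, stack, training=False)
    return compute_loss(outputs, record, delta=delta)


def evaluate_loss(
    model: ScreeningModel,
    records: list[InteractionRecord],
    embedder,
    cache: EmbeddingCache | None = None,
    delta: float = 2.0,
) -> float:
    """Mean over records of the per-record mean over non-zeroized terms."""
    cache = cache or EmbeddingCache()
    graph_cache: dict = {}
    means = []
    for rec in records:
        _, breakdown = _record_loss(model, cache, embedder, rec, graph_cache, delta)
        means.append(breakdown["mean"])
    return float(np.mean(means))


def fit(
    train_records: list[InteractionRecord],
    val_records: list[InteractionRecord],
    model_config: ModelConfig,
    train_config: TrainConfig,
    embedder,
    log_path: str | Path | None = None,
) -> TrainResult:
    """Train the screening network.

    Per micro-step a record is drawn (shuffled passes over the training
    set); with probability ``decoy_fraction`` its ligand is replaced by a
    sampled decoy and the record marked as such.  Gradients accumulate over
    ``accumulation_steps`` micro-batches of ``batch_size`` records before
    one AdamW update under the cosine-decayed learning rate.  Sequences
    longer than ``max_train_seq_len`` are excluded from training only.
    Returns the parameters with the best validation loss.
    """
    tc = train_config
    rng = np.random.default_rng(tc.seed)
    usable = [r for r in train_records if len(r.protein_sequence) <= tc.max_train_seq_len]
    if not usable:
        raise ValueError("no training records after the sequence-length cutoff")

    binder_index = build_binder_index(train_records)
    ligand_pool = sorted({r.smiles for r in train_records})
    model = ScreeningModel(model_config)
    optimizer = AdamW(model.params, lr=tc.lr, weight_decay=tc.weight_decay)
    cache = EmbeddingCache()
    graph_cache: dict = {}
    val_subset = val_records[: tc.val_max_records]

    history: list[dict] = []
    best_val = math.inf
    best_params = model.copy_parameters()
    decoy_count = 0
    micro_count = 0
    order = rng.permutation(len(usable))
    cursor = 0
    log_fh = open(log_path, "w") if log_path is not None else None

    try:
        for iteration in range(tc.total_iterations):
            lr = cosine_lr(tc.lr, iteration, tc.total_iterations)
            optimizer.zero_grad()
            running = []
            for _ in range(tc.accumulation_steps * tc.batch_size):
                if cursor >= len(order):
                    order = rng.permutation(len(usable))
                    cursor = 0
                record = usable[order[cursor]]
                cursor += 1
                if rng.random() < tc.decoy_fraction:
                    decoy_smiles = sample_decoy(record, binder_index, ligand_pool, rng)
                    record = InteractionRecord(
                        protein_sequence=record.protein_sequence,
                        smiles=decoy_smiles,
                        labels=AffinityLabels(),
                        is_decoy=True,
                    )
                    decoy_count += 1
                micro_count += 1
                graph = graph_cache.get(record.smiles)
                if graph is None:
                    graph = batch_graphs([smiles_to_graph(record.smiles)])
                    graph_cache[record.smiles] = graph
                stack = cache.get_or_compute(
                    record.protein_sequence, model_config.encoder_layer_indices, embedder
                )
                outputs = model.forward_tensors(graph, stack, training=True)
                loss, breakdown = compute_loss(outputs, record, delta=tc.huber_delta)
                (loss * (1.0 / (tc.accumulation_steps * tc.batch_size))).backward()
                running.append(breakdown["mean"])
            optimizer.step(lr=lr)

            entry = {
                "iteration": iteration,
                "lr": lr,
                "train_loss": float(np.mean(running)),
            }
            if val_subset and (
                (iteration + 1) % tc.val_every == 0
                or iteration == tc.total_iterations - 1
            ):
                val_loss = evaluate_loss(
                    model, val_subset, embedder, cache, delta=tc.huber_delta
                )
                entry["val_loss"] = val_loss
                if val_loss < best_val:
                    best_val = val_loss
                    best_params = model.copy_parameters()
            history.append(entry)
            if log_fh is not None:
                log_fh.write(json.dumps(entry) + "\n")
                log_fh.flush()
    finally:
        if log_fh is not None:
            log_fh.close()

    if math.isinf(best_val):  # no validation set: keep final parameters
        best_val = history[-1]["train_loss"] if history else math.inf
        best_params = model.copy_parameters()
    model.load_parameter_values(best_params)
    return TrainResult(
        model=model,
        history=history,
        best_val_loss=best_val,
        decoy_count=decoy_count,
        step_count=micro_count,
    )
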
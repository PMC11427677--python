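"""Forward and reverse screening drivers plus early-recognition metrics.

A screen produces a :class:`RankedScreen`: items (ligands in forward
screening, proteins in reverse screening) sorted by score, higher is
better, with stable input-order tie-breaking.  From a labeled ranking the
module derives:

* **enrichment factor** ``EF(f)`` — concentration of actives in the top
  ``ceil(f·N)`` entries divided by their concentration in the whole set;
* **success rate** — the concentration of actives in that top subset;
* **BEDROC** (Truchon–Bayly) at steepness ``alpha`` (default 80.5) — an
  exponentially early-weighted recognition score, min-max normalized so the
  best possible ranking scores 1 and the worst 0;
* **AUROC** — the probability that a random active outscores a random
  inactive, ties counted one half.

Per-target metrics are aggregated across a benchmark as unweighted means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .model import AFFINITY_HEADS, PredictionSet, ScreeningModel
from .molgraph import batch_graphs, smiles_to_graph, SmilesParseError
from .plm import EmbeddingCache

SCORE_NAMES = ("logit",) + AFFINITY_HEADS

DEFAULT_EF_FRACTIONS = (0.005, 0.01, 0.05)
DEFAULT_BEDROC_ALPHA = 80.5


@dataclass(frozen=True)
class ScreenEntry:
    item_id: str
    score: float
    is_active: bool | None = None


@dataclass(frozen=True)
class RankedScreen:
    """A scored, ordered item list (higher score is better).

    Ties keep the input order of the scored items (stable sort), which
    matters for enrichment at small cutoffs and is therefore fixed policy.
    """

    entries: tuple[ScreenEntry, ...]
    skipped: tuple[str, ...] = ()

    @classmethod
    def from_scores(
        cls,
        item_ids,
        scores,
        labels=None,
        skipped=(),
    ) -> "RankedScreen":
        scores = [float(s) for s in scores]
        if any(not math.isfinite(s) for s in scores):
            raise ValueError("scores must be finite")
        if labels is None:
            labels = [None] * len(scores)
        rows = list(zip(item_ids, scores, labels))
        rows.sort(key=lambda r: -r[1])  # stable: ties keep input order
        return cls(
            entries=tuple(ScreenEntry(i, s, None if a is None else bool(a)) for i, s, a in rows),
            skipped=tuple(skipped),
        )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def scores(self) -> np.ndarray:
        return np.asarray([e.score for e in self.entries])

    @property
    def labels(self) -> np.ndarray:
        if any(e.is_active is None for e in self.entries):
            raise ValueError("screen has unlabeled entries")
        return np.asarray([e.is_active for e in self.entries], dtype=bool)

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())

    def rank_of(self, item_id: str) -> int:
        """1-based rank of an item."""
        for pos, entry in enumerate(self.entries, start=1):
            if entry.item_id == item_id:
                return pos
        raise KeyError(item_id)


@dataclass
class ScreenMetrics:
    ef: dict[float, float] = field(default_factory=dict)
    success_rate: dict[float, float] = field(default_factory=dict)
    bedroc: dict[float, float] = field(default_factory=dict)
    auroc: float = float("nan")


def _check_labels(screen: RankedScreen) -> np.ndarray:
    labels = screen.labels
    if labels.all() or not labels.any():
        raise ValueError("metrics need at least one active and one inactive")
    return labels


def _subset_size(n: int, fraction: float) -> int:
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return math.ceil(fraction * n)


def enrichment_factor(screen: RankedScreen, fraction: float) -> float:
    """EF at a top fraction: (actives_subset/size_subset) / (actives/N).

    The subset is the top ``ceil(fraction·N)`` entries, so it is never
    empty.  Degenerate all-active screens return 1 by the formula's limit;
    screens with no actives raise.
    """
    labels = screen.labels
    n = len(screen)
    size = _subset_size(n, fraction)
    total_actives = int(labels.sum())
    if total_actives == 0:
        raise ValueError("no actives in screen")
    subset_actives = int(labels[:size].sum())
    return (subset_actives / size) / (total_actives / n)


def success_rate(screen: RankedScreen, fraction: float) -> float:
    """Concentration of actives in the top ``ceil(fraction·N)`` entries."""
    labels = screen.labels
    size = _subset_size(len(screen), fraction)
    if int(labels.sum()) == 0:
        raise ValueError("no actives in screen")
    return float(labels[:size].sum()) / size


def bedroc(screen: RankedScreen, alpha: float = DEFAULT_BEDROC_ALPHA) -> float:
    """Truchon–Bayly BEDROC from active ranks.

    With actives at 1-based ranks r_i among N entries, the raw score is
    S = Σ_i exp(-alpha·r_i/N).  The best possible ranking puts the n
    actives at ranks 1..n and the worst at ranks N-n+1..N; those extremes
    are geometric sums evaluated in closed form, and BEDROC is the min-max
    normalization (S - S_worst)/(S_best - S_worst) ∈ [0, 1].
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    labels = _check_labels(screen)
    n_total = len(screen)
    ranks = np.flatnonzero(labels) + 1  # 1-based
    n_act = len(ranks)
    x = math.exp(-alpha / n_total)

    def geometric(first_rank: int, count: int) -> float:
        # sum_{r=first..first+count-1} x^r  =  x^first (1 - x^count)/(1 - x)
        return x**first_rank * (1.0 - x**count) / (1.0 - x)

    s = float(np.exp(-alpha * ranks / n_total).sum())
    s_best = geometric(1, n_act)
    s_worst = geometric(n_total - n_act + 1, n_act)
    return (s - s_worst) / (s_best - s_worst)


def auroc(screen: RankedScreen) -> float:
    """Mann–Whitney probability that a random active outscores a random
    inactive (ties counted 1/2)."""
    labels = _check_labels(screen)
    return float(roc_auc_score(labels, screen.scores))


def compute_metrics(
    screen: RankedScreen,
    ef_fractions=DEFAULT_EF_FRACTIONS,
    bedroc_alphas=(DEFAULT_BEDROC_ALPHA,),
) -> ScreenMetrics:
    return ScreenMetrics(
        ef={f: enrichment_factor(screen, f) for f in ef_fractions},
        success_rate={f: success_rate(screen, f) for f in ef_fractions},
        bedroc={a: bedroc(screen, a) for a in bedroc_alphas},
        auroc=auroc(screen),
    )


def aggregate_benchmark(per_target_metrics: list[ScreenMetrics]) -> ScreenMetrics:
    """Unweighted arithmetic mean of each metric across targets."""
    if not per_target_metrics:
        raise ValueError("no per-target metrics to aggregate")
    first = per_target_metrics[0]
    for m in per_target_metrics[1:]:
        if (
            set(m.ef) != set(first.ef)
            or set(m.success_rate) != set(first.success_rate)
            or set(m.bedroc) != set(first.bedroc)
        ):
            raise ValueError("inconsistent metric keys across targets")
    return ScreenMetrics(
        ef={f: float(np.mean([m.ef[f] for m in per_target_metrics])) for f in first.ef},
        success_rate={
            f: float(np.mean([m.success_rate[f] for m in per_target_metrics]))
            for f in first.success_rate
        },
        bedroc={
            a: float(np.mean([m.bedroc[a] for m in per_target_metrics]))
            for a in first.bedroc
        },
        auroc=float(np.mean([m.auroc for m in per_target_metrics])),
    )


# -- screening drivers -----------------------------------------------------------


def predict_pairs(
    model: ScreeningModel,
    protein_sequence: str,
    smiles_list: list[str],
    embedder,
    cache: EmbeddingCache | None = None,
    chunk_size: int = 64,
) -> tuple[list[PredictionSet], list[int], list[str]]:
    """Score a ligand list against one protein.

    Returns (predictions, kept indices, skipped SMILES); the protein is
    embedded once (cache hit on repeat calls).
    """
    cache = cache or EmbeddingCache()
    stack = cache.get_or_compute(
        protein_sequence, model.config.encoder_layer_indices, embedder
    )
    graphs, kept, skipped = [], [], []
    for i, smi in enumerate(smiles_list):
        try:
            graphs.append(smiles_to_graph(smi))
            kept.append(i)
        except SmilesParseError:
            skipped.append(smi)
    predictions: list[PredictionSet] = []
    for start in range(0, len(graphs), chunk_size):
        batch = batch_graphs(graphs[start : start + chunk_size])
        predictions.extend(model.predict(batch, stack))
    return predictions, kept, skipped


def forward_screen(
    model: ScreeningModel,
    protein_sequence: str,
    ligand_smiles: list[str],
    embedder,
    score: str = "logit",
    labels=None,
    cache: EmbeddingCache | None = None,
    ligand_ids: list[str] | None = None,
) -> RankedScreen:
    """Rank a ligand library against one protein by the chosen score
    (classifier ``logit`` by default, or one of the affinity heads).

    Unparseable SMILES are excluded from the ranking and reported in
    ``RankedScreen.skipped``.
    """
    if not ligand_smiles:
        raise ValueError("empty ligand list")
    if score not in SCORE_NAMES:
        raise ValueError(f"score must be one of {SCORE_NAMES}")
    predictions, kept, skipped = predict_pairs(
        model, protein_sequence, ligand_smiles, embedder, cache
    )
    ids = ligand_ids or ligand_smiles
    return RankedScreen.from_scores(
        item_ids=[ids[i] for i in kept],
        scores=[p.score(score) for p in predictions],
        labels=None if labels is None else [labels[i] for i in kept],
        skipped=skipped,
    )


def reverse_screen(
    model: ScreeningModel,
    protein_sequences: list[str],
    ligand_smiles: str,
    embedder,
    score: str = "logit",
    labels=None,
    cache: EmbeddingCache | None = None,
    protein_ids: list[str] | None = None,
) -> RankedScreen:
    """Rank proteins by one ligand's score against each (proteome-wide
    target identification); embeddings are cached per protein."""
    if not protein_sequences:
        raise ValueError("empty protein list")
    if score not in SCORE_NAMES:
        raise ValueError(f"score must be one of {SCORE_NAMES}")
    cache = cache or EmbeddingCache()
    graph = batch_graphs([smiles_to_graph(ligand_smiles)])
    ids = protein_ids or [f"protein_{i}" for i in range(len(protein_sequences))]
    scores = []
    for seq in protein_sequences:
        stack = cache.get_or_compute(seq, model.config.encoder_layer_indices, embedder)
        scores.append(model.predict(graph, stack)[0].score(score))
    return RankedScreen.from_scores(ids, scores, labels=labels)


# -- reverse-screening rank summaries --------------------------------------------


def cumulative_correct_pairs(rankings: dict[str, int], ks: list[int]) -> dict[int, int]:
    """For each cutoff k, the number of ligands whose true protein ranks
    ≤ k; non-decreasing in k."""
    for ligand, rank in rankings.items():
        if rank < 1:
            raise ValueError(f"rank for {ligand!r} must be >= 1")
    return {k: sum(1 for r in rankings.values() if r <= k) for k in ks}


def topk_hit_rate(rankings: dict[str, int], k: int) -> float:
    """Fraction of ligands whose true-target rank is ≤ k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not rankings:
        raise ValueError("no rankings given")
    return sum(1 for r in rankings.values() if r <= k) / len(rankings)


# -- CSV outputs -----------------------------------------------------------------


def write_score_table(
    path: str | Path,
    ligand_ids: list[str],
    smiles_list: list[str],
    predictions: list[PredictionSet],
) -> None:
    rows = [
        {
            "id": lid,
            "smiles": smi,
            "logit": p.logit,
            "probability": p.probability,
            **{name: p.score(name) for name in AFFINITY_HEADS},
        }
        for lid, smi, p in zip(ligand_ids, smiles_list, predictions)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def metrics_to_frame(metrics: ScreenMetrics, target: str = "") -> pd.DataFrame:
    row = {"target": target}
    for f, v in sorted(metrics.ef.items()):
        row[f"EF_{f:g}"] = v
    for f, v in sorted(metrics.success_rate.items()):
        row[f"success_rate_{f:g}"] = v
    for a, v in sorted(metrics.bedroc.items()):
        row[f"BEDROC_{a:g}"] = v
    row["AUROC"] = metrics.auroc
    return pd.DataFrame([row])


def read_labeled_scores(path: str | Path, score_column: str = "score",
                        label_column: str = "is_active") -> RankedScreen:
    """Build a labeled screen from a CSV with id, score and active columns."""
    frame = pd.read_csv(path)
    for col in (score_column, label_column):
        if col not in frame.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    ids = frame["id"] if "id" in frame.columns else frame.index.astype(str)
    return RankedScreen.from_scores(
        ids.tolist(),
        frame[score_column].astype(float).tolist(),
        labels=frame[label_column].astype(int).astype(bool).tolist(),
    )
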
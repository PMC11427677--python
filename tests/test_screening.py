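import itertools
import math

import numpy as np
import pytest

from seqscreen.model import ScreeningModel, desk_config
from seqscreen.plm import EmbeddingCache, ToyEmbedder
from seqscreen.screening import (
    RankedScreen,
    aggregate_benchmark,
    auroc,
    bedroc,
    compute_metrics,
    cumulative_correct_pairs,
    enrichment_factor,
    forward_screen,
    metrics_to_frame,
    read_labeled_scores,
    reverse_screen,
    success_rate,
    topk_hit_rate,
    write_score_table,
)


def make_screen(labels, scores=None):
    labels = list(labels)
    if scores is None:  # already in rank order: descending dummy scores
        scores = list(range(len(labels), 0, -1))
    return RankedScreen.from_scores(
        [f"m{i}" for i in range(len(labels))], scores, labels=labels
    )


def bedroc_oracle(labels, alpha):
    """Direct summation of the exponentially weighted recognition score,
    min-max normalized over the best and worst possible rankings."""
    n_total = len(labels)
    ranks = [i + 1 for i, is_active in enumerate(labels) if is_active]
    n_act = len(ranks)
    s = sum(math.exp(-alpha * r / n_total) for r in ranks)
    s_best = sum(math.exp(-alpha * r / n_total) for r in range(1, n_act + 1))
    s_worst = sum(
        math.exp(-alpha * r / n_total)
        for r in range(n_total - n_act + 1, n_total + 1)
    )
    return (s - s_worst) / (s_best - s_worst)


class TestEnrichmentFactor:
    def test_perfect_ranking(self):
        screen = make_screen([True] * 10 + [False] * 90)
        assert enrichment_factor(screen, 0.10) == pytest.approx(10.0)

    def test_all_active_gives_one(self):
        screen = make_screen([True] * 20)
        assert enrichment_factor(screen, 0.25) == pytest.approx(1.0)

    def test_partial_subset(self):
        # N=200, 20 actives, top-5% (10 entries) holding 4 actives
        labels = [True] * 4 + [False] * 6 + [True] * 16 + [False] * 174
        assert enrichment_factor(make_screen(labels), 0.05) == pytest.approx(4.0)

    def test_subset_size_uses_ceil(self):
        screen = make_screen([True] + [False] * 9)
        # ceil(0.005 * 10) = 1: the single top entry
        assert enrichment_factor(screen, 0.005) == pytest.approx(10.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            enrichment_factor(make_screen([False] * 5), 0.2)
        with pytest.raises(ValueError):
            enrichment_factor(make_screen([True, False]), 0.0)
        with pytest.raises(ValueError):
            enrichment_factor(make_screen([True, False]), 1.5)


class TestSuccessRate:
    def test_perfect_ranking_saturates(self):
        screen = make_screen([True] * 10 + [False] * 90)
        assert success_rate(screen, 0.05) == 1.0

    def test_partial_and_empty_subsets(self):
        labels = [True] * 4 + [False] * 6 + [True] * 16 + [False] * 174
        assert success_rate(make_screen(labels), 0.05) == pytest.approx(0.4)
        inverted = make_screen([False] * 90 + [True] * 10)
        assert success_rate(inverted, 0.05) == 0.0


class TestBedroc:
    def test_extremes(self):
        best = make_screen([True] * 3 + [False] * 17)
        worst = make_screen([False] * 17 + [True] * 3)
        assert bedroc(best) == pytest.approx(1.0)
        assert bedroc(worst) == pytest.approx(0.0, abs=1e-12)

    def test_specific_configuration_against_oracle(self):
        labels = [False] * 20
        for rank in (1, 5, 12):
            labels[rank - 1] = True
        assert bedroc(make_screen(labels), 80.5) == pytest.approx(
            bedroc_oracle(labels, 80.5), abs=1e-10
        )

    def test_random_configurations_against_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 120))
            n_act = int(rng.integers(1, n))
            labels = np.zeros(n, dtype=bool)
            labels[rng.choice(n, size=n_act, replace=False)] = True
            alpha = float(rng.uniform(1.0, 120.0))
            assert bedroc(make_screen(labels), alpha) == pytest.approx(
                bedroc_oracle(labels.tolist(), alpha), abs=1e-10
            )

    def test_moving_an_active_up_never_decreases_bedroc(self):
        # exhaustive over all labelings for N <= 12
        for n in range(3, 13):
            for actives in itertools.combinations(range(n), 2):
                labels = [i in actives for i in range(n)]
                base = bedroc(make_screen(labels), 80.5)
                for pos in actives:
                    if pos > 0 and not labels[pos - 1]:
                        moved = labels.copy()
                        moved[pos], moved[pos - 1] = moved[pos - 1], moved[pos]
                        assert bedroc(make_screen(moved), 80.5) >= base

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bedroc(make_screen([True, True]))
        with pytest.raises(ValueError):
            bedroc(make_screen([True, False]), alpha=0.0)


class TestAuroc:
    def test_extremes_and_example(self):
        assert auroc(make_screen([True, True, False, False])) == 1.0
        assert auroc(make_screen([False, False, True, True])) == 0.0
        screen = RankedScreen.from_scores(
            ["a", "b", "c", "d"],
            [0.9, 0.8, 0.7, 0.6],
            labels=[True, False, True, False],
        )
        assert auroc(screen) == pytest.approx(0.75)

    def test_matches_pair_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 51))
            labels = np.zeros(n, dtype=bool)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
            scores = rng.choice(np.linspace(0, 1, 10), size=n)  # ties likely
            screen = RankedScreen.from_scores(
                [str(i) for i in range(n)], scores, labels=labels
            )
            conc = 0.0
            pairs = 0
            for i, j in itertools.product(range(n), range(n)):
                if labels[i] and not labels[j]:
                    pairs += 1
                    if scores[i] > scores[j]:
                        conc += 1.0
                    elif scores[i] == scores[j]:
                        conc += 0.5
            assert auroc(screen) == pytest.approx(conc / pairs)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auroc(make_screen([True, True]))


class TestRankedScreen:
    def test_sorted_descending_with_stable_ties(self):
        screen = RankedScreen.from_scores(
            ["a", "b", "c", "d"], [0.5, 0.9, 0.5, 0.1], labels=[0, 1, 0, 1]
        )
        assert [e.item_id for e in screen.entries] == ["b", "a", "c", "d"]

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError):
            RankedScreen.from_scores(["a"], [float("nan")])

    def test_ef_success_rate_consistency(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 200))
            labels = rng.random(n) < 0.2
            if labels.all() or not labels.any():
                continue
            screen = RankedScreen.from_scores(
                [str(i) for i in range(n)], rng.normal(size=n), labels=labels
            )
            for fraction in (0.01, 0.1, 0.5, 1.0):
                expected = success_rate(screen, fraction) / (labels.sum() / n)
                assert enrichment_factor(screen, fraction) == pytest.approx(expected)


class TestRankSummaries:
    def test_cumulative_correct_pairs(self):
        ranks = {"a": 1, "b": 3, "c": 10}
        assert cumulative_correct_pairs(ranks, [1, 5]) == {1: 1, 5: 2}
        assert cumulative_correct_pairs(ranks, [10])[10] == 3
        assert cumulative_correct_pairs({}, [1, 2]) == {1: 0, 2: 0}
        with pytest.raises(ValueError):
            cumulative_correct_pairs({"a": 0}, [1])

    def test_cumulative_counts_non_decreasing(self, rng):
        ranks = {f"l{i}": int(r) for i, r in enumerate(rng.integers(1, 50, size=30))}
        ks = list(range(1, 60))
        counts = cumulative_correct_pairs(ranks, ks)
        values = [counts[k] for k in ks]
        assert values == sorted(values)
        assert values[-1] == 30

    def test_topk_hit_rate(self):
        assert topk_hit_rate({"a": 1, "b": 2}, 1) == 0.5
        assert topk_hit_rate({"a": 1, "b": 2, "c": 5}, 5) == 1.0
        assert topk_hit_rate({"a": 3}, 1) == 0.0
        with pytest.raises(ValueError):
            topk_hit_rate({}, 1)
        with pytest.raises(ValueError):
            topk_hit_rate({"a": 1}, 0)


class TestAggregation:
    def test_single_target_is_identity(self):
        screen = make_screen([True, False, False, True, False])
        metrics = compute_metrics(screen)
        agg = aggregate_benchmark([metrics])
        assert agg.auroc == metrics.auroc
        assert agg.ef == metrics.ef

    def test_mean_and_order_invariance(self):
        a = make_screen([True] * 5 + [False] * 45)
        b = make_screen([False] * 45 + [True] * 5)
        ma, mb = compute_metrics(a), compute_metrics(b)
        agg = aggregate_benchmark([ma, mb])
        agg_rev = aggregate_benchmark([mb, ma])
        assert agg.ef[0.05] == pytest.approx((ma.ef[0.05] + mb.ef[0.05]) / 2)
        assert agg.auroc == pytest.approx(agg_rev.auroc)

    def test_inconsistent_keys_rejected(self):
        a = compute_metrics(make_screen([True, False] * 5), ef_fractions=(0.1,))
        b = compute_metrics(make_screen([True, False] * 5), ef_fractions=(0.2,))
        with pytest.raises(ValueError):
            aggregate_benchmark([a, b])


@pytest.fixture(scope="module")
def untrained_setup():
    embedder = ToyEmbedder()
    model = ScreeningModel(desk_config(seed=0))
    protein = "ACDEFGHIKLMNPQRSTVWYMKVLA"
    return model, protein, embedder


class TestScreenDrivers:
    def test_single_ligand_screen(self, untrained_setup):
        model, protein, embedder = untrained_setup
        screen = forward_screen(model, protein, ["CCO"], embedder)
        assert len(screen) == 1

    def test_screen_is_deterministic(self, untrained_setup):
        model, protein, embedder = untrained_setup
        ligands = ["CCO", "CCN", "CCS", "c1ccccc1", "CC(=O)O"]
        a = forward_screen(model, protein, ligands, embedder)
        b = forward_screen(model, protein, ligands, embedder)
        assert [e.item_id for e in a.entries] == [e.item_id for e in b.entries]
        assert a.scores.tolist() == b.scores.tolist()

    def test_bad_smiles_are_skipped_not_fatal(self, untrained_setup):
        model, protein, embedder = untrained_setup
        screen = forward_screen(
            model, protein, ["CCO", "xxxx", "CCN"], embedder
        )
        assert len(screen) == 2
        assert screen.skipped == ("xxxx",)

    def test_one_embedding_per_protein(self, untrained_setup):
        model, protein, embedder = untrained_setup
        cache = EmbeddingCache()
        forward_screen(model, protein, ["CCO"] * 30, embedder, cache=cache)
        forward_screen(model, protein, ["CCN"] * 30, embedder, cache=cache)
        assert cache.backend_calls == 1

    def test_empty_ligand_list_rejected(self, untrained_setup):
        model, protein, embedder = untrained_setup
        with pytest.raises(ValueError):
            forward_screen(model, protein, [], embedder)
        with pytest.raises(ValueError):
            forward_screen(model, protein, ["CCO"], embedder, score="pKx")

    def test_reverse_screen_order_invariant(self, untrained_setup):
        model, _, embedder = untrained_setup
        proteins = ["ACDEFGHIKL", "MKVLAYWQRH", "GGGGGGGGGG", "WYWYWYWYWY"]
        ids = ["p0", "p1", "p2", "p3"]
        a = reverse_screen(model, proteins, "CCO", embedder, protein_ids=ids)
        b = reverse_screen(
            model, proteins[::-1], "CCO", embedder, protein_ids=ids[::-1]
        )
        assert {e.item_id: e.score for e in a.entries} == {
            e.item_id: e.score for e in b.entries
        }
        assert a.rank_of("p2") == b.rank_of("p2")

    def test_reverse_screen_single_protein(self, untrained_setup):
        model, _, embedder = untrained_setup
        screen = reverse_screen(model, ["ACDEFGHIKL"], "CCO", embedder)
        assert screen.rank_of("protein_0") == 1


class TestTables:
    def test_score_table_and_labeled_read(self, tmp_path, untrained_setup):
        model, protein, embedder = untrained_setup
        from seqscreen.screening import predict_pairs

        ligands = ["CCO", "CCN", "CCS", "CC(=O)O"]
        preds, kept, _ = predict_pairs(model, protein, ligands, embedder)
        path = tmp_path / "scores.csv"
        write_score_table(path, [f"l{i}" for i in kept], ligands, preds)
        import pandas as pd

        frame = pd.read_csv(path)
        assert set(["id", "smiles", "logit", "probability", "pKi"]) <= set(frame.columns)

        labeled = tmp_path / "labeled.csv"
        frame["score"] = frame["logit"]
        frame["is_active"] = [1, 0, 0, 1]
        frame.to_csv(labeled, index=False)
        screen = read_labeled_scores(labeled)
        assert len(screen) == 4
        with pytest.raises(ValueError):
            read_labeled_scores(path)  # no score/label columns

    def test_metrics_frame_columns(self):
        metrics = compute_metrics(make_screen([True] * 3 + [False] * 37))
        frame = metrics_to_frame(metrics, target="t")
        assert "EF_0.05" in frame.columns and "AUROC" in frame.columns
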
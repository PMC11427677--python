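import numpy as np
import pytest

from seqscreen.autodiff import Tensor
from seqscreen.model import (
    ModelConfig,
    ScreeningModel,
    cross_attention_graph_block,
    desk_config,
    graph_conv,
    init_parameters,
    pool_nodes,
    scale_logit,
)
from seqscreen.molgraph import BatchedGraph, MolecularGraph, batch_graphs, smiles_to_graph
from seqscreen.plm import ResidueEmbeddingStack, ToyEmbedder


def identity_attention_params(d):
    eye = np.eye(d)
    return {
        name + suffix: Tensor(eye.copy() if suffix == ".w" else np.zeros(d))
        for name in ("q", "k", "v", "o")
        for suffix in (".w", ".b")
    }


def attention_oracle(nodes, latents, mask, n_heads):
    """Independent per-node loop: dense softmax attention, one node at a
    time, one head at a time."""
    n, d = nodes.shape
    d_head = d // n_heads
    out = np.zeros_like(nodes)
    for i in range(n):
        for h in range(n_heads):
            sl = slice(h * d_head, (h + 1) * d_head)
            q = nodes[i, sl]
            scores = np.full(latents.shape[0], -np.inf)
            for r in range(latents.shape[0]):
                if mask[r]:
                    scores[r] = q @ latents[r, sl] / np.sqrt(d_head)
            w = np.exp(scores - scores[mask].max())
            w[~mask] = 0.0
            w = w / w.sum()
            out[i, sl] = sum(w[r] * latents[r, sl] for r in range(latents.shape[0]))
    return out


class TestCrossAttention:
    def test_single_key_attention_returns_its_value(self):
        d = 4
        params = identity_attention_params(d)
        node = Tensor(np.array([[1.0, 2.0, 3.0, 4.0]]))
        residue = np.array([[5.0, 6.0, 7.0, 8.0]])
        out = cross_attention_graph_block(
            node,
            Tensor(residue),
            np.array([True]),
            params,
            n_heads=1,
            use_adapter=False,
            use_residual_norm=False,
        )
        # softmax over one key is 1 => output equals the (identity) value
        np.testing.assert_allclose(out.data, residue)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(5)
        d = 8
        nodes = rng.normal(size=(7, d))
        latents = rng.normal(size=(15, d))
        params = identity_attention_params(d)
        out = cross_attention_graph_block(
            Tensor(nodes),
            Tensor(latents),
            np.ones(15, dtype=bool),
            params,
            n_heads=2,
            use_adapter=False,
            use_residual_norm=False,
        )
        expected = attention_oracle(nodes, latents, np.ones(15, dtype=bool), 2)
        np.testing.assert_allclose(out.data, expected, rtol=1e-5)

    def test_masked_residues_get_exactly_zero_weight(self):
        rng = np.random.default_rng(6)
        d = 8
        params = identity_attention_params(d)
        mask = np.ones(10, dtype=bool)
        mask[[3, 4]] = False
        _, weights = cross_attention_graph_block(
            Tensor(rng.normal(size=(5, d))),
            Tensor(rng.normal(size=(10, d))),
            mask,
            params,
            n_heads=2,
            use_adapter=False,
            use_residual_norm=False,
            return_weights=True,
        )
        for w in weights:
            assert (w[:, 3] == 0.0).all() and (w[:, 4] == 0.0).all()
            np.testing.assert_allclose(w.sum(axis=1), 1.0)

    def test_all_masked_is_an_error(self):
        params = identity_attention_params(4)
        with pytest.raises(ValueError, match="masked"):
            cross_attention_graph_block(
                Tensor(np.ones((2, 4))),
                Tensor(np.ones((3, 4))),
                np.zeros(3, dtype=bool),
                params,
                use_adapter=False,
            )

    def test_width_mismatch_is_an_error(self):
        params = identity_attention_params(4)
        with pytest.raises(ValueError, match="width"):
            cross_attention_graph_block(
                Tensor(np.ones((2, 4))),
                Tensor(np.ones((3, 6))),  # latent width != node width
                np.ones(3, dtype=bool),
                params,
                use_adapter=False,
            )


def conv_params(config, seed=0):
    params = init_parameters(desk_config(d_hidden=config, seed=seed))
    return {k.removeprefix("block0.conv."): v for k, v in params.items()
            if k.startswith("block0.conv.")}


class TestGraphConv:
    def test_isolated_node_reduces_to_self_message(self):
        d = 8
        params = conv_params(d)
        h = Tensor(np.random.default_rng(0).normal(size=(1, d)))
        out = graph_conv(h, np.zeros((0, 2), dtype=np.intp), np.zeros((0, 4)), params)
        expected = (h @ params["src.w"] + params["src.b"]).data  # alpha == 1
        np.testing.assert_allclose(out.data, expected)

    def test_components_are_independent(self):
        d = 8
        params = conv_params(d)
        rng = np.random.default_rng(1)
        h = rng.normal(size=(4, d))
        edges = np.array([[0, 1], [1, 0], [2, 3], [3, 2]])
        feats = np.tile([1.0, 0, 0, 0], (4, 1))
        base = graph_conv(Tensor(h), edges, feats, params).data
        h2 = h.copy()
        h2[0] += 1.0  # perturb the first component only
        pert = graph_conv(Tensor(h2), edges, feats, params).data
        assert not np.allclose(base[:2], pert[:2])
        np.testing.assert_array_equal(base[2:], pert[2:])

    def test_symmetric_triangle_gives_identical_rows(self):
        d = 8
        params = conv_params(d)
        h = Tensor(np.ones((3, d)))
        edges = np.array(
            [[0, 1], [1, 0], [1, 2], [2, 1], [0, 2], [2, 0]]
        )
        feats = np.tile([1.0, 0, 0, 0], (6, 1))
        out = graph_conv(h, edges, feats, params).data
        np.testing.assert_allclose(out[0], out[1])
        np.testing.assert_allclose(out[1], out[2])

    def test_dangling_edge_rejected(self):
        params = conv_params(8)
        with pytest.raises(ValueError, match="dangling"):
            graph_conv(Tensor(np.ones((2, 8))), np.array([[0, 7]]), np.zeros((1, 4)), params)


class TestPooling:
    def test_sum_and_mean_examples(self):
        h = Tensor(np.array([[1.0, 2.0], [3.0, 4.0]]))
        out = pool_nodes(h, np.array([0, 0]), "sum")
        np.testing.assert_array_equal(out.data, [[4.0, 6.0]])
        single = pool_nodes(Tensor(np.array([[5.0, 7.0]])), np.array([0]), "mean")
        np.testing.assert_array_equal(single.data, [[5.0, 7.0]])

    def test_sum_pooling_permutation_invariant(self):
        rng = np.random.default_rng(2)
        h = rng.normal(size=(12, 6))
        membership = np.array([0] * 5 + [1] * 7)
        base = pool_nodes(Tensor(h), membership, "sum").data
        for _ in range(100):
            perm = rng.permutation(12)
            out = pool_nodes(Tensor(h[perm]), membership[perm], "sum").data
            np.testing.assert_allclose(out, base, rtol=1e-12, atol=1e-12)

    def test_lcm_binary_operator_is_commutative(self):
        cfg = desk_config(pooling="lcm", seed=3)
        params = init_parameters(cfg)
        rng = np.random.default_rng(3)
        h = rng.normal(size=(2, cfg.d_hidden))
        ab = pool_nodes(Tensor(h), np.array([0, 0]), "lcm", params).data
        ba = pool_nodes(Tensor(h[::-1].copy()), np.array([0, 0]), "lcm", params).data
        np.testing.assert_array_equal(ab, ba)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            pool_nodes(Tensor(np.ones((2, 3))), np.array([0, 0]), "sum", n_graphs=2)


class TestScaleLogit:
    def test_printed_rule_arithmetic(self):
        assert scale_logit(1.0, 0.07, 100.0).item() == pytest.approx(np.exp(0.07))

    def test_clipping(self):
        assert scale_logit(200.0, 0.0, 100.0).item() == 100.0
        assert scale_logit(-500.0, 0.0, 100.0).item() == -100.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            scale_logit(float("nan"), 0.0, 100.0)
        with pytest.raises(ValueError):
            scale_logit(float("inf"), 0.07, 100.0)

    def test_clip_bound_holds_for_adversarial_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            raw = float(rng.normal(scale=1e6))
            tau = float(rng.normal(scale=3.0))
            assert abs(scale_logit(raw, tau, 100.0).item()) <= 100.0


@pytest.fixture(scope="module")
def small_forward():
    embedder = ToyEmbedder()
    config = desk_config(seed=0)
    model = ScreeningModel(config)
    batch = batch_graphs([smiles_to_graph("CCOCC(=O)O"), smiles_to_graph("CCS")])
    stack = embedder.embed("ACDEFGHIKLMNPQRSTVWYMKVLAACDEFGHIKL", [0, 1, 2, 3])
    return model, batch, stack, embedder


class TestForward:
    def test_logit_respects_clip_for_fresh_models(self, small_forward):
        model, batch, stack, _ = small_forward
        for seed in range(5):
            fresh = ScreeningModel(desk_config(seed=seed))
            for pred in fresh.predict(batch, stack):
                assert abs(pred.logit) <= fresh.config.logit_clip
                assert pred.probability == pytest.approx(
                    1 / (1 + np.exp(-pred.logit))
                )

    def test_evaluation_mode_deterministic(self, small_forward):
        model, batch, stack, _ = small_forward
        assert model.predict(batch, stack) == model.predict(batch, stack)

    def test_layer_mismatch_rejected(self, small_forward):
        model, batch, _, embedder = small_forward
        wrong = embedder.embed("ACDEFGHIKL", [0, 1])
        with pytest.raises(ValueError, match="match"):
            model.predict(
                batch,
                ResidueEmbeddingStack(wrong.layers, (0, 1), wrong.sequence),
            )

    def test_no_embedder_parameters_are_trainable(self, small_forward):
        model, *_ = small_forward
        names = model.parameter_names()
        assert names  # non-empty census
        assert not any("embed" in n or "plm" in n for n in names)
        assert all(model.params[n].requires_grad for n in names)

    def test_forward_permutation_invariance_sum_mean(self):
        """Reordering nodes (mirrored in edge_index) leaves the pooled
        prediction unchanged for commutative pooling."""
        embedder = ToyEmbedder()
        stack = embedder.embed("ACDEFGHIKLMNPQRSTVWY", [0, 1, 2, 3])
        g = smiles_to_graph("CCOCC(=O)O")
        rng = np.random.default_rng(12)
        for pooling in ("sum", "mean"):
            model = ScreeningModel(desk_config(seed=1, pooling=pooling))
            base = model.predict(batch_graphs([g]), stack)[0]
            for _ in range(5):
                perm = rng.permutation(g.n_nodes)
                inverse = np.argsort(perm)
                permuted = MolecularGraph(
                    node_features=g.node_features[perm],
                    edge_index=inverse[g.edge_index],
                    edge_features=g.edge_features.copy(),
                    smiles=g.smiles,
                )
                out = model.predict(batch_graphs([permuted]), stack)[0]
                assert out.logit == pytest.approx(base.logit, abs=1e-6)
                assert out.pKi == pytest.approx(base.pKi, abs=1e-6)

    def test_protein_point_mutation_moves_the_logit(self):
        embedder = ToyEmbedder()
        model = ScreeningModel(desk_config(seed=7))
        batch = batch_graphs([smiles_to_graph("CCO")])
        seq = "ACDEFGHIKLMNPQRSTVWY"
        mutated = seq[:10] + "W" + seq[11:]
        a = model.predict(batch, embedder.embed(seq, [0, 1, 2, 3]))[0]
        b = model.predict(batch, embedder.embed(mutated, [0, 1, 2, 3]))[0]
        assert a.logit != b.logit


class TestConfigAndCheckpoint:
    def test_config_invariants(self):
        with pytest.raises(ValueError):
            ModelConfig(n_blocks=3)  # != len(encoder_layer_indices)
        with pytest.raises(ValueError):
            desk_config(dropout=1.5)
        with pytest.raises(ValueError):
            desk_config(logit_clip=-1)
        with pytest.raises(ValueError):
            desk_config(pooling="nope")

    def test_checkpoint_roundtrip(self, tmp_path, small_forward):
        model, batch, stack, _ = small_forward
        path = tmp_path / "model.npz"
        model.save(path)
        clone = ScreeningModel.load(path)
        assert clone.config == model.config
        assert clone.predict(batch, stack) == model.predict(batch, stack)

    def test_version_mismatch_refused(self, tmp_path, small_forward):
        model, *_ = small_forward
        path = tmp_path / "model.npz"
        model.save(path)
        data = dict(np.load(path))
        data["checkpoint_version"] = np.asarray(99)
        np.savez(path, **data)
        with pytest.raises(ValueError, match="version"):
            ScreeningModel.load(path)
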
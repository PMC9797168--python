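"""Model contracts: backbone shapes, GCN algebra, attention, fusion."""

from dataclasses import replace

import numpy as np
import pytest

import gacnn.autodiff as ad
from gacnn.graphbuild import GraphBuildConfig, build_graph
from gacnn.network import (BackboneConfig, FusionConfig, GACNN, GCNConfig,
                           HopStack, VGGBackbone, attention_aggregate,
                           cnn_forward, gcn_layer, graph_readout)
from gacnn.synthetic import SyntheticSpec, generate_image


def _small_model(tiny_graphs, seed=0, **fusion_overrides):
    fusion = FusionConfig(fused_dim=64, **fusion_overrides)
    return GACNN(BackboneConfig(input_side=64, width_multiplier=1 / 8),
                 GCNConfig(hidden=16), fusion, seed=seed)


class TestBackboneShapes:
    @pytest.mark.parametrize("side", [64, 96])
    def test_final_map_side_is_input_over_16(self, side):
        cfg = BackboneConfig(input_side=side, width_multiplier=1 / 8)
        feats, fmap = VGGBackbone(cfg, seed=0).forward(
            ad.Tensor(np.zeros((1, 3, side, side))))
        assert fmap.data.shape == (1, 64, side // 16, side // 16)
        assert feats.data.shape == (1, 64)

    def test_head_equals_channelwise_spatial_max(self):
        cfg = BackboneConfig(input_side=64, width_multiplier=1 / 8)
        bb = VGGBackbone(cfg, seed=1)
        x = ad.Tensor(np.random.default_rng(0).normal(size=(2, 3, 64, 64)))
        feats, fmap = bb.forward(x)
        np.testing.assert_allclose(feats.data, fmap.data.max(axis=(2, 3)),
                                   atol=1e-6)

    def test_wrong_input_shape_rejected(self):
        with pytest.raises(ValueError):
            cnn_forward(np.zeros((2, 32, 32, 3)),
                        BackboneConfig(input_side=64, width_multiplier=1 / 8))


class TestGcnLayer:
    def test_identity_weight_reduces_to_propagation(self):
        rng = np.random.default_rng(3)
        A_hat = np.full((2, 2), 0.5)
        H = rng.normal(size=(2, 4))
        got = gcn_layer(H, A_hat, np.eye(4), activation="identity")
        np.testing.assert_allclose(got, A_hat @ H)

    def test_identity_adjacency_is_dense_layer(self):
        rng = np.random.default_rng(4)
        H, W = rng.normal(size=(5, 3)), rng.normal(size=(3, 2))
        np.testing.assert_allclose(gcn_layer(H, np.eye(5), W),
                                   np.maximum(H @ W, 0))

    def test_hand_worked_two_node_example(self):
        A_hat = np.array([[0.5, 0.5], [0.5, 0.5]])
        got = gcn_layer(np.eye(2), A_hat, np.eye(2), activation="identity")
        np.testing.assert_allclose(got, A_hat)

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for n in (2, 7, 30):
            A = rng.uniform(0, 1, (n, n))
            A = (A + A.T) / 2
            H = rng.normal(size=(n, 6))
            W = rng.normal(size=(6, 4))
            oracle = np.maximum(A @ H @ W, 0)
            np.testing.assert_allclose(gcn_layer(H, A, W), oracle, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gcn_layer(np.zeros((3, 4)), np.zeros((3, 3)), np.zeros((5, 2)))


class TestAttentionAggregate:
    def setup_method(self):
        rng = np.random.default_rng(6)
        self.stack = HopStack([rng.normal(size=(5, 4)) for _ in range(3)])

    def test_one_hot_selects_single_hop_exactly(self):
        got = attention_aggregate(self.stack, [0.0, 1.0, 0.0])
        np.testing.assert_array_equal(got, self.stack.hops[1])

    def test_uniform_weights_give_hop_mean(self):
        got = attention_aggregate(self.stack, np.full(3, 1 / 3))
        np.testing.assert_allclose(got, np.mean(self.stack.hops, axis=0))

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(7)
        a = rng.dirichlet(np.ones(3))
        got = attention_aggregate(self.stack, a)
        lo = np.min(self.stack.hops, axis=0)
        hi = np.max(self.stack.hops, axis=0)
        assert np.all(got >= lo - 1e-12) and np.all(got <= hi + 1e-12)

    def test_depth_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention_aggregate(self.stack, [0.5, 0.5])


class TestGraphReadout:
    def test_constant_nodes(self):
        g = np.array([1.0, -2.0, 3.0])
        got = graph_readout(np.tile(g, (6, 1)))
        np.testing.assert_allclose(got, np.concatenate([g, g]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        G = rng.normal(size=(9, 5))
        perm = rng.permutation(9)
        np.testing.assert_allclose(graph_readout(G), graph_readout(G[perm]))

    def test_merged_mean_is_size_weighted(self):
        rng = np.random.default_rng(9)
        A, B = rng.normal(size=(3, 4)), rng.normal(size=(5, 4))
        merged = graph_readout(np.vstack([A, B]))[:4]
        expected = (3 * graph_readout(A)[:4] + 5 * graph_readout(B)[:4]) / 8
        np.testing.assert_allclose(merged, expected)


class TestFusionAndClassifier:
    def test_mu_zero_ignores_graph_branch(self, tiny_set, tiny_graphs):
        model = _small_model(tiny_graphs, mu=0.0)
        imgs = np.stack(tiny_set.images[:2])
        a = model.forward(imgs, tiny_graphs[:2]).data
        b = model.forward(imgs, [tiny_graphs[5], tiny_graphs[9]]).data
        np.testing.assert_array_equal(a, b)

    def test_graph_contribution_linear_in_mu(self, tiny_set, tiny_graphs):
        """Doubling mu doubles the graph-branch term of the fused vector."""
        imgs = np.stack(tiny_set.images[:2])
        outs = {}
        for mu in (0.0, 1.0, 2.0):
            model = _small_model(tiny_graphs, mu=mu)
            outs[mu] = model.fused(imgs, tiny_graphs[:2]).data
        np.testing.assert_allclose(outs[2.0] - outs[0.0],
                                   2 * (outs[1.0] - outs[0.0]),
                                   atol=1e-4)

    def test_probabilities_normalised(self, tiny_set, tiny_graphs):
        model = _small_model(tiny_graphs)
        p = model.predict_proba(np.stack(tiny_set.images[:4]),
                                tiny_graphs[:4])
        assert p.shape == (4, 5)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_classifier_alone_fits_separable_embeddings(self):
        """On a linearly separable toy embedding the classifier head
        reaches 100% train accuracy (logistic-regression oracle agrees)."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(10)
        means = np.eye(5) * 8.0
        Z = np.vstack([rng.normal(means[c], 0.3, size=(20, 5))
                       for c in range(5)])
        y = np.repeat(np.arange(5), 20)
        assert LogisticRegression(max_iter=1000).fit(Z, y).score(Z, y) == 1.0
        W = ad.Tensor(np.zeros((5, 5)), requires_grad=True)
        b = ad.Tensor(np.zeros(5), requires_grad=True)
        opt = ad.Adam([W, b], lr=0.05, weight_decay=0.0)
        T = np.eye(5)[y]
        for _ in range(200):
            logits = ad.add(ad.matmul(ad.Tensor(Z), W), b)
            probs = ad.add(1e-7, ad.mul(1 - 2e-7, ad.softmax(logits, axis=-1)))
            loss = ad.mul(-1.0 / len(y), ad.sum_(ad.add(
                ad.mul(T, ad.log(probs)),
                ad.mul(1 - T, ad.log(ad.add(1.0, ad.mul(-1.0, probs)))))))
            opt.zero_grad()
            loss.backward()
            opt.step()
        pred = (Z @ W.data + b.data).argmax(axis=1)
        assert (pred == y).mean() == 1.0


class TestWholeModelProperties:
    def test_node_permutation_changes_no_logit(self, tiny_set, tiny_graphs):
        model = _small_model(tiny_graphs, seed=3)
        imgs = np.stack(tiny_set.images[:3])
        graphs = tiny_graphs[:3]
        base = model.forward(imgs, graphs).data
        rng = np.random.default_rng(0)
        permuted = []
        for g in graphs:
            perm = rng.permutation(g.n_nodes)
            pg = replace_graph(g, perm)
            permuted.append(pg)
        shuffled = model.forward(imgs, permuted).data
        np.testing.assert_allclose(shuffled, base, atol=1e-5)

    def test_per_node_attention_variant(self, tiny_set, tiny_graphs):
        model = GACNN(BackboneConfig(input_side=64, width_multiplier=1 / 8),
                      GCNConfig(hidden=16, attention="per_node"),
                      FusionConfig(fused_dim=64), seed=0)
        p = model.predict_proba(np.stack(tiny_set.images[:2]),
                                tiny_graphs[:2])
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_attention_weights_on_simplex(self, tiny_graphs):
        model = _small_model(tiny_graphs)
        model.att_logits.data = np.array([3.0, -1.0], dtype=np.float32)
        a = model.attention_weights()
        assert np.all(a >= 0) and a.sum() == pytest.approx(1.0, abs=1e-12)

    def test_one_hot_attention_selects_single_hop(self, tiny_graphs):
        model = _small_model(tiny_graphs)
        model.att_logits.data = np.array([50.0, -50.0], dtype=np.float32)
        stack = model.hop_stack(tiny_graphs[0])
        gamma = model._aggregate(stack).data
        np.testing.assert_allclose(gamma, stack.hops[0].data, atol=1e-6)

    def test_checkpoint_round_trip(self, tmp_path, tiny_set, tiny_graphs):
        model = _small_model(tiny_graphs, seed=5)
        model.calibrate(tiny_graphs)
        imgs = np.stack(tiny_set.images[:3])
        before = model.predict_proba(imgs, tiny_graphs[:3])
        model.save(tmp_path / "ckpt.npz")
        back = GACNN.load(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(
            back.predict_proba(imgs, tiny_graphs[:3]), before)


def replace_graph(g, perm):
    """Apply a node permutation consistently to every graph field."""
    from gacnn.graphbuild import ImageGraph

    return ImageGraph(centers=g.centers[perm], X=g.X[perm],
                      A=g.A[np.ix_(perm, perm)],
                      D=np.diag(np.diag(g.D)[perm]),
                      A_hat=g.A_hat[np.ix_(perm, perm)],
                      regions=[g.regions[i] for i in perm])


def test_model_hop_stack_matches_functional_layers(tiny_graphs):
    """The trainable path reproduces the reference gcn_layer chain."""
    model = _small_model(tiny_graphs, seed=2)
    g = tiny_graphs[0]
    stack = model.hop_stack(g)
    H = (g.X - model.x_mu) / model.x_sd
    for hop, W in zip(stack.hops, model.gcn_W):
        H = gcn_layer(H, g.A_hat, W.data)
        np.testing.assert_allclose(hop.data, H, atol=1e-4)


class TestVizHooks:
    def test_tsne_embedding_shape(self):
        from gacnn.viz import tsne_embed

        feats = np.random.default_rng(0).normal(size=(30, 16))
        emb = tsne_embed(feats, seed=0)
        assert emb.shape == (30, 2)

    def test_input_saliency_highlights_pixels(self, tiny_set, tiny_graphs):
        from gacnn.viz import input_saliency

        model = _small_model(tiny_graphs, seed=1)
        sal = input_saliency(model, tiny_set.images[0], tiny_graphs[0])
        assert sal.shape == (64, 64)
        assert np.all(sal >= 0) and sal.max() > 0
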
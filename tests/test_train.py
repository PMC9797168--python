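"""Training contracts: splits, losses, schedule, pseudo labels, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gacnn.graphbuild import GraphBuildConfig
from gacnn.network import FusionConfig, GACNN, GCNConfig, BackboneConfig
from gacnn.train import (TrainConfig, cross_validate, fit,
                         generate_pseudo_labels, learning_rate_at_epoch,
                         one_hot, split_by_labeling_rate, stratified_folds,
                         supervised_loss, total_loss, unsupervised_loss)


def scalar_loop_bce(Z, P, eps=1e-7):
    """Independent elementwise oracle for the summed binary cross-entropy."""
    total = 0.0
    for i in range(Z.shape[0]):
        for k in range(Z.shape[1]):
            z = min(max(Z[i, k], eps), 1 - eps)
            total -= P[i, k] * np.log(z) + (1 - P[i, k]) * np.log(1 - z)
    return total


class TestSplit:
    def test_stratified_counts(self):
        labels = np.repeat(np.arange(5), 20)
        S, U = split_by_labeling_rate(labels, 0.2, seed=1)
        assert len(S) == 20 and len(U) == 80
        for c in range(5):
            assert (labels[S] == c).sum() == 4

    def test_rate_one_is_fully_supervised(self):
        S, U = split_by_labeling_rate(np.repeat(np.arange(5), 4), 1.0)
        assert len(U) == 0 and len(S) == 20

    def test_deterministic(self):
        labels = np.repeat(np.arange(5), 13)
        a = split_by_labeling_rate(labels, 0.3, seed=9)
        b = split_by_labeling_rate(labels, 0.3, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_tiny_rate_keeps_one_label_per_class(self):
        labels = np.repeat(np.arange(5), 10)
        with pytest.warns(UserWarning):
            S, _ = split_by_labeling_rate(labels, 0.01, seed=0)
        for c in range(5):
            assert (labels[S] == c).sum() >= 1

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            split_by_labeling_rate([0, 1], 0.0)


class TestLosses:
    def test_hand_worked_two_class_example(self):
        # single sample, uniform prediction: -[log .5 + log .5] = 2 ln 2
        loss = supervised_loss(np.array([[0.5, 0.5]]), np.array([[1.0, 0.0]]))
        assert loss == pytest.approx(2 * np.log(2), rel=1e-12)

    def test_perfect_prediction_is_near_zero(self):
        P = one_hot([2], 5)
        assert supervised_loss(P, P) < 1e-5

    def test_additive_over_disjoint_subsets(self):
        rng = np.random.default_rng(0)
        Z = rng.dirichlet(np.ones(5), size=10)
        P = one_hot(rng.integers(0, 5, 10), 5)
        whole = supervised_loss(Z, P)
        parts = supervised_loss(Z[:4], P[:4]) + supervised_loss(Z[4:], P[4:])
        assert whole == pytest.approx(parts, rel=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 12), st.integers(2, 6))
    def test_matches_scalar_loop_oracle(self, seed, n, k):
        rng = np.random.default_rng(seed)
        Z = rng.uniform(0, 1, size=(n, k))
        P = one_hot(rng.integers(0, k, n), k)
        assert supervised_loss(Z, P) == pytest.approx(
            scalar_loop_bce(Z, P), abs=1e-8)

    def test_unsupervised_equals_supervised_with_pseudo_targets(self):
        rng = np.random.default_rng(1)
        Z = rng.uniform(0, 1, size=(7, 5))
        P_hat = one_hot(rng.integers(0, 5, 7), 5)
        assert unsupervised_loss(Z, P_hat) == supervised_loss(Z, P_hat)

    def test_empty_unlabeled_set_gives_zero(self):
        assert unsupervised_loss(np.zeros((0, 5)), np.zeros((0, 5))) == 0.0

    def test_total_loss_arithmetic(self):
        assert total_loss(1.0, 2.0, 0.1) == pytest.approx(1.2)
        assert total_loss(3.7, 99.0, 0.0) == 3.7
        assert total_loss(1.0, 2.0, 0.5) > total_loss(1.0, 2.0, 0.2)
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, -0.1)


class TestSchedule:
    def test_staircase_decay_from_paper_defaults(self):
        cfg = TrainConfig()
        assert learning_rate_at_epoch(cfg, 1) == pytest.approx(1e-4)
        assert learning_rate_at_epoch(cfg, 20) == pytest.approx(1e-4)
        assert learning_rate_at_epoch(cfg, 21) == pytest.approx(1e-5)
        assert learning_rate_at_epoch(cfg, 41) == pytest.approx(1e-6)
        assert learning_rate_at_epoch(cfg, 60) == pytest.approx(1e-6)

    def test_warmup_ramp(self):
        cfg = TrainConfig(lr=0.01, warmup_epochs=3)
        lrs = [learning_rate_at_epoch(cfg, e) for e in (1, 2, 3, 4)]
        assert lrs == pytest.approx([0.0025, 0.005, 0.0075, 0.01])

    def test_invalid_epoch_rejected(self):
        with pytest.raises(ValueError):
            learning_rate_at_epoch(TrainConfig(), 0)


class TestPseudoLabels:
    def test_tie_broken_toward_lowest_class(self, tiny_set, tiny_graphs):
        model = GACNN(BackboneConfig(input_side=64, width_multiplier=1 / 8),
                      GCNConfig(hidden=16), FusionConfig(fused_dim=64), seed=0)
        for p in model.parameters().values():
            p.data = np.zeros_like(p.data)  # all logits identical -> tie
        P_hat = generate_pseudo_labels(model, np.stack(tiny_set.images[:4]),
                                       tiny_graphs[:4])
        np.testing.assert_array_equal(P_hat.argmax(axis=1), np.zeros(4))

    def test_one_hot_rows(self, tiny_set, tiny_graphs):
        model = GACNN(BackboneConfig(input_side=64, width_multiplier=1 / 8),
                      GCNConfig(hidden=16), FusionConfig(fused_dim=64), seed=1)
        P_hat = generate_pseudo_labels(model, np.stack(tiny_set.images[:5]),
                                       tiny_graphs[:5])
        assert P_hat.shape == (5, 5)
        np.testing.assert_array_equal(P_hat.sum(axis=1), np.ones(5))
        assert set(np.unique(P_hat)) <= {0.0, 1.0}

    def test_empty_unlabeled_batch(self, tiny_graphs):
        model = GACNN(BackboneConfig(input_side=64, width_multiplier=1 / 8),
                      GCNConfig(hidden=16), FusionConfig(fused_dim=64), seed=0)
        assert generate_pseudo_labels(model, np.zeros((0, 64, 64, 3)),
                                      []).shape == (0, 5)


class TestFit:
    @staticmethod
    def _quick_cfg(**kw):
        base = dict(epochs=2, batch_size=8, seed=3, eval_every=2)
        base.update(kw)
        return TrainConfig.desk_scale(**base)

    def test_two_runs_share_identical_trajectories(
            self, tiny_set, tiny_graphs, desk_backbone, desk_gcn, desk_fusion):
        kw = dict(backbone_cfg=desk_backbone, gcn_cfg=desk_gcn,
                  fusion_cfg=desk_fusion, graphs=tiny_graphs)
        a = fit(tiny_set, self._quick_cfg(), **kw)
        b = fit(tiny_set, self._quick_cfg(), **kw)
        np.testing.assert_allclose(a.history["train_loss"],
                                   b.history["train_loss"], atol=1e-6)

    def test_rate_one_invariant_to_semi_supervised_machinery(
            self, tiny_set, tiny_graphs, desk_backbone, desk_gcn, desk_fusion):
        kw = dict(backbone_cfg=desk_backbone, gcn_cfg=desk_gcn,
                  fusion_cfg=desk_fusion, graphs=tiny_graphs)
        a = fit(tiny_set, self._quick_cfg(labeling_rate=1.0, lambda_unl=0.1),
                **kw)
        b = fit(tiny_set, self._quick_cfg(labeling_rate=1.0, lambda_unl=0.0),
                **kw)
        np.testing.assert_array_equal(a.history["train_loss"],
                                      b.history["train_loss"])

    def test_history_records_curves(self, tiny_set, tiny_graphs,
                                    desk_backbone, desk_gcn, desk_fusion):
        res = fit(tiny_set, self._quick_cfg(eval_every=1),
                  backbone_cfg=desk_backbone, gcn_cfg=desk_gcn,
                  fusion_cfg=desk_fusion, graphs=tiny_graphs,
                  test_set=tiny_set, test_graphs=tiny_graphs)
        for col in ("epoch", "lr", "train_loss", "train_accuracy",
                    "train_kappa", "test_accuracy", "test_kappa"):
            assert col in res.history.columns
        assert len(res.history) == 2


class TestFolds:
    def test_partition_and_stratification(self):
        labels = np.repeat(np.arange(5), 12)
        folds = stratified_folds(labels, 4, seed=2)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(60))
        for f in folds:
            counts = np.bincount(labels[f], minlength=5)
            assert counts.min() == 3 and counts.max() == 3

    def test_cross_validate_aggregates(self, tiny_set, tiny_graphs,
                                       desk_backbone, desk_gcn, desk_fusion):
        cfg = TrainConfig.desk_scale(epochs=1, batch_size=8, folds=3, seed=0,
                                     eval_every=1)
        table = cross_validate(tiny_set, cfg, backbone_cfg=desk_backbone,
                               gcn_cfg=desk_gcn, fusion_cfg=desk_fusion,
                               graphs=tiny_graphs)
        assert len(table) == 4  # 3 folds + aggregate row
        assert table.iloc[-1]["fold"] == "mean+/-sd"
        assert table.iloc[-1]["accuracy"] == pytest.approx(
            table.iloc[:3]["accuracy"].mean())


class TestPipelineConfigFile:
    def test_yaml_round_trip_preserves_every_field(self, tmp_path):
        from gacnn.config import PipelineConfig, load_config, save_config

        cfg = PipelineConfig.defaults()
        cfg["train"] = TrainConfig(lambda_unl=0.3, epochs=7, seed=11)
        path = tmp_path / "run.yaml"
        save_config(cfg, path)
        back = load_config(path)
        for section in cfg:
            assert back[section] == cfg[section], section
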
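"""Architectures, forward-pass properties, sampler, training contracts."""

import numpy as np
import pytest

import trisimnet as tsn
from trisimnet.graph import PatientGraph
from trisimnet.model import TriageGNN
from trisimnet.nn import (
    TrainConfig,
    ablation_spec,
    make_model,
    predict,
    sample_neighborhoods,
    train,
)
from trisimnet.nn.architectures import ArchitectureError, architecture_spec
from trisimnet.nn.training import (
    NeighborBatching,
    forward_logits,
    load_model,
    save_model,
)


def random_graph(rng, n=30, d=5, C=4, p_edge=0.15):
    X = rng.uniform(0, 1, (n, d))
    y = rng.integers(0, C, n)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < p_edge
    return PatientGraph(
        node_features=X,
        node_labels=y,
        edge_src=iu[keep],
        edge_dst=ju[keep],
        edge_weights=np.ones(int(keep.sum())),
        class_names=[str(c) for c in range(C)],
    )


class TestArchitectureSpecs:
    def test_gcn5_layer_dims(self):
        spec, model = make_model("gcn5", 16, 4)
        assert spec.layer_dims == ((16, 64), (64, 64), (64, 64), (64, 64), (64, 4))
        assert len(model.layers) == 5

    def test_gcn4_hidden_32(self):
        spec, _ = make_model("gcn4", 16, 4)
        assert spec.layer_dims == ((16, 32), (32, 32), (32, 32), (32, 4))

    def test_gatv2_head_chaining(self):
        spec, _ = make_model("gatv2", 16, 4)
        assert spec.heads == 4
        assert spec.layer_dims == ((16, 8), (32, 4))  # 8 x 4 heads -> 32

    def test_sage5_taper_and_aggregators(self):
        spec, _ = make_model("sage5", 16, 4)
        assert spec.layer_dims == ((16, 64), (64, 32), (32, 16), (16, 8), (8, 4))
        assert spec.aggregators == ("max-pool", "max-pool", "mean", "max-pool", "max-pool")

    @pytest.mark.parametrize("family", ["gcn5", "gcn4", "gatv2", "sage5"])
    @pytest.mark.parametrize("F,C", [(16, 4), (14, 4), (7, 3)])
    def test_chaining_invariants_any_size(self, family, F, C):
        spec, _ = make_model(family, F, C)
        assert spec.in_dim == F and spec.out_dim == C

    def test_unknown_family_rejected(self):
        with pytest.raises(ArchitectureError):
            make_model("gcn7", 16, 4)

    def test_broken_chain_rejected(self):
        from trisimnet.nn.architectures import ArchitectureSpec

        with pytest.raises(ArchitectureError):
            ArchitectureSpec("x", ((16, 64), (32, 4)), conv="gcn")


class TestForward:
    @pytest.mark.parametrize("family", ["gcn5", "gcn4", "gatv2", "sage5"])
    def test_output_shape(self, family, rng):
        g = random_graph(rng, n=20, d=6)
        _, model = make_model(family, 6, 4, seed=1)
        logits = forward_logits(model, g)
        assert logits.shape == (20, 4)

    @pytest.mark.parametrize("family", ["gcn5", "gcn4", "gatv2", "sage5"])
    def test_permutation_equivariance(self, family, rng):
        g = random_graph(rng, n=25, d=5)
        _, model = make_model(family, 5, 4, seed=2)
        logits = forward_logits(model, g)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        src, dst = inv[g.edge_src], inv[g.edge_dst]
        lo, hi = np.minimum(src, dst), np.maximum(src, dst)
        gp = PatientGraph(
            node_features=g.node_features[perm],
            node_labels=g.node_labels[perm],
            edge_src=lo,
            edge_dst=hi,
            edge_weights=g.edge_weights,
            class_names=g.class_names,
        )
        logits_p = forward_logits(model, gp)
        assert np.allclose(logits_p, logits[perm], atol=1e-5)

    @pytest.mark.parametrize("family", ["gcn5", "sage5"])
    def test_isolated_node_depends_on_own_features(self, family, rng):
        """An isolated node's logits match a single-node graph's."""
        g = random_graph(rng, n=10, d=4, p_edge=0.5)
        x_iso = rng.uniform(0, 1, (1, 4))
        g_with = PatientGraph(
            node_features=np.vstack([g.node_features, x_iso]),
            node_labels=np.concatenate([g.node_labels, [0]]),
            edge_src=g.edge_src,
            edge_dst=g.edge_dst,
            edge_weights=g.edge_weights,
        )
        singleton = PatientGraph(
            node_features=x_iso,
            node_labels=np.array([0]),
            edge_src=np.empty(0, dtype=int),
            edge_dst=np.empty(0, dtype=int),
            edge_weights=np.empty(0),
        )
        _, model = make_model(family, 4, 4, seed=3)
        full = forward_logits(model, g_with)
        alone = forward_logits(model, singleton)
        assert np.allclose(full[-1], alone[0], atol=1e-10)

    def test_inference_determinism(self, rng):
        g = random_graph(rng, n=15, d=4)
        _, model = make_model("gatv2", 4, 4, seed=4)
        assert np.array_equal(forward_logits(model, g), forward_logits(model, g))

    def test_feature_width_mismatch(self, rng):
        g = random_graph(rng, n=10, d=5)
        _, model = make_model("gcn4", 7, 4)
        with pytest.raises(ArchitectureError):
            forward_logits(model, g)


class TestSampler:
    def test_batch_count_and_partition(self, rng):
        g = random_graph(rng, n=50, d=4, p_edge=0.2)
        train_nodes = np.arange(45)
        batches = sample_neighborhoods(g, train_nodes, batch_size=10, fanout=3, hops=2, seed=0)
        assert len(batches) == 5  # ceil(45/10)
        seeds = np.concatenate([b.seed_ids for b in batches])
        assert sorted(seeds.tolist()) == train_nodes.tolist()

    def test_fanout_cap_on_star_graph(self):
        n = 16  # center node 0 with degree 15
        g = PatientGraph(
            node_features=np.random.default_rng(0).uniform(0, 1, (n, 3)),
            node_labels=np.zeros(n, dtype=int),
            edge_src=np.zeros(n - 1, dtype=int),
            edge_dst=np.arange(1, n),
            edge_weights=np.ones(n - 1),
        )
        batches = sample_neighborhoods(g, np.array([0]), 1, fanout=10, hops=1, seed=1)
        assert batches[0].max_in_degree() <= 10
        assert batches[0].topology.dst.size == 10

    def test_sampler_determinism(self, rng):
        g = random_graph(rng, n=40, d=4, p_edge=0.3)
        b1 = sample_neighborhoods(g, np.arange(30), 8, 3, 2, seed=7)
        b2 = sample_neighborhoods(g, np.arange(30), 8, 3, 2, seed=7)
        for x, y in zip(b1, b2):
            assert np.array_equal(x.node_ids, y.node_ids)
            assert np.array_equal(x.topology.src, y.topology.src)


class TestTraining:
    def test_training_reduces_loss_on_separable_graph(self, small_graph):
        masks = tsn.make_split(small_graph.node_labels, seed=0)
        _, model = make_model("gcn4", small_graph.n_features, small_graph.n_classes, seed=0)
        tc = train(model, small_graph, masks, TrainConfig(epochs=30, patience=None, seed=0))
        losses = [h["loss"] for h in tc.history]
        assert np.median(losses[-10:]) < np.median(losses[:10])
        assert tc.history[-1]["train_accuracy"] >= 0.9

    def test_zero_epochs_is_random_baseline(self, small_graph):
        masks = tsn.make_split(small_graph.node_labels, seed=0)
        _, model = make_model("gcn4", small_graph.n_features, small_graph.n_classes, seed=0)
        tc = train(model, small_graph, masks, TrainConfig(epochs=0, seed=0))
        assert tc.history == []
        pred = predict(tc, small_graph)
        acc = float((pred == small_graph.node_labels).mean())
        assert acc < 0.5  # untrained: near 1/C on balanced labels

    def test_same_seed_identical_history(self, small_graph):
        masks = tsn.make_split(small_graph.node_labels, seed=1)
        cfg = TrainConfig(epochs=6, seed=5, batching=NeighborBatching(batch_size=200))
        runs = []
        for _ in range(2):
            _, model = make_model("sage5", small_graph.n_features, small_graph.n_classes, seed=5)
            runs.append(train(model, small_graph, masks, cfg))
        assert runs[0].history == runs[1].history

    def test_predict_tie_breaks_to_smallest_class(self):
        logits = np.array([[0.1, 3.0, -1.0, 0.0], [1.0, 1.0, 0.0, 0.0]])
        assert logits.argmax(axis=1).tolist() == [1, 0]

    def test_predictions_match_forward_argmax(self, small_graph, rng):
        masks = tsn.make_split(small_graph.node_labels, seed=0)
        _, model = make_model("gcn4", small_graph.n_features, small_graph.n_classes, seed=0)
        tc = train(model, small_graph, masks, TrainConfig(epochs=3, seed=0))
        ids = rng.choice(small_graph.n_nodes, 50, replace=False)
        oracle = forward_logits(tc.model, small_graph).argmax(axis=1)[ids]
        assert np.array_equal(predict(tc, small_graph, ids), oracle)

    def test_unknown_node_id_rejected(self, small_graph):
        masks = tsn.make_split(small_graph.node_labels, seed=0)
        _, model = make_model("gcn4", small_graph.n_features, small_graph.n_classes, seed=0)
        tc = train(model, small_graph, masks, TrainConfig(epochs=1, seed=0))
        with pytest.raises(IndexError):
            predict(tc, small_graph, np.array([small_graph.n_nodes]))

    def test_inductive_prediction_for_new_patient(self, small_graph):
        res = TriageGNN(small_graph, arch="sage5").fit(epochs=10, seed=0)
        x_new = small_graph.node_features[:3] + 0.01
        preds = res.predict_new(x_new)
        assert preds.shape == (3,)
        assert set(preds.tolist()) <= set(range(small_graph.n_classes))

    def test_save_load_round_trip(self, small_graph, tmp_path):
        res = TriageGNN(small_graph, arch="gcn4").fit(epochs=3, seed=1)
        path = tmp_path / "model.npz"
        save_model(res.trained, path)
        back = load_model(path)
        assert back.spec == res.trained.spec
        assert np.allclose(
            forward_logits(back.model, small_graph),
            forward_logits(res.trained.model, small_graph),
        )


class TestAblationSpecs:
    def test_remove_all_three_leaves_two_layers(self):
        spec = ablation_spec([2, 3, 4], hidden_width=8, F=16, C=4)
        assert spec.layer_dims == ((16, 8), (8, 4))

    @pytest.mark.parametrize("removed", [[2], [3], [4], [2, 3, 4]])
    @pytest.mark.parametrize("width", [8, 64])
    def test_variants_smaller_than_base(self, removed, width):
        from trisimnet.nn.architectures import GNNClassifier

        base = GNNClassifier(architecture_spec("sage5", 16, 4), seed=0)
        variant = GNNClassifier(ablation_spec(removed, width, 16, 4), seed=0)
        assert variant.n_parameters() < base.n_parameters()

    def test_mean_aggregator_at_third_layer_when_deep_enough(self):
        spec = ablation_spec([2], hidden_width=64, F=16, C=4)
        assert spec.aggregators[2] == "mean"
        shallow = ablation_spec([2, 3, 4], hidden_width=64, F=16, C=4)
        assert "mean" not in shallow.aggregators
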
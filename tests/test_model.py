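import numpy as np
import pytest

from gkmgraph.encoding import (
    EncoderConfig,
    SequenceFeatureGraph,
    build_sequence_feature_graph,
    full_kmer_universe,
)
from gkmgraph.model import (
    ModelConfig,
    ModelParams,
    TrainConfig,
    batch_loss,
    conv_stack,
    cross_entropy_loss,
    encode_dataset,
    graph_convolution_layer,
    head_forward,
    load_checkpoint,
    loss_and_gradients,
    predict,
    readout_to_tensor,
    relu,
    save_checkpoint,
    train_model,
)
from gkmgraph.sequence_io import Dataset, LabeledSequence
from gkmgraph.simulate import GeneratorConfig, generate_dataset


def _random_graph(rng, n_nodes, k=3, weighted=True):
    """Random sparse graph over the first n_nodes of the k-mer universe."""
    labels = full_kmer_universe(k)[:n_nodes]
    edges = {}
    n_edges = int(rng.integers(1, max(2, n_nodes * 2)))
    for _ in range(n_edges):
        i, j = sorted(rng.integers(0, n_nodes, size=2))
        w = float(rng.integers(1, 5)) if weighted else 1.0
        edges[(int(i), int(j))] = edges.get((int(i), int(j)), 0.0) + w
    feats = rng.random(n_nodes)
    return SequenceFeatureGraph(labels, feats, edges, n_windows=n_nodes)


def _dense_oracle(graph, h, w, use_edge_weights):
    """Brute-force D^{-1/2} A D^{-1/2} H W followed by ReLU."""
    n = graph.n_nodes
    a = np.zeros((n, n))
    for (i, j), wt in graph.edges.items():
        v = wt if use_edge_weights else 1.0
        a[i, j] += v
        if i != j:
            a[j, i] += v
    d = a.sum(axis=1)
    dinv = np.diag([1.0 / np.sqrt(x) if x > 0 else 0.0 for x in d])
    return np.maximum(0.0, dinv @ a @ dinv @ h @ w)


class TestRelu:
    def test_scalar_cases(self):
        assert relu(np.array(-2.0)) == 0.0
        assert relu(np.array(3.0)) == 3.0

    def test_elementwise_matrix(self):
        x = np.array([[-1.0, 0.5], [0.0, -3.0]])
        np.testing.assert_array_equal(relu(x), [[0.0, 0.5], [0.0, 0.0]])


class TestGraphConvolutionLayer:
    def test_isolated_node_outputs_zero(self):
        g = SequenceFeatureGraph(["AA", "AC", "AG"], np.ones(3), {(0, 1): 1.0}, 3)
        h = np.ones((3, 1))
        out = graph_convolution_layer(h, g, np.ones((1, 1)))
        assert out[2, 0] == 0.0  # node 2 has no neighbors

    def test_two_nodes_unit_edge_hand_value(self):
        # Z_1 = 1/sqrt(1*1) * h_2 * W = 1 for unit everything
        g = SequenceFeatureGraph(["AA", "AC"], np.ones(2), {(0, 1): 1.0}, 2)
        h = np.ones((2, 1))
        out = graph_convolution_layer(h, g, np.ones((1, 1)))
        assert out[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("use_edge_weights", [True, False])
    def test_dense_oracle_equivalence(self, rng, use_edge_weights):
        for _ in range(100):
            n = int(rng.integers(2, 65))
            g = _random_graph(rng, n, weighted=True)
            f_in, f_out = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            h = rng.standard_normal((n, f_in))
            w = rng.standard_normal((f_in, f_out))
            got = graph_convolution_layer(h, g, w, use_edge_weights)
            want = _dense_oracle(g, h, w, use_edge_weights)
            np.testing.assert_allclose(got, want, atol=1e-8)

    def test_negative_edge_weight_rejected(self):
        g = SequenceFeatureGraph(["AA", "AC"], np.ones(2), {(0, 1): -1.0}, 2)
        with pytest.raises(ValueError, match="negative"):
            graph_convolution_layer(np.ones((2, 1)), g, np.ones((1, 1)))

    def test_shape_mismatch_rejected(self):
        g = SequenceFeatureGraph(["AA", "AC"], np.ones(2), {(0, 1): 1.0}, 2)
        with pytest.raises(ValueError, match="incompatible"):
            graph_convolution_layer(np.ones((2, 3)), g, np.ones((1, 1)))


class TestReadout:
    def test_shape_contract(self):
        h = np.arange(64 * 8, dtype=float).reshape(64, 8)
        x = readout_to_tensor(h, full_kmer_universe(3))
        assert x.shape == (8, 64)

    def test_permutation_invariance(self, rng):
        labels = full_kmer_universe(2)
        h = rng.standard_normal((16, 4))
        perm = rng.permutation(16)
        x1 = readout_to_tensor(h, labels)
        x2 = readout_to_tensor(h[perm], [labels[i] for i in perm])
        np.testing.assert_array_equal(x1, x2)

    def test_all_zero_passthrough(self):
        x = readout_to_tensor(np.zeros((16, 2)), full_kmer_universe(2))
        assert not x.any()

    def test_observed_universe_rejected(self):
        with pytest.raises(ValueError, match="full fixed"):
            readout_to_tensor(np.zeros((3, 2)), ["AA", "AC", "GT"])


class TestConvStack:
    def test_identity_kernel_single_channel(self):
        x = np.linspace(-1, 1, 10).reshape(1, 10)
        ident = np.zeros((1, 1, 3))
        ident[0, 0, 1] = 1.0
        kernels = [ident, ident, ident]
        biases = [np.zeros(1)] * 3
        np.testing.assert_allclose(conv_stack(x, kernels, biases), relu(x).ravel())

    def test_zero_kernels_zero_output(self, rng):
        x = rng.standard_normal((2, 12))
        kernels = [np.zeros((3, 2, 3)), np.zeros((4, 3, 3)), np.zeros((2, 4, 3))]
        biases = [np.zeros(3), np.zeros(4), np.zeros(2)]
        assert not conv_stack(x, kernels, biases).any()

    def test_naive_sliding_window_oracle(self, rng):
        def naive_conv(x, kernel, bias):
            c_out, c_in, ks = kernel.shape
            pad = (ks - 1) // 2
            xp = np.pad(x, ((0, 0), (pad, pad)))
            out = np.zeros((c_out, x.shape[1]))
            for o in range(c_out):
                for m in range(x.shape[1]):
                    out[o, m] = np.sum(kernel[o] * xp[:, m : m + ks]) + bias[o]
            return out

        x = rng.standard_normal((3, 9))
        kernels = [rng.standard_normal((4, 3, 3)), rng.standard_normal((2, 4, 3)),
                   rng.standard_normal((3, 2, 3))]
        biases = [rng.standard_normal(4), rng.standard_normal(2), rng.standard_normal(3)]
        want = x
        for kern, b in zip(kernels, biases):
            want = np.maximum(0.0, naive_conv(want, kern, b))
        got = conv_stack(x, kernels, biases)
        np.testing.assert_allclose(got, want.ravel(), atol=1e-8)

    def test_channel_mismatch_rejected(self, rng):
        x = rng.standard_normal((2, 8))
        kernels = [np.zeros((3, 5, 3)), np.zeros((3, 3, 3)), np.zeros((3, 3, 3))]
        biases = [np.zeros(3)] * 3
        with pytest.raises(ValueError, match="channels"):
            conv_stack(x, kernels, biases)


class TestHeadForward:
    def _params_with_head(self, w1, b1, w2, b2):
        cfg = ModelConfig(n_gcn_layers=1, gcn_hidden_dims=(1,),
                          conv_channels=(1, 1, 1), fc_hidden_dim=w1.shape[0])
        p = ModelParams.initialize(cfg, k=1)
        p.W1, p.b1, p.W2, p.b2 = w1, b1, w2, b2
        return p

    def test_all_zero_weights_uniform_output(self):
        p = self._params_with_head(np.zeros((4, 3)), np.zeros(4),
                                   np.zeros((4, 2)), np.zeros(2))
        np.testing.assert_allclose(head_forward(np.ones(3), p), [0.5, 0.5])

    def test_hand_computed_softmax(self):
        # x=[2], identity first layer, logits (2, 0): softmax = e^2/(e^2+1)
        p = self._params_with_head(np.array([[1.0]]), np.zeros(1),
                                   np.array([[1.0, 0.0]]), np.zeros(2))
        out = head_forward(np.array([2.0]), p)
        np.testing.assert_allclose(out, [0.8808, 0.1192], atol=1e-4)
        # positive-class probability is the second component
        assert out[0] == pytest.approx(np.exp(2) / (np.exp(2) + 1), abs=1e-9)

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(20):
            p = self._params_with_head(rng.standard_normal((5, 4)), rng.standard_normal(5),
                                       rng.standard_normal((5, 2)), rng.standard_normal(2))
            out = head_forward(rng.standard_normal(4), p)
            assert out.sum() == pytest.approx(1.0, abs=1e-9)
            assert (out > 0).all()


class TestCrossEntropy:
    def test_uniform_predictor_is_ln2(self):
        labels = np.array([0, 1, 1, 0, 1])
        loss = cross_entropy_loss(labels, np.full(5, 0.5))
        assert loss == pytest.approx(np.log(2), abs=1e-9)

    def test_single_sample_closed_form(self):
        assert cross_entropy_loss(np.array([1]), np.array([0.25])) == \
            pytest.approx(-np.log(0.25), abs=1e-12)

    def test_perfect_prediction_near_zero(self):
        labels = np.array([1, 0])
        loss = cross_entropy_loss(labels, np.array([1.0, 0.0]))
        assert 0 <= loss <= -np.log(1 - 1e-12) + 1e-15

    def test_label_flip_symmetry(self, rng):
        labels = rng.integers(0, 2, size=30)
        p = rng.uniform(0.01, 0.99, size=30)
        assert cross_entropy_loss(labels, p) == pytest.approx(
            cross_entropy_loss(1 - labels, 1 - p), abs=1e-12
        )

    def test_balanced_weights_recover_unweighted(self, rng):
        labels = np.array([0, 1] * 10)
        p = rng.uniform(0.01, 0.99, size=20)
        assert cross_entropy_loss(labels, p, (1.0, 1.0)) == pytest.approx(
            cross_entropy_loss(labels, p)
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_entropy_loss(np.array([1, 0]), np.array([0.5]))


class TestGradientCheck:
    def test_full_model_matches_finite_differences(self, micro_batch):
        """Analytic gradients of the complete loss agree with central FD.

        Parameters are jittered before the check: zero-initialized biases sit
        exactly on the ReLU kink (pre-activation 0), where a central
        difference straddles two one-sided slopes and no gradient comparison
        is meaningful.
        """
        graphs, labels, params = micro_batch
        jitter = np.random.default_rng(99)
        params = params.from_vector(
            params.to_vector() + jitter.normal(scale=0.01, size=params.to_vector().size)
        )
        weights = (1.0, 1.3)
        _, grads = loss_and_gradients(graphs, labels, params, weights)
        vec = params.to_vector()
        gvec = grads.to_vector()
        h = 1e-6
        for i in range(vec.size):
            vp = vec.copy()
            vp[i] += h
            vm = vec.copy()
            vm[i] -= h
            fd = (
                batch_loss(graphs, labels, params.from_vector(vp), weights)
                - batch_loss(graphs, labels, params.from_vector(vm), weights)
            ) / (2 * h)
            rel = abs(fd - gvec[i]) / max(1e-8, abs(fd) + abs(gvec[i]))
            assert rel < 1e-4, f"coordinate {i}: analytic {gvec[i]}, FD {fd}"


class TestTraining:
    def _enc(self):
        return EncoderConfig(k=2, d=2)

    def _data(self, n=20, seed=2):
        return generate_dataset(GeneratorConfig(n_per_class=n, length=80, seed=seed))

    def test_zero_epochs_returns_initial_params(self, small_model_config):
        ds = self._data()
        init = ModelParams.initialize(small_model_config, k=2)
        params, log = train_model(ds, None, self._enc(), small_model_config,
                                  TrainConfig(epochs=0))
        np.testing.assert_array_equal(params.to_vector(), init.to_vector())
        assert len(log) == 0

    def test_same_seed_identical_logs(self, small_model_config):
        ds = self._data()
        tcfg = TrainConfig(epochs=3, batch_size=8, seed=5)
        _, log1 = train_model(ds, ds, self._enc(), small_model_config, tcfg)
        _, log2 = train_model(ds, ds, self._enc(), small_model_config, tcfg)
        assert log1.equals(log2)

    def test_loss_decreases_on_strong_signal(self, small_model_config):
        ds = generate_dataset(GeneratorConfig(n_per_class=30, length=150, seed=8))
        _, log = train_model(ds, None, self._enc(), small_model_config,
                             TrainConfig(epochs=15, batch_size=16, seed=1))
        assert log["train_loss"].iloc[-1] < log["train_loss"].iloc[0]

    def test_single_class_training_rejected(self, small_model_config):
        recs = [LabeledSequence(f"p{i}", "ACGTACGTACGT", 1) for i in range(10)]
        with pytest.raises(ValueError, match="both classes"):
            train_model(Dataset(records=recs), None, self._enc(),
                        small_model_config, TrainConfig(epochs=1))

    def test_early_stopping_restores_best(self, small_model_config):
        ds = self._data(n=15)
        tcfg = TrainConfig(epochs=30, batch_size=8, seed=3, early_stopping_patience=3)
        _, log = train_model(ds, ds, self._enc(), small_model_config, tcfg)
        assert len(log) <= 30


class TestPredict:
    def test_zero_weight_model_scores_half_and_negative(self, small_model_config):
        ds = generate_dataset(GeneratorConfig(n_per_class=3, length=50, seed=1))
        params = ModelParams.initialize(small_model_config, k=2)
        for t in params._tensors():
            t[...] = 0.0
        scores, hard = predict(ds, EncoderConfig(k=2, d=2), params)
        np.testing.assert_allclose(scores, 0.5)
        assert not hard.any()  # ties break toward the negative class

    def test_scores_in_open_unit_interval(self, micro_batch, small_model_config):
        ds = generate_dataset(GeneratorConfig(n_per_class=5, length=60, seed=4))
        params = ModelParams.initialize(small_model_config, k=2)
        scores, _ = predict(ds, EncoderConfig(k=2, d=2), params)
        assert ((scores > 0) & (scores < 1)).all()

    def test_record_order_invariance(self, small_model_config):
        ds = generate_dataset(GeneratorConfig(n_per_class=4, length=60, seed=9))
        params = ModelParams.initialize(small_model_config, k=2)
        enc = EncoderConfig(k=2, d=2)
        scores, _ = predict(ds, enc, params)
        rev = Dataset(records=list(reversed(ds.records)))
        scores_rev, _ = predict(rev, enc, params)
        np.testing.assert_allclose(scores, scores_rev[::-1], atol=1e-12)

    def test_encoder_mismatch_rejected(self, small_model_config):
        ds = generate_dataset(GeneratorConfig(n_per_class=2, length=50, seed=1))
        params = ModelParams.initialize(small_model_config, k=2)
        with pytest.raises(ValueError, match="does not match"):
            predict(ds, EncoderConfig(k=3, d=2), params)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, small_model_config):
        params = ModelParams.initialize(small_model_config, k=2)
        enc = EncoderConfig(k=2, d=2)
        path = tmp_path / "model.npz"
        save_checkpoint(path, params, enc)
        loaded, enc2 = load_checkpoint(path)
        np.testing.assert_array_equal(loaded.to_vector(), params.to_vector())
        assert enc2 == enc
        assert loaded.config.hidden_dims == params.config.hidden_dims
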
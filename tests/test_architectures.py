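"""Tests for the task-level architectures and minimum-spiking inference."""

import numpy as np
import pytest

from gtnn.architectures import (
    DomainDescriptor,
    GTLinearClassifier,
    LabelCodec,
    MultiLayerGTClassifier,
    _argmin_prediction,
)
from gtnn.core import NeuronConfig
from gtnn.datasets import LabeledDataset, gen_blobs2d, gen_xor, scale01
from gtnn.learning import TrainConfig

NCFG = NeuronConfig(alpha=0.1, T_settle=300, T_avg=500)
FAST = dict(per_sample_windows=(300, 500), shuffle=True)


class TestLabelCodec:
    def test_binary_scalar(self):
        c = LabelCodec([-1, 1])
        assert c.P == 1
        assert c.encode(-1)[0] == -1.0 and c.encode(1)[0] == 1.0

    def test_multiclass_onehot(self):
        c = LabelCodec([0, 1, 2])
        assert c.P == 3
        v = c.encode(1)
        assert v[1] == 1.0 and v[0] == v[2] == -1.0

    def test_forced_onehot_binary(self):
        c = LabelCodec([-1, 1], force_onehot=True)
        assert c.P == 2

    def test_rejects_single_class(self):
        with pytest.raises(ValueError):
            LabelCodec([3])


class TestPrediction:
    def test_argmin_and_margin(self):
        p = _argmin_prediction([0, 1, 2], np.array([0.3, 0.1, 0.5]))
        assert p.label == 1
        assert p.margin == pytest.approx(0.2)

    def test_tie_breaks_to_smallest_class(self):
        p = _argmin_prediction([0, 1], np.array([0.2, 0.2]))
        assert p.label == 0
        assert p.margin == 0.0

    def test_zero_count_candidate_wins(self):
        p = _argmin_prediction([-1, 1], np.array([0.0, 0.4]))
        assert p.label == -1


@pytest.fixture(scope="module")
def blobs():
    data = gen_blobs2d(n_per_class=30, separation=2.0, noise=0.25, seed=4)
    sc = scale01(LabeledDataset(data.X, data.y))
    return sc.X, data.y


@pytest.fixture(scope="module")
def trained_linear(blobs):
    X, y = blobs
    clf = GTLinearClassifier(2, "feed_forward", neuron_config=NCFG)
    cfg = TrainConfig(eta=0.05, epochs=10, seed=0, **FAST)
    clf.fit(X, y, cfg, track=False)
    return clf, X, y


class TestLinearClassifier:
    def test_feed_forward_mask_scope(self):
        clf = GTLinearClassifier(3, "feed_forward", neuron_config=NCFG)
        clf.fit(np.zeros((2, 3)), [-1, 1], TrainConfig(eta=0.0, epochs=1), track=False)
        mask = clf.layer.net.mask
        assert mask[:1, 1:].all() and not mask[1:, :].any()

    def test_learns_separable_blobs(self, trained_linear):
        clf, X, y = trained_linear
        assert clf.score(X, y) == 1.0

    def test_label_flip_symmetry(self, trained_linear):
        """The +-1 encoding is symmetric: flipped labels flip decisions."""
        clf, X, y = trained_linear
        clf2 = GTLinearClassifier(2, "feed_forward", neuron_config=NCFG)
        cfg = TrainConfig(eta=0.05, epochs=10, seed=0, **FAST)
        clf2.fit(X, -np.asarray(y), cfg, track=False)
        assert np.array_equal(clf2.predict_labels(X), -clf.predict_labels(X))

    def test_inference_deterministic(self, trained_linear):
        clf, X, _ = trained_linear
        p1, p2 = clf.predict(X[:5]), clf.predict(X[:5])
        for a, b in zip(p1, p2):
            assert a.label == b.label
            assert np.array_equal(a.rho_per_candidate, b.rho_per_candidate)

    def test_ff_inference_scope_is_output_pair(self, trained_linear):
        clf, X, _ = trained_linear
        Y = np.repeat([[1.0]], 3, axis=0)
        rho_var = clf._rho_batch(X[:3], Y, scope="variant")
        rho_net = clf._rho_batch(X[:3], Y, scope="network")
        # output-pair rho is normalized by 2 neurons, network by 2M
        assert rho_var.shape == (3,)
        assert not np.allclose(rho_var, rho_net)

    def test_rho_in_unit_interval(self, trained_linear):
        clf, X, y = trained_linear
        for p in clf.predict(X[:10]):
            assert np.all((0 <= p.rho_per_candidate) & (p.rho_per_candidate <= 1))

    def test_rejects_nonbinary(self):
        clf = GTLinearClassifier(2)
        with pytest.raises(ValueError):
            clf.fit(np.zeros((3, 2)), [0, 1, 2], TrainConfig(eta=0.1, epochs=1))

    def test_untrained_predict_raises(self):
        with pytest.raises(RuntimeError):
            GTLinearClassifier(2).predict(np.zeros((1, 2)))


class TestDomainDescriptor:
    def test_single_point_threshold(self):
        x = np.array([[0.5, 0.5]])
        dd = DomainDescriptor(2, seed=0,
                              train_config=TrainConfig(eta=0.1, epochs=60, seed=0,
                                                       per_sample_windows=(400, 600)))
        dd.fit(x, reject_frac=0.0)
        assert dd.threshold == pytest.approx(dd.train_rates[0])
        labels, _ = dd.predict(x)
        assert labels[0] == "member"  # boundary is inclusive

    def test_far_point_is_anomaly(self):
        rng = np.random.default_rng(0)
        X = rng.normal([0.6, 0.6], 0.05, (15, 2))
        dd = DomainDescriptor(2, seed=1)
        dd.fit(X, reject_frac=0.0)
        labels, rho_far = dd.predict(np.array([[0.05, 0.05]]))
        assert labels[0] == "anomaly"
        assert rho_far[0] > dd.threshold

    def test_unscaled_input_warns(self):
        dd = DomainDescriptor(2, seed=0,
                              train_config=TrainConfig(eta=0.1, epochs=5, seed=0,
                                                       per_sample_windows=(200, 300)))
        dd.fit(np.array([[0.5, 0.5]]))
        with pytest.warns(UserWarning):
            dd.predict(np.array([[5.0, 5.0]]))

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            DomainDescriptor(2).fit(np.empty((0, 2)))


class TestMultiLayer:
    def test_network1_feature_is_negative_l1_distance(self):
        m = MultiLayerGTClassifier(1, 2, [-1, 1], S=3, seed=0,
                                   neuron_config=NeuronConfig.fine(), random_scale=0.05)
        x = np.array([[0.3, 0.7]])
        F, _ = m.layer1_features(x)
        for s, net in enumerate(m.subnets):
            c_s = net.Q @ net.t
            expected = -np.abs(c_s - x[0]).sum()
            assert F[0, s] == pytest.approx(expected, abs=0.1)

    def test_network1_layer1_immutable(self):
        data = gen_xor(5, noise=0.1, seed=0)
        sc = scale01(LabeledDataset(data.X, data.y))
        m = MultiLayerGTClassifier(1, 2, [-1, 1], S=4, seed=0, neuron_config=NCFG)
        before = [n.Q.copy() for n in m.subnets]
        cfg = TrainConfig(eta=0.05, epochs=2, seed=0, **FAST)
        m.fit(sc.X, data.y, cfg, track=False)
        for Q0, net in zip(before, m.subnets):
            assert np.array_equal(Q0, net.Q)

    def test_layer1_feature_dimensions(self):
        m2 = MultiLayerGTClassifier(2, 16, list(range(6)), S=20, seed=0, neuron_config=NCFG)
        F, _ = m2.layer1_features(np.zeros((1, 16)))
        assert F.shape == (1, 320)
        m1 = MultiLayerGTClassifier(1, 16, [0, 1], S=50, seed=0, neuron_config=NCFG)
        F1, _ = m1.layer1_features(np.zeros((1, 16)))
        assert F1.shape == (1, 50)

    def test_layer1_zero_input_zero_features(self):
        m = MultiLayerGTClassifier(2, 3, [-1, 1], S=2, seed=0,
                                   neuron_config=NCFG, random_scale=0.0)
        F, counts = m.layer1_features(np.zeros((1, 3)))
        assert np.allclose(F, 0.0, atol=1e-9)
        assert counts[0] == 0.0

    def test_layer1_features_bounded(self):
        m = MultiLayerGTClassifier(3, 2, [-1, 1], S=4, seed=1, neuron_config=NCFG)
        Y = np.array([[1.0]])
        F, _ = m.layer1_features(np.array([[0.4, 0.9]]), Y)
        assert np.all(np.abs(F) <= m.neuron_config.v_c + 1e-9)

    def test_kind3_requires_labels_for_features(self):
        m = MultiLayerGTClassifier(3, 2, [-1, 1], S=2, seed=0, neuron_config=NCFG)
        with pytest.raises(ValueError):
            m.layer1_features(np.zeros((1, 2)))

    def test_invalid_kind_and_schedule(self):
        with pytest.raises(ValueError):
            MultiLayerGTClassifier(4, 2, [-1, 1])
        m = MultiLayerGTClassifier(2, 2, [-1, 1], S=2, seed=0, neuron_config=NCFG)
        with pytest.raises(ValueError):
            m.fit(np.zeros((2, 2)), [-1, 1], TrainConfig(eta=0.1, epochs=1),
                  schedule=(-1, 2))

    def test_rho_additivity_across_layers(self):
        """Model rho equals the count-weighted mean of per-layer rhos."""
        m = MultiLayerGTClassifier(2, 2, [-1, 1], S=3, seed=2, neuron_config=NCFG)
        X = np.array([[0.2, 0.8]])
        Y = np.array([[1.0]])
        F, counts1 = m.layer1_features(X)
        from gtnn.core import simulate_batch

        ss = simulate_batch(m.top.net, m.top.stimuli(Y, F * m.feature_scale))
        counts2 = (ss.s_plus + ss.s_minus).sum(axis=1)
        rho1 = counts1[0] / (2 * m.M_layer1)
        rho2 = counts2[0] / (2 * m.top.M)
        expected = (rho1 * m.M_layer1 + rho2 * m.top.M) / m.M_total
        assert m._rho_all_layers(X, Y)[0] == pytest.approx(expected, rel=1e-12)


class TestSequences:
    def test_constant_sequence_equals_static_fit(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.2, 0.8, (6, 1, 3))
        const = np.repeat(X, 4, axis=1)
        y = np.array([0, 1, 0, 1, 0, 1])
        kw = dict(S=2, seed=3, neuron_config=NCFG, random_scale=0.5)
        cfg = TrainConfig(eta=0.05, epochs=1, seed=0, per_sample_windows=(300, 500))
        m1 = MultiLayerGTClassifier(3, 3, [0, 1], **kw)
        m1.fit_sequences(const, y, cfg, schedule=(2, 0))
        m2 = MultiLayerGTClassifier(3, 3, [0, 1], **kw)
        m2.fit(const[:, 0, :], y, cfg, schedule=(2, 0), track=False)
        assert np.array_equal(m1.layer1.Q, m2.layer1.Q)
        assert np.array_equal(m1.top.net.Q, m2.top.net.Q)

    def test_sequence_mode_needs_kind3(self):
        m = MultiLayerGTClassifier(2, 3, [0, 1], S=2, seed=0, neuron_config=NCFG)
        with pytest.raises(ValueError):
            m.fit_sequences(np.zeros((2, 4, 3)), [0, 1], TrainConfig(eta=0.1, epochs=1))

    def test_ragged_shape_rejected(self):
        m = MultiLayerGTClassifier(3, 3, [0, 1], S=2, seed=0, neuron_config=NCFG)
        with pytest.raises(ValueError):
            m.fit_sequences(np.zeros((2, 4, 5)), [0, 1], TrainConfig(eta=0.1, epochs=1))


class TestSerialization:
    def test_linear_roundtrip(self, trained_linear, tmp_path):
        from gtnn.io import load_model, save_model

        clf, X, y = trained_linear
        path = tmp_path / "model.json"
        save_model(clf, path)
        clf2 = load_model(path)
        assert np.array_equal(clf2.layer.net.Q, clf.layer.net.Q)
        assert np.array_equal(clf2.predict_labels(X[:5]), clf.predict_labels(X[:5]))

    def test_multilayer_roundtrip(self, tmp_path):
        from gtnn.io import load_model, save_model

        m = MultiLayerGTClassifier(3, 2, [-1, 1], S=2, seed=0, neuron_config=NCFG)
        path = tmp_path / "ml.json"
        save_model(m, path)
        m2 = load_model(path)
        assert m2.kind == 3 and m2.S == 2
        assert np.array_equal(m2.layer1.Q, m.layer1.Q)

    def test_network_checkpoint_roundtrip(self, tmp_path):
        from gtnn.core import DifferentialNetwork
        from gtnn.io import load_network, save_network

        net = DifferentialNetwork.random_coupled(3, scale=0.3, seed=4,
                                                 t=np.array([0.1, 0.2, 0.3]))
        p = tmp_path / "net.json"
        save_network(net, p)
        back = load_network(p)
        assert np.array_equal(back.Q, net.Q)
        assert np.array_equal(back.mask, net.mask)
        assert np.array_equal(back.t, net.t)
        assert back.config == net.config

    def test_domain_roundtrip(self, tmp_path):
        from gtnn.io import load_model, save_model

        dd = DomainDescriptor(2, seed=0,
                              train_config=TrainConfig(eta=0.1, epochs=5, seed=0,
                                                       per_sample_windows=(200, 300)))
        dd.fit(np.array([[0.5, 0.5], [0.6, 0.4]]))
        path = tmp_path / "dd.json"
        save_model(dd, path)
        dd2 = load_model(path)
        assert dd2.threshold == dd.threshold
        assert np.array_equal(dd2.net.Q, dd.net.Q)
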
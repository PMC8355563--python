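"""Unit and property tests for the GT neuron dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtnn.core import (
    DifferentialNetwork,
    NetworkState,
    NeuronConfig,
    gt_step,
    local_gradient,
    relu_curve,
    simulate,
    simulate_batch,
    spike_fn,
)


class TestSpikeFn:
    @pytest.mark.parametrize(
        "v,I,expected",
        [(0.5, 1.0, 1.0), (-0.3, 1.0, 0.0), (0.0, 1.0, 0.0), (1e-12, 2.5, 2.5)],
    )
    def test_barrier_branches(self, v, I, expected):
        assert spike_fn(v, I) == expected

    def test_rejects_nonpositive_height(self):
        with pytest.raises(ValueError):
            spike_fn(0.5, 0.0)

    def test_vectorized(self):
        out = spike_fn(np.array([-1.0, 0.0, 0.1]), 1.0)
        assert np.array_equal(out, [0.0, 0.0, 1.0])


class TestGtStep:
    @pytest.mark.parametrize(
        "v,g,lam,vc,expected",
        [
            (0.3, 0.0, 2.0, 1.0, 0.3),  # zero gradient is a fixed point
            (1.0, 0.7, 2.0, 1.0, 1.0),  # the bound is a fixed point of the map
            (0.0, -0.5, 2.0, 1.0, 0.25),  # hand evaluation of the map
        ],
    )
    def test_map_values(self, v, g, lam, vc, expected):
        assert gt_step(v, g, lam, vc) == pytest.approx(expected, abs=1e-12)

    def test_rejects_small_lambda(self):
        with pytest.raises(ValueError):
            gt_step(0.0, 1.5, 1.0, 1.0)

    @settings(max_examples=200, deadline=None)
    @given(
        v=st.floats(-1.0, 1.0),
        g=st.floats(-1.9, 1.9),
        lam=st.floats(2.0, 50.0),
    )
    def test_bound_and_descent(self, v, g, lam):
        """The map keeps |v| <= v_c and moves opposite to the gradient."""
        out = gt_step(v, g, lam, 1.0)
        assert abs(out) <= 1.0 + 1e-12
        # direction check away from the bound, where the step is
        # resolvable in floating point
        if abs(v) < 1.0 - 1e-9 and abs(g) > 1e-6:
            assert np.sign(out - v) == np.sign(-g)


class TestLocalGradient:
    def test_isolated_pair(self):
        net = DifferentialNetwork.uncoupled(1, b=[0.5])
        state = NetworkState.zeros(1)
        assert local_gradient(net, state, 0, +1) == pytest.approx(-0.5)
        state.psi_plus[0] = 1.0
        assert local_gradient(net, state, 0, +1) == pytest.approx(0.5)

    def test_coupled_input(self):
        Q = np.array([[1.0, 0.4], [0.0, 1.0]])
        net = DifferentialNetwork(Q, b=np.array([0.5, 0.0]))
        state = NetworkState.zeros(2)
        state.v_plus[1] = 0.5  # v+_2 - v-_2 = 0.5
        assert local_gradient(net, state, 0, +1) == pytest.approx(-0.3)

    def test_index_error(self):
        net = DifferentialNetwork.uncoupled(1)
        with pytest.raises(IndexError):
            local_gradient(net, NetworkState.zeros(1), 3, +1)


class TestSimulate:
    def test_positive_input_solution(self):
        """ON pair spikes at rate b; OFF side holds v = -b silently."""
        net = DifferentialNetwork.uncoupled(1, b=[0.5])
        _, _, ss = simulate(net)
        tol = 2.0 / net.config.T_avg + 0.01
        assert ss.psi_bar_plus[0] == pytest.approx(0.5, abs=tol)
        assert ss.v_bar_plus[0] == pytest.approx(0.0, abs=0.05)
        assert ss.v_bar_minus[0] == pytest.approx(-0.5, abs=0.05)
        assert ss.psi_bar_minus[0] == 0.0

    def test_negative_input_mirror(self):
        net = DifferentialNetwork.uncoupled(1, b=[-0.5])
        _, _, ss = simulate(net)
        assert ss.psi_bar_plus[0] == 0.0
        assert ss.psi_bar_minus[0] == pytest.approx(0.5, abs=0.01)
        assert ss.v_bar_plus[0] == pytest.approx(-0.5, abs=0.05)

    def test_zero_input_silent(self):
        net = DifferentialNetwork.uncoupled(1, b=[0.0])
        _, _, ss = simulate(net)
        assert ss.total_spike_fraction == 0.0
        assert abs(ss.v_bar_plus[0]) < 1e-9

    def test_bound_and_barrier_consistency(self):
        """|v| <= v_c at every recorded step; spikes iff v > 0."""
        net = DifferentialNetwork.random_coupled(3, scale=0.3, seed=5)
        net.b = np.array([0.5, -0.4, 0.2])
        _, trace, _ = simulate(net, record=True)
        assert np.all(np.abs(trace.v_plus_hist) <= net.config.v_c + 1e-12)
        assert np.all(np.abs(trace.v_minus_hist) <= net.config.v_c + 1e-12)
        # every + event coincides with v_plus > 0 at that step
        ev = trace.spike_events
        plus = ev[ev[:, 2] > 0]
        assert np.all(trace.v_plus_hist[plus[:, 0], plus[:, 1]] > 0)
        # and count matches
        assert len(plus) == int((trace.v_plus_hist > 0).sum())

    def test_determinism_bit_identical(self):
        net = DifferentialNetwork.random_coupled(4, scale=0.2, seed=9)
        net.b = np.linspace(-0.5, 0.5, 4)
        _, tr1, ss1 = simulate(net, record=True)
        _, tr2, ss2 = simulate(net, record=True)
        assert np.array_equal(tr1.v_plus_hist, tr2.v_plus_hist)
        assert np.array_equal(ss1.s_plus, ss2.s_plus)

    def test_spike_count_grid(self):
        """Normalized counts sit on the 1/T_avg grid exactly."""
        net = DifferentialNetwork.uncoupled(2, b=[0.37, -0.61])
        _, _, ss = simulate(net)
        for s in (ss.s_plus, ss.s_minus):
            assert np.all(np.abs(s * ss.window - np.round(s * ss.window)) < 1e-9)
            assert np.all((0 <= s) & (s <= 1))

    def test_batch_matches_single(self):
        net = DifferentialNetwork.random_coupled(3, scale=0.2, seed=3)
        B = np.array([[0.5, -0.2, 0.1], [0.0, 0.3, -0.4]])
        ssb = simulate_batch(net, B)
        for i in range(2):
            _, _, ss = simulate(net, b=B[i])
            assert np.array_equal(ssb.s_plus[i], ss.s_plus)
            assert np.allclose(ssb.v_bar_minus[i], ss.v_bar_minus, rtol=0, atol=0)

    def test_steady_state_first_order_condition(self):
        """psi_bar + Q_self v_bar tracks the effective input per neuron."""
        cfg = NeuronConfig.fine()
        rng = np.random.default_rng(2)
        net = DifferentialNetwork.random_coupled(4, scale=0.2, seed=11, config=cfg)
        net.b = rng.uniform(-0.6, 0.6, 4)
        _, _, ss = simulate(net)
        off = net.Q - np.diag(np.diag(net.Q))
        beta = net.b - off @ ss.v_bar
        resid = ss.psi_bar_plus + net.config.Q_self * ss.v_bar_plus - beta
        tol = 2 / cfg.T_avg + 0.05 * max(1.0, np.abs(beta).max())
        assert np.all(np.abs(resid) <= tol)


class TestReluCurve:
    def test_small_leakage_tracks_relu(self):
        psi = relu_curve([0.5], Q_self=0.01)
        assert psi[0] == pytest.approx(0.5, abs=0.01)

    def test_negative_input_silent(self):
        assert relu_curve([-0.5], Q_self=0.5)[0] == 0.0

    def test_error_shrinks_with_leakage(self):
        b = np.linspace(0.05, 0.85, 9)
        relu = np.maximum(b, 0)
        e1 = np.abs(relu_curve(b, 0.1) - relu).max()
        e2 = np.abs(relu_curve(b, 0.01) - relu).max()
        assert e2 < e1

    def test_rejects_nonpositive_leakage(self):
        with pytest.raises(ValueError):
            relu_curve([0.1], 0.0)


class TestConfigAndTypes:
    @pytest.mark.parametrize(
        "kw",
        [
            {"v_c": 0.0},
            {"I_psi": -1.0},
            {"lambda_margin": 1.0},
            {"T_avg": 0},
            {"Q_self": 0.0},
            {"alpha": 0.0},
        ],
    )
    def test_config_validation(self, kw):
        with pytest.raises(ValueError):
            NeuronConfig(**kw)

    def test_config_json_roundtrip(self):
        cfg = NeuronConfig(v_c=2.0, T_avg=500, alpha=0.25)
        assert NeuronConfig.from_json(cfg.to_json()) == cfg

    def test_network_diagonal_pinned(self):
        Q = np.full((3, 3), 0.7)
        net = DifferentialNetwork(Q)
        assert np.all(np.diag(net.Q) == net.config.Q_self)
        assert not net.mask.diagonal().any()

    def test_trace_exports(self):
        net = DifferentialNetwork.uncoupled(2, b=[0.5, -0.3])
        _, trace, ss = simulate(net, T=300, record=True)
        ev = trace.to_events_frame()
        assert set(ev.columns) == {"step", "pair_index", "polarity"}
        dense = trace.to_membrane_frame()
        assert len(dense) == 300
        assert "residual_l1" in ss.to_json()
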
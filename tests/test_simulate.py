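"""Memory-kernel integrators against brute-force transcriptions and reductions."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

from fdneuron.frac_calc import OrderSpec
from fdneuron.model import NeuronParams, apply_reset, resolve_preset, rhs
from fdneuron.simulate import (
    SimConfig,
    System,
    integrate,
    neuron_system,
    simulate_commensurate,
    simulate_incommensurate,
    simulate_variable_order,
    vo_presets,
)


def classical_iteration(params, config, variant, steps):
    """Independent direct iteration of the one-step map (with resets)."""
    z = config.initial_state(params)
    out = [z.copy()]
    spikes = []
    for n in range(1, steps + 1):
        f = np.array(rhs((z[0], z[1]), params, variant))
        z = z + f
        (x, y), spiked = apply_reset((z[0], z[1]), params)
        z = np.array([x, y])
        if spiked:
            spikes.append(n)
        out.append(z.copy())
    return np.array(out), spikes


def w(k, beta):
    return math.exp(gammaln(k + beta) - gammaln(beta) - gammaln(k + 1))


class TestBetaOneReduction:
    """At order 1 every scheme collapses to the classical one-step map."""

    def test_commensurate(self, b1_I4):
        cfg = SimConfig(steps=200)
        traj = simulate_commensurate(b1_I4, 1.0, cfg)
        ref, spikes = classical_iteration(b1_I4, cfg, "difference", 200)
        assert traj.resets > 0  # the reduction holds through resets
        np.testing.assert_allclose(traj.states, ref, atol=1e-10)
        assert traj.spikes.tolist() == spikes

    def test_incommensurate(self, b1_I4):
        cfg = SimConfig(steps=200)
        traj = simulate_incommensurate(b1_I4, 1.0, 1.0, cfg)
        ref, _ = classical_iteration(b1_I4, cfg, "direct", 200)
        np.testing.assert_allclose(traj.states, ref, atol=1e-10)

    def test_variable_order_clipped_to_one(self, b1_I4):
        cfg = SimConfig(steps=200)
        traj = simulate_variable_order(b1_I4, vo_presets("exp_plus"), cfg)
        ref, _ = classical_iteration(b1_I4, cfg, "direct", 200)
        np.testing.assert_allclose(traj.states, ref, atol=1e-10)


class TestBruteForceOracles:
    """Short runs against literal double-loop transcriptions of the schemes."""

    def test_commensurate(self, b1):
        beta, steps = 0.7, 5
        cfg = SimConfig(steps=steps, apply_reset=False)
        traj = simulate_commensurate(b1, beta, cfg)
        z0 = cfg.initial_state(b1)
        X, Y = [z0[0]], [z0[1]]
        for n in range(1, steps + 1):
            sx = sy = 0.0
            for j in range(1, n + 1):
                fx, fy = rhs((X[j - 1], Y[j - 1]), b1, "difference")
                sx += w(n - j, beta) * fx
                sy += w(n - j, beta) * fy
            X.append(z0[0] + sx)
            Y.append(z0[1] + sy)
        m = len(traj.states)
        np.testing.assert_allclose(traj.x, X[:m], rtol=1e-12)
        np.testing.assert_allclose(traj.y, Y[:m], rtol=1e-12)

    def test_incommensurate(self, b1):
        b1o, b2o, steps = 0.9, 0.6, 4
        cfg = SimConfig(steps=steps, apply_reset=False)
        traj = simulate_incommensurate(b1, b1o, b2o, cfg)
        z0 = cfg.initial_state(b1)
        X, Y = [z0[0]], [z0[1]]
        for n in range(1, steps + 1):
            sx = sy = 0.0
            for j in range(n):
                fx, fy = rhs((X[j], Y[j]), b1, "direct")
                sx += w(n - 1 - j, b1o) * fx
                sy += w(n - 1 - j, b2o) * fy
            X.append(z0[0] + sx)
            Y.append(z0[1] + sy)
        m = len(traj.states)
        np.testing.assert_allclose(traj.x, X[:m], rtol=1e-12)
        np.testing.assert_allclose(traj.y, Y[:m], rtol=1e-12)

    def test_variable_order_source_attached(self, b1):
        beta_fn = lambda r: 0.5 + 0.4 * math.exp(-0.3 * r)
        steps = 4
        cfg = SimConfig(steps=steps, apply_reset=False)
        traj = simulate_variable_order(b1, beta_fn, cfg)
        z0 = cfg.initial_state(b1)
        X, Y = [z0[0]], [z0[1]]
        for n in range(1, steps + 1):
            sx = sy = 0.0
            for j in range(n):
                bj = beta_fn(j)  # order travels with the source index
                fx, fy = rhs((X[j], Y[j]), b1, "direct")
                sx += w(n - 1 - j, bj) * fx
                sy += w(n - 1 - j, bj) * fy
            X.append(z0[0] + sx)
            Y.append(z0[1] + sy)
        m = len(traj.states)
        np.testing.assert_allclose(traj.x, X[:m], rtol=1e-12)
        np.testing.assert_allclose(traj.y, Y[:m], rtol=1e-12)


class TestSchemeConsistency:
    def test_incommensurate_equal_orders_matches_commensurate_direct(self, b1):
        cfg = SimConfig(steps=80, variant="direct")
        a = simulate_commensurate(b1, 0.8, cfg)
        b = simulate_incommensurate(b1, 0.8, 0.8, cfg)
        np.testing.assert_allclose(a.states, b.states, atol=1e-10)

    def test_constant_vo_matches_incommensurate(self, b1):
        cfg = SimConfig(steps=80)
        a = simulate_variable_order(b1, lambda r: 0.8, cfg)
        b = simulate_incommensurate(b1, 0.8, 0.8, cfg)
        np.testing.assert_allclose(a.states, b.states, atol=1e-12)

    def test_zero_rhs_constant_trajectory(self):
        sys_ = System(rhs=lambda z: np.zeros(2), dim=2)
        traj = integrate(sys_, OrderSpec.commensurate(0.7), 50, np.array([1.0, -2.0]))
        np.testing.assert_array_equal(traj.states, np.tile([1.0, -2.0], (51, 1)))

    def test_order_swap_symmetry(self):
        # symmetric engineered system: swapping the two orders swaps x and y
        sys_ = System(rhs=lambda z: np.array([0.1 * z[1], 0.1 * z[0]]), dim=2)
        z0 = np.array([1.0, 1.0])
        a = integrate(sys_, OrderSpec.incommensurate(0.9, 0.5), 40, z0)
        b = integrate(sys_, OrderSpec.incommensurate(0.5, 0.9), 40, z0)
        np.testing.assert_allclose(a.states[:, 0], b.states[:, 1], atol=1e-12)
        np.testing.assert_allclose(a.states[:, 1], b.states[:, 0], atol=1e-12)


class TestMemoryAndDivergence:
    def test_truncation_exact_when_window_covers_run(self, b1):
        full = simulate_commensurate(b1, 0.8, SimConfig(steps=60))
        trunc = simulate_commensurate(b1, 0.8, SimConfig(steps=60, memory=60))
        np.testing.assert_array_equal(full.states, trunc.states)

    def test_truncation_error_grows_as_window_shrinks(self):
        # measured on a smooth linear fractional relaxation, where the
        # discarded tail contributes coherently
        A = np.array([[-0.5, 0.2], [0.1, -0.3]])
        sys_ = System(rhs=lambda z: A @ z, dim=2)
        z0 = np.array([1.0, -1.0])
        spec = OrderSpec.commensurate(0.6)
        full = integrate(sys_, spec, 200, z0)
        errs = []
        for L in (150, 100, 50, 20, 10, 5, 2):
            t = integrate(sys_, spec, 200, z0, memory=L)
            errs.append(np.abs(t.states - full.states).max())
        assert errs[0] > 0
        assert all(a <= b for a, b in zip(errs, errs[1:]))

    def test_divergence_recorded_not_raised(self, b1):
        traj = simulate_commensurate(b1, 0.7, SimConfig(steps=50, apply_reset=False))
        assert traj.n0 is not None
        assert np.abs(traj.states[traj.n0]).max() >= 1e8
        assert np.all(np.abs(traj.states[: traj.n0, 0]) < 1e8)

    def test_determinism(self, b1_I4):
        cfg = SimConfig(steps=300, seed=7)
        a = simulate_commensurate(b1_I4, 0.9, cfg)
        b = simulate_commensurate(b1_I4, 0.9, cfg)
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_array_equal(a.spikes, b.spikes)


class TestSpikeBookkeeping:
    def test_resets_equal_spikes_and_post_state(self, b1_I4):
        traj = simulate_commensurate(b1_I4, 0.9, SimConfig(steps=400))
        assert traj.resets == len(traj.spikes) > 0
        np.testing.assert_array_equal(traj.states[traj.spikes, 0],
                                      np.full(traj.resets, b1_I4.psi))

    def test_memory_restart_mode_differs(self, b1_I4):
        a = simulate_commensurate(b1_I4, 0.9, SimConfig(steps=300))
        b = simulate_commensurate(b1_I4, 0.9,
                                  SimConfig(steps=300, reset_mode="memory-restart"))
        assert not np.array_equal(a.states, b.states)
        # but both respect the reset rule
        np.testing.assert_array_equal(b.states[b.spikes, 0],
                                      np.full(b.resets, b1_I4.psi))


class TestBetaContinuity:
    def test_near_one_close_to_classical_before_resets(self):
        p = resolve_preset("B1", I=3.5)
        cfg = SimConfig(steps=50)
        a = simulate_commensurate(p, 0.999, cfg)
        b = simulate_commensurate(p, 1.0, cfg)
        first_spike = min([s for s in a.spikes.tolist() + b.spikes.tolist()] or [50])
        n = min(first_spike, 50)
        assert np.abs(a.states[:n] - b.states[:n]).max() < 1e-1


class TestVoPresets:
    @pytest.mark.parametrize(
        "name, r, expected",
        [
            ("logistic", 0, 0.5),
            ("cos2", 0, 0.5),
            ("tanh", 3, math.tanh(4.0)),   # ~0.99933, below 1, unclipped
            ("cos_printed", 0, 1.0),       # 9.67 clipped into (0, 1]
            ("cos_corrected", 0, (97 - 0.3) / 100),
            ("sin_pi", 1, 0.8),
            ("exp_plus", 5, 1.0),          # 1 + e^-5 clipped to 1
        ],
    )
    def test_values(self, name, r, expected):
        assert vo_presets(name)(r) == pytest.approx(expected, rel=1e-10)

    def test_unknown_lists_registry(self):
        with pytest.raises(KeyError, match="logistic"):
            vo_presets("bogus")
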
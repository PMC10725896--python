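"""Izhikevich map, fixed points, Jacobians and the fractional stability test."""

import cmath

import numpy as np
import pytest

from fdneuron.model import (
    NeuronParams,
    apply_reset,
    eigen_stability,
    fixed_points,
    hopf_analysis,
    in_stability_region,
    jacobian,
    resolve_preset,
    rhs,
    saddle_node_current,
)


class TestRhs:
    def test_direct_at_conventional_ic(self):
        p = NeuronParams(0.02, 0.2, -55, 4, I=0.0)
        fx, fy = rhs((-63.0, -12.6), p, "direct")
        assert fx == pytest.approx(-3.64, abs=1e-12)
        assert fy == pytest.approx(0.0, abs=1e-14)  # y = eta x on the nullcline

    def test_difference_subtracts_state(self):
        p = NeuronParams(0.02, 0.2, -55, 4, I=0.0)
        fx, fy = rhs((-63.0, -12.6), p, "difference")
        assert fx == pytest.approx(-3.64 + 63.0, abs=1e-12)
        assert fy == pytest.approx(12.6, abs=1e-12)

    def test_cancellation(self):
        p = NeuronParams(1.0, 0.0, -55, 0, I=-140.0)
        fx, _ = rhs((0.0, 0.0), p, "direct")
        assert fx == 0.0


class TestReset:
    def test_spike(self):
        p = NeuronParams(0.02, 0.2, -55, 4)
        (x, y), spiked = apply_reset((31.0, 0.0), p)
        assert spiked and (x, y) == (-55.0, 4.0)

    def test_below_threshold_unchanged(self):
        p = NeuronParams(0.02, 0.2, -55, 4)
        state, spiked = apply_reset((29.9, 1.0), p)
        assert not spiked and state == (29.9, 1.0)

    def test_idempotent_on_x(self):
        p = NeuronParams(0.02, 0.2, -55, 4)
        s1, _ = apply_reset((45.0, 0.0), p)
        s2, spiked = apply_reset(s1, p)
        assert not spiked and s2[0] == -55.0


class TestFixedPoints:
    def test_two_equilibria_at_I3(self, b1):
        fps = fixed_points(b1, recovery_slope=0.2)
        xs = sorted(fp.x_star for fp in fps)
        assert xs == pytest.approx([-65.0, -55.0], abs=1e-9)
        ys = sorted(fp.y_star for fp in fps)
        assert ys == pytest.approx([-13.0, -11.0], abs=1e-9)

    def test_double_root_at_I4(self, b1_I4):
        fps = fixed_points(b1_I4, recovery_slope=0.2)
        assert len(fps) == 1 and fps[0].branch == "double"
        assert fps[0].x_star == pytest.approx(-60.0, abs=1e-9)
        assert fps[0].y_star == pytest.approx(-12.0, abs=1e-9)

    def test_complex_pair_at_I10(self):
        p = resolve_preset("B1", I=10.0)
        fps = fixed_points(p, recovery_slope=0.2)
        x = [fp.x_star for fp in fps if fp.x_star.imag > 0][0]
        assert x.real == pytest.approx(-60.0, abs=1e-9)
        assert abs(x.imag) == pytest.approx(12.2474487, abs=1e-6)
        y = [fp.y_star for fp in fps if fp.y_star.imag < 0][0]
        assert abs(y.imag) == pytest.approx(2.4495, abs=1e-4)

    def test_residual_is_zero(self, b1):
        # direct-variant equilibria satisfy the nullcline system exactly
        for fp in fixed_points(b1, recovery_slope=0.2):
            fx, _ = rhs(fp.as_tuple(), b1, "direct")
            # x-nullcline uses y = slope*x, which the returned y_star obeys
            assert abs(fx) < 1e-9

    def test_difference_variant_residual(self, b1):
        for fp in fixed_points(b1, variant="difference"):
            fx, fy = rhs(fp.as_tuple(), b1, "difference")
            assert abs(fx) < 1e-9 and abs(fy) < 1e-9


class TestJacobian:
    def test_entries(self, b1_I4):
        fp = fixed_points(b1_I4, recovery_slope=0.2)[0]
        J = jacobian(fp, b1_I4)
        np.testing.assert_allclose(J, [[0.2, -1.0], [0.004, -0.02]], atol=1e-12)

    def test_simple(self):
        from fdneuron.model import FixedPoint

        J = jacobian(FixedPoint(0.0, 0.0, "plus"), NeuronParams(1.0, 0.0, -55, 0))
        np.testing.assert_allclose(J, [[5.0, -1.0], [0.0, -1.0]])

    def test_complex_entry(self):
        from fdneuron.model import FixedPoint

        J = jacobian(FixedPoint(-60 + 1j, 0.0, "plus"), NeuronParams(0.02, 0.2, -55, 4))
        assert J[0, 0].imag != 0 and J[1, 0].imag == 0 and J[1, 1].imag == 0


class TestEigenStability:
    def test_printed_eigen_chain_I3(self, b1):
        fps = fixed_points(b1, recovery_slope=0.2)
        node = [f for f in fps if f.x_star == pytest.approx(-65.0)][0]
        sad = [f for f in fps if f.x_star == pytest.approx(-55.0)][0]
        ev_node = eigen_stability(jacobian(node, b1)).eigenvalues
        assert sorted(e.real for e in ev_node) == pytest.approx(
            [-0.1740, -0.0460], abs=5e-5)
        ev_sad = eigen_stability(jacobian(sad, b1)).eigenvalues
        assert max(e.real for e in ev_sad) == pytest.approx(0.5935, abs=5e-5)

    def test_double_root_eigen_I4(self, b1_I4):
        fp = fixed_points(b1_I4, recovery_slope=0.2)[0]
        ev = eigen_stability(jacobian(fp, b1_I4)).eigenvalues
        assert sorted(e.real for e in ev) == pytest.approx([0.0, 0.18], abs=1e-9)

    def test_reproduction_chain_complex_I10(self):
        # complex equilibrium -> eigenvalue 0.1991+0.9837i -> 2 min|arg| = 2.7421
        p = resolve_preset("B1", I=10.0)
        fp = [f for f in fixed_points(p, recovery_slope=0.2) if f.x_star.imag > 0][0]
        res = eigen_stability(jacobian(fp, p))
        lead = res.eigenvalues[0]
        assert lead.real == pytest.approx(0.1991, abs=1e-4)
        assert lead.imag == pytest.approx(0.9837, abs=1e-4)
        assert 2 * res.min_abs_arg == pytest.approx(2.7421, abs=1e-4)
        assert 0.0 <= res.beta_crit <= 2.0
        assert res.beta_crit == pytest.approx(2.7421 / np.pi, abs=1e-4)

    def test_classical_shifted_disk_case(self):
        assert in_stability_region(-1.0 + 0j, 1.0)

    def test_region_at_beta1_equals_shifted_disk(self):
        re, im = np.meshgrid(np.linspace(-2.5, 1.0, 100), np.linspace(-1.8, 1.8, 100))
        for s in (re + 1j * im).ravel():
            assert in_stability_region(s, 1.0) == (abs(s + 1) < 1), s

    def test_eigen_match_characteristic_roots(self, rng):
        # eigenvalues solve s^2 - tr s + det on random matrices
        for _ in range(200):
            J = rng.normal(size=(2, 2))
            ev = eigen_stability(J).eigenvalues
            tr, det = np.trace(J), np.linalg.det(J)
            for s in ev:
                assert abs(s * s - tr * s + det) < 1e-9

    def test_ordering(self):
        ev = eigen_stability(np.diag([0.1, 0.9])).eigenvalues
        assert ev[0].real >= ev[1].real

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            eigen_stability(np.array([[np.nan, 0], [0, 1.0]]))


class TestSaddleNode:
    def test_slope_02_gives_4(self, b1):
        assert saddle_node_current(b1, 0.2) == pytest.approx(4.0, abs=1e-10)

    def test_slope_2_closed_form(self, b1):
        assert saddle_node_current(b1, 2.0) == pytest.approx(9 / 0.16 - 140, abs=1e-10)

    def test_discriminant_zero_at_returned_current(self, b1):
        for slope in (0.2, 1.0, 2.0):
            I = saddle_node_current(b1, slope)
            disc = (5 - slope) ** 2 - 4 * 0.04 * (140 + I)
            assert abs(disc) < 1e-9


class TestHopf:
    def test_critical_voltage_and_current(self):
        p = resolve_preset("B1_printed", I=-104.0)  # sigma=0.2, eta=2
        h = hopf_analysis(p)
        assert h.x_star_crit == pytest.approx(-60.0, abs=1e-12)
        assert h.I_critical == pytest.approx(-104.0, abs=1e-9)

    def test_pure_imaginary_pair_at_critical(self):
        p = resolve_preset("B1_printed", I=-104.0)
        h = hopf_analysis(p)
        assert h.g1_coeffs[1] == pytest.approx(0.0, abs=1e-12)
        assert h.g1_coeffs[2] == pytest.approx(0.36, abs=1e-12)
        assert sorted(e.imag for e in h.eigen_at_crit) == pytest.approx([-0.6, 0.6])
        # trace of the Jacobian vanishes at the critical equilibrium
        from fdneuron.model import FixedPoint, jacobian

        J = jacobian(FixedPoint(h.x_star_crit, 2 * h.x_star_crit, "minus"), p)
        assert abs(np.trace(J)) < 1e-9

    def test_transversality(self):
        p = resolve_preset("B1_printed", I=-104.0)
        assert hopf_analysis(p).transversality

    def test_complex_equilibrium_is_returned_not_raised(self):
        p = resolve_preset("B1_printed", I=0.0)  # radicand negative
        h = hopf_analysis(p)
        assert h.x_star_at_I.imag != 0

    def test_real_branch_condition(self):
        # x* real iff -0.16 I - 13.4 >= 0, i.e. I <= -83.75
        p = resolve_preset("B1_printed")
        assert hopf_analysis(p, I=-83.75).x_star_at_I.imag == pytest.approx(0.0, abs=1e-6)
        assert hopf_analysis(p, I=-83.0).x_star_at_I.imag != 0


class TestPresets:
    def test_b1_is_effective_set(self):
        p = resolve_preset("B1")
        assert (p.sigma, p.eta, p.psi, p.nu) == (0.02, 0.2, -55.0, 4.0)

    def test_printed_set_kept(self):
        p = resolve_preset("B1_printed")
        assert (p.sigma, p.eta) == (0.2, 2.0)

    def test_network_mod_reset_below_cutoff(self):
        assert resolve_preset("network_mod").psi == -65.0

    def test_unknown_lists_registry(self):
        with pytest.raises(KeyError, match="B1"):
            resolve_preset("nope")

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            NeuronParams(-0.1, 0.2, -55, 4)
        with pytest.raises(ValueError):
            NeuronParams(0.02, 0.2, 31.0, 4)
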
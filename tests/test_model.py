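"""Unit tests of the single-neuron vector field and steady-state utilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burstlab.model import (
    GateSpec,
    NeuronParams,
    NeuronState,
    equilibrium_state,
    gate_steady_state,
    ionic_currents,
    rhs,
    steady_state_current,
)


class TestGateSteadyState:
    def test_midpoint_is_half(self):
        spec = GateSpec(k=83.0, theta=0.0075, power=2, tau=2.0, orientation=+1)
        assert gate_steady_state(-0.0075, spec) == pytest.approx(0.5, abs=1e-15)

    def test_saturation_limits(self):
        spec = GateSpec(k=150.0, theta=0.0305, power=3, tau=None, orientation=+1)
        assert gate_steady_state(1.0, spec) == pytest.approx(1.0, abs=1e-12)
        assert gate_steady_state(-1.0, spec) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_boltzmann(self):
        # k=83/V, offset 7.5 mV, depolarization-activated, V = -46 mV:
        # 1/(1+exp(83*0.0385)) evaluated by direct arithmetic
        spec = GateSpec(k=83.0, theta=0.0075, power=2, tau=2.0, orientation=+1)
        expected = 1.0 / (1.0 + math.exp(83.0 * 0.0385))
        assert gate_steady_state(-0.046, spec) == pytest.approx(expected, rel=1e-14)

    @given(
        v=st.floats(-0.2, 0.2),
        k=st.floats(10.0, 500.0),
        theta=st.floats(-0.05, 0.05),
        orientation=st.sampled_from([+1, -1]),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, v, k, theta, orientation):
        from hypothesis import assume

        # keep the exponent out of float saturation so strict bounds and
        # strict monotonicity are numerically meaningful
        assume(abs(k * (v + theta)) < 20.0)
        spec = GateSpec(k=k, theta=theta, power=1, tau=1.0, orientation=orientation)
        x = gate_steady_state(v, spec)
        assert 0.0 < x < 1.0
        dx = gate_steady_state(v + 1e-6, spec) - x
        assert math.copysign(1.0, dx) == orientation

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            GateSpec(k=-1.0, theta=0.0, power=1, tau=1.0, orientation=+1)
        with pytest.raises(ValueError):
            GateSpec(k=1.0, theta=0.0, power=4, tau=1.0, orientation=+1)
        with pytest.raises(ValueError):
            GateSpec(k=1.0, theta=0.0, power=1, tau=-2.0, orientation=+1)


class TestIonicCurrents:
    def test_currents_vanish_at_reversal(self):
        p = NeuronParams()
        s = NeuronState(p.e_k, 0.5, 0.3, 0.2)
        assert ionic_currents(s, p).i_k2 == 0.0
        s = NeuronState(p.e_na, 0.5, 0.3, 0.2)
        assert ionic_currents(s, p).i_na == 0.0
        s = NeuronState(p.e_h, 0.5, 0.3, 0.2)
        assert ionic_currents(s, p).i_h == 0.0
        s = NeuronState(p.e_leak, 0.5, 0.3, 0.2)
        assert ionic_currents(s, p).i_leak == 0.0

    def test_passive_cell_is_stationary(self):
        p = NeuronParams(g_na=0.0, g_k2=0.0, g_h=0.0, g_leak=0.0, i_pol=0.0)
        s = NeuronState(-0.03, 0.5, 0.3, 0.2)
        assert ionic_currents(s, p).total == 0.0

    def test_each_current_matches_formula(self):
        # independent single-line re-evaluation of each current
        rng = np.random.default_rng(7)
        p = NeuronParams()
        for _ in range(20):
            v = rng.uniform(-0.08, 0.03)
            h, m, mh = rng.uniform(0.0, 1.0, 3)
            s = NeuronState(v, h, m, mh)
            cb = ionic_currents(s, p, i_ext=0.1)
            m_na = 1.0 / (1.0 + math.exp(-150.0 * (v + 0.0305)))
            assert cb.i_na == pytest.approx(105.0 * m_na**3 * h * (v - 0.045), rel=1e-12)
            assert cb.i_k2 == pytest.approx(30.0 * m**2 * (v + 0.07), rel=1e-12)
            assert cb.i_h == pytest.approx(4.0 * mh**2 * (v + 0.021), rel=1e-12)
            assert cb.i_leak == pytest.approx(8.0 * (v + 0.046), rel=1e-12)
            total = (-cb.i_na - cb.i_k2 - cb.i_h - cb.i_leak + p.i_pol + 0.1) / p.c
            assert cb.total == pytest.approx(total, rel=1e-12)


class TestRhs:
    def test_gate_relaxation_is_linear(self):
        p = NeuronParams()
        v = -0.04
        eq = equilibrium_state(v, p)
        delta = 0.01
        s = NeuronState(v, eq.h_na + delta, eq.m_k2, eq.m_h)
        d = rhs(s, p)
        assert d[1] == pytest.approx(-delta / p.tau_hna, rel=1e-9)
        assert d[2] == pytest.approx(0.0, abs=1e-12)

    def test_nonfinite_state_rejected(self):
        p = NeuronParams()
        with pytest.raises(FloatingPointError):
            rhs(NeuronState(float("nan"), 0.5, 0.5, 0.5), p)

    def test_equilibrium_from_root_scan_annihilates_rhs(self):
        # brute-force root scan of the steady-state current, then the full
        # rhs must vanish with every gate at steady state
        p = NeuronParams(theta_k2=-0.010, theta_h=0.045)  # silent region
        vg = np.linspace(-0.06, -0.035, 20001)
        i = steady_state_current(vg, p)
        sign_change = np.nonzero(np.sign(i[:-1]) * np.sign(i[1:]) < 0)[0]
        assert sign_change.size >= 1
        from scipy.optimize import brentq

        v0 = brentq(lambda v: steady_state_current(v, p),
                    vg[sign_change[0]], vg[sign_change[0] + 1], xtol=1e-15)
        d = rhs(equilibrium_state(v0, p), p)
        assert np.linalg.norm(d) < 1e-10

    def test_rhs_finite_on_random_boxes(self):
        rng = np.random.default_rng(11)
        p = NeuronParams()
        for _ in range(50):
            s = NeuronState(rng.uniform(-0.1, 0.05), *rng.uniform(0, 1, 3))
            assert np.all(np.isfinite(rhs(s, p)))


class TestSteadyStateCurrent:
    def test_far_field_positive_and_increasing(self):
        p = NeuronParams()
        v = np.linspace(0.06, 0.2, 50)
        i = steady_state_current(v, p)
        assert np.all(i > 0)
        assert np.all(np.diff(i) > 0)

    def test_grid_scan_bracket_matches_bisection(self):
        p = NeuronParams(theta_k2=-0.010, theta_h=0.045)
        vg = np.arange(-0.06, -0.035, 1e-6)
        i = steady_state_current(vg, p)
        k = np.nonzero(np.sign(i[:-1]) * np.sign(i[1:]) < 0)[0][0]
        from scipy.optimize import brentq

        root = brentq(lambda v: steady_state_current(v, p), vg[k], vg[k + 1])
        assert vg[k] <= root <= vg[k + 1]


class TestNeuronParams:
    def test_reversal_ordering_enforced(self):
        with pytest.raises(ValueError):
            NeuronParams(e_k=0.0)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(g_na=-1.0)

    def test_pack_roundtrip_layout(self):
        from burstlab import _kernels

        p = NeuronParams()
        v = p.pack()
        assert v.shape == (25,)
        assert v[_kernels.G_NA] == p.g_na
        assert v[_kernels.TH_K2] == p.theta_k2
        assert v[_kernels.TMH0] == p.tau_mh.t_min
        assert v[_kernels.K_MH2] == p.k_mh2

    def test_kernel_matches_python_rhs(self):
        from burstlab import _kernels

        rng = np.random.default_rng(3)
        p = NeuronParams()
        for _ in range(10):
            s = NeuronState(rng.uniform(-0.08, 0.02), *rng.uniform(0, 1, 3))
            d_py = rhs(s, p, i_ext=0.05)
            d_nb = _kernels.cell_rhs(s.as_array(), p.pack(), 0.05, np.empty(4))
            np.testing.assert_allclose(d_nb, d_py, rtol=1e-12)
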
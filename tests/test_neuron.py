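"""Membrane, Nernst and pump unit tests, including the fixed-E HH oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gliovasc as gv
from gliovasc import neuron
from gliovasc.constants import rt_over_f
from gliovasc.state import NeuronState


@pytest.fixture(scope="module")
def p():
    return gv.ModelParams()


class TestNernst:
    def test_equal_concentrations_give_zero(self):
        assert neuron.nernst_potential(1, 10.0, 10.0) == pytest.approx(0.0)

    def test_physiological_potassium_value(self):
        # direct evaluation of the Nernst formula with CODATA constants
        e_k = neuron.nernst_potential(1, 9.5, 140.0, 310.15)
        assert e_k == pytest.approx(-71.9, abs=0.1)

    def test_valence_scales_and_flips(self):
        e1 = neuron.nernst_potential(1, 20.0, 10.0)
        e2 = neuron.nernst_potential(2, 20.0, 10.0)
        em = neuron.nernst_potential(-1, 20.0, 10.0)
        assert e1 == pytest.approx(2 * e2)
        assert em == pytest.approx(-e1)

    @pytest.mark.parametrize("c_out,c_in", [(0.0, 10.0), (10.0, -1.0)])
    def test_nonpositive_concentration_names_ion(self, c_out, c_in):
        with pytest.raises(ValueError, match="K\\+"):
            neuron.nernst_potential(1, c_out, c_in, ion="K+")

    def test_zero_valence_rejected(self):
        with pytest.raises(ValueError, match="valence"):
            neuron.nernst_potential(0, 10.0, 10.0)


class TestPump:
    def test_no_fuel_no_pumping(self, p):
        assert neuron.pump_currents(0.0, 10.0, 9.5, p) == (0.0, 0.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(atp=st.floats(0.01, 100.0), na=st.floats(0.1, 60.0),
           ko=st.floats(0.1, 40.0))
    def test_stoichiometry_exactly_three_to_two(self, atp, na, ko):
        p = gv.ModelParams()
        i_na, i_k = neuron.pump_currents(atp, na, ko, p)
        assert i_na >= 0.0 and i_k <= 0.0
        if i_na > 0:
            assert abs(i_na) / abs(i_k) == pytest.approx(1.5, rel=1e-12)

    def test_monotone_and_saturating_in_atp(self, p):
        vals = [neuron.pump_currents(a, 10.0, 9.5, p)[0]
                for a in (1.0, 5.0, 20.0, 100.0, 1e6)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        # closed-form ion-limited maximum as ATP -> infinity
        d = p.derived()
        n = p.neuron
        na2 = n.Na_i_rest ** 2
        f_na = (na2 / (na2 + n.K_Na_pump ** 2)) ** 3
        f_k = (n.K_o_rest / (n.K_o_rest + n.K_K_pump)) ** 2
        limit = 3.0 * d["pump_max"] * f_na * f_k
        assert vals[-1] == pytest.approx(limit, rel=1e-4)

    def test_rest_state_matches_prescribed_pump_current(self, p):
        n = p.neuron
        i_na, i_k = neuron.pump_currents(n.ATP_ref, n.Na_i_rest,
                                         n.K_o_rest, p)
        assert i_na + i_k == pytest.approx(n.pump_rest_current, rel=1e-9)

    def test_negative_input_rejected(self, p):
        with pytest.raises(ValueError, match="Na_i"):
            neuron.pump_currents(10.0, -1.0, 9.5, p)


def _classical_hh_euler(p, i_stim_ua, e_na, e_k, t_end, dt=1e-6):
    """Independent fixed-E Hodgkin-Huxley reference (explicit Euler).

    Re-implements the classical equations directly from their textbook
    parameterisation; shares nothing with the package's integrator.
    """
    n_par = p.neuron
    d = p.derived()
    v = n_par.V_rest

    def am(v): return 0.1 * (v + 40) / (1 - math.exp(-(v + 40) / 10))
    def bm(v): return 4 * math.exp(-(v + 65) / 18)
    def ah(v): return 0.07 * math.exp(-(v + 65) / 20)
    def bh(v): return 1 / (1 + math.exp(-(v + 35) / 10))
    def an(v): return 0.01 * (v + 55) / (1 - math.exp(-(v + 55) / 10))
    def bn(v): return 0.125 * math.exp(-(v + 65) / 80)

    m = am(v) / (am(v) + bm(v))
    h = ah(v) / (ah(v) + bh(v))
    n = an(v) / (an(v) + bn(v))
    cyc = n_par.pump_rest_current
    traj = []
    steps = int(round(t_end / dt))
    for k in range(steps):
        i_na = (n_par.g_Na * m**3 * h + d["g_Na_leak"]) * (v - e_na)
        i_k = (n_par.g_K * n**4 + d["g_K_leak"]) * (v - e_k)
        dv = 1000.0 * (i_stim_ua - i_na - i_k - cyc) / n_par.C_m
        dm = 1000.0 * (am(v) * (1 - m) - bm(v) * m)
        dh = 1000.0 * (ah(v) * (1 - h) - bh(v) * h)
        dn = 1000.0 * (an(v) * (1 - n) - bn(v) * n) / n_par.k_tau
        v += dt * dv
        m += dt * dm
        h += dt * dh
        n += dt * dn
        traj.append(v)
    return np.array(traj)


class TestMembrane:
    def test_matches_fixed_e_hh_oracle(self, p):
        """With concentrations clamped the membrane is a classical HH
        neuron: integrating the module's right-hand side must reproduce an
        independent explicit-Euler HH reference to solver tolerance."""
        n_par = p.neuron
        rtf = rt_over_f()
        e_na = rtf * math.log(n_par.Na_o_rest / n_par.Na_i_rest)
        e_k = rtf * math.log(n_par.K_o_rest / n_par.K_i_rest)
        oracle = _classical_hh_euler(p, 100.0, e_na, e_k, t_end=0.02)

        # integrate membrane_rhs with the same clamped concentrations
        dt = 1e-6
        state = NeuronState(V_m=n_par.V_rest, m=neuron.m_inf(n_par.V_rest),
                            h=neuron.h_inf(n_par.V_rest),
                            n=neuron.n_inf(n_par.V_rest),
                            Na_i=n_par.Na_i_rest, Na_o=n_par.Na_o_rest,
                            K_i=n_par.K_i_rest, K_o=n_par.K_o_rest,
                            Ca_n=0.1, ATP_n=n_par.ATP_ref)
        vs = []
        for _ in range(int(0.02 / dt)):
            dv, dm, dh, dn = neuron.membrane_rhs(state, 0.1, p)
            state.V_m += dt * dv
            state.m += dt * dm
            state.h += dt * dh
            state.n += dt * dn
            vs.append(state.V_m)
        vs = np.array(vs)
        # same spike amplitude and threshold behaviour, pointwise close
        assert np.max(np.abs(vs - oracle)) < 2.0  # mV
        assert np.sign(vs.max()) == np.sign(oracle.max())

    def test_nan_state_names_field(self, p):
        state = NeuronState(V_m=float("nan"), m=0.1, h=0.5, n=0.3,
                            Na_i=10, Na_o=145, K_i=190, K_o=9.5,
                            Ca_n=0.1, ATP_n=20)
        with pytest.raises(FloatingPointError, match="V_m"):
            neuron.membrane_rhs(state, 0.0, p)


class TestIonBalance:
    def test_all_zero_currents_give_zero_derivatives(self, p):
        state = None  # unused by the operation
        d = neuron.ion_balance_rhs(state, (0.0, 0.0), (0.0, 0.0), 0.0, p)
        assert d == (0.0, 0.0, 0.0, 0.0)

    def test_conservation_under_pump_channel_buffer(self, p):
        """Total Na and K amounts over neuron + interstitium (+ buffer) are
        conserved when pump, channel and buffer are the only terms."""
        n = p.neuron
        g_n, g_o = n.gamma_n, n.gamma_o
        rng = np.random.default_rng(7)
        for _ in range(20):
            i_na, i_k = rng.normal(0, 50, 2)
            cyc = rng.uniform(0, 60)
            j_buf = rng.normal(0, 1)
            dna_i, dna_o, dk_i, dk_o = neuron.ion_balance_rhs(
                None, (i_na, i_k), (3 * cyc, -2 * cyc), j_buf, p)
            assert dna_i / g_n + dna_o / g_o == pytest.approx(0.0, abs=1e-9)
            # buffered K is stored, not destroyed
            assert dk_i / g_n + (dk_o + j_buf) / g_o == \
                pytest.approx(0.0, abs=1e-9)

    def test_outward_sodium_current_depletes_cell(self, p):
        dna_i, dna_o, _, _ = neuron.ion_balance_rhs(
            None, (10.0, 0.0), (0.0, 0.0), 0.0, p)
        assert dna_i < 0 < dna_o


def test_e_na_monotone_in_gradient_rundown():
    """E_Na decreases along any path where Na_i rises and Na_o falls."""
    na_i = np.linspace(10, 20, 20)
    na_o = np.linspace(145, 130, 20)
    e = [neuron.nernst_potential(1, o, i) for o, i in zip(na_o, na_i)]
    assert all(b < a for a, b in zip(e, e[1:]))
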
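"""IP3/store-calcium/EET transduction and K+ buffering tests."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import gliovasc as gv
from gliovasc import astrocyte


@pytest.fixture(scope="module")
def p():
    return gv.ModelParams()


class TestIP3:
    def test_zero_glu_zero_ip3_is_fixed(self, p):
        assert astrocyte.ip3_rhs(0.0, 0.0, p) == 0.0

    def test_pure_degradation_without_glutamate(self, p):
        assert astrocyte.ip3_rhs(0.0, 0.5, p) < 0.0

    def test_production_saturates_in_glutamate(self, p):
        d1 = astrocyte.ip3_rhs(0.5, 0.0, p)
        d2 = astrocyte.ip3_rhs(5.0, 0.0, p)
        d3 = astrocyte.ip3_rhs(50.0, 0.0, p)
        assert 0 < d1 < d2 < d3
        assert d3 - d2 < d2 - d1  # saturating

    def test_sustained_glutamate_gives_ip3_transient_before_calcium(self, p):
        """Sustained glutamate raises IP3, which then gates store release:
        the IP3 rise leads the cytosolic Ca2+ rise.  A brief pulse stays
        below the store's critical stimulation duration, so the drive here
        lasts several seconds (IP3 integrates activity over ~8 s)."""
        ca0, h0 = astrocyte.ca_rest_fixed_point(p)

        def rhs(t, y):
            ip3, ca, h = y
            glu = 1.0 if t < 8.0 else 0.0
            dip3 = astrocyte.ip3_rhs(glu, ip3, p)
            dca, dh = astrocyte.store_calcium_rhs(ip3, ca, h, p)
            return [dip3, dca, dh]

        sol = solve_ivp(rhs, (0, 20), [0.0, ca0, h0], max_step=0.01,
                        dense_output=True)
        ip3 = sol.y[0]
        ca = sol.y[1]
        t_ip3 = sol.t[np.argmax(ip3 > 0.15)]
        assert ca.max() > 2 * ca0            # store release happened
        t_ca = sol.t[np.argmax(ca > 2 * ca0)]
        assert t_ip3 < t_ca                  # IP3 transient leads


class TestStoreCalcium:
    def test_rest_fixed_point_is_stationary(self, p):
        ca0, h0 = astrocyte.ca_rest_fixed_point(p)
        dca, _ = astrocyte.store_calcium_rhs(0.0, ca0, h0, p)
        assert dca == pytest.approx(0.0, abs=1e-9)

    def test_low_ip3_relaxes_to_rest(self, p):
        ca0, h0 = astrocyte.ca_rest_fixed_point(p)

        def rhs(t, y):
            return astrocyte.store_calcium_rhs(0.0, y[0], y[1], p)

        sol = solve_ivp(rhs, (0, 60), [ca0 * 3, h0], max_step=0.05)
        assert sol.y[0, -1] == pytest.approx(ca0, rel=0.05)

    def test_sustained_ip3_produces_oscillations(self, p):
        """Bifurcation smoke test: constant mid-range IP3 drives a store
        limit cycle whose period and amplitude match an independent
        explicit-Euler integration of the same equations."""
        ca0, h0 = astrocyte.ca_rest_fixed_point(p)
        ip3 = 0.45

        def rhs(t, y):
            return astrocyte.store_calcium_rhs(ip3, y[0], y[1], p)

        sol = solve_ivp(rhs, (0, 120), [ca0, h0], max_step=0.02,
                        t_eval=np.arange(60, 120, 0.01))
        ca = sol.y[0]
        assert ca.max() - ca.min() > 0.1  # oscillating, not fixed

        # explicit-Euler oracle
        dt = 2e-4
        y = [ca0, h0]
        trace = []
        for k in range(int(120 / dt)):
            dca, dh = astrocyte.store_calcium_rhs(ip3, y[0], y[1], p)
            y = [y[0] + dt * dca, y[1] + dt * dh]
            if k * dt >= 60 and k % 50 == 0:
                trace.append(y[0])
        trace = np.array(trace)
        assert trace.max() == pytest.approx(ca.max(), rel=0.05)
        assert trace.min() == pytest.approx(ca.min(), rel=0.2)


class TestEET:
    def test_hard_threshold_exactly_zero_at_and_below(self, p):
        th = p.astrocyte.Ca_threshold
        assert astrocyte.eet_rhs(th, 0.0, p) == 0.0
        assert astrocyte.eet_rhs(th - 1e-9, 0.0, p) == 0.0
        assert astrocyte.eet_rhs(th + 1e-6, 0.0, p) > 0.0

    def test_pure_degradation_below_threshold(self, p):
        assert astrocyte.eet_rhs(0.05, 3.0, p) < 0.0

    def test_step_reaches_closed_form_balance_point(self, p):
        """For a Ca step above threshold, EET approaches the fixed point
        where production equals Michaelis-Menten removal, solvable in
        closed form."""
        a = p.astrocyte
        ca = a.Ca_threshold + 0.3
        prod = a.k_EET * 0.3
        assert prod < a.Vmax_EET
        expected = a.Km_EET * prod / (a.Vmax_EET - prod)
        eet = 0.0
        dt = 1e-3
        for _ in range(int(60 / dt)):
            eet += dt * astrocyte.eet_rhs(ca, eet, p)
        assert eet == pytest.approx(expected, rel=1e-3)


class TestBuffer:
    def test_rest_equilibrium_flux_is_zero(self, p):
        a = p.astrocyte
        flux = astrocyte.k_buffer_flux(p.neuron.K_o_rest, a.K_buf_rest, p)
        assert flux == pytest.approx(0.0, abs=1e-12)

    def test_elevated_ko_drives_net_uptake(self, p):
        a = p.astrocyte
        assert astrocyte.k_buffer_flux(15.0, a.K_buf_rest, p) > 0.0

    def test_equilibrium_recovered_by_root_finding(self, p):
        """The flux-zero locus across occupancies matches the analytic
        inversion used by buffer_equilibrium_ko."""
        from scipy.optimize import brentq

        for k_buf in (20.0, 30.0, 60.0):
            k_eq = astrocyte.buffer_equilibrium_ko(k_buf, p)
            root = brentq(
                lambda ko: astrocyte.k_buffer_flux(ko, k_buf, p), 1.0, 30.0)
            assert root == pytest.approx(k_eq, rel=1e-6)

    def test_uptake_fades_with_astrocytic_atp(self, p):
        j_fed = astrocyte.k_buffer_flux(15.0, 30.0, p, atp_a=20.0)
        j_starved = astrocyte.k_buffer_flux(15.0, 30.0, p, atp_a=0.5)
        assert j_starved < 0.2 * j_fed


class TestUptake:
    def test_zero_glutamate_zero_fluxes(self, p):
        assert astrocyte.glutamate_uptake_flux(0.0, 15.0, p) == (0.0, 0.0)

    def test_fixed_na_stoichiometry_across_random_inputs(self, p, rng):
        for _ in range(25):
            glu = rng.uniform(0.001, 5.0)
            up, na = astrocyte.glutamate_uptake_flux(glu, 15.0, p)
            assert na / up == pytest.approx(p.astrocyte.na_per_glu)

    def test_saturable(self, p):
        up1, _ = astrocyte.glutamate_uptake_flux(1.0, 15.0, p)
        up2, _ = astrocyte.glutamate_uptake_flux(100.0, 15.0, p)
        assert up1 < up2 <= p.astrocyte.v_glu_up
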
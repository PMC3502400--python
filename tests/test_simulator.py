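"""Assembly, integration, determinism and scenario-library tests."""

import numpy as np
import pytest

import gliovasc as gv
from gliovasc.errors import ConfigError, IntegrationError
from gliovasc.state import IATPN, IKO, INAI, IKI, IKBUF, NSTATE
from gliovasc.analysis import detect_spikes


@pytest.fixture(scope="module")
def p():
    return gv.ModelParams()


class TestAssembly:
    def test_rest_is_an_approximate_fixed_point(self, p):
        """The constructed resting state nulls the ionic equations
        exactly; the metabolic pools drift only slowly (the ATP pool has
        no rest equilibrium by design)."""
        y0 = gv.resting_state(p)
        cfg = gv.ScenarioConfig(stim_type="constant", amplitude=0.0,
                                duration=1.0)
        dy = gv.assemble_rhs(y0, 0.5, cfg, p)
        ionic = [0, 1, 2, 3, 4, 5, 6, 7, 8]  # V, gates, ions, buffer
        assert np.max(np.abs(dy[ionic])) < 1e-6
        assert np.max(np.abs(dy)) < 1.0       # everything else slow

    def test_repeated_evaluation_is_identical(self, p):
        y0 = gv.resting_state(p, atp0=20.0)
        cfg = gv.ScenarioConfig(stim_type="constant", amplitude=0.1,
                                duration=1.0)
        d1 = gv.assemble_rhs(y0, 0.3, cfg, p)
        d2 = gv.assemble_rhs(y0, 0.3, cfg, p)
        assert np.array_equal(d1, d2)

    def test_nonfinite_state_names_component(self, p):
        y0 = gv.resting_state(p)
        y0[IKO] = np.inf
        cfg = gv.ScenarioConfig(duration=1.0)
        with pytest.raises(IntegrationError, match="K_o"):
            gv.assemble_rhs(y0, 0.0, cfg, p)

    def test_wrong_shape_rejected(self, p):
        with pytest.raises(ConfigError):
            gv.assemble_rhs(np.zeros(5), 0.0, gv.ScenarioConfig(), p)


class TestConfig:
    def test_negative_duration_rejected(self):
        with pytest.raises(ConfigError, match="duration"):
            gv.ScenarioConfig(duration=-1.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ConfigError, match="amplitude"):
            gv.ScenarioConfig(amplitude=-0.1)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError, match="mode"):
            gv.ScenarioConfig(mode="open_loop")

    def test_forced_mode_gets_default_protocol(self):
        cfg = gv.ScenarioConfig(mode="forced_vessel")
        assert cfg.vasomotion is not None
        assert cfg.vasomotion.frequency == pytest.approx(0.2)


class TestScenarioLibrary:
    def test_five_published_scenarios(self, library):
        assert set(library) == {"continuous", "pulse", "subthreshold",
                                "bursting", "vasomotion"}

    def test_printed_parameters(self, library):
        assert library["continuous"].amplitude == 0.1
        assert library["continuous"].atp0 == 20.0
        assert library["subthreshold"].amplitude == 0.05
        assert library["bursting"].atp0 == 5.0
        assert library["bursting"].stim_type == "pulse"
        assert library["bursting"].pulse_duration == 1.0
        vm = library["vasomotion"].vasomotion
        assert vm.frequency == 0.2
        assert vm.dilated_radius == 30.0
        assert vm.dilation_duration == 0.5


class TestIntegration:
    def test_bit_reproducible_for_fixed_seed(self, p):
        cfg = gv.ScenarioConfig(stim_type="constant", amplitude=0.1,
                                duration=2.0, seed=11)
        s1 = gv.run_simulation(cfg, p)
        cfg2 = gv.ScenarioConfig(stim_type="constant", amplitude=0.1,
                                 duration=2.0, seed=11)
        s2 = gv.run_simulation(cfg2, p)
        assert np.array_equal(s1.y, s2.y)

    def test_timeseries_shape_and_monotone_grid(self, p):
        cfg = gv.ScenarioConfig(stim_type="constant", amplitude=0.0,
                                duration=1.0)
        s = gv.run_simulation(cfg, p)
        assert s.y.shape == (len(s.t), NSTATE)
        assert np.all(np.diff(s.t) > 0)
        assert np.all(np.isfinite(s.y))

    def test_solver_tolerance_convergence(self, p):
        """Halving the solver tolerances moves spike times by less than
        the sampling interval (self-check standing in for method
        equivalence)."""
        kw = dict(stim_type="constant", amplitude=0.1, duration=1.5,
                  seed=0, recycling=False)
        s1 = gv.run_simulation(gv.ScenarioConfig(**kw), p)
        s2 = gv.run_simulation(
            gv.ScenarioConfig(rtol=5e-7, atol=5e-9, **kw), p)
        t1 = detect_spikes(s1.t, s1.column("V_m")).times
        t2 = detect_spikes(s2.t, s2.column("V_m")).times
        n = min(len(t1), len(t2))
        assert n > 50
        assert np.max(np.abs(t1[:n] - t2[:n])) < 2 * s1.config.dt_sample

    def test_ion_conservation_during_stimulus_off_window(self, p):
        """With stimulation off, total K+ over neuron + interstitium +
        buffer and total Na+ over neuron + interstitium (+ astrocytic
        exchange) are conserved to quadrature tolerance."""
        n = p.neuron
        cfg = gv.ScenarioConfig(stim_type="constant", amplitude=0.0,
                                duration=2.0, recycling=False)
        s = gv.run_simulation(cfg, p)
        k_total = (s.y[:, IKI] / n.gamma_n
                   + (s.y[:, IKO] + s.y[:, IKBUF]) / n.gamma_o)
        drift = np.abs(k_total - k_total[0]) / k_total[0]
        assert drift.max() < 1e-6

    def test_atp_never_negative(self, continuous_run, bursting_run):
        for s in (continuous_run, bursting_run):
            assert s.y[:, IATPN].min() >= 0.0

    def test_closed_loop_radius_stays_in_physical_range(self, continuous_run):
        r = continuous_run.radius
        assert r.min() >= 8.0 - 1e-9 and r.max() <= 30.0 + 1e-9
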